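"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own code paths: the RIN
oracle is an exhaustive all-atom-pairs scan with plain Python loops, and the
alignment oracle is a quadratic-space Gotoh dynamic program.
"""

from __future__ import annotations

import numpy as np
import pytest

from rinmap import build_rin, fixtures
from rinmap.comparison import blosum62
from rinmap.structure_io import BACKBONE_ATOMS, Structure


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_rin_pairs(
    s: Structure,
    contact_cutoff: float = 5.0,
    hbond_cutoff: float = 3.5,
    exclude_neighbors: int = 1,
):
    """Exhaustive O(n_atoms^2) scan; returns (contact_pairs, hbond_pairs) as
    sets of unordered node_id pairs, plus per-pair qualifying atom counts."""
    rank = {}
    for chain in s.chains:
        for i, res in enumerate(s.chain_residues(chain)):
            rank[res.node_id] = i
    contacts, hbonds = {}, {}
    res_list = s.residues
    for i in range(len(res_list)):
        for j in range(i + 1, len(res_list)):
            ri, rj = res_list[i], res_list[j]
            if (
                ri.chain == rj.chain
                and abs(rank[ri.node_id] - rank[rj.node_id]) <= exclude_neighbors
            ):
                continue
            nc = nh = 0
            for a in ri.atoms:
                if not a.is_heavy:
                    continue
                for b in rj.atoms:
                    if not b.is_heavy:
                        continue
                    d = float(np.linalg.norm(a.coords - b.coords))
                    if d <= contact_cutoff:
                        nc += 1
                        if (
                            d <= hbond_cutoff
                            and a.element.upper() in ("N", "O")
                            and b.element.upper() in ("N", "O")
                        ):
                            nh += 1
            key = tuple(sorted((ri.node_id, rj.node_id)))
            if nc:
                contacts[key] = nc
            if nh:
                hbonds[key] = nh
    return contacts, hbonds


def gotoh_score(a: str, b: str, open_: float = -10.0, ext: float = -1.0) -> float:
    """Affine-gap global alignment optimum (first gap position costs open_,
    each further one ext); quadratic-space reference DP."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Iy[0, j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum62(a[i - 1], b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] + open_, Ix[i - 1, j] + ext, Iy[i - 1, j] + open_)
            Iy[i, j] = max(M[i, j - 1] + open_, Iy[i, j - 1] + ext, Ix[i, j - 1] + open_)
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))


# ---------------------------------------------------------------------------
# Shared fixtures


@pytest.fixture(scope="session")
def helix12():
    return fixtures.make_helix(12)


@pytest.fixture(scope="session")
def helix_rin(helix12):
    return build_rin(helix12)


@pytest.fixture(scope="session")
def dimer():
    return fixtures.make_dimer(5, [(2, 2), (3, 4)])


@pytest.fixture()
def tmp_pdb(tmp_path, helix12):
    from rinmap import write_pdb

    p = tmp_path / "helix.pdb"
    write_pdb(helix12, p)
    return p
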