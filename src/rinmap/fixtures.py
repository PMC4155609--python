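"""Deterministic toy structures, alignments and annotation tables.

Every generator here produces data with *known* ground truth — designed
cross-chain contacts, planted mutations, ideal secondary-structure geometry —
so that the network builder, the comparison machinery and the layout can be
validated end to end without downloading real structures.

Helix and strand backbones are grown by internal-coordinate chaining (the
NeRF construction: each atom is placed from the previous three given a bond
length, bond angle and torsion) at ideal torsions — helix phi/psi =
(-57°, -47°), strand (-120°, +120°) — which reproduces the textbook alpha
helix: CA atoms on a helix of radius ~2.3 Å, rise 1.5 Å and ~100° turn per
residue, consecutive CA atoms 3.8 Å apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .comparison import GAP, PairwiseAlignment
from .structure_io import AA1_TO_AA3, Atom, Residue, SSSegment, Structure

__all__ = [
    "make_helix",
    "make_strand",
    "make_dimer",
    "make_random_coil",
    "MutationSpec",
    "make_mutant_pair",
]

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_N_CA_CB = 120.8, 110.5
_OMEGA = 180.0

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -120.0, 120.0


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Place atom D bonded to C given bond length r, angle B-C-D, torsion A-B-C-D."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -r * math.cos(theta),
            r * math.sin(theta) * math.cos(phi),
            r * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _grow_backbone(n: int, phi: float, psi: float, with_cb: bool) -> list[dict[str, np.ndarray]]:
    """Backbone coordinates for n residues at fixed (phi, psi) torsions."""
    res: list[dict[str, np.ndarray]] = []
    # seed the first three atoms in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n):
        prev = res[-1]
        n_next = _nerf(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca_next = _nerf(prev["CA"], prev["C"], n_next, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_next = _nerf(prev["C"], n_next, ca_next, _B_CA_C, _A_N_CA_C, phi)
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    # carbonyl oxygens: torsion N-CA-C-O = psi + 180 (trans to the next N)
    for i, r in enumerate(res):
        r["O"] = _nerf(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        if with_cb:
            r["CB"] = _nerf(r["C"], r["N"], r["CA"], _B_CA_CB, _A_N_CA_CB, -120.0)
    return res


def _residues_from_backbone(
    backbone: list[dict[str, np.ndarray]], chain: str, sequence: str, start_num: int = 1
) -> list[Residue]:
    out = []
    for i, atoms in enumerate(backbone):
        aa1 = sequence[i]
        aa3 = AA1_TO_AA3.get(aa1.upper(), "UNK")
        atom_order = [k for k in ("N", "CA", "C", "O", "CB") if k in atoms]
        out.append(
            Residue(
                chain=chain,
                seq_num=start_num + i,
                ins_code="",
                aa3=aa3,
                atoms=[
                    Atom(name=k, element=k[0], coords=np.round(atoms[k], 3))
                    for k in atom_order
                ],
            )
        )
    return out


def _default_sequence(n: int, sequence: str | None) -> str:
    if sequence is None:
        # varied but deterministic: cycle through a handful of residue types
        return ("AVLSGKDEFT" * (n // 10 + 1))[:n]
    if len(sequence) != n:
        raise ValueError(f"sequence length {len(sequence)} != n_residues {n}")
    return sequence.upper()


def make_helix(n: int, chain: str = "A", sequence: str | None = None,
               with_cb: bool = False) -> Structure:
    """Ideal alpha-helix of n residues (full backbone, one HELIX record)."""
    if n < 4:
        raise ValueError("a helix fixture needs at least 4 residues")
    seq = _default_sequence(n, sequence)
    residues = _residues_from_backbone(_grow_backbone(n, HELIX_PHI, HELIX_PSI, with_cb), chain, seq)
    return Structure(
        id=f"helix{n}",
        chains=[chain],
        residues=residues,
        ss_segments=[SSSegment("H1", "helix", chain, 1, n)],
        header_helices=[(chain, 1, n)],
    )


def make_strand(n: int, chain: str = "A", sequence: str | None = None,
                with_cb: bool = False) -> Structure:
    """Ideal extended beta-strand of n residues (one SHEET record)."""
    if n < 2:
        raise ValueError("a strand fixture needs at least 2 residues")
    seq = _default_sequence(n, sequence)
    residues = _residues_from_backbone(
        _grow_backbone(n, STRAND_PHI, STRAND_PSI, with_cb), chain, seq
    )
    return Structure(
        id=f"strand{n}",
        chains=[chain],
        residues=residues,
        ss_segments=[SSSegment("E1", "strand", chain, 1, n)],
        header_strands=[(chain, 1, n)],
    )


def make_two_strands(n: int = 6, separation: float = 4.8) -> Structure:
    """Two parallel strands in one chain, separated along y by ``separation`` Å.

    With the default separation the facing residues are in contact range,
    giving a known set of cross-strand interactions for aggregation tests.
    """
    back1 = _grow_backbone(n, STRAND_PHI, STRAND_PSI, False)
    back2 = [{k: v + np.array([0.0, separation, 0.0]) for k, v in r.items()} for r in back1]
    seq = _default_sequence(n, None)
    residues = _residues_from_backbone(back1, "A", seq, start_num=1)
    residues += _residues_from_backbone(back2, "A", seq, start_num=n + 11)  # sequence gap
    return Structure(
        id="two_strands",
        chains=["A"],
        residues=residues,
        ss_segments=[
            SSSegment("E1", "strand", "A", 1, n),
            SSSegment("E2", "strand", "A", n + 11, 2 * n + 10),
        ],
        header_strands=[("A", 1, n), ("A", n + 11, 2 * n + 10)],
    )


# ---------------------------------------------------------------------------
# Dimer with designed interface contacts

# rigid per-residue atom offsets for dimer fixtures (compact, non-physical)
_DIMER_OFFSETS = {
    "N": np.array([-1.46, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.52, 0.0, 0.0]),
    "O": np.array([2.20, 1.0, 0.0]),
}
_SPACING = 9.0      # intra-chain CA spacing, Å
_FAR_Y = 30.0       # default separation of chain B
_CONTACT_Y = 5.7    # facing O atoms end up 3.7 Å apart: contact range, not hbond range


def make_dimer(
    n_per_chain: int,
    contact_pairs: list[tuple[int, int]] | None = None,
    chains: tuple[str, str] = ("A", "B"),
) -> Structure:
    """Two-chain fixture where exactly ``contact_pairs`` touch across chains.

    ``contact_pairs`` lists 1-based (residue_in_A, residue_in_B) pairs; those
    pairs end up with heavy atoms 3.5 Å apart (well inside contact range)
    while every other cross-chain residue pair stays > 6 Å away.  Requests
    that would force two chain-B residues onto the same spot are refused.
    """
    contact_pairs = list(contact_pairs or [])
    ca, cb = chains
    for i, j in contact_pairs:
        if not (1 <= i <= n_per_chain and 1 <= j <= n_per_chain):
            raise ValueError(f"contact pair ({i},{j}) out of range 1..{n_per_chain}")
    b_target: dict[int, int] = {}
    for i, j in contact_pairs:
        if j in b_target:
            raise ValueError(f"unrealizable: residue {cb}:{j} in two contact pairs")
        b_target[j] = i
    if len({i for i, _ in contact_pairs}) != len(contact_pairs):
        raise ValueError("unrealizable: one chain-A residue in two contact pairs")

    seq = _default_sequence(n_per_chain, None)
    residues: list[Residue] = []
    for idx in range(1, n_per_chain + 1):
        center = np.array([_SPACING * (idx - 1), 0.0, 0.0])
        residues.append(_dimer_residue(ca, idx, seq[idx - 1], center, flip=False))
    for idx in range(1, n_per_chain + 1):
        if idx in b_target:
            center = np.array([_SPACING * (b_target[idx] - 1), _CONTACT_Y, 0.0])
        else:
            center = np.array([_SPACING * (idx - 1), _FAR_Y, 0.0])
        residues.append(_dimer_residue(cb, idx, seq[idx - 1], center, flip=True))

    s = Structure(id=f"dimer{n_per_chain}", chains=[ca, cb], residues=residues)
    _check_dimer(s, contact_pairs, chains)
    return s


def _dimer_residue(chain: str, seq_num: int, aa1: str, center: np.ndarray,
                   flip: bool) -> Residue:
    atoms = []
    for name, off in _DIMER_OFFSETS.items():
        off = off * np.array([1.0, -1.0, 1.0]) if flip else off
        atoms.append(Atom(name=name, element=name[0], coords=np.round(center + off, 3)))
    return Residue(chain=chain, seq_num=seq_num, ins_code="",
                   aa3=AA1_TO_AA3.get(aa1, "UNK"), atoms=atoms)


def _check_dimer(s: Structure, contact_pairs, chains) -> None:
    """Brute-force verification of the construction guarantees."""
    ca, cb = chains
    res_a = s.chain_residues(ca)
    res_b = s.chain_residues(cb)
    wanted = {(i, j) for i, j in contact_pairs}
    for ia, ra in enumerate(res_a, start=1):
        for ib, rb in enumerate(res_b, start=1):
            dmin = min(
                float(np.linalg.norm(x.coords - y.coords))
                for x in ra.atoms
                for y in rb.atoms
            )
            if dmin < 2.5:
                raise ValueError(f"unrealizable: clash ({dmin:.2f} Å) at ({ia},{ib})")
            if (ia, ib) in wanted and dmin > 4.0:
                raise ValueError(f"unrealizable: contact ({ia},{ib}) ended up {dmin:.2f} Å")
            if (ia, ib) not in wanted and dmin <= 6.0:
                raise ValueError(
                    f"unrealizable: unwanted proximity {dmin:.2f} Å at ({ia},{ib})"
                )


def make_random_coil(n: int, chain: str = "A", seed: int = 0) -> Structure:
    """Self-avoiding CA-trace random walk (step 3.8 Å); seeded, deterministic."""
    if n < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    coords = [np.zeros(3)]
    while len(coords) < n:
        for _ in range(1000):
            step = rng.normal(size=3)
            step *= 3.8 / np.linalg.norm(step)
            cand = coords[-1] + step
            if all(np.linalg.norm(cand - c) >= 3.0 for c in coords[:-1]):
                coords.append(cand)
                break
        else:  # pragma: no cover - practically unreachable at these sizes
            raise RuntimeError("self-avoiding walk failed to extend")
    seq = _default_sequence(n, None)
    residues = [
        Residue(
            chain=chain,
            seq_num=i + 1,
            ins_code="",
            aa3=AA1_TO_AA3[seq[i]],
            atoms=[Atom(name="CA", element="C", coords=np.round(c, 3))],
        )
        for i, c in enumerate(coords)
    ]
    return Structure(id=f"coil{n}_s{seed}", chains=[chain], residues=residues)


# ---------------------------------------------------------------------------
# Parent/mutant sequence pairs with ground-truth alignment


@dataclass
class MutationSpec:
    """Planted differences relative to a parent sequence (1-based positions)."""

    substitutions: list[tuple[int, str]] = field(default_factory=list)  # (pos, new_aa)
    deletions: list[int] = field(default_factory=list)                  # parent pos removed
    insertions: list[tuple[int, str]] = field(default_factory=list)     # (after_pos, aa)

    @classmethod
    def random(cls, sequence: str, n_sub: int, n_del: int, n_ins: int,
               seed: int) -> "MutationSpec":
        """Random spec with non-overlapping edit positions; deterministic per seed."""
        rng = np.random.default_rng(seed)
        n = len(sequence)
        positions = rng.permutation(np.arange(1, n + 1))
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        subs, dels = [], []
        k = 0
        for _ in range(n_sub):
            pos = int(positions[k]); k += 1
            old = sequence[pos - 1]
            new = alphabet[int(rng.integers(len(alphabet)))]
            while new == old:
                new = alphabet[int(rng.integers(len(alphabet)))]
            subs.append((pos, new))
        for _ in range(n_del):
            dels.append(int(positions[k])); k += 1
        ins = [
            (int(positions[k + m]), alphabet[int(rng.integers(len(alphabet)))])
            for m in range(n_ins)
        ]
        return cls(substitutions=sorted(subs), deletions=sorted(dels),
                   insertions=sorted(ins))


def make_mutant_pair(
    structure: Structure,
    spec: MutationSpec,
    chain: str | None = None,
) -> tuple[str, str, PairwiseAlignment]:
    """Parent sequence, mutant sequence, and their ground-truth alignment.

    The alignment row for the parent keeps every parent position (with gap
    columns at insertion points); the mutant row applies substitutions, puts
    gaps at deleted positions, and carries the inserted letters.  The parent
    column map is bound to the structure's node_ids.
    """
    chain = chain or structure.chains[0]
    residues = structure.chain_residues(chain)
    seq_a = "".join(r.aa1 for r in residues)
    n = len(seq_a)
    subs = dict(spec.substitutions)
    for pos in list(subs) + spec.deletions + [p for p, _ in spec.insertions]:
        if not 1 <= pos <= n:
            raise ValueError(f"position {pos} out of range 1..{n}")
    for pos, new in spec.substitutions:
        if seq_a[pos - 1] == new:
            raise ValueError(f"substitution at {pos} does not change the residue")
    dels = set(spec.deletions)
    if dels & set(subs):
        raise ValueError("a position cannot be both substituted and deleted")
    ins_after: dict[int, str] = {}
    for pos, aa in spec.insertions:
        if pos in ins_after:
            raise ValueError(f"two insertions after position {pos}")
        ins_after[pos] = aa

    row_a, row_b = [], []
    node_ids_a = [r.node_id for r in residues]
    for pos in range(1, n + 1):
        aa = seq_a[pos - 1]
        if pos in dels:
            row_a.append(aa)
            row_b.append(GAP)
        elif pos in subs:
            row_a.append(aa)
            row_b.append(subs[pos])
        else:
            row_a.append(aa)
            row_b.append(aa)
        if pos in ins_after:
            row_a.append(GAP)
            row_b.append(ins_after[pos])

    aln = PairwiseAlignment(
        id_a=f"{structure.id}_{chain}", id_b=f"{structure.id}_{chain}_mut",
        rows=("".join(row_a), "".join(row_b)),
    )
    seq_b = "".join(c for c in aln.rows[1] if c != GAP)
    aln.attach_node_ids(node_ids_a, [str(k) for k in range(1, len(seq_b) + 1)])
    return seq_a, seq_b, aln


def mutant_structure(structure: Structure, spec: MutationSpec,
                     chain: str | None = None) -> Structure:
    """Apply a MutationSpec to the structure itself (substitutions rename the
    residue; deletions remove it; insertions are skipped — no geometry exists
    for them).  Useful for generating a mutant RIN with perturbed contacts."""
    chain = chain or structure.chains[0]
    out_res = []
    subs = dict(spec.substitutions)
    dels = set(spec.deletions)
    pos = 0
    for r in structure.residues:
        if r.chain != chain:
            out_res.append(r)
            continue
        pos += 1
        if pos in dels:
            continue
        aa3 = AA1_TO_AA3.get(subs.get(pos, r.aa1), "UNK") if pos in subs else r.aa3
        out_res.append(Residue(chain=r.chain, seq_num=r.seq_num, ins_code=r.ins_code,
                               aa3=aa3, atoms=list(r.atoms)))
    return Structure(
        id=structure.id + "_mut",
        chains=list(structure.chains),
        residues=out_res,
        ss_segments=list(structure.ss_segments),
        header_helices=list(structure.header_helices),
        header_strands=list(structure.header_strands),
    )
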