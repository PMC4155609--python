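"""Residue interaction network construction and SIF/TSV/GraphML interchange.

A RIN is a multigraph whose nodes are polymer residues (named by the
``chain:seq:ins:aa3`` convention) and whose edges are non-covalent
interactions detected by explicit geometric criteria:

* **contact** — some heavy-atom pair of the two residues lies within
  ``contact_cutoff`` (default 5.0 Å);
* **hbond** — some donor/acceptor heavy-atom pair (N or O on both sides)
  lies within ``hbond_cutoff`` (default 3.5 Å); no angle term is applied
  because hydrogens are not required.

Sequence-adjacent residues of the same chain (up to ``exclude_neighbors``
positions apart, default 1) are skipped: peptide-bond neighbours are trivially
in contact.  Each edge records a ``subtype`` describing mainchain/sidechain
involvement and ``natom_pairs``, the number of qualifying atom pairs, which
serves as an edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure

__all__ = ["RIN", "build_rin", "extract_interface", "write_rin", "read_rin"]

# SIF labels for the two interaction types
_ITYPE_TO_SIF = {"contact": "cnt", "hbond": "hbond"}
_SIF_TO_ITYPE = {v: k for k, v in _ITYPE_TO_SIF.items()}
_SUBTYPES = ("mc_mc", "mc_sc", "sc_sc")

#: Fixed leading columns of the node-attribute TSV.
_CORE_ATTR_COLUMNS = ("chain", "seq_num", "aa1", "ss_segment")


@dataclass
class RIN:
    """Residue interaction network: an attributed multigraph keyed by itype."""

    name: str = "rin"
    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)

    # -- nodes ------------------------------------------------------------
    def add_node(self, node_id: str, **attrs) -> None:
        self.graph.add_node(node_id, **attrs)

    @property
    def nodes(self):
        return self.graph.nodes

    def node_attrs(self, node_id: str) -> dict:
        return self.graph.nodes[node_id]

    # -- edges ------------------------------------------------------------
    def add_edge(self, u: str, v: str, itype: str, subtype: str, natom_pairs: int) -> None:
        if u == v:
            raise ValueError(f"self-interaction on {u}")
        if natom_pairs < 1:
            raise ValueError("natom_pairs must be >= 1")
        if subtype not in _SUBTYPES:
            raise ValueError(f"unknown subtype {subtype!r}")
        u, v = sorted((u, v))
        self.graph.add_edge(u, v, key=itype, subtype=subtype, natom_pairs=natom_pairs)

    def edges(self) -> list[tuple[str, str, str, dict]]:
        """Edges as (u, v, itype, data) with canonically ordered endpoints."""
        out = []
        for u, v, itype, data in self.graph.edges(keys=True, data=True):
            a, b = sorted((u, v))
            out.append((a, b, itype, data))
        return sorted(out, key=lambda e: (e[0], e[1], e[2]))

    def residue_pairs(self, itype: str | None = None) -> set[tuple[str, str]]:
        """Unordered residue pairs with at least one edge (optionally of itype)."""
        return {
            (u, v)
            for u, v, k, _ in self.edges()
            if itype is None or k == itype
        }

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def subnetwork(self, node_ids: Iterable[str], name: str | None = None) -> "RIN":
        sub = RIN(name=name or self.name)
        sub.graph = self.graph.subgraph(list(node_ids)).copy()
        return sub

    def to_graphml(self, path: str | Path) -> None:
        g = nx.MultiGraph(name=self.name)
        for n, attrs in self.graph.nodes(data=True):
            g.add_node(n, **{k: v for k, v in attrs.items() if v is not None})
        for u, v, itype, data in self.edges():
            g.add_edge(u, v, key=itype, itype=itype, **data)
        nx.write_graphml(g, str(path))


def _atom_class(atom_name: str) -> str:
    from .structure_io import BACKBONE_ATOMS

    return "mc" if atom_name in BACKBONE_ATOMS else "sc"


def _subtype_from_classes(classes: set[tuple[str, str]]) -> str:
    if classes == {("mc", "mc")}:
        return "mc_mc"
    if classes == {("sc", "sc")}:
        return "sc_sc"
    return "mc_sc"


def build_rin(
    s: Structure,
    contact_cutoff: float = 5.0,
    hbond_cutoff: float = 3.5,
    exclude_neighbors: int = 1,
    name: str | None = None,
) -> RIN:
    """Build a residue interaction network from a structure.

    A k-d tree over all heavy atoms finds candidate atom pairs within
    ``contact_cutoff``; results are identical to an exhaustive all-pairs
    distance scan.  Secondary-structure segments, if assigned on ``s``, are
    copied onto the nodes as the ``ss_segment`` attribute.
    """
    if not s.residues:
        raise ValueError("empty structure")
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    if hbond_cutoff > contact_cutoff:
        raise ValueError("hbond_cutoff must not exceed contact_cutoff")

    rin = RIN(name=name or s.id)
    # rank of each residue within its chain, for neighbour exclusion
    rank: dict[str, int] = {}
    for chain in s.chains:
        for i, res in enumerate(s.chain_residues(chain)):
            rank[res.node_id] = i
    for res in s.residues:
        rin.add_node(
            res.node_id,
            chain=res.chain,
            seq_num=res.seq_num,
            aa1=res.aa1,
            ss_segment=s.ss_segment_of(res),
        )

    coords, owner, names = [], [], []
    for ri, res in enumerate(s.residues):
        for atom in res.atoms:
            if atom.is_heavy:
                coords.append(atom.coords)
                owner.append(ri)
                names.append(atom.name)
    coords = np.asarray(coords)
    elements = [
        atom.element.upper()
        for res in s.residues
        for atom in res.atoms
        if atom.is_heavy
    ]

    tree = cKDTree(coords)
    pairs = tree.query_pairs(contact_cutoff, output_type="ndarray")

    # accumulate per residue pair
    contact_count: dict[tuple[int, int], int] = {}
    contact_classes: dict[tuple[int, int], set] = {}
    hbond_count: dict[tuple[int, int], int] = {}
    hbond_classes: dict[tuple[int, int], set] = {}
    for ai, aj in pairs:
        ri, rj = owner[ai], owner[aj]
        if ri == rj:
            continue
        res_i, res_j = s.residues[ri], s.residues[rj]
        if (
            res_i.chain == res_j.chain
            and abs(rank[res_i.node_id] - rank[res_j.node_id]) <= exclude_neighbors
        ):
            continue
        key = (min(ri, rj), max(ri, rj))
        cls = tuple(sorted((_atom_class(names[ai]), _atom_class(names[aj]))))
        contact_count[key] = contact_count.get(key, 0) + 1
        contact_classes.setdefault(key, set()).add(cls)
        if (
            elements[ai] in ("N", "O")
            and elements[aj] in ("N", "O")
            and np.linalg.norm(coords[ai] - coords[aj]) <= hbond_cutoff
        ):
            hbond_count[key] = hbond_count.get(key, 0) + 1
            hbond_classes.setdefault(key, set()).add(cls)

    for (ri, rj), n in sorted(contact_count.items()):
        u, v = s.residues[ri].node_id, s.residues[rj].node_id
        rin.add_edge(u, v, "contact", _subtype_from_classes(contact_classes[(ri, rj)]), n)
    for (ri, rj), n in sorted(hbond_count.items()):
        u, v = s.residues[ri].node_id, s.residues[rj].node_id
        rin.add_edge(u, v, "hbond", _subtype_from_classes(hbond_classes[(ri, rj)]), n)
    return rin


def extract_interface(r: RIN, chain_a: str, chain_b: str) -> RIN:
    """Subnetwork of interactions spanning two different chains.

    Contains exactly the edges with one endpoint in ``chain_a`` and the other
    in ``chain_b``, plus their endpoint nodes (the interface residues).
    """
    if chain_a == chain_b:
        raise ValueError("interface chains must differ")
    chains_present = {d.get("chain") for _, d in r.graph.nodes(data=True)}
    for c in (chain_a, chain_b):
        if c not in chains_present:
            raise ValueError(f"chain {c!r} not present in network")
    out = RIN(name=f"{r.name}_interface_{chain_a}{chain_b}")
    for u, v, itype, data in r.edges():
        cu = r.graph.nodes[u].get("chain")
        cv = r.graph.nodes[v].get("chain")
        if {cu, cv} == {chain_a, chain_b}:
            for n in (u, v):
                if n not in out.graph:
                    out.add_node(n, **dict(r.graph.nodes[n]))
            out.add_edge(u, v, itype, data["subtype"], data["natom_pairs"])
    return out


# ---------------------------------------------------------------------------
# SIF + attribute-table interchange


def write_rin(r: RIN, sif_path: str | Path, attr_path: str | Path) -> None:
    """Write the network as a SIF edge file plus a TSV node-attribute table.

    SIF dialect: one edge per line, ``node_id<TAB>itype:subtype<TAB>node_id``,
    with the qualifying-atom-pair count appended as an optional fourth column;
    isolated nodes are written as bare node lines.  The attribute table starts
    with the core columns (node_id, chain, seq_num, aa1, ss_segment) followed
    by any imported attributes in sorted order.
    """
    lines = []
    connected = set()
    for u, v, itype, data in r.edges():
        lines.append(
            f"{u}\t{_ITYPE_TO_SIF[itype]}:{data['subtype']}\t{v}\t{data['natom_pairs']}"
        )
        connected.update((u, v))
    for n in sorted(r.graph.nodes):
        if n not in connected:
            lines.append(n)
    Path(sif_path).write_text("\n".join(lines) + ("\n" if lines else ""))

    extra = sorted(
        {
            k
            for _, attrs in r.graph.nodes(data=True)
            for k in attrs
            if k not in _CORE_ATTR_COLUMNS
        }
    )
    cols = ["node_id", *_CORE_ATTR_COLUMNS, *extra]
    rows = [("\t".join(cols))]
    for n in sorted(r.graph.nodes):
        attrs = r.graph.nodes[n]
        rows.append(
            "\t".join(
                [n] + ["" if attrs.get(c) is None else str(attrs.get(c, "")) for c in cols[1:]]
            )
        )
    Path(attr_path).write_text("\n".join(rows) + "\n")


def _parse_attr_value(text: str):
    if text == "":
        return None
    for conv in (int, float):
        try:
            return conv(text)
        except ValueError:
            pass
    if text in ("True", "False"):
        return text == "True"
    return text


def read_rin(sif_path: str | Path, attr_path: str | Path, name: str | None = None) -> RIN:
    """Read a SIF edge file plus attribute table; inverse of :func:`write_rin`."""
    rin = RIN(name=name or Path(sif_path).stem)

    with open(attr_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "node_id":
            raise ValueError(f"{attr_path}: first column must be node_id")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            node_id = parts[0]
            attrs = {
                col: _parse_attr_value(val)
                for col, val in zip(header[1:], parts[1:])
            }
            rin.add_node(node_id, **attrs)

    with open(sif_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                if parts[0] not in rin.graph:
                    raise ValueError(
                        f"{sif_path}:{lineno}: node {parts[0]!r} missing from attribute table"
                    )
                continue
            if len(parts) not in (3, 4):
                raise ValueError(f"{sif_path}:{lineno}: expected 3 or 4 tab-separated fields")
            u, label, v = parts[:3]
            natom_pairs = int(parts[3]) if len(parts) == 4 else 1
            try:
                sif_itype, subtype = label.split(":", 1)
                itype = _SIF_TO_ITYPE[sif_itype]
                if subtype not in _SUBTYPES:
                    raise KeyError(subtype)
            except (KeyError, ValueError):
                raise ValueError(
                    f"{sif_path}:{lineno}: unknown interaction label {label!r}"
                ) from None
            for n in (u, v):
                if n not in rin.graph:
                    raise ValueError(
                        f"{sif_path}:{lineno}: node {n!r} missing from attribute table"
                    )
            rin.add_edge(u, v, itype, subtype, natom_pairs)
    return rin
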