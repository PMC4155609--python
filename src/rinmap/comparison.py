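"""Parent/mutant comparison of residue interaction networks.

Given two structures of (nearly) the same protein — a parent and a mutant —
and a pairwise alignment of their sequences, the comparison network has one
node per alignment column that carries a residue in either RIN, and an edge
between two columns whenever the corresponding residue pair interacts in
either network.  Edges are labelled by what happened upon mutation:

* ``conserved`` — the interaction exists in both networks,
* ``lost``      — only in the parent (network A),
* ``gained``    — only in the mutant (network B).

Each node is scored with the *unchanged fraction*: the share of its incident
comparison edges that are conserved (1 = no interaction change around that
residue), and mutated columns additionally carry the BLOSUM62 substitution
score — low or negative scores flag chemically drastic replacements.

Sequence alignment is standard global Needleman–Wunsch with affine gap
penalties and BLOSUM62 scores (via Biopython); alternatively a pre-computed
aligned-FASTA pair can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rin_builder import RIN

__all__ = [
    "PairwiseAlignment",
    "MutationSet",
    "ComparisonNetwork",
    "global_align",
    "find_mutations",
    "blosum62",
    "build_comparison_network",
    "unchanged_fraction",
    "read_aligned_fasta",
    "write_aligned_fasta",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP = "-"


def blosum62(aa_x: str, aa_y: str) -> int:
    """Symmetric BLOSUM62 substitution score (alphabet: 20 aa + B, Z, X, *)."""
    for aa in (aa_x, aa_y):
        if aa not in _BLOSUM62.alphabet:
            raise ValueError(f"unknown amino acid letter {aa!r}")
    return int(_BLOSUM62[aa_x][aa_y])


@dataclass
class PairwiseAlignment:
    """Gapped two-row alignment with 1-based column → node_id maps."""

    id_a: str
    id_b: str
    rows: tuple[str, str]
    col_to_res_a: dict[int, str] = field(default_factory=dict)
    col_to_res_b: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ra, rb = self.rows
        if len(ra) != len(rb):
            raise ValueError("alignment rows must have equal length")
        if not self.col_to_res_a:
            self.col_to_res_a = _default_col_map(ra)
        if not self.col_to_res_b:
            self.col_to_res_b = _default_col_map(rb)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def attach_node_ids(self, node_ids_a: list[str], node_ids_b: list[str]) -> None:
        """Rebind the column maps to RIN node_ids (ungapped order)."""
        for row, ids, which in ((self.rows[0], node_ids_a, "a"), (self.rows[1], node_ids_b, "b")):
            n_res = sum(1 for c in row if c != GAP)
            if len(ids) != n_res:
                raise ValueError(
                    f"row {which}: {n_res} residues but {len(ids)} node_ids given"
                )
            mapping, k = {}, 0
            for col, c in enumerate(row, start=1):
                if c != GAP:
                    mapping[col] = ids[k]
                    k += 1
            if which == "a":
                self.col_to_res_a = mapping
            else:
                self.col_to_res_b = mapping

    def res_to_col_a(self) -> dict[str, int]:
        return {v: k for k, v in self.col_to_res_a.items()}

    def res_to_col_b(self) -> dict[str, int]:
        return {v: k for k, v in self.col_to_res_b.items()}


def _default_col_map(row: str) -> dict[int, str]:
    mapping, k = {}, 0
    for col, c in enumerate(row, start=1):
        if c != GAP:
            k += 1
            mapping[col] = str(k)
    return mapping


def global_align(
    seq_a: str,
    seq_b: str,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
    id_a: str = "a",
    id_b: str = "b",
) -> PairwiseAlignment:
    """Global Needleman–Wunsch alignment with affine gaps and BLOSUM62 scores.

    Deterministic: of the co-optimal alignments, the aligner's first reported
    traceback is returned.  ``gap_open`` is the score of the first gapped
    position, ``gap_extend`` of each further one.
    """
    for name, seq in (("a", seq_a), ("b", seq_b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = set(seq) - set(_BLOSUM62.alphabet)
        if bad:
            raise ValueError(f"sequence {name}: letters outside alphabet: {sorted(bad)}")
    aligner = Align.PairwiseAligner(
        mode="global",
        substitution_matrix=_BLOSUM62,
        open_gap_score=gap_open,
        extend_gap_score=gap_extend,
    )
    aln = aligner.align(seq_a, seq_b)[0]
    return PairwiseAlignment(id_a=id_a, id_b=id_b, rows=(str(aln[0]), str(aln[1])))


def alignment_score(aln: PairwiseAlignment, gap_open: float = -10.0,
                    gap_extend: float = -1.0) -> float:
    """Affine-gap BLOSUM62 score of an explicit alignment."""
    ra, rb = aln.rows
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(ra, rb):
        if ca == GAP and cb == GAP:
            raise ValueError("column gapped in both rows")
        if ca == GAP:
            score += gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == GAP:
            score += gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += blosum62(ca, cb)
            in_gap_a = in_gap_b = False
    return score


# ---------------------------------------------------------------------------
# Mutation identification


@dataclass
class MutationSet:
    """Differences between the two alignment rows, classified per column."""

    substitutions: list[tuple[int, str, str, str, str, int]] = field(default_factory=list)
    # (column, aa_a, aa_b, node_id_a, node_id_b, blosum62)
    insertions_in_b: list[int] = field(default_factory=list)
    deletions_from_a: list[int] = field(default_factory=list)

    @property
    def n_changes(self) -> int:
        return len(self.substitutions) + len(self.insertions_in_b) + len(self.deletions_from_a)


def find_mutations(aln: PairwiseAlignment) -> MutationSet:
    """Classify every alignment column: match, substitution, insertion, deletion.

    A column gapped in row A is an insertion in the mutant; gapped in row B a
    deletion from the parent; unequal non-gap letters are substitutions and
    carry their BLOSUM62 score.
    """
    ms = MutationSet()
    ra, rb = aln.rows
    for col in range(1, aln.n_columns + 1):
        ca, cb = ra[col - 1], rb[col - 1]
        if ca == GAP and cb == GAP:
            raise ValueError(f"column {col} gapped in both rows: invalid alignment")
        if ca == GAP:
            ms.insertions_in_b.append(col)
        elif cb == GAP:
            ms.deletions_from_a.append(col)
        elif ca != cb:
            ms.substitutions.append(
                (
                    col,
                    ca,
                    cb,
                    aln.col_to_res_a[col],
                    aln.col_to_res_b[col],
                    blosum62(ca, cb),
                )
            )
    return ms


# ---------------------------------------------------------------------------
# Comparison network


@dataclass
class ComparisonNetwork:
    """Graph over alignment columns; see module docstring for edge statuses."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    name: str = "comparison"

    def edges_with_status(self, status: str) -> list[tuple[int, int]]:
        return sorted(
            (min(u, v), max(u, v))
            for u, v, d in self.graph.edges(data=True)
            if d["status"] == status
        )

    def status_counts(self) -> dict[str, int]:
        counts = {"conserved": 0, "lost": 0, "gained": 0}
        for _, _, d in self.graph.edges(data=True):
            counts[d["status"]] += 1
        return counts

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph(name=self.name)
        for n, attrs in self.graph.nodes(data=True):
            g.add_node(n, **{k: v for k, v in attrs.items() if v is not None})
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, **d)
        nx.write_graphml(g, str(path))

    def to_sif(self, path: str | Path) -> None:
        # "both" mirrors conserved edges; lost/gained keep their names
        label = {"conserved": "both", "lost": "lost", "gained": "gained"}
        lines = []
        for u, v, d in sorted(self.graph.edges(data=True)):
            a, b = sorted((u, v))
            lines.append(f"col{a}\t{label[d['status']]}\tcol{b}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _rin_pairs_as_columns(
    r: RIN, res_to_col: dict[str, int], which: str
) -> set[tuple[int, int]]:
    pairs = set()
    missing = []
    for u, v in r.residue_pairs():
        if u not in res_to_col or v not in res_to_col:
            missing.extend(n for n in (u, v) if n not in res_to_col)
            continue
        cu, cv = res_to_col[u], res_to_col[v]
        pairs.add((min(cu, cv), max(cu, cv)))
    if missing:
        raise ValueError(
            f"RIN {which} nodes not covered by the alignment: {sorted(set(missing))}"
        )
    return pairs


def build_comparison_network(
    rin_a: RIN, rin_b: RIN, aln: PairwiseAlignment
) -> ComparisonNetwork:
    """Build the aligned-pair comparison network of a parent (A) and mutant (B).

    Interaction-type labels are collapsed: edge identity is the unordered
    residue pair, and an edge's status reflects presence of *any* interaction
    between the pair in each network.
    """
    res_col_a = aln.res_to_col_a()
    res_col_b = aln.res_to_col_b()
    pairs_a = _rin_pairs_as_columns(rin_a, res_col_a, "A")
    pairs_b = _rin_pairs_as_columns(rin_b, res_col_b, "B")

    muts = find_mutations(aln)
    sub_cols = {m[0]: m for m in muts.substitutions}
    unaligned_cols = set(muts.insertions_in_b) | set(muts.deletions_from_a)

    cn = ComparisonNetwork(name=f"{rin_a.name}_vs_{rin_b.name}")
    cols_with_residue = set()
    for node in rin_a.graph.nodes:
        if node in res_col_a:
            cols_with_residue.add(res_col_a[node])
    for node in rin_b.graph.nodes:
        if node in res_col_b:
            cols_with_residue.add(res_col_b[node])

    ra, rb = aln.rows
    for col in sorted(cols_with_residue):
        ca = ra[col - 1]
        cb = rb[col - 1]
        sub = sub_cols.get(col)
        cn.graph.add_node(
            col,
            aa_a=None if ca == GAP else ca,
            aa_b=None if cb == GAP else cb,
            node_id_a=aln.col_to_res_a.get(col),
            node_id_b=aln.col_to_res_b.get(col),
            mutated=sub is not None,
            unaligned=col in unaligned_cols,
            blosum62=sub[5] if sub else None,
        )

    for pair in sorted(pairs_a | pairs_b):
        in_a, in_b = pair in pairs_a, pair in pairs_b
        status = "conserved" if (in_a and in_b) else ("lost" if in_a else "gained")
        cn.graph.add_edge(*pair, status=status)

    for col in cn.graph.nodes:
        cn.graph.nodes[col]["unchanged_fraction"] = unchanged_fraction(cn, col)
    return cn


def unchanged_fraction(cn: ComparisonNetwork, node: int) -> float:
    """Fraction of a node's incident comparison edges that are conserved.

    An isolated node scores 1.0: no interaction around it changed because
    there are none to change.
    """
    if node not in cn.graph:
        raise KeyError(f"node {node} not in comparison network")
    incident = list(cn.graph.edges(node, data=True))
    if not incident:
        return 1.0
    conserved = sum(1 for _, _, d in incident if d["status"] == "conserved")
    return conserved / len(incident)


# ---------------------------------------------------------------------------
# Aligned FASTA I/O


def read_aligned_fasta(path: str | Path) -> PairwiseAlignment:
    """Read a two-record aligned FASTA (equal gapped lengths, '-' gaps)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, found {len(records)}")
    ra, rb = str(records[0].seq).upper(), str(records[1].seq).upper()
    if len(ra) != len(rb):
        raise ValueError(f"{path}: rows differ in gapped length")
    return PairwiseAlignment(id_a=records[0].id, id_b=records[1].id, rows=(ra, rb))


def write_aligned_fasta(aln: PairwiseAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(aln.rows[0]), id=aln.id_a, description=""),
        SeqRecord(Seq(aln.rows[1]), id=aln.id_b, description=""),
    ]
    SeqIO.write(records, str(path), "fasta")
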