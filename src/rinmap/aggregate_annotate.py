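"""Aggregated network views, residue annotation import, and attribute filters.

Aggregation collapses a RIN by any node attribute — most usefully the
secondary-structure segment, which yields the coarse helix/strand/loop
adjacency map used as an intermediate between the full RIN and the 3D
cartoon.  Annotations (conservation grades, functional-site flags, surface
areas, ...) are imported from TSV tables keyed by node_id and become
queryable node attributes; the filter grammar supports comparisons and
boolean connectives over those attributes, e.g. ``mutated and
consurf_score >= 7`` to select mutated residues at conserved positions.
"""

from __future__ import annotations

import ast
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .rin_builder import RIN

__all__ = [
    "AggregatedNetwork",
    "AnnotationTable",
    "aggregate",
    "load_annotations",
    "filter_nodes",
    "FilterError",
]


@dataclass
class AggregatedNetwork:
    """RIN collapsed by a node attribute: groups plus weighted inter-group edges."""

    by: str
    groups: dict[str, list[str]]                       # group_id -> member node_ids
    edges: dict[tuple[str, str], int]                  # unordered group pair -> weight
    group_attrs: dict[str, dict] = field(default_factory=dict)
    intra_group_edges: int = 0

    @property
    def total_edge_weight(self) -> int:
        return sum(self.edges.values())

    def to_tsv(self, path: str | Path) -> None:
        lines = ["group_a\tgroup_b\tweight"]
        for (a, b), w in sorted(self.edges.items()):
            lines.append(f"{a}\t{b}\t{w}")
        Path(path).write_text("\n".join(lines) + "\n")


def aggregate(r: RIN, by: str = "ss_segment", keep_intra: bool = False) -> AggregatedNetwork:
    """Collapse a RIN into one group per distinct value of attribute ``by``.

    Inter-group edge weight counts the RIN edges spanning the two groups;
    intra-group edges are dropped (counted in ``intra_group_edges``) unless
    ``keep_intra`` is set, in which case they appear as self-pairs.
    """
    missing = sorted(
        n for n, attrs in r.graph.nodes(data=True)
        if attrs.get(by) is None or attrs.get(by) == ""
    )
    if missing:
        raise ValueError(f"nodes missing attribute {by!r}: {missing}")

    # group ids in order of first occurrence over (chain, seq_num)-sorted nodes
    def node_key(n):
        a = r.graph.nodes[n]
        return (a.get("chain", ""), a.get("seq_num", 0), n)

    groups: dict[str, list[str]] = {}
    for n in sorted(r.graph.nodes, key=node_key):
        groups.setdefault(str(r.graph.nodes[n][by]), []).append(n)

    group_of = {n: str(r.graph.nodes[n][by]) for n in r.graph.nodes}
    edges: dict[tuple[str, str], int] = {}
    intra = 0
    for u, v, _itype, _d in r.edges():
        gu, gv = group_of[u], group_of[v]
        if gu == gv:
            intra += 1
            if not keep_intra:
                continue
        key = tuple(sorted((gu, gv)))
        edges[key] = edges.get(key, 0) + 1

    group_attrs = {}
    for gid, members in groups.items():
        chains = {r.graph.nodes[n].get("chain") for n in members}
        group_attrs[gid] = {
            "size": len(members),
            "chain": chains.pop() if len(chains) == 1 else "*",
            "kind": _kind_from_segment_id(gid),
        }
    return AggregatedNetwork(
        by=by, groups=groups, edges=edges, group_attrs=group_attrs, intra_group_edges=intra
    )


def _kind_from_segment_id(gid: str) -> str:
    if gid[:1] == "H":
        return "helix"
    if gid[:1] == "E":
        return "strand"
    if gid[:1] == "L":
        return "loop"
    return "other"


# ---------------------------------------------------------------------------
# Annotation import


@dataclass
class AnnotationTable:
    """Typed per-residue annotation table keyed by node_id."""

    data: pd.DataFrame  # index: node_id

    @classmethod
    def from_tsv(cls, path: str | Path, types: dict[str, str] | None = None) -> "AnnotationTable":
        """Load a TSV whose first column is node_id.

        Column types are taken from a sidecar JSON (``{"col": "numeric" |
        "boolean" | "categorical"}``, path given via ``types`` loaded by the
        caller or a ``<path>.types.json`` file) or inferred: int-like →
        numeric, true/false → boolean, else categorical.
        """
        path = Path(path)
        df = pd.read_csv(path, sep="\t", dtype=str)
        key = df.columns[0]
        if key != "node_id":
            raise ValueError(f"{path}: first column must be node_id, found {key!r}")
        df = df.set_index("node_id")
        if types is None:
            sidecar = path.with_suffix(path.suffix + ".types.json")
            if sidecar.exists():
                types = json.loads(sidecar.read_text())
        out = {}
        for col in df.columns:
            declared = (types or {}).get(col)
            out[col] = _coerce_column(df[col], declared, col)
        return cls(data=pd.DataFrame(out, index=df.index))

    def columns(self) -> list[str]:
        return list(self.data.columns)


def _coerce_column(series: pd.Series, declared: str | None, col: str) -> pd.Series:
    vals = series.astype(str)
    if declared == "boolean" or (
        declared is None and set(vals.str.lower().dropna()) <= {"true", "false"}
    ):
        coerced = vals.str.lower().map({"true": True, "false": False})
        if declared == "boolean" and coerced.isna().any():
            raise ValueError(f"column {col!r}: non-boolean values under boolean type")
        return coerced
    if declared == "numeric" or declared is None:
        numeric = pd.to_numeric(vals, errors="coerce")
        if not numeric.isna().any():
            return numeric
        if declared == "numeric":
            raise ValueError(f"column {col!r}: non-numeric values under numeric type")
    return vals


def load_annotations(
    r: RIN, table: AnnotationTable, on_conflict: str = "error"
) -> dict[str, int]:
    """Attach table columns as node attributes; returns per-column coverage.

    ``on_conflict`` controls collisions with existing attribute names:
    ``error`` raises, ``overwrite`` replaces, ``skip`` leaves existing values.
    Unknown node_ids in the table are reported as a warning, not an error —
    external resources often use a shifted numbering.
    """
    if on_conflict not in ("error", "overwrite", "skip"):
        raise ValueError(f"unknown on_conflict policy {on_conflict!r}")
    unknown = [nid for nid in table.data.index if nid not in r.graph]
    if unknown:
        warnings.warn(f"{len(unknown)} annotation rows match no network node: {unknown[:5]}")

    existing_attrs = {k for _, attrs in r.graph.nodes(data=True) for k in attrs}
    coverage: dict[str, int] = {}
    for col in table.data.columns:
        if col in existing_attrs:
            if on_conflict == "error":
                raise ValueError(f"attribute {col!r} already present on the network")
            if on_conflict == "skip":
                coverage[col] = 0
                continue
        count = 0
        for nid, value in table.data[col].items():
            if nid in r.graph and pd.notna(value):
                r.graph.nodes[nid][col] = (
                    value.item() if hasattr(value, "item") else value
                )
                count += 1
        coverage[col] = count
    return coverage


# ---------------------------------------------------------------------------
# Predicate filters


class FilterError(ValueError):
    """Raised for syntax errors or unknown attribute names in a filter."""


_ALLOWED_NODES = (
    ast.Expression, ast.BoolOp, ast.UnaryOp, ast.Compare, ast.Name, ast.Load,
    ast.Constant, ast.And, ast.Or, ast.Not,
    ast.Eq, ast.NotEq, ast.Lt, ast.LtE, ast.Gt, ast.GtE,
)


def _validate_filter_ast(tree: ast.AST, known_attrs: set[str], expr: str) -> None:
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise FilterError(
                f"unsupported syntax {type(node).__name__!r} at position "
                f"{getattr(node, 'col_offset', '?')}"
            )
        if isinstance(node, ast.Name) and node.id not in known_attrs:
            raise FilterError(
                f"unknown attribute {node.id!r} at position {node.col_offset}"
            )


class _MissingAttr(Exception):
    pass


def _eval_node(node: ast.AST, attrs: dict):
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, attrs)
    if isinstance(node, ast.Constant):
        return node.value
    if isinstance(node, ast.Name):
        if node.id not in attrs or attrs[node.id] is None:
            raise _MissingAttr(node.id)
        return attrs[node.id]
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Not):
        return not _eval_node(node.operand, attrs)
    if isinstance(node, ast.BoolOp):
        op = all if isinstance(node.op, ast.And) else any
        return op(bool(_eval_node(v, attrs)) for v in node.values)
    if isinstance(node, ast.Compare):
        left = _eval_node(node.left, attrs)
        for op, comparator in zip(node.ops, node.comparators):
            right = _eval_node(comparator, attrs)
            ok = {
                ast.Eq: lambda a, b: a == b,
                ast.NotEq: lambda a, b: a != b,
                ast.Lt: lambda a, b: a < b,
                ast.LtE: lambda a, b: a <= b,
                ast.Gt: lambda a, b: a > b,
                ast.GtE: lambda a, b: a >= b,
            }[type(op)](left, right)
            if not ok:
                return False
            left = right
        return True
    raise FilterError(f"unsupported syntax {type(node).__name__!r}")


def filter_nodes(r: RIN, expression: str) -> set[str]:
    """Node_ids satisfying a boolean predicate over node attributes.

    Grammar: comparisons (``==, !=, <, <=, >, >=``), ``and/or/not``, and
    parentheses; bare boolean attributes may be used directly.  A node
    missing a referenced attribute simply fails the predicate; an attribute
    unknown to the whole network is an error.
    """
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise FilterError(f"syntax error at position {exc.offset}: {exc.msg}") from None
    known = {k for _, attrs in r.graph.nodes(data=True) for k in attrs}
    _validate_filter_ast(tree, known, expression)
    selected = set()
    for n, attrs in r.graph.nodes(data=True):
        try:
            if _eval_node(tree, attrs):
                selected.add(n)
        except (_MissingAttr, TypeError):
            continue
    return selected
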