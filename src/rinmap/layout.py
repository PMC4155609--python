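"""Anchored weighted-stress layout for residue interaction networks.

The 2D layout problem: place every residue node so that pairwise layout
distances reproduce the 3D inter-residue distances (weighted stress, with
local emphasis), while staying close to a fixed 2D projection of the 3D
coordinates so the user keeps their spatial orientation from the structure
view.  The energy is a convex blend of the two terms,

    E(X) = (1 - lam) * S(X)/S0 + lam * A(X)/A0

with  S(X) = sum_{u<v} w_uv (||x_u - x_v|| - d_uv)^2   (weighted stress)
and   A(X) = sum_u ||x_u - a_u||^2                     (anchor pull),

where ``a_u`` are the projected coordinates.  ``S0 = sum w_uv d_uv^2`` and
``A0 = n * (mean pairwise anchor distance)^2`` are fixed normalisers that
make the two terms dimensionless and comparable.  Weights default to
``w_uv = d_uv^-2`` (local emphasis) and are multiplied by ``ss_weight_factor``
for pairs within the same secondary-structure element, tightening helices
and strands in the drawing.

The minimiser is SMACOF-style majorization: each sweep replaces the stress
with a touching quadratic upper bound and solves the resulting linear system
exactly — the anchor term is already quadratic and enters the update without
approximation, so the energy is non-increasing at fixed blend weight.  The
blend weight follows a linear schedule from ``anchor_start`` to
``anchor_end`` over the sweeps, raising the priority of the projection as
the optimisation proceeds.  The procedure is fully deterministic: the
initial configuration is the projection itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .rin_builder import RIN
from .structure_io import Structure, ViewTransform, project_coordinates

__all__ = [
    "LayoutConfig",
    "Layout2D",
    "target_distances",
    "stress_energy",
    "anchored_stress_layout",
]

_D_FLOOR = 1e-6  # coincident representative points get this target distance


@dataclass
class LayoutConfig:
    weight_exponent: float = -2.0
    ss_weight_factor: float = 4.0
    anchor_start: float = 0.1
    anchor_end: float = 0.9
    iterations: int = 200
    tol: float = 1e-6
    pair_scope: str = "all"  # all | graph_k
    graph_k: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.anchor_start <= self.anchor_end <= 1.0:
            raise ValueError("need 0 <= anchor_start <= anchor_end <= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.ss_weight_factor < 1:
            raise ValueError("ss_weight_factor must be >= 1")
        if self.pair_scope not in ("all", "graph_k"):
            raise ValueError(f"unknown pair_scope {self.pair_scope!r}")


@dataclass
class Layout2D:
    positions: dict[str, np.ndarray]
    anchors: dict[str, np.ndarray]
    final_energy: float
    energy_trace: list[float] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        lines = ["node_id\tx\ty"]
        for n in sorted(self.positions):
            x, y = self.positions[n]
            lines.append(f"{n}\t{x:.6f}\t{y:.6f}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def target_distances(
    s: Structure, r: RIN, pair_scope: str = "all", graph_k: int = 3
) -> dict[tuple[str, str], float]:
    """Pairwise 3D distances between representative atoms of the RIN nodes.

    With ``pair_scope="all"`` every node pair gets a target distance; with
    ``"graph_k"`` only pairs within graph distance ``graph_k`` in the RIN do,
    trading stress fidelity for O(n k) pairs on large networks.
    """
    nodes = sorted(r.graph.nodes)
    coords = {}
    for n in nodes:
        try:
            res = s.residue_by_node_id(n)
        except KeyError:
            raise ValueError(f"RIN node {n} not found in structure") from None
        coords[n] = res.representative_coords()

    if pair_scope == "all":
        pairs = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]
    else:
        simple = nx.Graph(r.graph)
        pairs = set()
        for u in nodes:
            lengths = nx.single_source_shortest_path_length(simple, u, cutoff=graph_k)
            for v in lengths:
                if u < v:
                    pairs.add((u, v))
        pairs = sorted(pairs)

    out: dict[tuple[str, str], float] = {}
    for u, v in pairs:
        d = float(np.linalg.norm(coords[u] - coords[v]))
        out[(u, v)] = d
        out[(v, u)] = d
    return out


def _normalizers(D: np.ndarray, W: np.ndarray, anchors: np.ndarray) -> tuple[float, float]:
    n = anchors.shape[0]
    iu = np.triu_indices(n, k=1)
    s0 = float(np.sum(W[iu] * D[iu] ** 2))
    if n > 1:
        pd = np.linalg.norm(anchors[iu[0]] - anchors[iu[1]], axis=1)
        a0 = n * float(np.mean(pd)) ** 2
    else:
        a0 = 1.0
    # degenerate inputs (all anchors coincident, or no weighted pairs)
    return (s0 if s0 > 0 else 1.0), (a0 if a0 > 0 else 1.0)


def _stress(X: np.ndarray, D: np.ndarray, W: np.ndarray) -> float:
    n = X.shape[0]
    iu = np.triu_indices(n, k=1)
    diff = np.linalg.norm(X[iu[0]] - X[iu[1]], axis=1)
    return float(np.sum(W[iu] * (diff - D[iu]) ** 2))


def stress_energy(
    X: dict[str, np.ndarray],
    D: dict[tuple[str, str], float],
    W: dict[tuple[str, str], float],
    anchors: dict[str, np.ndarray],
    lam: float,
) -> float:
    """Blended layout energy E = (1-lam)*S/S0 + lam*A/A0 (see module docstring)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("blend weight must be in [0, 1]")
    nodes = sorted(X)
    if set(anchors) != set(nodes):
        raise ValueError("positions and anchors must cover the same nodes")
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    Xa = np.array([X[u] for u in nodes], dtype=float)
    Aa = np.array([anchors[u] for u in nodes], dtype=float)
    Dm = np.zeros((n, n))
    Wm = np.zeros((n, n))
    for (u, v), d in D.items():
        if u in idx and v in idx:
            Dm[idx[u], idx[v]] = d
    for (u, v), w in W.items():
        if u in idx and v in idx:
            Wm[idx[u], idx[v]] = w
    Dm = np.maximum(Dm, Dm.T)
    Wm = np.maximum(Wm, Wm.T)
    s0, a0 = _normalizers(Dm, Wm, Aa)
    s = _stress(Xa, Dm, Wm)
    a = float(np.sum((Xa - Aa) ** 2))
    return (1.0 - lam) * s / s0 + lam * a / a0


def _majorize_sweep(
    X: np.ndarray,
    D: np.ndarray,
    W: np.ndarray,
    L_w: np.ndarray,
    anchors: np.ndarray,
    lam: float,
    s0: float,
    a0: float,
) -> np.ndarray:
    """One exact minimisation of the majorizing quadratic at the current X.

    The Cauchy–Schwarz bound linearises the -2 w d ||x_u - x_v|| term at X,
    giving the Guttman matrix B(X); the anchor term is quadratic already, so
    the update solves ((1-lam)/s0 * L_w + lam/a0 * I) X+ = (1-lam)/s0 * B X
    + lam/a0 * A exactly.  At lam = 0 the system is singular (translation
    invariance); the least-squares solution is re-centred on the previous
    iterate's mean so translations of the input carry through.
    """
    n = X.shape[0]
    delta = X[:, None, :] - X[None, :, :]
    dist = np.linalg.norm(delta, axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dist > 0, W * D / np.where(dist > 0, dist, 1.0), 0.0)
    np.fill_diagonal(ratio, 0.0)
    B = -ratio
    np.fill_diagonal(B, ratio.sum(axis=1))

    cs = (1.0 - lam) / s0
    ca = lam / a0
    rhs = cs * (B @ X) + ca * anchors
    if ca > 0:
        M = cs * L_w + ca * np.eye(n)
        return np.linalg.solve(M, rhs)
    X_new, *_ = np.linalg.lstsq(cs * L_w, rhs, rcond=None)
    return X_new - X_new.mean(axis=0) + X.mean(axis=0)


def anchored_stress_layout(
    r: RIN,
    s: Structure,
    view: ViewTransform | None = None,
    cfg: LayoutConfig | None = None,
) -> Layout2D:
    """Compute the anchored stress layout of a RIN (see module docstring).

    The initial configuration is the projection of the representative 3D
    coordinates under ``view``; those same projected points are the anchors.
    The energy trace records E(X_t, lam_t) after every sweep.
    """
    cfg = cfg or LayoutConfig()
    nodes = sorted(r.graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    idx = {u: i for i, u in enumerate(nodes)}

    projected = project_coordinates(s, view)
    missing = [u for u in nodes if u not in projected]
    if missing:
        raise ValueError(f"RIN nodes without structure coordinates: {missing}")
    anchors = np.array([projected[u] for u in nodes], dtype=float)

    D = np.zeros((n, n))
    W = np.zeros((n, n))
    dmap = target_distances(s, r, pair_scope=cfg.pair_scope, graph_k=cfg.graph_k)
    clamped = False
    for (u, v), d in dmap.items():
        i, j = idx[u], idx[v]
        if d <= 0:
            d = _D_FLOOR
            clamped = True
        D[i, j] = d
        W[i, j] = d ** cfg.weight_exponent
    if clamped:
        warnings.warn("coincident representative atoms: target distance clamped to 1e-6")
    # same-segment pairs get tighter distance-error weights
    seg = {u: _segment_label(s, u) for u in nodes}
    for u in nodes:
        for v in nodes:
            if u != v and seg[u] and seg[u] == seg[v]:
                W[idx[u], idx[v]] *= cfg.ss_weight_factor

    L_w = -W.copy()
    np.fill_diagonal(L_w, W.sum(axis=1))
    s0, a0 = _normalizers(D, W, anchors)

    X = anchors.copy()
    T = cfg.iterations
    trace: list[float] = []
    for t in range(1, T + 1):
        lam = cfg.anchor_start + (cfg.anchor_end - cfg.anchor_start) * t / T
        e_before = _energy(X, D, W, anchors, lam, s0, a0)
        X = _majorize_sweep(X, D, W, L_w, anchors, lam, s0, a0)
        e_after = _energy(X, D, W, anchors, lam, s0, a0)
        trace.append(e_after)
        # stop once the schedule is exhausted of movement: relative decrease at
        # the current (now effectively fixed) blend weight below tol
        at_final_lam = lam >= cfg.anchor_end - 1e-15
        denom = max(abs(e_before), 1e-300)
        if at_final_lam and (e_before - e_after) / denom < cfg.tol:
            break

    positions = {u: X[idx[u]].copy() for u in nodes}
    anchor_map = {u: anchors[idx[u]].copy() for u in nodes}
    return Layout2D(
        positions=positions,
        anchors=anchor_map,
        final_energy=trace[-1] if trace else 0.0,
        energy_trace=trace,
    )


def _segment_label(s: Structure, node_id: str) -> str:
    return s.ss_segment_of(s.residue_by_node_id(node_id))


def _energy(X, D, W, anchors, lam, s0, a0) -> float:
    s = _stress(X, D, W)
    a = float(np.sum((X - anchors) ** 2))
    return (1.0 - lam) * s / s0 + lam * a / a0
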