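"""Protein structure model: PDB reading/writing, secondary structure, 2D projection.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of polymer residues, each holding its atoms with 3D coordinates, plus the
secondary-structure segmentation of every chain.  Residues are addressed by a
canonical ``node_id`` string ``chain:seq_num:ins_code:aa3`` (blank insertion
code rendered as ``_``), which is the node naming convention used throughout
the residue-interaction-network machinery.

PDB parsing is delegated to :mod:`gemmi`; alternate locations are resolved
here (highest occupancy wins, ties broken by lexicographically smallest altloc
identifier) so that downstream geometry sees exactly one conformer per atom.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "SSSegment",
    "ViewTransform",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "assign_secondary_structure",
    "project_coordinates",
    "AA3_TO_AA1",
]

#: Three-letter to one-letter codes for the 20 standard amino acids.
AA3_TO_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3 = {v: k for k, v in AA3_TO_AA1.items()}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be turned into a Structure."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


@dataclass
class Residue:
    chain: str
    seq_num: int
    ins_code: str
    aa3: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def aa1(self) -> str:
        return AA3_TO_AA1.get(self.aa3, "X")

    @property
    def node_id(self) -> str:
        ins = self.ins_code if self.ins_code.strip() else "_"
        return f"{self.chain}:{self.seq_num}:{ins}:{self.aa3}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def representative_coords(self) -> np.ndarray:
        """CA position, or the centroid of heavy atoms when CA is absent."""
        ca = self.atom("CA")
        if ca is not None:
            return ca.coords
        heavy = [a.coords for a in self.atoms if a.is_heavy]
        if not heavy:
            raise ValueError(f"residue {self.node_id} has no heavy atoms")
        return np.mean(heavy, axis=0)


@dataclass
class SSSegment:
    segment_id: str  # e.g. "H1", "E3", "L2"
    kind: str        # helix | strand | loop
    chain: str
    start: int       # inclusive residue seq_num
    end: int         # inclusive

    def contains(self, res: Residue) -> bool:
        return res.chain == self.chain and self.start <= res.seq_num <= self.end


@dataclass
class Structure:
    id: str
    chains: list[str]
    residues: list[Residue]
    ss_segments: list[SSSegment] = field(default_factory=list)
    # helix/strand ranges parsed from HELIX/SHEET header records of the source
    # file, as (chain, start_seqnum, end_seqnum) tuples
    header_helices: list[tuple[str, int, int]] = field(default_factory=list)
    header_strands: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.node_id for r in self.residues]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate node_ids in structure: {dupes}")

    def chain_residues(self, chain: str) -> list[Residue]:
        return [r for r in self.residues if r.chain == chain]

    def residue_by_node_id(self, node_id: str) -> Residue:
        for r in self.residues:
            if r.node_id == node_id:
                return r
        raise KeyError(node_id)

    def sequence(self, chain: str) -> str:
        return "".join(r.aa1 for r in self.chain_residues(chain))

    def ss_segment_of(self, res: Residue) -> str:
        for seg in self.ss_segments:
            if seg.contains(res):
                return seg.segment_id
        return ""


@dataclass
class ViewTransform:
    """Orthonormal rotation plus isotropic scale taken from a 3D viewer camera."""

    rotation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @classmethod
    def identity(cls) -> "ViewTransform":
        return cls(rotation=np.eye(3), scale=1.0)

    @classmethod
    def from_json(cls, path: str | Path) -> "ViewTransform":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            rotation=np.asarray(doc.get("rotation", np.eye(3).tolist()), dtype=float),
            scale=float(doc.get("scale", 1.0)),
        )


# ---------------------------------------------------------------------------
# PDB reading


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, tie → smallest altloc."""
    by_name: dict[str, list[Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name, group in by_name.items():
        best = min(group, key=lambda a: (-a.occupancy, a.altloc))
        out.append(best)
    return out


def _locate_bad_line(path: Path) -> int | None:
    """Best-effort line number of the first malformed ATOM coordinate field."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(("ATOM  ", "HETATM")):
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        try:
                            float(line[lo:hi])
                        except ValueError:
                            return lineno
    except OSError:
        return None
    return None


def read_pdb(path: str | Path, model: int = 1, include_het: bool = False) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path:
        PDB-format file.
    model:
        1-based model index (NMR ensembles); defaults to the first model.
    include_het:
        When true, HETATM residues other than water are kept as polymer
        residues (useful for modified residues present in SEQRES).  Waters
        are always excluded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        lineno = _locate_bad_line(path)
        where = f" (line {lineno})" if lineno else ""
        raise PDBParseError(f"{path}: malformed PDB record{where}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no ATOM records")
    if not 1 <= model <= len(st):
        raise PDBParseError(f"{path}: model {model} not present ({len(st)} models)")
    gm = st[model - 1]

    residues: list[Residue] = []
    chains: list[str] = []
    for gchain in gm:
        for gres in gchain:
            if gres.name == "HOH":
                continue
            if gres.het_flag == "H" and not include_het:
                continue
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    altloc=(ga.altloc if ga.altloc != "\x00" else ""),
                )
                for ga in gres
            ]
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain=gchain.name,
                    seq_num=gres.seqid.num,
                    ins_code=gres.seqid.icode.strip(),
                    aa3=gres.name,
                    atoms=_resolve_altlocs(atoms),
                )
            )
            if gchain.name not in chains:
                chains.append(gchain.name)
    if not residues:
        raise PDBParseError(f"{path}: no polymer ATOM records in model {model}")

    residues.sort(key=lambda r: (chains.index(r.chain), r.seq_num, r.ins_code))

    helices = [
        (h.start.chain_name, h.start.res_id.seqid.num, h.end.res_id.seqid.num)
        for h in st.helices
    ]
    strands = [
        (s.start.chain_name, s.start.res_id.seqid.num, s.end.res_id.seqid.num)
        for sheet in st.sheets
        for s in sheet.strands
    ]
    return Structure(
        id=st.name or path.stem,
        chains=chains,
        residues=residues,
        header_helices=helices,
        header_strands=strands,
    )


# ---------------------------------------------------------------------------
# PDB writing


def _format_atom_line(serial: int, atom: Atom, res: Residue) -> str:
    # PDB v3.3 fixed columns; 1-3 char atom names are indented one space
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    x, y, z = atom.coords
    return (
        f"ATOM  {serial:5d} {name}{atom.altloc or ' '}{res.aa3:>3s} "
        f"{res.chain:1s}{res.seq_num:4d}{res.ins_code or ' '}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a Structure as PDB text (ATOM/HELIX/SHEET/TER/END records)."""
    lines: list[str] = []
    n_h = n_e = 0
    for seg in s.ss_segments:
        res_in = [r for r in s.residues if seg.contains(r)]
        if not res_in:
            continue
        first, last = res_in[0], res_in[-1]
        if seg.kind == "helix":
            n_h += 1
            lines.append(
                f"HELIX  {n_h:3d} {n_h:3d} {first.aa3:>3s} {seg.chain:1s} {first.seq_num:4d}"
                f"{first.ins_code or ' '} {last.aa3:>3s} {seg.chain:1s} {last.seq_num:4d}"
                f"{last.ins_code or ' '} 1{'':30s}{len(res_in):6d}"
            )
        elif seg.kind == "strand":
            n_e += 1
            lines.append(
                f"SHEET  {n_e:3d}   S 1 {first.aa3:>3s} {seg.chain:1s}{first.seq_num:4d}"
                f"{first.ins_code or ' '} {last.aa3:>3s} {seg.chain:1s}{last.seq_num:4d}"
                f"{last.ins_code or ' '} 0"
            )
    serial = 0
    for i, res in enumerate(s.residues):
        if i > 0 and s.residues[i - 1].chain != res.chain:
            lines.append("TER")
        for atom in res.atoms:
            serial += 1
            lines.append(_format_atom_line(serial, atom, res))
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Secondary structure


def _dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees for four points."""
    b0 = -(p1 - p0)
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(residues: list[Residue]) -> list[tuple[float | None, float | None]]:
    """(phi, psi) per residue of one chain; None where atoms are missing."""
    out: list[tuple[float | None, float | None]] = []
    for i, res in enumerate(residues):
        phi = psi = None
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        if i > 0 and None not in (n, ca, c):
            c_prev = residues[i - 1].atom("C")
            if c_prev is not None:
                phi = _dihedral(c_prev.coords, n.coords, ca.coords, c.coords)
        if i < len(residues) - 1 and None not in (n, ca, c):
            n_next = residues[i + 1].atom("N")
            if n_next is not None:
                psi = _dihedral(n.coords, ca.coords, c.coords, n_next.coords)
        out.append((phi, psi))
    return out


def _is_helix(phi: float | None, psi: float | None) -> bool:
    return phi is not None and psi is not None and -100 < phi < -30 and -80 < psi < -5


def _is_strand(phi: float | None, psi: float | None) -> bool:
    if phi is None or psi is None:
        return False
    return -180 < phi < -40 and (90 < psi < 180 or -180 < psi < -170)


def _segments_from_labels(chain: str, residues: list[Residue], labels: list[str],
                          counters: dict[str, int]) -> list[SSSegment]:
    segs: list[SSSegment] = []
    i = 0
    prefix = {"helix": "H", "strand": "E", "loop": "L"}
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        kind = labels[i]
        counters[kind] += 1
        segs.append(
            SSSegment(
                segment_id=f"{prefix[kind]}{counters[kind]}",
                kind=kind,
                chain=chain,
                start=residues[i].seq_num,
                end=residues[j - 1].seq_num,
            )
        )
        i = j
    return segs


def assign_secondary_structure(s: Structure, source: str = "header") -> Structure:
    """Fill ``s.ss_segments`` in place (and return ``s``).

    ``source="header"`` uses the HELIX/SHEET records read from the source PDB;
    residues not covered become maximal loop runs.  ``source="dihedral"`` is a
    window-based fallback on backbone phi/psi angles: helix for runs of >= 4
    residues with phi in (-100, -30) and psi in (-80, -5); strand for runs of
    >= 3 with phi in (-180, -40) and psi in (90, 180) or (-180, -170).
    """
    if source not in ("header", "dihedral"):
        raise ValueError(f"unknown secondary-structure source {source!r}")
    segments: list[SSSegment] = []
    counters = {"helix": 0, "strand": 0, "loop": 0}
    if source == "header" and not (s.header_helices or s.header_strands):
        warnings.warn("no HELIX/SHEET records; assigning all residues to loops")
    for chain in s.chains:
        residues = s.chain_residues(chain)
        labels = ["loop"] * len(residues)
        if source == "header":
            for ch, start, end in s.header_helices:
                if ch != chain:
                    continue
                for k, r in enumerate(residues):
                    if start <= r.seq_num <= end:
                        labels[k] = "helix"
            for ch, start, end in s.header_strands:
                if ch != chain:
                    continue
                for k, r in enumerate(residues):
                    if start <= r.seq_num <= end:
                        labels[k] = "strand"
        else:
            dihedrals = backbone_dihedrals(residues)
            raw = []
            for phi, psi in dihedrals:
                if _is_helix(phi, psi):
                    raw.append("helix")
                elif _is_strand(phi, psi):
                    raw.append("strand")
                else:
                    raw.append("loop")
            # enforce minimum run lengths: helix >= 4, strand >= 3
            i = 0
            while i < len(raw):
                j = i
                while j < len(raw) and raw[j] == raw[i]:
                    j += 1
                run = j - i
                min_run = {"helix": 4, "strand": 3, "loop": 1}[raw[i]]
                labels[i:j] = [raw[i] if run >= min_run else "loop"] * run
                i = j
        segments.extend(_segments_from_labels(chain, residues, labels, counters))
    s.ss_segments = segments
    return s


# ---------------------------------------------------------------------------
# Projection


def project_coordinates(
    s: Structure, view: ViewTransform | None = None
) -> dict[str, np.ndarray]:
    """Project each residue's representative 3D point to the view plane.

    Returns ``{node_id: (x, y)}`` with ``p = scale * (rotation @ c)[:2]``.
    """
    if view is None:
        view = ViewTransform.identity()
    out: dict[str, np.ndarray] = {}
    for res in s.residues:
        if not res.atoms:
            raise ValueError(f"residue {res.node_id} has no atoms to project")
        c = res.representative_coords()
        out[res.node_id] = view.scale * (view.rotation @ c)[:2]
    return out
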