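"""Receptor and docking-pose I/O.

Receptor structures are plain PDB files read through :mod:`gemmi` and
flattened into a light in-memory :class:`Structure` (ordered atom list in a
single coordinate frame).  Docking pose ensembles come in two text dialects:

* multi-MODEL PDB with a per-model score remark
  (``REMARK VINA RESULT: -7.0 ...``), the format constructed fixtures use;
* AutoDock-family result text (PDBQT-like ATOM records inside MODEL blocks,
  energies on ``USER`` lines), the family the deposited ``*.dock4`` files
  belong to.

Scores are binding affinities in kcal/mol, more negative = better.  A third
helper generates cubic docking search boxes centred on Cα atoms, the scheme
used to tile a trimeric channel ectodomain with overlapping search volumes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Pose",
    "PoseEnsemble",
    "SearchBox",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "read_pose_ensemble",
    "write_pose_ensemble",
    "write_complexes",
    "make_search_boxes",
]


class StructureParseError(ValueError):
    """Raised when a structural file cannot be interpreted."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class Atom:
    """One atom record: identity plus Cartesian coordinates in Å."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    coords: np.ndarray
    icode: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite floats")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")
        if self.res_seq < 1:
            raise ValueError(f"atom {self.name}: res_seq must be >= 1, got {self.res_seq}")

    @property
    def res_key(self) -> str:
        """Residue number with any insertion code appended (e.g. ``"100A"``)."""
        return f"{self.res_seq}{self.icode}"

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def moved(self, coords: np.ndarray) -> "Atom":
        return Atom(self.serial, self.name, self.element, self.res_name,
                    self.res_seq, self.chain, np.asarray(coords, float), self.icode)


@dataclass
class Structure:
    """An ordered collection of atoms (one model, one frame)."""

    atoms: list[Atom]
    id: str = ""

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError(f"structure {self.id!r}: duplicate atom serials")

    @property
    def chains(self) -> set[str]:
        return {a.chain for a in self.atoms}

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def residue_atoms(self, chain: str, res_seq: int, icode: str = "") -> list[Atom]:
        return [a for a in self.atoms
                if a.chain == chain and a.res_seq == res_seq and a.icode == icode]

    def find_atom(self, chain: str, res_seq: int, name: str) -> Atom | None:
        for a in self.atoms:
            if a.chain == chain and a.res_seq == res_seq and a.name == name:
                return a
        return None

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Pose:
    """A scored ligand conformation (peptide atoms only)."""

    atoms: list[Atom]
    score: float
    pose_id: str

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"pose {self.pose_id!r}: needs at least one atom")
        if not np.isfinite(self.score):
            raise ValueError(f"pose {self.pose_id!r}: non-finite score")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def translated(self, t: np.ndarray, pose_id: str | None = None) -> "Pose":
        t = np.asarray(t, float)
        return Pose([a.moved(a.coords + t) for a in self.atoms],
                    self.score, pose_id or self.pose_id)

    def transformed(self, rot: np.ndarray, t: np.ndarray,
                    pose_id: str | None = None, score: float | None = None) -> "Pose":
        rot = np.asarray(rot, float)
        t = np.asarray(t, float)
        return Pose([a.moved(rot @ a.coords + t) for a in self.atoms],
                    self.score if score is None else score,
                    pose_id or self.pose_id)


@dataclass
class PoseEnsemble:
    """All scored poses of one peptide docked to one rigid receptor.

    Poses are kept sorted best-score-first (ascending affinity); every pose
    shares the receptor's coordinate frame.
    """

    peptide_name: str
    poses: list[Pose]
    receptor_id: str = ""

    def __post_init__(self) -> None:
        self.poses = sorted(self.poses, key=lambda p: (p.score, p.pose_id))

    @property
    def best_score(self) -> float:
        if not self.poses:
            raise ValueError(f"ensemble {self.peptide_name!r} is empty")
        return self.poses[0].score

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)


@dataclass
class SearchBox:
    """Cubic docking search volume centred on a landmark atom."""

    center: np.ndarray
    side: float
    label: str

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.side <= 0:
            raise ValueError(f"search box {self.label!r}: side must be > 0")

    def to_vina_config(self) -> str:
        cx, cy, cz = self.center
        return (f"center_x = {cx:.3f}\ncenter_y = {cy:.3f}\ncenter_z = {cz:.3f}\n"
                f"size_x = {self.side:.3f}\nsize_y = {self.side:.3f}\nsize_z = {self.side:.3f}\n")


# ---------------------------------------------------------------------------
# element inference
# ---------------------------------------------------------------------------

# PDBQT atom types that are not bare element symbols
_PDBQT_TYPES = {
    "A": "C", "OA": "O", "NA": "N", "SA": "S", "HD": "H", "HS": "H",
    "NX": "N", "OS": "O", "NS": "N", "CL": "Cl", "BR": "Br",
}

_TWO_LETTER = {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "CA", "SE"}


def _element_from_name(name: str, res_name: str = "") -> str:
    """Fallback element inference from an atom name."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    # two-letter ions only when the residue is the ion itself
    if stripped[:2].upper() in _TWO_LETTER and res_name.strip().upper() == stripped[:2].upper():
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _element_from_columns(line: str, name: str, res_name: str) -> str:
    tail = line[76:79].strip().upper() if len(line) > 76 else ""
    if tail in _PDBQT_TYPES:
        return _PDBQT_TYPES[tail]
    if tail and tail.isalpha():
        return tail.capitalize() if len(tail) == 2 else tail
    return _element_from_name(name, res_name)


# ---------------------------------------------------------------------------
# receptor reading / writing
# ---------------------------------------------------------------------------


def read_structure(path: str | Path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Atoms are returned in file order; only the first model and the first
    alternate location of each atom are kept; elements come from columns
    77–78 with an atom-name fallback.
    """
    path = Path(path)
    if not path.is_file():
        raise StructureParseError(f"cannot read structure file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models / no ATOM records")

    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            seen: set[str] = set()
            for at in res:
                if at.altloc and at.name in seen:  # keep first altloc only
                    continue
                if at.altloc:
                    seen.add(at.name)
                el = at.element.name if at.element and at.element.name != "X" else ""
                if not el:
                    el = _element_from_name(at.name, res.name)
                atoms.append(Atom(
                    serial=at.serial,
                    name=at.name,
                    element=el,
                    res_name=res.name,
                    res_seq=res.seqid.num,
                    chain=chain.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    icode=(res.seqid.icode or "").strip(),
                ))
    if not atoms:
        raise StructureParseError(f"{path}: zero ATOM records")
    return Structure(atoms=atoms, id=path.stem)


def _pdb_atom_line(a: Atom, serial: int | None = None) -> str:
    name = a.name
    if len(name) < 4:
        # element in columns 13–14 for single-letter elements
        name = (" " + name) if len(a.element) == 1 else name
    el = a.element.upper().rjust(2)[:2]
    return (f"ATOM  {serial if serial is not None else a.serial:>5d} "
            f"{name:<4s} {a.res_name:>3s} {a.chain[:1]:1s}{a.res_seq:>4d}"
            f"{a.icode[:1] or ' '}   "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {el}")


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as fixed-column PDB (coordinates to 3 dp)."""
    lines = [_pdb_atom_line(a) for a in structure.atoms]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pose-ensemble reading / writing
# ---------------------------------------------------------------------------

_SCORE_PATTERNS = [
    re.compile(r"VINA\s+RESULT:\s*([-+]?\d+(?:\.\d+)?)"),
    re.compile(r"Free\s+Energy\s+of\s+Binding\s*[:=]?\s*([-+]?\d+(?:\.\d+)?)", re.I),
    re.compile(r"Binding\s+energy\s*[:=]?\s*([-+]?\d+(?:\.\d+)?)", re.I),
    re.compile(r"\bScore\s*[:=]\s*([-+]?\d+(?:\.\d+)?)", re.I),
]


def _parse_pose_atoms(lines: list[str]) -> list[Atom]:
    atoms = []
    serial = 0
    for ln in lines:
        if not (ln.startswith("ATOM") or ln.startswith("HETATM")):
            continue
        serial += 1
        try:
            ser = int(ln[6:11])
        except ValueError:
            ser = serial
        name = ln[12:16].strip()
        res_name = ln[17:20].strip()
        chain = ln[21:22].strip() or "L"
        try:
            res_seq = int(ln[22:26])
        except ValueError as exc:
            raise StructureParseError(f"bad residue number in line: {ln.rstrip()}") from exc
        icode = ln[26:27].strip()
        try:
            xyz = np.array([float(ln[30:38]), float(ln[38:46]), float(ln[46:54])])
        except ValueError as exc:
            raise StructureParseError(f"bad coordinates in line: {ln.rstrip()}") from exc
        el = _element_from_columns(ln, name, res_name)
        atoms.append(Atom(ser, name, el, res_name, res_seq, chain, xyz, icode))
    return atoms


def _find_score(lines: list[str]) -> float | None:
    for ln in lines:
        if not (ln.startswith("REMARK") or ln.startswith("USER")):
            continue
        for pat in _SCORE_PATTERNS:
            m = pat.search(ln)
            if m:
                return float(m.group(1))
    return None


def read_pose_ensemble(path: str | Path, peptide_name: str,
                       receptor_id: str = "") -> PoseEnsemble:
    """Read a multi-pose docking result file.

    Supports multi-MODEL PDB with ``REMARK VINA RESULT`` scores and
    AutoDock-family result text (``USER``-tagged energy lines, PDBQT-like
    atom records).  Poses are returned sorted best-score-first regardless of
    file order.
    """
    path = Path(path)
    if not path.is_file():
        raise StructureParseError(f"cannot read pose file: {path}")
    text = path.read_text()

    # split into MODEL blocks; a file without MODEL records is one block
    blocks: list[tuple[str, list[str]]] = []
    current: list[str] | None = None
    model_id = ""
    for ln in text.splitlines():
        if ln.startswith("MODEL"):
            current = []
            parts = ln.split()
            model_id = parts[1] if len(parts) > 1 else str(len(blocks) + 1)
        elif ln.startswith("ENDMDL"):
            if current is not None:
                blocks.append((model_id, current))
            current = None
        elif current is not None:
            current.append(ln)
    if not blocks:
        blocks = [("1", text.splitlines())]

    poses: list[Pose] = []
    for idx, (mid, lines) in enumerate(blocks, start=1):
        atoms = _parse_pose_atoms(lines)
        if not atoms:
            continue
        score = _find_score(lines)
        if score is None:
            raise StructureParseError(
                f"{path}: pose/model {mid} has no parseable score record")
        poses.append(Pose(atoms, score, pose_id=f"{peptide_name}_m{mid}"))
    if not poses:
        raise StructureParseError(f"{path}: no poses found")
    return PoseEnsemble(peptide_name=peptide_name, poses=poses,
                        receptor_id=receptor_id)


def write_pose_ensemble(ensemble: PoseEnsemble, path: str | Path) -> None:
    """Write an ensemble as multi-MODEL PDB with VINA-style score remarks."""
    lines: list[str] = []
    for i, pose in enumerate(ensemble.poses, start=1):
        lines.append(f"MODEL     {i:>4d}")
        lines.append(f"REMARK VINA RESULT:    {pose.score:8.3f}      0.000      0.000")
        lines.extend(_pdb_atom_line(a) for a in pose.atoms)
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_complexes(receptor: Structure, poses: Sequence[Pose],
                    path: str | Path) -> None:
    """Write receptor + each selected pose as one multi-MODEL PDB file."""
    lines: list[str] = []
    for i, pose in enumerate(poses, start=1):
        lines.append(f"MODEL     {i:>4d}")
        lines.append(f"REMARK POSE {pose.pose_id} SCORE {pose.score:.3f}")
        serial = 0
        for a in receptor.atoms:
            serial += 1
            lines.append(_pdb_atom_line(a, serial=serial))
        for a in pose.atoms:
            serial += 1
            lines.append(_pdb_atom_line(a, serial=serial))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# search boxes
# ---------------------------------------------------------------------------


def make_search_boxes(structure: Structure,
                      residue_ids: Iterable[tuple[str, int, str]],
                      side: float = 35.0) -> list[SearchBox]:
    """One cubic search box per (chain, residue), centred on its Cα.

    ``residue_ids`` are ``(chain, res_seq, res_name)`` triples; the residue
    name is checked when non-empty.  Tiling a trimer with four residues per
    subunit yields the twelve overlapping boxes used to cover the whole
    ectodomain.
    """
    boxes = []
    for chain, res_seq, res_name in residue_ids:
        ca = structure.find_atom(chain, res_seq, "CA")
        if ca is None:
            raise ValueError(
                f"residue {res_name or '?'}{res_seq} chain {chain}: missing or has no CA atom")
        if res_name and ca.res_name.strip().upper() != res_name.strip().upper():
            raise ValueError(
                f"residue {res_seq} chain {chain}: expected {res_name}, found {ca.res_name}")
        boxes.append(SearchBox(center=ca.coords.copy(), side=side,
                               label=f"{ca.res_name}{res_seq}:{chain}"))
    return boxes
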