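"""Grid-based cavity detection, pose-to-pocket assignment and
protein–peptide interaction fingerprints.

Cavity volumes are computed on a rectilinear voxel grid as a documented
approximation to alpha-shape pocket measurement: the reported quantity is
the solvent-accessible cavity volume a spherical probe (default radius
1.4 Å) can delimit.  Algorithm:

1. lay a grid with padding around the structure;
2. mark voxels inside the van der Waals surface (volume grid) and inside
   the probe-inflated surface (connectivity grid for probe centres);
3. flood-fill probe-centre space from the grid boundary (6-connectivity) to
   find bulk solvent, then dilate bulk probe centres by the probe radius —
   every point a bulk probe can touch;
4. remaining vdW-free, non-bulk connected components (26-connectivity) are
   cavities; volume = voxel_count x spacing^3.  A cavity is ``sealed`` when
   its voxels have no vdW-level path to the boundary (e.g. a fully enclosed
   void); pockets reachable through a mouth narrower than the probe are
   reported unsealed.

Interaction detection uses standard geometric criteria (thresholds exposed
in :class:`InteractionCriteria`) over fixed per-residue chemistry tables —
the same classes 2-D interaction diagrams report: hydrogen bonds,
hydrophobic contacts, ring stacking, cation-π and salt bridges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure_io import Atom, Pose, Structure

__all__ = [
    "GridSpec",
    "PocketRegion",
    "CavityMap",
    "Interaction",
    "InteractionFingerprint",
    "InteractionCriteria",
    "probe_accessible_cavities",
    "assign_pose_pocket",
    "detect_interactions",
    "load_landmarks",
    "default_landmarks",
    "write_cavities_tsv",
    "write_fingerprints_tsv",
]

# Bondi-style united-atom radii; hydrogens are ignored by all grid algorithms
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
FALLBACK_RADIUS = 1.70


@dataclass
class GridSpec:
    """Voxel-grid parameters for cavity detection.

    spacing: voxel edge, Å.  probe_radius: solvent probe, Å (1.4 = water;
    2.0 separates pockets connected through narrow channels).  padding: bulk
    solvent margin around the structure, Å.  min_volume: discard cavity
    slivers below this many Å^3.  voxel_budget: hard cap on grid size.
    """

    spacing: float = 0.5
    probe_radius: float = 1.4
    padding: float = 4.0
    radii_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    min_volume: float = 20.0
    voxel_budget: int = 60_000_000

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")

    def radius_of(self, element: str) -> float:
        return self.radii_table.get(element.upper().capitalize(),
                                    self.radii_table.get(element.upper(), FALLBACK_RADIUS))


@dataclass
class PocketRegion:
    """One detected cavity: voxels, volume and the residues lining it."""

    label: str
    voxel_count: int
    volume: float
    centroid: np.ndarray
    lining_residues: list[tuple[str, int, str]]
    sealed: bool
    voxel_indices: np.ndarray = field(repr=False, default=None)
    parent_map: "CavityMap" = field(repr=False, default=None, compare=False)

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("cavity volume must be > 0")


@dataclass
class CavityMap:
    """Cavity regions plus the grids needed for burial-depth queries.

    Iterable/indexable as the list of :class:`PocketRegion`.
    """

    regions: list[PocketRegion]
    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    free_vdw: np.ndarray = field(repr=False)
    bulk_solvent: np.ndarray = field(repr=False)
    _depth: np.ndarray | None = field(default=None, repr=False)

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, float) * self.spacing

    def nearest_free_voxel(self, point: np.ndarray) -> tuple[int, int, int]:
        """Grid index of the accessible (vdW-free) voxel nearest to a point."""
        idx = np.clip(np.round((np.asarray(point, float) - self.origin) / self.spacing),
                      0, np.array(self.shape) - 1).astype(int)
        if self.free_vdw[tuple(idx)]:
            return tuple(idx)
        # expand a small search window until a free voxel is found
        for r in range(1, max(self.shape)):
            lo = np.maximum(idx - r, 0)
            hi = np.minimum(idx + r + 1, self.shape)
            sub = self.free_vdw[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            if sub.any():
                cand = np.argwhere(sub) + lo
                d = np.linalg.norm(cand - idx, axis=1)
                return tuple(cand[int(np.argmin(d))])
        raise ValueError("no accessible voxel in grid")

    @property
    def depth_grid(self) -> np.ndarray:
        """Burial depth (Å) of every accessible voxel: 6-connected BFS path
        length to bulk solvent; inf where unreachable (sealed voids)."""
        if self._depth is None:
            depth = np.full(self.shape, np.inf)
            frontier = self.bulk_solvent & self.free_vdw
            visited = frontier.copy()
            struct = ndimage.generate_binary_structure(3, 1)
            d = 0.0
            while frontier.any():
                depth[frontier] = d
                grown = ndimage.binary_dilation(frontier, structure=struct)
                frontier = grown & self.free_vdw & ~visited
                visited |= frontier
                d += self.spacing
            self._depth = depth
        return self._depth

    def burial_depth(self, point: np.ndarray) -> float:
        return float(self.depth_grid[self.nearest_free_voxel(point)])


# ---------------------------------------------------------------------------
# cavity detection
# ---------------------------------------------------------------------------


def _occupancy(coords: np.ndarray, radii: np.ndarray, origin: np.ndarray,
               shape: tuple[int, int, int], spacing: float, inflate: float) -> np.ndarray:
    """Boolean grid: voxel centre within (radius + inflate) of any atom."""
    occ = np.zeros(shape, dtype=bool)
    nx, ny, nz = shape
    for c, r in zip(coords, radii):
        rr = r + inflate
        lo = np.maximum(np.floor((c - rr - origin) / spacing), 0).astype(int)
        hi = np.minimum(np.ceil((c + rr - origin) / spacing) + 1,
                        [nx, ny, nz]).astype(int)
        if np.any(lo >= hi):
            continue
        ax = origin[0] + np.arange(lo[0], hi[0]) * spacing - c[0]
        ay = origin[1] + np.arange(lo[1], hi[1]) * spacing - c[1]
        az = origin[2] + np.arange(lo[2], hi[2]) * spacing - c[2]
        d2 = (ax[:, None, None] ** 2 + ay[None, :, None] ** 2 + az[None, None, :] ** 2)
        occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= rr * rr
    return occ


def _boundary_labels(labels: np.ndarray) -> set[int]:
    faces = [labels[0], labels[-1], labels[:, 0], labels[:, -1],
             labels[:, :, 0], labels[:, :, -1]]
    out: set[int] = set()
    for f in faces:
        out.update(np.unique(f).tolist())
    out.discard(0)
    return out


def _bulk_mask(free: np.ndarray) -> np.ndarray:
    """Connected components of free space (6-conn) reaching the grid boundary."""
    struct = ndimage.generate_binary_structure(3, 1)
    labels, _ = ndimage.label(free, structure=struct)
    keep = _boundary_labels(labels)
    if not keep:
        return np.zeros_like(free)
    return np.isin(labels, sorted(keep))


def probe_accessible_cavities(structure: Structure, spec: GridSpec | None = None,
                              landmarks: dict[str, list[str]] | None = None) -> CavityMap:
    """Detect probe-inaccessible cavities of a structure and their volumes.

    Returns a :class:`CavityMap` whose regions are sorted by volume
    (largest first) and labelled ``cavity_01`` ... unless a landmark residue
    set matches (see :func:`load_landmarks`).
    """
    spec = spec or GridSpec()
    heavy = structure.heavy_atoms()
    if not heavy:
        raise ValueError("structure has no heavy atoms")
    coords = np.array([a.coords for a in heavy])
    radii = np.array([spec.radius_of(a.element) for a in heavy])

    margin = radii.max() + spec.probe_radius + spec.padding
    origin = coords.min(axis=0) - margin
    top = coords.max(axis=0) + margin
    shape = tuple(int(np.ceil((top[i] - origin[i]) / spec.spacing)) + 1 for i in range(3))
    n_vox = int(np.prod(shape))
    if n_vox > spec.voxel_budget:
        raise ValueError(
            f"grid of {n_vox} voxels exceeds budget {spec.voxel_budget}; "
            f"use coarser spacing (current {spec.spacing} Å)")

    occ_vdw = _occupancy(coords, radii, origin, shape, spec.spacing, 0.0)
    occ_probe = _occupancy(coords, radii, origin, shape, spec.spacing, spec.probe_radius)
    free_vdw = ~occ_vdw
    free_probe = ~occ_probe

    bulk_pc = _bulk_mask(free_probe)
    # every point within probe_radius of a bulk probe centre is bulk solvent;
    # half a voxel diagonal compensates for probe centres living off-grid
    dist = ndimage.distance_transform_edt(~bulk_pc, sampling=spec.spacing)
    bulk_solvent = dist <= spec.probe_radius + 0.5 * np.sqrt(3.0) * spec.spacing

    cavity_space = free_vdw & ~bulk_solvent
    struct26 = ndimage.generate_binary_structure(3, 3)
    labels, n_lab = ndimage.label(cavity_space, structure=struct26)

    bulk_vdw = _bulk_mask(free_vdw)

    regions: list[tuple[int, np.ndarray]] = []
    for lab in range(1, n_lab + 1):
        vox = np.argwhere(labels == lab)
        vol = len(vox) * spec.spacing ** 3
        if vol < spec.min_volume:
            continue
        regions.append((lab, vox))
    regions.sort(key=lambda t: (-len(t[1]), t[0]))

    atom_tree = cKDTree(coords)
    lining_reach = spec.probe_radius + spec.spacing

    cavity_map = CavityMap(regions=[], origin=origin, spacing=spec.spacing,
                           shape=shape, free_vdw=free_vdw, bulk_solvent=bulk_solvent)
    for rank, (lab, vox) in enumerate(regions, start=1):
        centers = origin + vox * spec.spacing
        idx_sets = atom_tree.query_ball_point(centers, r=radii.max() + lining_reach)
        lining_idx: set[int] = set()
        for ctr, hits in zip(centers, idx_sets):
            for ai in hits:
                if np.linalg.norm(coords[ai] - ctr) <= radii[ai] + lining_reach:
                    lining_idx.add(ai)
        lining = sorted({(heavy[i].chain, heavy[i].res_seq, heavy[i].res_name)
                         for i in lining_idx})
        sealed = not bool(bulk_vdw[tuple(vox.T)].any())
        region = PocketRegion(
            label=f"cavity_{rank:02d}",
            voxel_count=len(vox),
            volume=len(vox) * spec.spacing ** 3,
            centroid=centers.mean(axis=0),
            lining_residues=lining,
            sealed=sealed,
            voxel_indices=vox,
            parent_map=cavity_map,
        )
        cavity_map.regions.append(region)

    if landmarks:
        _apply_landmarks(cavity_map.regions, landmarks)
    return cavity_map


_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _apply_landmarks(regions: list[PocketRegion],
                     landmarks: dict[str, list[str]]) -> None:
    """Rename regions whose lining contains a full landmark residue set.

    Landmarks are one-letter + residue-number strings (e.g. ``"D237"``),
    matched on any chain.  If several regions qualify for one label the
    largest wins; each region takes at most one name.
    """
    taken: set[int] = set()
    for name, residues in landmarks.items():
        want = set(residues)
        best, best_vol = None, -1.0
        for i, reg in enumerate(regions):
            if i in taken:
                continue
            have = {f"{_ONE_LETTER.get(rn, 'X')}{rs}" for _, rs, rn in reg.lining_residues}
            if want <= have and reg.volume > best_vol:
                best, best_vol = i, reg.volume
        if best is not None:
            regions[best].label = name
            taken.add(best)


def default_landmarks() -> dict[str, list[str]]:
    """Shipped landmark residue sets (human ASIC1a numbering)."""
    with resources.files("rfamap.data").joinpath("asic1a_landmarks.json").open() as fh:
        return json.load(fh)


def load_landmarks(path: str | Path) -> dict[str, list[str]]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: landmark file must map label -> residue list")
    return data


# ---------------------------------------------------------------------------
# pose -> pocket assignment
# ---------------------------------------------------------------------------


def assign_pose_pocket(pose: Pose, cavities: CavityMap | Sequence[PocketRegion],
                       spec: GridSpec | None = None, contact_dist: float = 2.0,
                       min_fraction: float = 0.25) -> str | None:
    """Label of the cavity containing the pose, or ``None`` if unassigned.

    A pose belongs to the cavity holding the largest number of its heavy
    atoms within ``contact_dist`` Å of a cavity voxel centre; below
    ``min_fraction`` of the heavy atoms it stays unassigned.  Ties break on
    larger cavity volume, then label order.
    """
    regions = list(cavities)
    if not regions:
        raise ValueError("empty cavity list")
    heavy = np.array([a.coords for a in pose.heavy_atoms()])

    scored = []
    for reg in regions:
        cmap = reg.parent_map
        centers = cmap.voxel_centers(reg.voxel_indices) if cmap is not None \
            else np.asarray(reg.voxel_indices, float)
        tree = cKDTree(centers)
        d, _ = tree.query(heavy, k=1)
        scored.append((int(np.sum(d <= contact_dist)), reg.volume, reg.label))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    count, _, label = scored[0]
    if count < min_fraction * len(heavy):
        return None
    return label


# ---------------------------------------------------------------------------
# interaction fingerprints
# ---------------------------------------------------------------------------


@dataclass
class InteractionCriteria:
    """Geometric thresholds for contact typing (all distances in Å)."""

    hbond_dist: float = 3.5
    hbond_angle: float = 120.0   # D-H...A, degrees, when an H is present
    hydrophobic_dist: float = 4.0
    stacking_dist: float = 5.0
    stacking_parallel_max: float = 30.0  # inter-plane angle, degrees
    stacking_tshape_min: float = 60.0
    stacking_tshape_max: float = 90.0
    cation_pi_dist: float = 6.0
    salt_bridge_dist: float = 4.0


@dataclass
class Interaction:
    kind: str  # hbond | hydrophobic | stacking | cation_pi | salt_bridge
    peptide_atom: str  # e.g. "ARG3:NH1" or "PHE4:ring"
    receptor_residue: tuple[str, int, str]
    distance: float
    angle: float | None = None

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("interaction distance must be > 0")


@dataclass
class InteractionFingerprint:
    pose_id: str
    interactions: list[Interaction]


# chemistry tables (standard residues; the amide cap donates like a backbone N)
_SIDE_DONORS = {
    "ARG": ["NE", "NH1", "NH2"], "LYS": ["NZ"], "SER": ["OG"], "THR": ["OG1"],
    "TYR": ["OH"], "ASN": ["ND2"], "GLN": ["NE2"], "HIS": ["ND1", "NE2"],
    "TRP": ["NE1"], "CYS": ["SG"],
}
_SIDE_ACCEPTORS = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"], "GLN": ["OE1"],
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "HIS": ["ND1", "NE2"],
    "MET": ["SD"],
}
_APOLAR_C = {
    "ALA": ["CB"], "ARG": ["CB", "CG"], "ASN": ["CB"], "ASP": ["CB"],
    "CYS": ["CB"], "GLN": ["CB", "CG"], "GLU": ["CB", "CG"], "HIS": ["CB"],
    "ILE": ["CB", "CG1", "CG2", "CD1"], "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD"], "MET": ["CB", "CG", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["CB", "CG", "CD"], "THR": ["CG2"],
    "TRP": ["CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2"],
    "VAL": ["CB", "CG1", "CG2"],
}
_RINGS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
}
_CATION_CENTERS = {"ARG": ["CZ"], "LYS": ["NZ"]}
_SALT_CATIONS = {"ARG": ["NE", "NH1", "NH2"], "LYS": ["NZ"]}
_SALT_ANIONS = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}


def _res_groups(atoms: Sequence[Atom]) -> list[list[Atom]]:
    groups: list[list[Atom]] = []
    key = None
    for a in atoms:
        k = (a.chain, a.res_seq, a.icode)
        if k != key:
            groups.append([])
            key = k
        groups[-1].append(a)
    return groups


def _atom_label(a: Atom) -> str:
    return f"{a.res_name}{a.res_seq}:{a.name}"


def _res_id(a: Atom) -> tuple[str, int, str]:
    return (a.chain, a.res_seq, a.res_name)


def _donors(res: list[Atom], is_peptide: bool, last: bool) -> list[Atom]:
    rn = res[0].res_name.upper()
    names = set(_SIDE_DONORS.get(rn, []))
    if rn != "PRO":
        names.add("N")
    if rn in {"NH2", "NHE", "CONH2"}:
        names.update({"N", "NT", "NH2", "NXT"})
    return [a for a in res if a.name in names and a.is_heavy]


def _acceptors(res: list[Atom]) -> list[Atom]:
    rn = res[0].res_name.upper()
    names = set(_SIDE_ACCEPTORS.get(rn, []))
    names.update({"O", "OXT"})
    return [a for a in res if a.name in names and a.is_heavy]


def _hydrogens_near(res: list[Atom], donor: Atom, cutoff: float = 1.3) -> list[Atom]:
    return [a for a in res if a.element.upper() == "H"
            and np.linalg.norm(a.coords - donor.coords) <= cutoff]


def _ring_geometry(res: list[Atom]) -> list[tuple[np.ndarray, np.ndarray]]:
    """(centroid, unit normal) of each aromatic ring present in a residue."""
    rn = res[0].res_name.upper()
    out = []
    for names in _RINGS.get(rn, []):
        pts = [a.coords for n in names for a in res if a.name == n]
        if len(pts) < len(names):
            continue
        pts = np.array(pts)
        centroid = pts.mean(axis=0)
        # plane normal via SVD of centred coordinates
        _, _, vt = np.linalg.svd(pts - centroid)
        out.append((centroid, vt[2] / np.linalg.norm(vt[2])))
    return out


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.clip(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)
    return float(np.degrees(np.arccos(c)))


def detect_interactions(pose: Pose, structure: Structure,
                        criteria: InteractionCriteria | None = None) -> InteractionFingerprint:
    """Type all peptide–receptor contacts satisfying the geometric criteria.

    One :class:`Interaction` per (peptide atom or ring, receptor residue,
    kind), carrying the minimal distance; deterministic ordering.  Uses only
    pairwise geometry, hence invariant under global rigid motion of the
    complex and under chain relabelling.
    """
    crit = criteria or InteractionCriteria()
    pep_res = _res_groups(pose.atoms)
    rec_atoms = structure.atoms

    # prefilter receptor residues near the pose
    pose_xyz = pose.coords
    reach = max(crit.hbond_dist, crit.hydrophobic_dist, crit.stacking_dist,
                crit.cation_pi_dist, crit.salt_bridge_dist) + 3.0
    tree = cKDTree(np.array([a.coords for a in rec_atoms]))
    near_idx = sorted({i for hits in tree.query_ball_point(pose_xyz, r=reach)
                       for i in hits})
    near_res = _res_groups([rec_atoms[i] for i in near_idx])

    found: dict[tuple[str, str, tuple], tuple[float, float | None]] = {}

    def record(kind: str, pep_label: str, rec_res: tuple, dist: float,
               angle: float | None = None) -> None:
        key = (kind, pep_label, rec_res)
        if key not in found or dist < found[key][0]:
            found[key] = (dist, angle)

    n_pep = len(pep_res)
    for pi, pres in enumerate(pep_res):
        p_rings = _ring_geometry(pres)
        rn = pres[0].res_name.upper()
        p_apolar = [a for a in pres if a.name in _APOLAR_C.get(rn, [])]
        p_cations = [a for a in pres if a.name in _SALT_CATIONS.get(rn, [])]
        if pi == 0:  # free N-terminal amine is positively charged
            p_cations += [a for a in pres if a.name == "N"]
        p_cation_centers = [a for a in pres if a.name in _CATION_CENTERS.get(rn, [])]
        p_donors = _donors(pres, True, pi == n_pep - 1)
        p_acceptors = _acceptors(pres)

        for rres in near_res:
            rrn = rres[0].res_name.upper()
            rid = _res_id(rres[0])

            # hydrogen bonds, both directions
            for donor_side, d_list, a_list in (
                    ("pep", p_donors, _acceptors(rres)),
                    ("rec", _donors(rres, False, False), p_acceptors)):
                d_res = pres if donor_side == "pep" else rres
                for d in d_list:
                    for acc in a_list:
                        dist = float(np.linalg.norm(d.coords - acc.coords))
                        if dist > crit.hbond_dist:
                            continue
                        angle = None
                        hs = _hydrogens_near(d_res, d)
                        if hs:
                            angle = max(_angle_deg(d.coords - h.coords,
                                                   acc.coords - h.coords) for h in hs)
                            if angle < crit.hbond_angle:
                                continue
                        pep_atom = d if donor_side == "pep" else acc
                        record("hbond", _atom_label(pep_atom), rid, dist, angle)

            # hydrophobic contacts (apolar carbon pairs)
            r_apolar = [a for a in rres if a.name in _APOLAR_C.get(rrn, [])]
            for pa in p_apolar:
                for ra in r_apolar:
                    dist = float(np.linalg.norm(pa.coords - ra.coords))
                    if dist <= crit.hydrophobic_dist:
                        record("hydrophobic", _atom_label(pa), rid, dist)

            # ring stacking
            r_rings = _ring_geometry(rres)
            for rc, (pc, pn) in enumerate(p_rings):
                for cc, cn in r_rings:
                    dist = float(np.linalg.norm(pc - cc))
                    if dist > crit.stacking_dist:
                        continue
                    ang = _angle_deg(pn, cn)
                    ang = min(ang, 180.0 - ang)  # plane angle in [0, 90]
                    if (ang <= crit.stacking_parallel_max
                            or crit.stacking_tshape_min <= ang <= crit.stacking_tshape_max):
                        record("stacking", f"{rn}{pres[0].res_seq}:ring", rid, dist, ang)

            # cation-pi, both directions
            for cat in p_cation_centers:
                for cc, _ in r_rings:
                    dist = float(np.linalg.norm(cat.coords - cc))
                    if dist <= crit.cation_pi_dist:
                        record("cation_pi", _atom_label(cat), rid, dist)
            r_cation_centers = [a for a in rres if a.name in _CATION_CENTERS.get(rrn, [])]
            for pc, _ in p_rings:
                for cat in r_cation_centers:
                    dist = float(np.linalg.norm(pc - cat.coords))
                    if dist <= crit.cation_pi_dist:
                        record("cation_pi", f"{rn}{pres[0].res_seq}:ring", rid, dist)

            # salt bridges, both directions
            r_anions = [a for a in rres if a.name in _SALT_ANIONS.get(rrn, [])]
            r_cations = [a for a in rres if a.name in _SALT_CATIONS.get(rrn, [])]
            p_anions = [a for a in pres if a.name in _SALT_ANIONS.get(rn, [])]
            for cat in p_cations:
                for an in r_anions:
                    dist = float(np.linalg.norm(cat.coords - an.coords))
                    if dist <= crit.salt_bridge_dist:
                        record("salt_bridge", _atom_label(cat), rid, dist)
            for an in p_anions:
                for cat in r_cations:
                    dist = float(np.linalg.norm(an.coords - cat.coords))
                    if dist <= crit.salt_bridge_dist:
                        record("salt_bridge", _atom_label(an), rid, dist)

    interactions = [Interaction(kind=k, peptide_atom=pa, receptor_residue=rr,
                                distance=round(d, 4), angle=ang)
                    for (k, pa, rr), (d, ang) in sorted(found.items())]
    return InteractionFingerprint(pose_id=pose.pose_id, interactions=interactions)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_cavities_tsv(cavities: Iterable[PocketRegion], path: str | Path) -> None:
    lines = ["label\tvolume_A3\tsealed\tvoxels\tlining_residues"]
    for c in cavities:
        lining = ",".join(f"{ch}:{rn}{rs}" for ch, rs, rn in c.lining_residues)
        lines.append(f"{c.label}\t{c.volume:.1f}\t{c.sealed}\t{c.voxel_count}\t{lining}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fingerprints_tsv(fps: Iterable[InteractionFingerprint],
                           path: str | Path) -> None:
    lines = ["pose\tkind\tpeptide_atom\treceptor_residue\tdistance_A\tangle_deg"]
    for fp in fps:
        for x in fp.interactions:
            ch, rs, rn = x.receptor_residue
            ang = f"{x.angle:.1f}" if x.angle is not None else ""
            lines.append(f"{fp.pose_id}\t{x.kind}\t{x.peptide_atom}\t"
                         f"{ch}:{rn}{rs}\t{x.distance:.3f}\t{ang}")
    Path(path).write_text("\n".join(lines) + "\n")
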