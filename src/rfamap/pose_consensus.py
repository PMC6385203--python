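"""Cross-peptide docking-pose consensus selection.

RFamide neuropeptides share a C-terminal Arg-Phe-NH2 (RFa) motif, so two
different RFa peptides docked to the same rigid receptor should place that
moiety similarly if a pose reflects a binding mode common to the peptide
family.  The selection procedure implemented here:

1. keep poses of peptide A scoring within an energy window (default
   1 kcal/mol) of its best pose;
2. for each surviving A pose, compute the RMSD over the 9 heavy atoms of the
   RFa moiety (Arg and Phe backbone N/CA, side-chain CG/CZ, plus the
   C-terminal amide nitrogen) against every pose of peptide B;
3. keep A poses whose best partner lies below an RMSD cutoff (default,
   strictly below 1 Å) — these are the consensus binding modes;
4. optionally require the peptide N-terminus to point towards the pocket
   entrance (shallower burial than the C-terminal amide), since longer
   family members extend from the N-terminus.

No superposition is performed before the RMSD: both ensembles share the
receptor frame, so rigid fitting would be the identity.  An optional
receptor-Cα alignment is provided for inputs that do not share a frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TYPE_CHECKING

import numpy as np

from .structure_io import Atom, Pose, PoseEnsemble, Structure

if TYPE_CHECKING:  # pragma: no cover
    from .pocket_analysis import PocketRegion

__all__ = [
    "RfaFrame",
    "ConsensusParams",
    "ConsensusMatch",
    "RfaMotifError",
    "extract_rfa_frame",
    "rfa_rmsd",
    "energy_window",
    "match_consensus",
    "nterm_orientation_ok",
    "align_to_receptor",
    "write_matches_tsv",
]

# canonical atom order of the RFa frame
RFA_FRAME_ORDER = ("Arg N", "Arg CA", "Arg CG", "Arg CZ",
                   "Phe N", "Phe CA", "Phe CG", "Phe CZ", "amide N")

# C-terminal amide nitrogen naming varies between structure builders
AMIDE_N_ALIASES = {"NT", "NH2", "NXT"}
AMIDE_CAP_RESIDUES = {"NH2", "NHE", "CONH2"}


class RfaMotifError(ValueError):
    """Raised when a pose lacks the C-terminal Arg-Phe-amide motif."""


@dataclass
class RfaFrame:
    """The 9 ordered heavy-atom coordinates of a pose's RFa moiety (Å)."""

    coords: np.ndarray  # (9, 3)
    source_pose: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (9, 3):
            raise ValueError(f"RfaFrame needs exactly 9 points, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("RfaFrame coordinates must be finite")


@dataclass
class ConsensusParams:
    """Tunables of the consensus run.

    energy_window: kcal/mol retained around the best score of peptide A.
    rmsd_cutoff: Å; matches require RFa RMSD strictly below this.
    window_b: also energy-window peptide B before matching (off by default;
        the reference procedure compares windowed A poses with *all* B poses).
    """

    energy_window: float = 1.0
    rmsd_cutoff: float = 1.0
    window_b: bool = False

    def __post_init__(self) -> None:
        if self.energy_window <= 0 or self.rmsd_cutoff <= 0:
            raise ValueError("energy_window and rmsd_cutoff must be > 0")


@dataclass
class ConsensusMatch:
    """A windowed A pose paired with its closest B pose below the cutoff."""

    pose_a: str
    pose_b: str
    rmsd: float
    score_a: float = float("nan")


def _group_residues(atoms: Sequence[Atom]) -> list[list[Atom]]:
    """Group atoms by residue in order of first appearance."""
    groups: list[list[Atom]] = []
    key = None
    for a in atoms:
        k = (a.chain, a.res_seq, a.icode, a.res_name)
        if k != key:
            groups.append([])
            key = k
        groups[-1].append(a)
    return groups


def _residue_atom(res: Sequence[Atom], name: str) -> Atom | None:
    for a in res:
        if a.name == name:
            return a
    return None


def extract_rfa_frame(pose: Pose) -> RfaFrame:
    """Extract the canonical 9-atom RFa frame from a peptide pose.

    The Arg/Phe pair chosen is the C-terminal-most (residues 3–4 of a
    Phe-Arg-Arg-Phe-amide, 5–6 of a Lys-Asn-Phe-Leu-Arg-Phe-amide); the
    amide nitrogen may be a separate cap residue or an ``NT``-style atom on
    the final residue.
    """
    residues = _group_residues(pose.atoms)

    amide_atom: Atom | None = None
    if residues and residues[-1][0].res_name.upper() in AMIDE_CAP_RESIDUES:
        cap = residues[-1]
        amide_atom = next((a for a in cap
                           if a.name in AMIDE_N_ALIASES or a.name == "N"), None)
        if amide_atom is None:
            raise RfaMotifError(
                f"pose {pose.pose_id}: amide cap residue lacks a nitrogen atom")
        residues = residues[:-1]
    elif residues:
        last = residues[-1]
        amide_atom = next((a for a in last if a.name in AMIDE_N_ALIASES), None)
    if amide_atom is None:
        raise RfaMotifError(
            f"pose {pose.pose_id}: missing C-terminal amide nitrogen "
            f"(expected a cap residue or one of {sorted(AMIDE_N_ALIASES)})")

    if len(residues) < 2:
        raise RfaMotifError(f"pose {pose.pose_id}: fewer than two residues before the amide")
    phe_res, arg_res = residues[-1], residues[-2]
    if phe_res[0].res_name.upper() != "PHE" or arg_res[0].res_name.upper() != "ARG":
        raise RfaMotifError(
            f"pose {pose.pose_id}: C-terminal motif is "
            f"{arg_res[0].res_name}-{phe_res[0].res_name}, expected ARG-PHE")

    coords = []
    for res, res_label in ((arg_res, "Arg"), (phe_res, "Phe")):
        for name in ("N", "CA", "CG", "CZ"):
            a = _residue_atom(res, name)
            if a is None:
                raise RfaMotifError(
                    f"pose {pose.pose_id}: missing atom {name} in "
                    f"{res_label} {res[0].res_seq}")
            coords.append(a.coords)
    coords.append(amide_atom.coords)
    return RfaFrame(coords=np.array(coords), source_pose=pose.pose_id)


def rfa_rmsd(a: RfaFrame, b: RfaFrame) -> float:
    """RMSD between two RFa frames over the 9 canonical atoms, in Å.

    Positional correspondence, no superposition: both frames are expected in
    the common receptor frame, so a rigid translation by ``t`` yields exactly
    ``|t|``.
    """
    d = a.coords - b.coords
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def energy_window(ensemble: PoseEnsemble, window: float = 1.0) -> PoseEnsemble:
    """Retain poses scoring within ``window`` kcal/mol of the best (inclusive)."""
    if not ensemble.poses:
        raise ValueError(f"ensemble {ensemble.peptide_name!r} is empty")
    best = ensemble.best_score
    kept = [p for p in ensemble.poses if p.score <= best + window]
    return PoseEnsemble(peptide_name=ensemble.peptide_name, poses=kept,
                        receptor_id=ensemble.receptor_id)


def match_consensus(ens_a: PoseEnsemble, ens_b: PoseEnsemble,
                    params: ConsensusParams | None = None) -> list[ConsensusMatch]:
    """Cross-peptide consensus matching.

    Every energy-windowed pose of ``ens_a`` is compared against all poses of
    ``ens_b`` (RFa-frame RMSD); poses whose minimum RMSD is strictly below
    the cutoff yield one :class:`ConsensusMatch` naming the best partner.
    Ties break on (rmsd, pose_b id); output is ordered by (score, pose id)
    of the A pose, hence invariant to input pose order.
    """
    params = params or ConsensusParams()
    if ens_a.receptor_id != ens_b.receptor_id:
        raise ValueError(
            f"receptor mismatch: {ens_a.receptor_id!r} vs {ens_b.receptor_id!r}")
    if not ens_a.poses or not ens_b.poses:
        raise ValueError("both ensembles must be non-empty")

    windowed_a = energy_window(ens_a, params.energy_window).poses
    candidates_b = (energy_window(ens_b, params.energy_window).poses
                    if params.window_b else ens_b.poses)

    frames_b = [(p.pose_id, extract_rfa_frame(p)) for p in candidates_b]
    frames_b.sort(key=lambda t: t[0])  # lexicographic tie-break base

    matches: list[ConsensusMatch] = []
    for pose_a in sorted(windowed_a, key=lambda p: (p.score, p.pose_id)):
        frame_a = extract_rfa_frame(pose_a)
        best_id, best_rmsd = None, np.inf
        for pid, frame_b in frames_b:
            r = rfa_rmsd(frame_a, frame_b)
            if r < best_rmsd:  # strict: first lexicographic id wins ties
                best_id, best_rmsd = pid, r
        if best_id is not None and best_rmsd < params.rmsd_cutoff:
            matches.append(ConsensusMatch(pose_a=pose_a.pose_id, pose_b=best_id,
                                          rmsd=best_rmsd, score_a=pose_a.score))
    return matches


# ---------------------------------------------------------------------------
# orientation criterion
# ---------------------------------------------------------------------------


def nterm_orientation_ok(pose: Pose, cavity: "PocketRegion",
                         structure: Structure | None = None,
                         margin: float = 2.0) -> bool:
    """True iff the peptide N-terminus points towards the pocket entrance.

    Operationalised as a burial-depth comparison: the N-terminal amine
    nitrogen must be no more deeply buried than the C-terminal amide
    nitrogen, where burial depth is the shortest path through
    solvent-accessible grid voxels to bulk solvent.  Raises if the pose does
    not lie within ``margin`` Å of the cavity (e.g. a pose in bulk solvent).
    """
    cavity_map = getattr(cavity, "parent_map", None)
    if cavity_map is None:
        raise ValueError("cavity region carries no grid (not produced by "
                         "probe_accessible_cavities)")

    heavy = np.array([a.coords for a in pose.heavy_atoms()])
    centers = cavity_map.voxel_centers(cavity.voxel_indices)
    from scipy.spatial import cKDTree

    tree = cKDTree(centers)
    dmin, _ = tree.query(heavy, k=1)
    if not np.any(dmin <= margin):
        raise ValueError(
            f"pose {pose.pose_id}: no heavy atom within {margin} Å of cavity "
            f"{cavity.label} (pose outside cavity / in bulk solvent)")

    residues = _group_residues(pose.atoms)
    nterm = _residue_atom(residues[0], "N")
    if nterm is None:
        raise RfaMotifError(f"pose {pose.pose_id}: first residue lacks backbone N")
    amide = extract_rfa_frame(pose).coords[8]

    depth_n = cavity_map.burial_depth(nterm.coords)
    depth_c = cavity_map.burial_depth(amide)
    return depth_n <= depth_c


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def align_to_receptor(mobile: Structure, reference: Structure) -> np.ndarray:
    """Kabsch Cα alignment for ensembles that do not share a frame.

    Returns the 4x4 homogeneous transform mapping ``mobile`` onto
    ``reference`` using common (chain, res_seq) Cα pairs.
    """
    ref_ca = {(a.chain, a.res_seq): a.coords for a in reference.atoms if a.name == "CA"}
    pairs = [(a.coords, ref_ca[(a.chain, a.res_seq)])
             for a in mobile.atoms if a.name == "CA" and (a.chain, a.res_seq) in ref_ca]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 common CA atoms; cannot align")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    out = np.eye(4)
    out[:3, :3] = rot
    out[:3, 3] = yc - rot @ xc
    return out


def write_matches_tsv(matches: Sequence[ConsensusMatch], path: str | Path,
                      pocket_labels: dict[str, str] | None = None) -> None:
    """Write matches as TSV: pose_a, pose_b, rmsd, score_a, pocket_label."""
    lines = ["pose_a\tpose_b\trmsd\tscore_a\tpocket_label"]
    for m in matches:
        pocket = (pocket_labels or {}).get(m.pose_a, "unassigned")
        lines.append(f"{m.pose_a}\t{m.pose_b}\t{m.rmsd:.4f}\t{m.score_a:.3f}\t{pocket}")
    Path(path).write_text("\n".join(lines) + "\n")
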