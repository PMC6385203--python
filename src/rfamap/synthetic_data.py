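"""Seeded generators for every input the pipeline consumes.

Three families:

* docking pose ensembles of two RFa peptides (an FRRFa-like 4-mer and a
  KNFLRFa-like 6-mer) with Vina-style scores, containing a known set of
  planted cross-peptide RFa-frame matches among well-separated decoys;
* pseudo-atom cavity phantoms (sealed sphere, open pocket, double void)
  with analytically known interior volumes;
* voltage-clamp current traces (instant peak, mono-exponential
  desensitization to a sustained plateau) plus companion steady-state
  desensitization, concentration–response and kinetic series drawn from the
  same Hill / Hill–Langmuir / exponential models the fitters assume.

Every generator is a pure function of its spec including the seed, so
fixtures are reproducible and planted truth tables are exact (decoys are
rejection-sampled with a margin, making recovery tests non-flaky).
Peptide templates carry idealized geometry — only atom names and topology
need to be right, chemistry realism is not a goal.

Default truth values for the electrophysiology generators are the study
conditions of the modelled experiments: EC50 37 µM (WT) / 11 µM (F302A-like),
k_off 0.025 s⁻¹, k_on 162 s⁻¹·M⁻¹, I_sust/I_peak 0.03 (WT, 1 mM peptide) /
0.17 (enhanced mutant), an nH(peptide)/nH(control) SSD ratio of ~0.5 in WT.
The absolute WT SSD midpoint is not constrained by those experiments; 7.20
with nH 3.0 is used as a representative ASIC1a value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np

from .ephys_analysis import (CurrentTrace, ModulationReplicates,
                             StimulusProtocol, hill_langmuir, ssd_hill)
from .structure_io import Atom, Pose, PoseEnsemble, Structure

__all__ = [
    "PoseGenSpec",
    "TraceGenSpec",
    "gen_pose_ensembles",
    "gen_cavity_structure",
    "gen_current_traces",
    "gen_ssd_series",
    "gen_dose_response_series",
    "gen_kinetics_series",
    "gen_modulation_replicates",
    "make_peptide_template",
    "WT_TRUTH",
    "SUPPRESSED_TRUTH",
    "ENHANCED_TRUTH",
]


# ---------------------------------------------------------------------------
# peptide templates
# ---------------------------------------------------------------------------

# minimal idealized side-chain offsets (Å) relative to the residue base point
_BACKBONE = {"N": (0.0, 0.0, 0.0), "CA": (1.2, 0.7, 0.3), "C": (2.5, 0.0, 0.2),
             "O": (2.6, -1.2, 0.4)}
_SIDE = {
    "ARG": {"CB": (1.3, 2.0, 0.9), "CG": (2.3, 3.0, 0.5), "CD": (2.4, 4.3, 1.2),
            "NE": (3.4, 5.1, 0.8), "CZ": (3.5, 6.4, 1.0),
            "NH1": (2.6, 7.1, 1.7), "NH2": (4.5, 7.0, 0.5)},
    "PHE": {"CB": (1.3, 2.0, 0.9), "CG": (2.3, 3.0, 0.5),
            "CD1": (2.2, 4.2, 1.2), "CD2": (3.3, 2.9, -0.4),
            "CE1": (3.1, 5.2, 0.9), "CE2": (4.2, 3.9, -0.7),
            "CZ": (4.1, 5.1, 0.0)},
    "LYS": {"CB": (1.3, 2.0, 0.9), "CG": (2.3, 3.0, 0.5), "CD": (2.4, 4.3, 1.2),
            "CE": (3.4, 5.1, 0.8), "NZ": (3.5, 6.4, 1.0)},
    "ASN": {"CB": (1.3, 2.0, 0.9), "CG": (2.3, 3.0, 0.5),
            "OD1": (2.2, 4.1, 1.0), "ND2": (3.4, 2.8, -0.1)},
    "LEU": {"CB": (1.3, 2.0, 0.9), "CG": (2.3, 3.0, 0.5),
            "CD1": (2.2, 4.3, 1.1), "CD2": (3.6, 2.6, 0.2)},
}

FRRFA_SEQUENCE = ("PHE", "ARG", "ARG", "PHE")
KNFLRFA_SEQUENCE = ("LYS", "ASN", "PHE", "LEU", "ARG", "PHE")
_RESIDUE_PITCH = 3.6  # Å along the chain axis


def make_peptide_template(sequence: Iterable[str] = FRRFA_SEQUENCE,
                          chain: str = "P") -> Pose:
    """Idealized extended peptide with a C-terminal amide cap residue.

    Residues are laid out N→C along +x; the C-terminal residue of every
    template ends at x = 0 so that two templates of different length share
    the geometry of their C-terminal Arg-Phe-amide moiety exactly.
    """
    sequence = tuple(sequence)
    n = len(sequence)
    atoms: list[Atom] = []
    serial = 0
    for ri, res in enumerate(sequence, start=1):
        base = np.array([(ri - n) * _RESIDUE_PITCH, 0.0, 0.0])
        for name, off in {**_BACKBONE, **_SIDE[res]}.items():
            serial += 1
            atoms.append(Atom(serial, name, name[0], res, ri, chain,
                              base + np.asarray(off, float)))
    # amide cap: nitrogen bonded to the final carbonyl carbon
    serial += 1
    cap_base = np.array([0.0, 0.0, 0.0]) + np.array([3.8, 0.6, 0.3])
    atoms.append(Atom(serial, "N", "N", "NH2", n + 1, chain, cap_base))
    return Pose(atoms=atoms, score=0.0, pose_id="template")


# ---------------------------------------------------------------------------
# pose ensembles with planted consensus matches
# ---------------------------------------------------------------------------


@dataclass
class PoseGenSpec:
    """Conditions for the pose-ensemble generator.

    ``planted_rmsd`` must stay below the consensus cutoff and
    ``decoy_margin`` above it (recovery is exact when the margin exceeds
    twice the cutoff).
    """

    seed: int = 0
    n_decoys_a: int = 50
    n_decoys_b: int = 50
    n_planted: int = 3
    planted_rmsd: float = 0.5
    decoy_margin: float = 3.0
    score_range: tuple[float, float] = (-9.0, -4.0)
    box_size: float = 40.0
    receptor_id: str = "synthetic_receptor"
    max_retries: int = 20000

    def __post_init__(self) -> None:
        if self.planted_rmsd >= self.decoy_margin:
            raise ValueError("planted_rmsd must be < decoy_margin")
        if self.planted_rmsd <= 0 or self.decoy_margin <= 0:
            raise ValueError("distances must be positive")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _rfa_centroid(pose: Pose) -> np.ndarray:
    from .pose_consensus import extract_rfa_frame
    return extract_rfa_frame(pose).coords.mean(axis=0)


def gen_pose_ensembles(spec: PoseGenSpec) -> tuple[PoseEnsemble, PoseEnsemble,
                                                   list[dict]]:
    """Two peptide ensembles in a common frame plus the planted-match truth.

    Exactly ``n_planted`` A poses carry an RFa frame at ``planted_rmsd`` of
    one B pose; every other cross-pair is separated by at least
    ``decoy_margin`` (guaranteed by centroid rejection sampling, since the
    frame RMSD bounds the centroid distance from below).  Planted A poses
    receive the best scores so they survive the energy window.
    """
    rng = np.random.default_rng(spec.seed)
    tmpl_a = make_peptide_template(FRRFA_SEQUENCE)
    tmpl_b = make_peptide_template(KNFLRFA_SEQUENCE)

    n_placements = spec.n_planted + spec.n_decoys_a + spec.n_decoys_b
    min_sep = spec.decoy_margin + spec.planted_rmsd + 0.1
    placements: list[tuple[np.ndarray, np.ndarray]] = []  # (rot, translation)
    centroids: list[np.ndarray] = []
    tries = 0
    while len(placements) < n_placements:
        tries += 1
        if tries > spec.max_retries:
            raise ValueError(
                f"could not place {n_placements} poses with margin "
                f"{spec.decoy_margin} Å in a {spec.box_size} Å box; spec infeasible")
        rot = _random_rotation(rng)
        t = rng.uniform(0.0, spec.box_size, size=3)
        probe = tmpl_a.transformed(rot, t)
        c = _rfa_centroid(probe)
        if all(np.linalg.norm(c - prev) >= min_sep for prev in centroids):
            placements.append((rot, t))
            centroids.append(c)

    planted = placements[:spec.n_planted]
    decoys_a = placements[spec.n_planted:spec.n_planted + spec.n_decoys_a]
    decoys_b = placements[spec.n_planted + spec.n_decoys_a:]

    lo, hi = min(spec.score_range), max(spec.score_range)
    scores_a = rng.uniform(lo, hi, size=spec.n_decoys_a)
    scores_b = rng.uniform(lo, hi, size=spec.n_planted + spec.n_decoys_b)
    best_decoy = scores_a.min() if spec.n_decoys_a else lo + 1.0
    planted_scores = best_decoy - rng.uniform(0.1, 0.6, size=spec.n_planted)

    poses_a, poses_b, truth = [], [], []
    for i, (rot, t) in enumerate(planted):
        pid_a, pid_b = f"A_planted_{i:03d}", f"B_planted_{i:03d}"
        pose_a = tmpl_a.transformed(rot, t, pose_id=pid_a,
                                    score=float(planted_scores[i]))
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pose_b = tmpl_b.transformed(rot, t).translated(u * spec.planted_rmsd)
        pose_b = Pose(pose_b.atoms, float(scores_b[i]), pid_b)
        poses_a.append(pose_a)
        poses_b.append(pose_b)
        truth.append({"pose_a": pid_a, "pose_b": pid_b,
                      "rmsd": float(spec.planted_rmsd)})
    for i, (rot, t) in enumerate(decoys_a):
        poses_a.append(tmpl_a.transformed(rot, t, pose_id=f"A_decoy_{i:03d}",
                                          score=float(scores_a[i])))
    for i, (rot, t) in enumerate(decoys_b):
        poses_b.append(tmpl_b.transformed(
            rot, t, pose_id=f"B_decoy_{i:03d}",
            score=float(scores_b[spec.n_planted + i])))

    if not poses_a or not poses_b:
        raise ValueError("spec produced an empty ensemble; "
                         "need n_planted + n_decoys >= 1 on both sides")
    ens_a = PoseEnsemble("FRRFa", poses_a, receptor_id=spec.receptor_id)
    ens_b = PoseEnsemble("KNFLRFa", poses_b, receptor_id=spec.receptor_id)
    return ens_a, ens_b, truth


# ---------------------------------------------------------------------------
# cavity phantoms
# ---------------------------------------------------------------------------

_SHELL_VDW = 1.70  # carbon pseudo-atoms


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _shell_atoms(center: np.ndarray, interior_radius: float,
                 atom_spacing: float, start_serial: int,
                 mouth_radius: float | None = None,
                 chain: str = "S") -> list[Atom]:
    rc = interior_radius + _SHELL_VDW  # centres so the vdW surface sits at r
    n = int(np.ceil(4 * np.pi * rc * rc / atom_spacing ** 2))
    pts = center + rc * _fibonacci_sphere(n)
    atoms = []
    serial = start_serial
    for p in pts:
        if mouth_radius is not None:
            radial = p - center
            if radial[2] > 0 and np.hypot(radial[0], radial[1]) < mouth_radius:
                continue  # carve the mouth around the +z pole
        serial += 1
        # one pseudo-residue per atom (wrapping at the 4-digit PDB limit)
        atoms.append(Atom(serial, "C", "C", "SPH", (serial - 1) % 9999 + 1,
                          chain, p))
    return atoms


def gen_cavity_structure(kind: Literal["sealed_sphere", "open_pocket",
                                       "double_void"],
                         radius: float = 5.0,
                         mouth_radius: float = 2.5,
                         separation: float = 20.0,
                         atom_spacing: float = 0.35) -> tuple[Structure, dict]:
    """Pseudo-atom shell phantom with analytically known interior volume.

    ``radius`` is the interior (vdW-surface) radius; the analytic truth
    volume is 4/3·π·radius³.  ``open_pocket`` carves a circular mouth of
    ``mouth_radius`` around +z, sized so a 1.4 Å water probe cannot pass
    (vdW clearance 1.7 Å < mouth < 3.1 Å probe clearance by default).
    Shell atoms are spaced densely (default 0.35 Å) so the bumpiness of the
    discrete wall biases the volume by well under 1 %.
    """
    if radius <= 0 or atom_spacing <= 0:
        raise ValueError("geometric parameters must be positive")
    truth: dict = {"volume": 4.0 / 3.0 * np.pi * radius ** 3, "radius": radius}
    if kind == "sealed_sphere":
        center = np.zeros(3)
        atoms = _shell_atoms(center, radius, atom_spacing, 0)
        truth.update(center=center, sealed=True)
    elif kind == "open_pocket":
        if mouth_radius >= radius:
            raise ValueError("mouth_radius must be smaller than the pocket radius")
        center = np.zeros(3)
        atoms = _shell_atoms(center, radius, atom_spacing, 0,
                             mouth_radius=mouth_radius)
        truth.update(center=center, sealed=False, mouth_radius=mouth_radius,
                     axis=np.array([0.0, 0.0, 1.0]),
                     mouth_point=center + np.array([0.0, 0.0, radius]))
    elif kind == "double_void":
        c1 = np.zeros(3)
        c2 = np.array([separation, 0.0, 0.0])
        atoms = _shell_atoms(c1, radius, atom_spacing, 0, chain="S")
        atoms += _shell_atoms(c2, radius, atom_spacing, len(atoms), chain="T")
        truth.update(centers=[c1, c2], sealed=True, n_voids=2)
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    return Structure(atoms=atoms, id=f"phantom_{kind}"), truth


# ---------------------------------------------------------------------------
# current traces and companion series
# ---------------------------------------------------------------------------


@dataclass
class TraceGenSpec:
    """Conditions for the trace generator (amplitudes in µA, times in s)."""

    seed: int = 0
    protocol: StimulusProtocol = field(
        default_factory=lambda: StimulusProtocol(acid_start=10.0, acid_end=20.0))
    i_peak: float = 5.0          # peak magnitude (inward => trace dips to -i_peak)
    ratio: float = 0.03          # sustained/peak truth
    tau_desensitization: float = 0.5
    dt: float = 0.01
    total_time: float = 25.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.protocol.acid_end > self.total_time or self.protocol.acid_start < 0:
            raise ValueError("stimulus protocol inconsistent with trace length")


def gen_current_traces(spec: TraceGenSpec, n_replicates: int = 1) -> list[CurrentTrace]:
    """Seeded acid-evoked traces: instant peak, mono-exponential
    desensitization to the sustained plateau, Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.total_time + spec.dt / 2, spec.dt)
    p = spec.protocol
    i_sust = spec.ratio * spec.i_peak
    clean = np.zeros_like(t)
    acid = (t >= p.acid_start) & (t <= p.acid_end)
    ta = t[acid] - p.acid_start
    clean[acid] = -(i_sust + (spec.i_peak - i_sust)
                    * np.exp(-ta / spec.tau_desensitization))
    traces = []
    for _ in range(n_replicates):
        noise = rng.normal(0.0, spec.noise_sd, size=t.shape) if spec.noise_sd else 0.0
        traces.append(CurrentTrace(t=t.copy(), i=clean + noise, protocol=p))
    return traces


def gen_ssd_series(seed: int, pHD50: float = 7.20, nH: float = 3.0,
                   Imax: float = 1.0,
                   pH_values: np.ndarray | None = None,
                   noise_sd: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state desensitization series from the Hill model."""
    rng = np.random.default_rng(seed)
    pH = np.asarray(pH_values, float) if pH_values is not None \
        else np.arange(6.6, 8.0, 0.175)
    y = ssd_hill(pH, pHD50, nH, Imax)
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd * Imax, size=y.shape)
    return pH, y


def gen_dose_response_series(seed: int, ec50: float = 37e-6, hill: float = 1.0,
                             r_max: float = 0.03, r_0: float = 0.002,
                             concentrations: np.ndarray | None = None,
                             noise_sd: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Concentration–response series (mol/L) from the Hill–Langmuir model."""
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations, float) if concentrations is not None \
        else ec50 * np.array([0.0, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0])
    y = hill_langmuir(c, ec50, hill, r_max, r_0)
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd * (r_max - r_0), size=y.shape)
    return c, y


def gen_kinetics_series(seed: int, rate: float = 0.025,
                        mode: Literal["decay", "rise"] = "decay",
                        amplitude: float = 1.0, offset: float = 0.0,
                        t: np.ndarray | None = None,
                        noise_sd: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Mono-exponential effect-onset/washout series."""
    rng = np.random.default_rng(seed)
    if t is None:
        span = 4.0 / rate
        t = np.linspace(0.0, span, 16)
    t = np.asarray(t, float)
    if mode == "decay":
        y = amplitude * np.exp(-rate * t) + offset
    elif mode == "rise":
        y = amplitude * (1.0 - np.exp(-rate * t)) + offset
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd * amplitude, size=y.shape)
    return t, y


# ---------------------------------------------------------------------------
# modulation replicate sets (summary-table scenarios)
# ---------------------------------------------------------------------------

# genotype truth: peptide-induced fold change of I_sust/I_peak at 50 µM,
# peptide-induced pHD50 shift, nH(peptide)/nH(control) ratio
WT_TRUTH = {"isust_fold": 6.0, "delta_pHD50": -0.15, "nH_ratio": 0.5}
# suppressed sustained-current effect, unchanged SSD shift, attenuated nH change
SUPPRESSED_TRUTH = {"isust_fold": 1.5, "delta_pHD50": -0.15, "nH_ratio": 0.85}
# enhanced sustained-current effect, WT-like SSD behaviour
ENHANCED_TRUTH = {"isust_fold": 20.0, "delta_pHD50": -0.15, "nH_ratio": 0.5}

_NOISE_SD = {"isust_fold": 0.5, "delta_pHD50": 0.03, "nH_ratio": 0.05}


def gen_modulation_replicates(seed: int, truth: dict[str, float],
                              n: int = 10, name: str = "",
                              noise: dict[str, float] | None = None
                              ) -> ModulationReplicates:
    """Per-cell replicate set around a genotype truth with Gaussian noise."""
    rng = np.random.default_rng(seed)
    sd = {**_NOISE_SD, **(noise or {})}
    return ModulationReplicates(
        isust_fold=rng.normal(truth["isust_fold"], sd["isust_fold"], size=n),
        delta_pHD50=rng.normal(truth["delta_pHD50"], sd["delta_pHD50"], size=n),
        nH_ratio=rng.normal(truth["nH_ratio"], sd["nH_ratio"], size=n),
        name=name,
    )
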