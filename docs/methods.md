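# Methods

This note documents the models, algorithms, parameter defaults and
numerical choices behind `rfamap`, plus what its synthetic generators do
and do not emulate.

## Cross-peptide pose consensus

Rigid-receptor docking of a short RFa peptide produces many near-degenerate
poses. The selection procedure assumes that a physiologically meaningful
binding mode must be shared by longer peptides of the same family, which
all end in Arg-Phe-NH₂. Two filters encode this:

1. **Energy window.** Poses of the query peptide scoring within
   `energy_window` (default 1.0 kcal/mol, inclusive) of its best pose are
   retained. The window is applied to the query (shorter) peptide only;
   every pose of the comparison peptide is a candidate partner. A flag
   (`window_b`) also windows the comparison ensemble, off by default.
2. **RFa-frame RMSD.** For each surviving query pose, the RMSD over the 9
   heavy atoms of the C-terminal Arg-Phe-amide moiety — Arg N, Cα, Cγ, Cζ;
   Phe N, Cα, Cγ, Cζ; amide N, in that fixed order — is minimized over the
   comparison ensemble. Pairs strictly below `rmsd_cutoff` (default 1.0 Å)
   are consensus matches. Atom correspondence is positional, never
   permutation-optimized: the 9 atoms are chemically unambiguous.

No superposition precedes the RMSD. Both peptides are docked to the same
rigid receptor, so their poses share a coordinate frame and rigid fitting
would be the identity; skipping it also keeps the cutoff's meaning exact
(a frame translated by *t* scores exactly |*t*|). For inputs in different
frames, `align_to_receptor` provides a receptor-Cα Kabsch alignment.

Ties between equally close partners break deterministically on
(rmsd, partner id); output order follows (score, pose id) of the query
pose, making the result invariant to input pose order.

**Orientation criterion.** Longer family members extend from the
N-terminus, so a transferable pose must leave the N-terminus towards the
pocket entrance. "Towards the entrance" is operationalized as a burial
comparison: the N-terminal amine nitrogen's burial depth must not exceed
the C-terminal amide nitrogen's, where burial depth is the shortest
6-connected path through solvent-accessible (vdW-free) voxels from the
atom's nearest accessible voxel to bulk solvent. A pose with no heavy atom
within 2 Å of the cavity is rejected with an error rather than classified.

## Grid cavity detection and volumes

Cavity volumes are measured on a rectilinear voxel grid as a documented
approximation to alpha-shape pocket measurement; reported volumes are
approximations, not alpha-shape-exact. Defaults: spacing 0.5 Å, probe
radius 1.4 Å (a water probe; 2.0 Å separates pockets connected through
narrow channels), padding 4.0 Å, united-atom Bondi-style radii C 1.70,
N 1.55, O 1.52, S/P 1.80 Å; hydrogens are ignored everywhere.

Algorithm:

1. two occupancy grids over the padded bounding box: inside the vdW
   surface (volume grid) and inside the probe-inflated surface
   (connectivity grid for probe centres);
2. bulk probe centres = 6-connected flood fill of probe-free space from
   the grid boundary (6-connectivity is deliberate: 26-connectivity would
   let bulk leak diagonally through occupied walls);
3. bulk solvent = every voxel within `probe_radius + √3/2·spacing` of a
   bulk probe centre (the half-voxel-diagonal term compensates for probe
   centres living off-grid; without it, a skirt of spurious surface
   "cavities" appears at coarse spacings);
4. cavities = 26-connected components of vdW-free, non-bulk voxels;
   volume = voxel_count × spacing³; components below `min_volume`
   (default 20 ų) are discarded as surface slivers;
5. a cavity is `sealed` if its voxels have no vdW-level flood-fill path to
   the boundary; pockets whose mouth is too narrow for the probe but open
   at the vdW surface are reported unsealed;
6. lining residues are those with a heavy atom within
   (vdW + probe + spacing) of a cavity voxel. Named pocket labels
   (acidic_pocket, thumb_base, central_vestibule, side_cavity) are
   attached when a cavity's lining contains a landmark residue set; a
   default landmark file in human ASIC1a numbering ships with the package
   and is user-replaceable JSON.

**Accuracy.** On a sealed-sphere phantom of interior radius 5 Å the
measured volume is within 0.4 % of 4/3·π·5³ at every tested spacing
(0.8/0.4/0.2 Å). The residual error is dominated by lattice-counting
oscillation (the error of counting grid points inside a smooth region is
sign-alternating and not pointwise monotone in the spacing), so refining
the grid shrinks the error envelope rather than every individual error.
A hard voxel budget (default 6·10⁷) guards memory; exceeding it raises an
error advising coarser spacing.

**Pose-to-pocket assignment.** A pose belongs to the cavity containing the
largest number of its heavy atoms within 2.0 Å of a cavity voxel centre;
below 25 % of heavy atoms it is unassigned. Ties break on larger volume,
then label order.

## Interaction fingerprints

Contact typing uses fixed per-residue chemistry tables and geometric
criteria chosen from common practice (2-D interaction-diagram tools vary
in stringency, so every threshold is exposed in `InteractionCriteria`):

* hydrogen bond: donor–acceptor heavy-atom distance ≤ 3.5 Å; when a
  hydrogen is present on the donor, D–H···A angle ≥ 120°;
* hydrophobic: apolar-carbon pair ≤ 4.0 Å;
* stacking: ring-centroid distance ≤ 5.0 Å and inter-plane angle ≤ 30°
  (parallel) or 60–90° (T-shaped);
* cation-π: Arg Cζ or Lys Nζ (and the free N-terminal amine) to ring
  centroid ≤ 6.0 Å;
* salt bridge: opposite-charge heavy atoms ≤ 4.0 Å.

One interaction is reported per (peptide atom or ring, receptor residue,
kind) carrying the minimal distance; output ordering is deterministic, and
the criteria use only pairwise geometry, so fingerprints are invariant
under global rigid motion and chain relabelling.

## Electrophysiology analysis

Traces are uniformly sampled currents (inward negative) with a stimulus
protocol (conditioning pH, acid window, ligand concentration). The
baseline is the mean current over the 2 s before the acid switch; the peak
is the largest baseline-subtracted magnitude in the acid window; the
sustained current is the mean magnitude over the last 2 s of the acid
application; I_sust/I_peak is their ratio. All three are magnitudes, hence
offset- and sign-convention-invariant. Traces whose peak falls below a
configurable noise floor are flagged unusable.

Model fits (all Levenberg–Marquardt least squares with three deterministic
starts — a data-driven midpoint estimate and ±0.5 log-units — to avoid
local minima; no randomized restarts):

* **SSD:** `I = Imax·(1 − 1/(1 + (10^−pHD50/10^−pH)^nH))`, requiring ≥ 4
  distinct conditioning pH values. The fitted curve passes Imax/2 at
  pHD50 by construction of the parameterization.
* **Concentration–response:** `r(c) = r0 + (rmax − r0)·c^h/(EC50^h + c^h)`
  with EC50 fitted on a log scale for stability.
* **Kinetics:** washout `y = A·e^(−k·t) + y∞` (k = k_off) and onset
  `y = A·(1 − e^(−k·t)) + y0` (k = k_obs). The association rate constant
  uses the pseudo-first-order form k_on = k_obs/[L] by default; the
  two-state form k_on = (k_obs − k_off)/[L] is available by flag. The two
  conventions are both provided because a k_obs fitted from slow onset
  data can be numerically inconsistent with an independently measured
  k_off under a strict two-state scheme; neither is asserted.

**WT-vs-mutant classification.** Each mutant is compared with WT on three
per-cell readouts: the peptide-induced fold change of I_sust/I_peak, the
peptide-induced pHD50 shift, and the nH(peptide)/nH(control) ratio.
Symbols `<`/`=`/`>` are assigned by Welch's t-test at level α (default
0.05), with Holm correction across mutants when several are classified
together. This replaces an ANOVA/Kruskal–Wallis + Dunnett/Dunn workflow:
Holm-adjusted pairwise Welch tests control the family-wise error without
multivariate-t tables, at some power cost; the symbols depend only on
rejection at α.

## Synthetic generators: what they emulate, and what not

Every generator is a pure function of its spec (including the seed), and
every output satisfies the invariants of the type it instantiates.

* **Pose ensembles.** Two idealized peptide templates (a 4-mer and a 6-mer
  sharing their C-terminal Arg-Phe-amide geometry exactly) are placed by
  random rigid transforms. Planted consensus pairs are built by applying
  the same transform to both templates and translating the partner by
  exactly `planted_rmsd` (default 0.5 Å); decoys are rejection-sampled so
  all other RFa-frame pairs stay ≥ `decoy_margin` (default 3.0 Å) apart —
  the frame centroid distance lower-bounds the frame RMSD, so the margin
  is guaranteed, making recovery tests exact and non-flaky. Planted poses
  receive the best scores so they survive the energy window. Geometry is
  idealized: atom names and topology are correct, but bond lengths and
  scores are not physically meaningful.
* **Cavity phantoms.** Pseudo-atom shells (carbon, one pseudo-residue per
  atom) on a Fibonacci sphere, wall pitch 0.35 Å, with centres at
  r + 1.7 Å so the vdW surface sits at the stated interior radius; the
  analytic truth is 4/3·π·r³ (wall bumpiness biases the realizable volume
  by ≈ +0.2 %). The open-pocket phantom carves a mouth (default 2.5 Å)
  sized between the vdW clearance (1.7 Å) and the probe clearance
  (3.1 Å), so it reads as a probe-enclosed but unsealed pocket.
* **Current traces.** Baseline plus an instantaneous acid-evoked peak
  decaying mono-exponentially (τ = 0.5 s) to a sustained plateau, with
  seeded Gaussian noise; companion SSD, concentration–response and kinetic
  series come from the same closed-form models the fitters assume.

Generator defaults are the study conditions of the modelled experiments:
EC50 37 µM (WT-like) and 11 µM (enhanced-efficacy mutant), k_off
0.025 s⁻¹, k_on 162 s⁻¹·M⁻¹ at 50 µM peptide, I_sust/I_peak 0.03 (WT,
1 mM peptide) and 0.17, an nH(peptide)/nH(control) SSD ratio of ≈ 0.5,
and a 10 s pH-5 application. The absolute WT SSD midpoint is not
constrained by those experiments; pHD50 7.20 with nH 3.0 is used as a
representative ASIC1a value and is documented as arbitrary. Noise levels
(5 % of amplitude for fit series, 0.02 µA for traces) are typical of
oocyte recordings but not calibrated to any dataset.

Because the generators draw from the same functional forms the estimators
fit, parameter-recovery tests demonstrate estimator correctness and
numerical stability — not robustness to model misspecification, leak
currents, series-resistance artefacts, rundown, or real conformational
ensembles. Passing tests therefore validate the pipeline's arithmetic and
logic, not the biology of any particular dataset.

## Problem sizes and defaults used in the shipped checks

The test suite and `scripts/acceptance.py` use 10–50 pose decoys per
ensemble, 20–200 seeded consensus draws, cavity grids at 0.8/0.4/0.2 Å on
5 Å phantoms, 30–100 replicate fits per recovery estimate and 10–12 cells
per genotype for the classification scenarios — sizes chosen so the whole
verification runs in a couple of minutes on one CPU while keeping Monte
Carlo error well below the asserted tolerances.

## Known limitations

* Grid volumes approximate alpha-shape pocket volumes; partitioning of
  cavities connected through wide channels depends on the probe radius,
  and connected-component splitting can differ from alpha-shape flow
  partitioning.
* The "N-terminus towards the entrance" rule is this package's geometric
  operationalization of an otherwise informal criterion.
* The AutoDock-family pose reader accepts MODEL-blocked text with `USER`/
  `REMARK` energy lines and PDBQT-style atom records; exotic result-file
  layouts may need the multi-MODEL PDB route instead.
* Interaction thresholds are conventions; different diagram tools will
  disagree near the cutoffs.
* Hill-type fits assume equilibrium and a single transition; the SSD and
  dose–response forms share that assumption.
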