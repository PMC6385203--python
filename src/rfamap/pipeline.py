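"""End-to-end orchestration: binding-site mapping and ephys batch analysis.

``run_site_mapping`` chains the docking post-processing stages —
energy-window filtering, cross-peptide RFa consensus, cavity detection,
pose-to-pocket assignment, N-terminus orientation filtering and interaction
fingerprinting — over a receptor structure plus two pose ensembles, and
writes deterministic TSV/JSON reports.

``run_ephys`` batch-processes current-trace CSVs (``t_s,i_uA`` columns, one
protocol JSON per trace or per directory) into per-cell metrics, and
optionally classifies mutants against WT from a replicate table CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pocket_analysis, pose_consensus, structure_io
from .ephys_analysis import (CurrentTrace, ModulationReplicates,
                             StimulusProtocol, modulation_table, trace_metrics)

logger = logging.getLogger("rfamap")

__all__ = ["RunConfig", "PipelineError", "run_site_mapping", "run_ephys",
           "load_config"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    receptor: str | None = None
    ensemble_a: str | None = None
    ensemble_b: str | None = None
    peptide_a: str = "FRRFa"
    peptide_b: str = "KNFLRFa"
    traces_dir: str | None = None
    replicates_csv: str | None = None
    out_dir: str = "rfamap_out"
    seed: int = 0
    energy_window: float = 1.0
    rmsd_cutoff: float = 1.0
    window_b: bool = False
    grid_spacing: float = 0.5
    probe_radius: float = 1.4
    min_volume: float = 20.0
    landmarks: str | None = None  # JSON path; None = shipped defaults
    orientation_filter: bool = True
    alpha: float = 0.05
    log_level: str = "INFO"

    def consensus_params(self) -> pose_consensus.ConsensusParams:
        return pose_consensus.ConsensusParams(
            energy_window=self.energy_window, rmsd_cutoff=self.rmsd_cutoff,
            window_b=self.window_b)

    def grid_spec(self) -> pocket_analysis.GridSpec:
        return pocket_analysis.GridSpec(spacing=self.grid_spacing,
                                        probe_radius=self.probe_radius,
                                        min_volume=self.min_volume)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = json.load(fh)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _require(config: RunConfig, attr: str, stage: str) -> Path:
    value = getattr(config, attr)
    if not value:
        raise PipelineError(stage, f"config field {attr!r} is required")
    p = Path(value)
    if not p.exists():
        raise PipelineError(stage, f"{attr} path does not exist: {p}")
    return p


def run_site_mapping(config: RunConfig) -> dict:
    """Map consensus peptide poses to receptor pockets; returns the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}

    def stage(name: str):
        logger.info("stage: %s", name)
        report["stages"].append(name)

    try:
        stage("read_inputs")
        receptor = structure_io.read_structure(_require(config, "receptor", "read_inputs"))
        ens_a = structure_io.read_pose_ensemble(
            _require(config, "ensemble_a", "read_inputs"), config.peptide_a,
            receptor_id=receptor.id)
        ens_b = structure_io.read_pose_ensemble(
            _require(config, "ensemble_b", "read_inputs"), config.peptide_b,
            receptor_id=receptor.id)
    except structure_io.StructureParseError as exc:
        _fail(out, report, "read_inputs", exc)

    try:
        stage("consensus")
        matches = pose_consensus.match_consensus(ens_a, ens_b,
                                                 config.consensus_params())
    except (ValueError, pose_consensus.RfaMotifError) as exc:
        _fail(out, report, "consensus", exc)

    try:
        stage("cavities")
        landmarks = (pocket_analysis.load_landmarks(config.landmarks)
                     if config.landmarks else pocket_analysis.default_landmarks())
        cavities = pocket_analysis.probe_accessible_cavities(
            receptor, config.grid_spec(), landmarks=landmarks)
        pocket_analysis.write_cavities_tsv(cavities, out / "cavities.tsv")
    except ValueError as exc:
        _fail(out, report, "cavities", exc)

    stage("assign_and_fingerprint")
    poses_by_id = {p.pose_id: p for p in ens_a.poses}
    selected, fingerprints, pocket_labels = [], [], {}
    rows = []
    for m in matches:
        pose = poses_by_id[m.pose_a]
        label = (pocket_analysis.assign_pose_pocket(pose, cavities)
                 if len(cavities) else None)
        pocket_labels[m.pose_a] = label or "unassigned"
        orientation = None
        if label is not None and config.orientation_filter:
            region = next(r for r in cavities if r.label == label)
            try:
                orientation = pose_consensus.nterm_orientation_ok(pose, region)
            except ValueError:
                orientation = None
        keep = label is not None and (orientation is not False)
        if keep:
            selected.append(pose)
            fingerprints.append(pocket_analysis.detect_interactions(pose, receptor))
        rows.append({"pose_a": m.pose_a, "pose_b": m.pose_b,
                     "rmsd": round(m.rmsd, 4), "score_a": m.score_a,
                     "pocket": label or "unassigned",
                     "orientation_ok": orientation, "selected": keep})

    stage("write_reports")
    pose_consensus.write_matches_tsv(matches, out / "matches.tsv", pocket_labels)
    pocket_analysis.write_fingerprints_tsv(fingerprints, out / "interactions.tsv")
    if selected:
        structure_io.write_complexes(receptor, selected, out / "selected_complexes.pdb")
    report.update({
        "n_poses_a": len(ens_a), "n_poses_b": len(ens_b),
        "n_matches": len(matches), "n_selected": len(selected),
        "cavities": [{"label": c.label, "volume_A3": round(c.volume, 1),
                      "sealed": c.sealed} for c in cavities],
        "poses": rows,
        "poses_per_pocket": _per_pocket(rows),
        "status": "ok",
    })
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _per_pocket(rows: list[dict]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in rows:
        if r["selected"]:
            counts[r["pocket"]] = counts.get(r["pocket"], 0) + 1
    return dict(sorted(counts.items()))


def _fail(out: Path, report: dict, stage: str, exc: Exception) -> None:
    report.update({"status": "failed", "failed_stage": stage, "error": str(exc)})
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    raise PipelineError(stage, str(exc)) from exc


# ---------------------------------------------------------------------------
# ephys batch
# ---------------------------------------------------------------------------


def _load_trace(csv_path: Path) -> CurrentTrace:
    df = pd.read_csv(csv_path)
    for col in ("t_s", "i_uA"):
        if col not in df.columns:
            raise PipelineError("read_traces",
                                f"{csv_path.name}: missing column {col!r}")
    proto_path = csv_path.with_suffix(".json")
    if not proto_path.exists():
        proto_path = csv_path.parent / "protocol.json"
    if not proto_path.exists():
        raise PipelineError("read_traces",
                            f"{csv_path.name}: no protocol JSON found")
    proto = json.loads(proto_path.read_text())
    return CurrentTrace(t=df["t_s"].to_numpy(), i=df["i_uA"].to_numpy(),
                        protocol=StimulusProtocol(**proto))


def run_ephys(config: RunConfig) -> dict:
    """Per-cell trace metrics and, when replicates are given, the WT-vs-mutant
    classification table."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"status": "ok"}

    if config.traces_dir:
        tdir = _require(config, "traces_dir", "read_traces")
        csvs = sorted(tdir.glob("*.csv"))
        if not csvs:
            raise PipelineError("read_traces", f"no trace CSVs in {tdir}")
        rows = []
        for f in csvs:
            trace = _load_trace(f)
            try:
                m = trace_metrics(trace)
            except ValueError as exc:
                raise PipelineError("trace_metrics", f"{f.name}: {exc}") from exc
            rows.append({"trace": f.stem, "i_peak_uA": m.i_peak,
                         "i_sust_uA": m.i_sust, "ratio": m.ratio,
                         "baseline_uA": m.baseline, "usable": m.usable})
        metrics = pd.DataFrame(rows)
        metrics.to_csv(out / "trace_metrics.csv", index=False)
        report["n_traces"] = len(rows)
        report["mean_ratio"] = float(metrics["ratio"].mean())

    if config.replicates_csv:
        rpath = _require(config, "replicates_csv", "compare")
        df = pd.read_csv(rpath)
        needed = {"genotype", "isust_fold", "delta_pHD50", "nH_ratio"}
        if not needed <= set(df.columns):
            raise PipelineError("compare",
                                f"{rpath.name}: needs columns {sorted(needed)}")
        groups = {}
        for name, g in df.groupby("genotype"):
            groups[name] = ModulationReplicates(
                isust_fold=g["isust_fold"].to_numpy(),
                delta_pHD50=g["delta_pHD50"].to_numpy(),
                nH_ratio=g["nH_ratio"].to_numpy(), name=str(name))
        if "WT" not in groups:
            raise PipelineError("compare", "replicate table needs a WT genotype")
        wt = groups.pop("WT")
        if groups:
            table = modulation_table(wt, groups, alpha=config.alpha)
            rows = [{"genotype": nm,
                     "isust": c.symbols["isust"], "dpHD50": c.symbols["dpHD50"],
                     "nH": c.symbols["nH"],
                     "fold_change_ratio": round(c.fold_change_ratio, 3),
                     "p_isust": c.p_values["isust"],
                     "p_dpHD50": c.p_values["dpHD50"], "p_nH": c.p_values["nH"]}
                    for nm, c in sorted(table.items())]
            pd.DataFrame(rows).to_csv(out / "modulation_table.csv", index=False)
            report["comparison"] = {r["genotype"]:
                                    {"isust": r["isust"], "dpHD50": r["dpHD50"],
                                     "nH": r["nH"]} for r in rows}
        else:
            report["comparison"] = None

    (out / "ephys_report.json").write_text(json.dumps(report, indent=2))
    return report
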