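"""End-to-end orchestration: simulate → align → segment → extract →
label → stats → classify.

Every artifact is a pure function of (inputs, config, seed): the run seed
is recorded in each output's metadata together with a hash of the full
configuration, and rerunning with the same seed reproduces the CSV
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import features as feat
from . import label as lab
from . import preprocess as prep
from . import segment as seg
from . import simulate as sim
from . import stats as st
from .errors import DegenerateDataError
from .io import write_recording, write_table

log = logging.getLogger("capnotype")


@dataclass
class Scenario:
    """One simulated acquisition: a patient, a circuit, a duration."""

    name: str
    patient: sim.PatientConfig
    circuit: sim.CircuitConfig
    duration: float = 120.0
    interface: str = "invasive"


@dataclass
class PipelineConfig:
    scenarios: list[Scenario] = field(default_factory=list)
    alignment: prep.AlignmentConfig | None = None
    segmentation: seg.SegmentationConfig = field(default_factory=seg.SegmentationConfig)
    labeler: lab.LabelerConfig = field(default_factory=lab.LabelerConfig)
    mlp: clf.MlpConfig = field(default_factory=clf.MlpConfig)
    #: predictor set for CDA and the MLP; None = the 16 CO2-free parameters
    predictors: list[str] | None = None
    #: smoothing applied to CO2 channels before labeling, seconds
    co2_smoothing: float = 0.05
    seed: int = 0

    def resolved_predictors(self) -> list[str]:
        if self.predictors is not None:
            return list(self.predictors)
        return [c for c in feat.FEATURE_COLUMNS if c != clf.FORBIDDEN_PREDICTOR]

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def demo_scenarios(seed: int = 0) -> list[Scenario]:
    """Three acquisitions spanning the three CO2-movement regimes.

    Slow, small-breath ventilation through a high-conductance port keeps
    all expired CO2 on the patient side (type I); a mid-range pattern
    pushes CO2 into the ventilator limb but washes it out (type II); fast,
    large breaths through a low-conductance port leave CO2 in the limb at
    inspiration onset (type III).
    """
    return [
        Scenario(
            name="washout_complete",
            patient=sim.PatientConfig(respiratory_rate=14, tidal_volume=350,
                                      exp_flow_tau=0.6, seed=seed * 101 % (2**31)),
            circuit=sim.CircuitConfig(leak_conductance=200.0),
            interface="noninvasive",
        ),
        Scenario(
            name="reversal_washed",
            patient=sim.PatientConfig(respiratory_rate=15, tidal_volume=500,
                                      exp_flow_tau=0.4, seed=(seed * 101 + 1) % (2**31)),
            circuit=sim.CircuitConfig(leak_conductance=100.0),
            interface="invasive",
        ),
        Scenario(
            name="rebreathing",
            patient=sim.PatientConfig(respiratory_rate=28, tidal_volume=650,
                                      exp_flow_tau=0.35, seed=(seed * 101 + 2) % (2**31)),
            circuit=sim.CircuitConfig(leak_conductance=60.0),
            interface="invasive",
        ),
    ]


def process_recording(recording, config: PipelineConfig,
                      circuit: sim.CircuitConfig | None = None):
    """Align, segment, extract and label one recording.

    Returns (cycles, features DataFrame, labels DataFrame).  The alignment
    delay comes from ``config.alignment`` or, failing that, the circuit's
    sampling-line settings.
    """
    alignment = config.alignment
    if alignment is None:
        if circuit is None:
            raise DegenerateDataError("no alignment config and no circuit to derive it")
        alignment = prep.AlignmentConfig(
            sample_line_volume=circuit.sample_line_volume,
            pump_flow=circuit.pump_flow,
            smoothing_window=config.co2_smoothing)
    else:
        alignment = dataclasses.replace(
            alignment, smoothing_window=alignment.smoothing_window or config.co2_smoothing)
    aligned = prep.align_capnogram(recording, alignment)
    cycles = seg.segment_recording(aligned, config.segmentation)
    log.info("segmented %d cycles", len(cycles))
    features = feat.extract_feature_table(aligned, cycles)
    labels = lab.label_recording(aligned, cycles, config.labeler)
    return cycles, features, labels


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full demo pipeline over the configured scenarios.

    Writes recordings, per-cycle tables, the stats report and the CV
    report under ``outdir`` and returns a summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}

    all_features, all_labels = [], []
    n_truth_match = n_truth_total = 0
    for scenario in config.scenarios:
        log.info("scenario %s", scenario.name)
        simulated = sim.simulate_recording(
            scenario.patient, scenario.circuit, scenario.duration,
            interface=scenario.interface, subject_id=scenario.name)
        measured = sim.apply_capnometer(simulated.recording, scenario.circuit)
        measured.metadata.update(stamp)
        write_recording(measured, outdir / f"recording_{scenario.name}")
        write_table(simulated.truth_frame(), outdir / f"truth_{scenario.name}.csv")

        cycles, features, labels = process_recording(
            measured, config, circuit=scenario.circuit)
        features["scenario"] = scenario.name
        labels["scenario"] = scenario.name

        truth = simulated.truth_frame()
        matched = _match_truth(cycles, labels, truth)
        n_truth_match += matched[0]
        n_truth_total += matched[1]

        all_features.append(features)
        all_labels.append(labels)

    features = pd.concat(all_features, ignore_index=True)
    labels = pd.concat(all_labels, ignore_index=True)
    table = features.merge(
        labels[["cycle_id", "scenario", "type"]].rename(columns={"type": "cycle_type"}),
        on=["cycle_id", "scenario"])
    analyzable = table[table["cycle_type"].isin(["I", "II", "III"])].copy()
    write_table(features, outdir / "features.csv")
    write_table(labels, outdir / "labels.csv")

    summary = lab.summarize_labels(labels)
    write_table(summary, outdir / "label_summary.csv")
    log.info("cycle composition:\n%s", summary)

    report: dict = {
        **stamp,
        "n_cycles": int(len(labels)),
        "n_analyzable": int(len(analyzable)),
        "composition": {r["type"]: int(r["count"]) for _, r in summary.iterrows()},
        "truth_agreement": (n_truth_match / n_truth_total) if n_truth_total else None,
    }

    predictors = config.resolved_predictors()
    types_present = sorted(analyzable["cycle_type"].unique())
    if len(types_present) < 2:
        raise DegenerateDataError(
            f"only type {types_present} cycles present; the statistics and "
            "the classifier need at least two cycle types")
    numeric = [p for p in predictors]

    anova = st.anova_table(analyzable, analyzable["cycle_type"],
                           [p for p in numeric if p != "invasive"])
    write_table(anova, outdir / "anova.csv")

    snk_rows = []
    for name in (p for p in numeric if p != "invasive"):
        groups = {t: analyzable.loc[analyzable["cycle_type"] == t, name].to_numpy()
                  for t in types_present}
        flags = st.snk_pairwise(groups)
        for (a, b), sig in sorted(flags.items()):
            snk_rows.append({"feature": name, "pair": f"{a}-{b}", "significant": sig})
    write_table(pd.DataFrame(snk_rows), outdir / "snk.csv")

    cda = st.cda_fit(analyzable[numeric].to_numpy(dtype=float),
                     analyzable["cycle_type"].to_numpy(),
                     feature_names=numeric, ridge=1e-8)
    report["cda"] = {
        "wilks_lambda": cda.wilks_lambda,
        "overall_percent": cda.percent_correct["overall_percent"],
        "per_class_percent": cda.percent_correct["per_class_percent"],
        "ridge_applied": cda.ridge_applied,
    }

    cv = clf.run_cv(analyzable, predictors, config.mlp, label_col="cycle_type")
    write_table(cv.quality_frame(), outdir / "cv_quality.csv")
    write_table(cv.auc_frame(), outdir / "cv_auc.csv")
    report["mlp"] = {
        "mean_accuracy": cv.mean_accuracy,
        "auc": {str(k): v[0] for k, v in cv.auc.items()},
    }

    (outdir / "report.json").write_text(json.dumps(_as_jsonable(report), indent=1))
    return report


def _match_truth(cycles, labels: pd.DataFrame, truth: pd.DataFrame,
                 tolerance: int = 5) -> tuple[int, int]:
    """Count rule labels agreeing with ground truth on matched cycles.

    Cycles are matched on their expiration-start sample (within
    ``tolerance`` samples); borderline/excluded rule labels do not enter
    the comparison, mirroring their exclusion from analysis.
    """
    t_starts = truth["exp_start"].to_numpy()
    t_types = truth["type"].to_numpy()
    order = np.argsort(t_starts)
    t_starts, t_types = t_starts[order], t_types[order]
    match = total = 0
    for _, row in labels.iterrows():
        if row["type"] not in ("I", "II", "III"):
            continue
        start = cycles[int(row["cycle_id"])].exp_start
        j = np.searchsorted(t_starts, start)
        best = min((abs(int(t_starts[k]) - start), k)
                   for k in (max(j - 1, 0), min(j, len(t_starts) - 1)))
        if best[0] <= tolerance:
            total += 1
            match += int(row["type"] == t_types[best[1]])
    return match, total


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    scenarios = [
        Scenario(
            name=s.get("name", f"scenario{i}"),
            patient=sim.PatientConfig(**s.get("patient", {})),
            circuit=sim.CircuitConfig(**s.get("circuit", {})),
            duration=s.get("duration", 120.0),
            interface=s.get("interface", "invasive"),
        )
        for i, s in enumerate(raw.get("scenarios", []))
    ]
    config = PipelineConfig(
        scenarios=scenarios,
        segmentation=seg.SegmentationConfig(**raw.get("segmentation", {})),
        labeler=lab.LabelerConfig(**raw.get("labeler", {})),
        mlp=clf.MlpConfig(**raw.get("mlp", {})),
        predictors=raw.get("predictors"),
        co2_smoothing=raw.get("co2_smoothing", 0.05),
        seed=raw.get("seed", 0),
    )
    if "alignment" in raw:
        config.alignment = prep.AlignmentConfig(**raw["alignment"])
    return config
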