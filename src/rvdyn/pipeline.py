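"""Configuration, orchestration and reporting for end-to-end runs.

``run_pipeline`` executes simulate -> extract -> analyze -> report against
a validated :class:`RunConfig`: it synthesises the configured cohorts,
measures every beat and paced complex, aggregates per-patient metrics and
hysteresis features, runs the group statistics (Welch/Holm tests,
reference-model predictions with ROC, CART on hysteresis features) and
writes CSV tables plus a versioned ``report.json`` and a run manifest
(seed, config hash, package versions).  Runs are deterministic for a
fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .core import PatientRecord
from .ecg import (LandmarkRejection, aggregate_measurements,
                  detect_paced_ecg_landmarks, hysteresis_features)
from .egm import DetectionWindows, ExtractionConfig, FractionationParams, \
    measure_record
from .restitution import patient_metrics
from .stats import (REFERENCE_DIAGNOSTIC_MODEL, cart_fit, group_tests,
                    predict_logistic, roc_auc)
from .synth import CohortSpec, synth_cohort

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: int = Field(ge=1, default=4)
    sampling: str = "iid"
    include_ecg: bool = True
    noise_sd_mv: float = 0.02
    overrides: dict = Field(default_factory=dict)


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start_ms: float = 400.0
    coarse_step: float = 20.0
    coarse_floor: float = 300.0
    fine_step: float = 5.0
    bump_ms: float = 8.0
    refine_step: float = 2.0
    abort_floor: float = 150.0


class WindowsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    activation: tuple[float, float] = (5.0, 200.0)
    repolarization: tuple[float, float] = (80.0, 450.0)
    blanking_ms: float = 5.0


class FracConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    band_hz: tuple[float, float] = (30.0, 250.0)
    snr_cutoff: float = 0.4
    min_separation_ms: float = 5.0
    relative_floor: float = 0.20


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cart_min_leaf: int = 5
    cart_max_depth: int = 3
    positive_group: str = "definite_arvc"


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    fs_egm: float = 1200.0
    fs_ecg: float = 1000.0
    groups: dict[str, CohortConfig] = Field(
        default_factory=lambda: {"definite_arvc": CohortConfig(),
                                 "rvot_ectopy": CohortConfig()})
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    windows: WindowsConfig = Field(default_factory=WindowsConfig)
    fractionation: FracConfig = Field(default_factory=FracConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    output_dir: str = "rvdyn_run"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml
        try:
            data = yaml.safe_load(Path(path).read_text())
            return cls.model_validate(data or {})
        except (ValidationError, OSError, yaml.YAMLError) as err:
            raise ConfigError(str(err)) from err

    def config_hash(self) -> str:
        data = self.model_dump()
        data.pop("output_dir", None)  # hash covers the science, not paths
        blob = json.dumps(data, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate(config: RunConfig) -> dict[str, list[PatientRecord]]:
    rng = np.random.default_rng(config.seed)
    cohorts: dict[str, list[PatientRecord]] = {}
    for group, gcfg in sorted(config.groups.items()):
        spec = CohortSpec(group=group, n_patients=gcfg.n_patients,
                          sampling=gcfg.sampling,
                          include_ecg=gcfg.include_ecg,
                          noise_sd_mv=gcfg.noise_sd_mv,
                          params=gcfg.overrides)
        cohorts[group] = synth_cohort(
            spec, rng, fs=config.fs_egm,
            protocol_kwargs=config.protocol.model_dump())
    return cohorts


def extract(config: RunConfig,
            cohorts: dict[str, list[PatientRecord]]) -> dict:
    windows = DetectionWindows(activation=config.windows.activation,
                               repolarization=config.windows.repolarization,
                               blanking_ms=config.windows.blanking_ms)
    frac = FractionationParams(**config.fractionation.model_dump())
    cfg = ExtractionConfig(windows=windows, frac_params=frac)
    beat_tables, ecg_rows = [], []
    n_rejected = 0
    for group, records in cohorts.items():
        for rec in records:
            beat_tables.append(measure_record(rec, cfg))
            landmarks = []
            for (lead, state, rep), tr in rec.ecg_traces.items():
                try:
                    landmarks.append(detect_paced_ecg_landmarks(
                        tr, 0.0, lead=lead, state=state, repeat=rep))
                except LandmarkRejection as err:
                    n_rejected += 1
                    logger.debug("ECG rejection %s %s: %s",
                                 rec.patient_id, (lead, state, rep), err)
            if landmarks:
                ecg_rows.append((rec.patient_id, group, landmarks))
    return {"beat_tables": beat_tables, "ecg": ecg_rows,
            "n_ecg_rejected": n_rejected}


def analyze(config: RunConfig, cohorts: dict, extracted: dict) -> pd.DataFrame:
    records = {rec.patient_id: rec
               for recs in cohorts.values() for rec in recs}
    rows = []
    ecg_by_pid = {pid: lms for pid, _, lms in extracted["ecg"]}
    for bt in extracted["beat_tables"]:
        pid = bt.patient_id.iloc[0]
        rec = records[pid]
        m = patient_metrics(bt, rec.protocol, rec.electrode_map)
        if pid in ecg_by_pid:
            try:
                steady = aggregate_measurements(ecg_by_pid[pid], "steady")
                pre = aggregate_measurements(ecg_by_pid[pid], "pre_erp")
                hyst = hysteresis_features(steady, pre)
                for k, v in hyst.hysteresis.items():
                    m[f"hyst_{k}_ms"] = v
            except ValueError:
                pass
        rows.append(m)
    return pd.DataFrame(rows)


def report_stats(config: RunConfig, features: pd.DataFrame) -> dict:
    out: dict = {"schema_version": REPORT_SCHEMA_VERSION, "tests": {},
                 "warnings": []}
    counts = features.group.value_counts()
    multi = (counts >= 2).sum() >= 2
    test_metrics = ("verp_ms", "delta_at_preverp_ms", "delta_rt_preverp_ms",
                    "frac_ss", "mid", "hyst_stim_to_j_ms")
    for metric in test_metrics:
        if metric not in features or not multi:
            out["warnings"].append(f"group tests skipped for {metric}")
            continue
        sub = features[[metric, "group"]].dropna()
        if sub.group.nunique() < 2 or len(sub) < 4:
            out["warnings"].append(f"group tests skipped for {metric}")
            continue
        out["tests"][metric] = group_tests(
            sub[metric], sub.group).to_dict(orient="records")

    # reference-model predictions + ROC against the positive group
    pos = config.stats.positive_group
    needed = REFERENCE_DIAGNOSTIC_MODEL.covariates()
    have = features.dropna(subset=[c for c in needed
                                   if c in features.columns])
    if set(needed) <= set(features.columns) and have.group.nunique() >= 2 \
            and pos in set(have.group):
        probs = [predict_logistic(REFERENCE_DIAGNOSTIC_MODEL, row)
                 for _, row in have.iterrows()]
        labels = (have.group == pos).astype(int)
        curve, auc_val = roc_auc(probs, labels)
        out["reference_model"] = {
            "auc": auc_val,
            "roc": curve.to_dict(orient="list"),
            "n": int(len(have)),
        }
    else:
        out["warnings"].append("reference-model ROC skipped")

    hyst_cols = [c for c in features.columns if c.startswith("hyst_")]
    cart_data = features.dropna(subset=hyst_cols) if hyst_cols \
        else pd.DataFrame()
    if hyst_cols and len(cart_data) >= 2 * config.stats.cart_min_leaf \
            and cart_data.group.nunique() >= 2:
        tree = cart_fit(cart_data[hyst_cols],
                        (cart_data.group == pos).map(
                            {True: pos, False: "other"}),
                        min_leaf=config.stats.cart_min_leaf,
                        max_depth=config.stats.cart_max_depth)
        out["cart"] = tree.to_dict()
    else:
        out["warnings"].append("CART skipped (insufficient data)")
    return out


def qc_report(extracted: dict) -> dict:
    """Counts of rejected beats per reason and excluded channels."""
    flags: dict[str, int] = {}
    n_beats = 0
    for bt in extracted["beat_tables"]:
        n_beats += len(bt)
        for f in bt.qc_flags:
            if f:
                for part in f.split(";"):
                    flags[part] = flags.get(part, 0) + 1
    return {"n_beats": n_beats, "rejections_by_reason": flags,
            "n_ecg_rejected": extracted.get("n_ecg_rejected", 0)}


def run_pipeline(config: RunConfig, write_raw: bool = False) -> dict:
    """Run simulate -> extract -> analyze -> report; returns the report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = {}
    t0 = time.perf_counter()

    def stage(name, fn, *args):
        t = time.perf_counter()
        try:
            result = fn(*args)
        except (ConfigError, PipelineError):
            raise
        except Exception as err:
            raise PipelineError(name, str(err)) from err
        stages[name] = round(time.perf_counter() - t, 3)
        logger.info("stage %-9s %6.2f s", name, stages[name])
        return result

    cohorts = stage("simulate", simulate, config)
    if write_raw:
        from .io import write_record
        for group, records in cohorts.items():
            for rec in records:
                write_record(rec, outdir / "raw" / group / rec.patient_id)
    extracted = stage("extract", extract, config, cohorts)
    features = stage("analyze", analyze, config, cohorts, extracted)
    stats = stage("report", report_stats, config, features)

    beats = pd.concat(extracted["beat_tables"], ignore_index=True)
    beats.to_csv(outdir / "beats.csv", index=False)
    features.to_csv(outdir / "features.csv", index=False)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "qc": qc_report(extracted),
        "group_means": {
            g: {c: (None if not np.isfinite(v) else round(float(v), 4))
                for c, v in sub.mean(numeric_only=True).items()}
            for g, sub in features.groupby("group")},
        "stats": stats,
    }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=str))
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.model_dump(),
        "timing_s": {**stages,
                     "total": round(time.perf_counter() - t0, 3)},
        "versions": {"rvdyn": __version__,
                     "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return report
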