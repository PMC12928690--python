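"""End-to-end pipeline: raw recordings -> features -> classifier comparison.

Per subject: R-peak detection, quality screening for a 240 s window,
airflow integration to ILV, 4 Hz resampling/detrending of both tachogram
and ILV, then the three feature families (spectral HRV, FRF band gains,
causal IR descriptors).  Subjects failing any stage are excluded with a
machine-readable reason, never fatally.  The cohort-level experiment
runs the full grid of feature sets x balancing strategies x classifiers
under stratified cross-validation and writes tidy results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import frf as frf_mod
from . import impulse, ml, preprocess, spectral
from .types import BandScheme, NoBeatsError, Rejection, SampledSignal

logger = logging.getLogger("cardioresp")

__all__ = [
    "PipelineConfig",
    "read_cohort",
    "subject_features",
    "extract_feature_table",
    "run_grid",
    "run_pipeline",
]

FEATURE_COLUMNS = [c for cols in ml.FEATURE_FAMILIES.values() for c in cols]


@dataclass
class PipelineConfig:
    manifest: Optional[Path] = None
    out_dir: Path = Path("run_out")
    segment_s: float = 240.0
    target_fs: float = 4.0
    bands: BandScheme = field(default_factory=BandScheme)
    welch: spectral.WelchConfig = field(default_factory=spectral.WelchConfig)
    ir: impulse.IrConfig = field(default_factory=impulse.IrConfig)
    coherence_min: float = 0.0
    feature_sets: tuple = tuple(ml.FEATURE_SETS)
    balancings: tuple = ("none", "nearmiss1", "smote")
    classifiers: tuple = ("logreg", "svm_linear", "svm_rbf")
    n_folds: int = 5
    seed: int = 0


def read_csv_signal(path, channel: str, units: str = "") -> SampledSignal:
    """Read a two-column (time_s, value) CSV into a SampledSignal."""
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    t, v = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError(f"{path}: times must be strictly increasing")
    fs = 1.0 / np.median(dt)
    return SampledSignal(t0=float(t[0]), fs=fs, samples=v, units=units, channel=channel)


def read_cohort(manifest_path) -> tuple:
    """Load a cohort manifest; returns (records, exclusions).

    The manifest is a CSV with columns subject_id, label, ecg_path,
    airflow_path (paths relative to the manifest's directory).  A
    subject with an unreadable or missing channel is excluded with a
    reason, not fatally.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    if df.empty:
        raise ValueError("empty cohort manifest")
    base = manifest_path.parent
    records, exclusions = [], []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        try:
            ecg = read_csv_signal(base / row["ecg_path"], channel="ecg", units="au")
            airflow = read_csv_signal(base / row["airflow_path"], channel="airflow", units="mL/s")
        except (OSError, ValueError, KeyError) as exc:
            exclusions.append({"subject_id": sid, "reason": "unreadable_channel", "detail": str(exc)})
            continue
        records.append({"subject_id": sid, "label": int(row["label"]), "ecg": ecg, "airflow": airflow})
    return records, exclusions


def subject_features(
    ecg: SampledSignal,
    airflow: SampledSignal,
    cfg: PipelineConfig = None,
) -> dict:
    """All three feature families for one subject's ECG + airflow.

    Raises ValueError (with a reason message) when the subject cannot be
    processed: no beats, no clean segment, or an undefined feature.
    """
    cfg = cfg or PipelineConfig()
    try:
        beats = preprocess.detect_r_peaks(ecg)
    except NoBeatsError as exc:
        raise ValueError(f"no_beats: {exc}") from exc
    sel = preprocess.screen_quality(beats, airflow, segment_s=cfg.segment_s)
    if isinstance(sel, Rejection):
        raise ValueError("rejected_segment: " + "; ".join(sel.reasons))
    ilv_raw = preprocess.integrate_airflow(airflow.crop(sel.start_s, sel.end_s))
    rri4 = preprocess.resample_detrend(beats, cfg.target_fs, sel.start_s, sel.end_s)
    ilv4 = preprocess.resample_detrend(ilv_raw, cfg.target_fs, sel.start_s, sel.end_s)

    hrv = spectral.hrv_features(rri4, cfg.bands, cfg.welch)
    fe = frf_mod.estimate_frf(ilv4, rri4, cfg.welch)
    fg = frf_mod.frf_band_gains(fe, cfg.bands, cfg.coherence_min)
    ir = impulse.estimate_ir(ilv4, rri4, cfg.ir)
    ird = impulse.ir_descriptors(ir, cfg.bands)

    feats = {
        "hrv_lf": hrv.hrv_lf,
        "hrv_hf": hrv.hrv_hf,
        "hrv_lf_hf": hrv.hrv_lf_hf,
        "frf_gain_lf": fg.frf_gain_lf,
        "frf_gain_hf": fg.frf_gain_hf,
        "ir_magnitude": ird.ir_magnitude,
        "dg_total": ird.dg_total,
        "dg_lf": ird.dg_lf,
        "dg_hf": ird.dg_hf,
        "t_char": ird.t_char,
    }
    missing = [k for k, v in feats.items() if v is None or not np.isfinite(v)]
    if missing:
        raise ValueError("undefined_features: " + ",".join(missing))
    return feats


def extract_feature_table(records: list, cfg: PipelineConfig = None) -> tuple:
    """Run feature extraction over a cohort; returns (FeatureTable, exclusions)."""
    cfg = cfg or PipelineConfig()
    rows, labels, exclusions = {}, {}, []
    for rec in records:
        sid = rec["subject_id"] if isinstance(rec, dict) else rec.subject_id
        ecg = rec["ecg"] if isinstance(rec, dict) else rec.ecg
        airflow = rec["airflow"] if isinstance(rec, dict) else rec.airflow
        label = rec["label"] if isinstance(rec, dict) else rec.label
        t0 = time.perf_counter()
        try:
            rows[sid] = subject_features(ecg, airflow, cfg)
            labels[sid] = int(label)
        except ValueError as exc:
            reason = str(exc).split(":", 1)[0]
            exclusions.append({"subject_id": sid, "reason": reason, "detail": str(exc)})
            logger.info("excluded %s: %s", sid, exc)
        logger.debug("subject %s processed in %.2f s", sid, time.perf_counter() - t0)
    if not rows:
        raise RuntimeError("no subjects survived preprocessing")
    frame = pd.DataFrame.from_dict(rows, orient="index")[FEATURE_COLUMNS]
    table = ml.FeatureTable(frame, pd.Series(labels, name="label"), {"exclusions": exclusions})
    return table, exclusions


def run_grid(table: ml.FeatureTable, cfg: PipelineConfig = None) -> pd.DataFrame:
    """Evaluate the full grid; returns a tidy DataFrame.

    One row per (feature_set, balancing, classifier, metric) with the
    cross-fold mean and SD.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for fs in cfg.feature_sets:
        for bal in cfg.balancings:
            for clf in cfg.classifiers:
                ec = ml.ExperimentConfig(
                    feature_set=fs, balancing=bal, classifier=clf, n_folds=cfg.n_folds, seed=cfg.seed
                )
                rep = ml.run_experiment(table, ec)
                for metric in ml.METRICS:
                    rows.append(
                        {
                            "feature_set": fs,
                            "balancing": bal,
                            "classifier": clf,
                            "metric": metric,
                            "mean": rep.mean[metric],
                            "sd": rep.sd[metric],
                        }
                    )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Full run: read cohort, extract features, evaluate grid, write outputs.

    Writes features.csv, results.csv, exclusions.csv and a JSON run
    manifest (config + seed + package version) sufficient to reproduce
    the run.  Returns the output directory.
    """
    from . import __version__

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, read_excl = read_cohort(cfg.manifest)
    if not records:
        raise RuntimeError("no readable subjects in manifest")
    table, proc_excl = extract_feature_table(records, cfg)
    feat = table.frame.copy()
    feat.insert(0, "label", table.labels)
    feat.to_csv(out / "features.csv", index_label="subject_id")
    results = run_grid(table, cfg)
    results.to_csv(out / "results.csv", index=False)
    pd.DataFrame(read_excl + proc_excl).to_csv(out / "exclusions.csv", index=False)
    manifest = {
        "config": _config_dict(cfg),
        "version": __version__,
        "n_subjects": int(len(table.frame)),
        "n_excluded": len(read_excl) + len(proc_excl),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["manifest"] = str(d["manifest"])
    d["out_dir"] = str(d["out_dir"])
    return d
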