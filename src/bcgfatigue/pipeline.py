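"""End-to-end pipeline: simulate -> estimate HR -> HRV -> classify -> evaluate.

Every stage boundary is a plain CSV with a documented schema, so any
stage can be fed real sensor exports instead of synthetic data (the
natural entry point for the real device, which outputs only heart rate,
is the per-second ``second,hr_bpm`` series).  A run manifest records the
configuration hash, seeds and SHA-256 checksums of every file written;
rerunning the same configuration reproduces identical checksums.
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

from . import classify, evaluation, hrv, spectral, synthetic

__all__ = [
    "PipelineConfig",
    "validate_config",
    "run_pipeline",
    "load_hr_series_csv",
    "write_hr_series_csv",
    "load_hrv_series_csv",
    "write_hrv_series_csv",
]

logger = logging.getLogger("bcgfatigue")


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, nested by stage."""

    n_subjects: int = 20
    duration_s: float = 7200.0
    sampling_rate: float = 10.0
    drift_fraction: float = 0.1
    seed: int = 0

    filter_spec: spectral.FilterSpec = field(default_factory=spectral.FilterSpec)
    window_s: float = 10.0
    pad_factor: int = 8
    ref_duration_s: int = 600
    classifier: classify.ClassifierConfig = field(
        default_factory=classify.ClassifierConfig
    )
    output_dir: Path = Path("bcgfatigue_run")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "filter" in kwargs:
            kwargs["filter_spec"] = spectral.FilterSpec(**kwargs.pop("filter"))
        if "classifier" in kwargs:
            kwargs["classifier"] = classify.ClassifierConfig(**kwargs.pop("classifier"))
        if "output_dir" in kwargs:
            kwargs["output_dir"] = Path(kwargs["output_dir"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        return d


def validate_config(config: PipelineConfig) -> list[str]:
    """Check every nested block's invariants; violations are returned, not raised."""
    violations: list[str] = []
    if config.n_subjects < 1:
        violations.append("n_subjects must be >= 1")
    if config.duration_s <= 0:
        violations.append("duration_s must be positive")
    nyq = config.sampling_rate / 2.0
    f = config.filter_spec
    if not (0.0 < f.low_cut < f.high_cut):
        violations.append("filter: need 0 < low_cut < high_cut")
    if f.high_cut >= nyq:
        violations.append(
            f"filter.high_cut {f.high_cut} Hz must be below the Nyquist "
            f"frequency {nyq} Hz at sampling_rate {config.sampling_rate} Hz"
        )
    if not (0.0 <= config.drift_fraction < 0.5):
        violations.append("drift_fraction must lie in [0, 0.5)")
    if config.window_s < 4.0:
        violations.append("window_s must be at least 4 s")
    if config.window_s > config.duration_s:
        violations.append("window_s must not exceed duration_s")
    if config.ref_duration_s <= 0 or config.ref_duration_s > config.duration_s:
        violations.append("ref_duration_s must be positive and within duration_s")
    violations.extend(f"classifier: {v}" for v in config.classifier.violations())
    return violations


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_hr_series_csv(series: spectral.HeartRateSeries, path: Path) -> None:
    pd.DataFrame({"second": series.seconds, "hr_bpm": series.hr}).to_csv(
        path, index=False, float_format="%.6f"
    )


def load_hr_series_csv(path: str | Path, subject_id: str | None = None) -> spectral.HeartRateSeries:
    df = pd.read_csv(path, comment="#")
    return spectral.HeartRateSeries(
        subject_id=subject_id or Path(path).stem.replace("_hr", ""),
        seconds=df["second"].to_numpy(int),
        hr=df["hr_bpm"].to_numpy(float),
    )


def write_hrv_series_csv(series: hrv.HRVSeries, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# h_ref_bpm={series.h_ref:.6f}\n")
        pd.DataFrame({"second": series.seconds, "v": series.v}).to_csv(
            fh, index=False, float_format="%.8f"
        )


def load_hrv_series_csv(path: str | Path, subject_id: str | None = None) -> hrv.HRVSeries:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# h_ref_bpm="):
        raise ValueError(f"{path} lacks the '# h_ref_bpm=' header line")
    h_ref = float(first.split("=", 1)[1])
    df = pd.read_csv(path, comment="#")
    return hrv.HRVSeries(
        subject_id=subject_id or path.stem.replace("_hrv", ""),
        seconds=df["second"].to_numpy(int),
        v=df["v"].to_numpy(float),
        h_ref=h_ref,
    )


def run_pipeline(config: PipelineConfig, write_waveforms: bool = True) -> dict:
    """Run every stage in order and return the manifest dict.

    Stages: cohort simulation, per-second heart-rate estimation, HRV
    index, per-window random-forest evaluation, HRV-accuracy
    correlation, and device agreement on the packaged sensor-vs-monitor
    fixture.  Any stage failure raises with the stage name and offending
    subject or window in the message.

    ``write_waveforms=False`` skips the (large) raw-waveform CSVs while
    keeping every derived table; the computation is identical.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    logger.info("stage simulate: %d subjects, %.0f s", config.n_subjects, config.duration_s)
    records = synthetic.simulate_cohort(
        n_subjects=config.n_subjects,
        duration=config.duration_s,
        seed=config.seed,
        sampling_rate=config.sampling_rate,
        drift_fraction=config.drift_fraction,
    )
    if write_waveforms:
        for rec in records:
            for key, p in synthetic.write_record(rec, out / "bcg").items():
                files[f"bcg/{p.name}"] = _sha256(p)

    hr_dir = out / "hr"
    hr_dir.mkdir(exist_ok=True)
    hr_list = []
    for rec in records:
        logger.info("stage estimate-hr: subject %s", rec.subject_id)
        try:
            series = spectral.hr_series(
                rec,
                window_s=config.window_s,
                spec=config.filter_spec,
                pad_factor=config.pad_factor,
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage estimate-hr failed for subject {rec.subject_id}: {exc}"
            ) from exc
        hr_list.append(series)
        p = hr_dir / f"{rec.subject_id}_hr.csv"
        write_hr_series_csv(series, p)
        files[f"hr/{p.name}"] = _sha256(p)

    hrv_dir = out / "hrv"
    hrv_dir.mkdir(exist_ok=True)
    hrv_list = []
    for series in hr_list:
        try:
            vseries = hrv.hrv_series(series, ref_duration_s=config.ref_duration_s)
        except Exception as exc:
            raise RuntimeError(
                f"stage hrv failed for subject {series.subject_id}: {exc}"
            ) from exc
        hrv_list.append(vseries)
        p = hrv_dir / f"{series.subject_id}_hrv.csv"
        write_hrv_series_csv(vseries, p)
        files[f"hrv/{p.name}"] = _sha256(p)
    manifest_subjects = [s.subject_id for s in hrv_list]
    (hrv_dir / "manifest.json").write_text(json.dumps(manifest_subjects))

    logger.info("stage classify: %d windows candidate", int(config.duration_s // 600) - 1)
    try:
        profile = classify.evaluate_all_windows(hrv_list, config.classifier)
    except Exception as exc:
        raise RuntimeError(f"stage classify failed: {exc}") from exc
    p = out / "accuracy_profile.csv"
    profile.to_frame().to_csv(p, index=False, float_format="%.6f")
    files[p.name] = _sha256(p)
    p = out / "accuracy_per_repeat.csv"
    profile.per_repeat_frame().to_csv(p, index=False, float_format="%.6f")
    files[p.name] = _sha256(p)

    logger.info("stage evaluate: correlation + device agreement")
    if len(profile.window_indices) >= 3:
        try:
            corr = evaluation.hrv_accuracy_correlation(profile)
            corr_payload = {
                "pearson_r": corr.pearson_r,
                "mean_v": corr.x.tolist(),
                "mean_accuracy_pct": corr.y.tolist(),
                "mean_v_norm": corr.x_norm.tolist(),
                "mean_accuracy_norm": corr.y_norm.tolist(),
            }
        except Exception as exc:
            raise RuntimeError(f"stage evaluate (correlation) failed: {exc}") from exc
    else:
        # a correlation over <3 windows is meaningless; record why
        corr_payload = {
            "pearson_r": None,
            "note": "fewer than 3 candidate windows; correlation not computed",
        }
    p = out / "hrv_accuracy_correlation.json"
    p.write_text(json.dumps(corr_payload, indent=2))
    files[p.name] = _sha256(p)

    pairs = evaluation.load_sensor_monitor_pairs()
    report = evaluation.agreement(pairs[["hr_sensor", "hr_monitor"]].to_numpy())
    p = out / "device_agreement.json"
    p.write_text(json.dumps(report.summary(), indent=2))
    files[p.name] = _sha256(p)

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "n_windows": int(len(profile.window_indices)),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
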