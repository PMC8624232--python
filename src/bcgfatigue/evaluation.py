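"""Agreement and correlation statistics for the fatigue pipeline.

Two analyses live here.  First, device agreement: paired heart-rate
readings from the fiber-optic BCG sensor and a reference ECG monitor
(one pair per subject, shipped as a packaged fixture) are summarised by
their absolute errors.  Note on dispersion: the published "1.30 +/- 0.81
beats/min" summary of these pairs is reproduced here as the *population
variance* of the absolute errors; the population and sample standard
deviations of the same numbers are 0.90 and 0.92.  All three are
reported so the reader can see which statistic the +/- figure matches.

Second, the fatigue-trend correlation: the Pearson correlation between
per-window mean HRV index and per-window classification accuracy, with
min-max normalised copies of both vectors for plotting on a common 0-1
scale (Pearson r is unchanged by that normalisation).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .classify import AccuracyProfile

__all__ = [
    "AgreementReport",
    "CorrelationReport",
    "agreement",
    "hrv_accuracy_correlation",
    "load_sensor_monitor_pairs",
    "minmax_normalize",
]


@dataclass
class AgreementReport:
    """Absolute-error summary of paired test-vs-reference heart rates."""

    hr_test: np.ndarray
    hr_reference: np.ndarray
    abs_errors: np.ndarray
    mean_abs_error: float
    std_abs_error_population: float
    std_abs_error_sample: float
    var_abs_error_population: float
    max_abs_error: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hr_test": self.hr_test,
                "hr_reference": self.hr_reference,
                "abs_error": self.abs_errors,
            }
        )

    def summary(self) -> dict[str, float]:
        return {
            "mean_abs_error": self.mean_abs_error,
            "std_abs_error_population": self.std_abs_error_population,
            "std_abs_error_sample": self.std_abs_error_sample,
            "var_abs_error_population": self.var_abs_error_population,
            "max_abs_error": self.max_abs_error,
        }


@dataclass
class CorrelationReport:
    """Pearson correlation between window-mean HRV and window accuracy."""

    x: np.ndarray  # per-window mean HRV index
    y: np.ndarray  # per-window mean accuracy, %
    x_norm: np.ndarray
    y_norm: np.ndarray
    pearson_r: float


def load_sensor_monitor_pairs() -> pd.DataFrame:
    """The packaged 20-subject sensor-vs-monitor heart-rate table."""
    with resources.files("bcgfatigue.data").joinpath(
        "sensor_vs_monitor_hr.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def agreement(pairs) -> AgreementReport:
    """Summarise paired heart-rate readings by their absolute errors.

    ``pairs`` is a sequence of (hr_test, hr_reference) rows or a
    DataFrame with those two columns first.  Both the population (/n)
    and sample (/(n-1)) standard deviations of the absolute errors are
    reported, plus the population variance (see the module note on the
    published +/- figure).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("pairs must be a sequence of (hr_test, hr_reference)")
    if len(arr) < 2:
        raise ValueError("need at least 2 pairs")
    hr_test, hr_ref = arr[:, 0], arr[:, 1]
    if np.any(hr_test <= 0) or np.any(hr_ref <= 0):
        raise ValueError("heart rates must be positive")
    errs = np.abs(hr_test - hr_ref)
    return AgreementReport(
        hr_test=hr_test,
        hr_reference=hr_ref,
        abs_errors=errs,
        mean_abs_error=float(errs.mean()),
        std_abs_error_population=float(errs.std(ddof=0)),
        std_abs_error_sample=float(errs.std(ddof=1)),
        var_abs_error_population=float(errs.var(ddof=0)),
        max_abs_error=float(errs.max()),
    )


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Map a vector affinely onto [0, 1]; min -> 0, max -> 1 exactly."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("cannot min-max normalise a constant vector")
    return (x - lo) / (hi - lo)


def hrv_accuracy_correlation(profile: AccuracyProfile) -> CorrelationReport:
    """Pearson correlation of window-mean HRV against window accuracy.

    Fatigue raises the HRV index and separates the candidate windows
    from the reference state, so a strong positive correlation between
    the two per-window summaries indicates that classification accuracy
    tracks the fatigue trend and can serve as its quantitative readout.
    """
    x = np.asarray(profile.mean_v, dtype=float)
    y = np.asarray(profile.mean_accuracy, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 windows for a correlation")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("window means must be finite")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined: constant HRV or accuracy")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationReport(
        x=x,
        y=y,
        x_norm=minmax_normalize(x),
        y_norm=minmax_normalize(y),
        pearson_r=r,
    )
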