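"""The frequency-domain heart-rate-variability (HRV) index.

The index compares the current heart rate h against a reference heart
rate h_ref (the mean over the first 10 minutes of the task, taken as the
non-fatigued state):

    V = (h_ref / h) ** 4

V equals 1 in the reference state, rises above 1 as heart rate falls
below its reference (the direction associated with deepening mental
fatigue), and the fourth power expands the sensitivity of the index to
small heart-rate changes.  V is dimensionless and invariant to a common
rescaling of h and h_ref.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import HeartRateSeries

__all__ = ["HRVSeries", "reference_hr", "hrv_value", "hrv_series"]


@dataclass
class HRVSeries:
    """Per-second HRV index values and the reference heart rate behind them."""

    subject_id: str
    seconds: np.ndarray
    v: np.ndarray
    h_ref: float

    def __post_init__(self) -> None:
        if len(self.seconds) != len(self.v):
            raise ValueError("seconds and v must have equal length")
        if not self.h_ref > 0:
            raise ValueError("h_ref must be positive")


def reference_hr(series: HeartRateSeries, ref_duration_s: int = 600) -> float:
    """Mean heart rate over the first ``ref_duration_s`` seconds.

    The first 10 minutes of the task define the non-fatigued reference
    state; their average heart rate is the reference h_ref.
    """
    if len(series.hr) < ref_duration_s:
        raise ValueError(
            f"series covers {len(series.hr)} s, shorter than the "
            f"{ref_duration_s} s reference window"
        )
    return float(np.mean(series.hr[:ref_duration_s]))


def hrv_value(h, h_ref):
    """Evaluate the HRV index V = (h_ref / h)^4; accepts scalars or arrays."""
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("heart rate h must be positive")
    if not np.all(np.asarray(h_ref, dtype=float) > 0):
        raise ValueError("reference heart rate h_ref must be positive")
    out = (h_ref / h) ** 4
    return float(out) if out.ndim == 0 else out


def hrv_series(series: HeartRateSeries, ref_duration_s: int = 600) -> HRVSeries:
    """Per-second HRV index over a full heart-rate series.

    The index is computed over the reference window too (there V
    fluctuates around 1); those seconds provide the reference-state
    samples for classification.
    """
    h_ref = reference_hr(series, ref_duration_s)
    return HRVSeries(
        subject_id=series.subject_id,
        seconds=series.seconds.copy(),
        v=hrv_value(series.hr, h_ref),
        h_ref=h_ref,
    )
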