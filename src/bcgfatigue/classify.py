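"""Reference-vs-window fatigue classification with a random forest.

Each second of recording yields one sample: the HRV index value at that
second (optionally with a few preceding seconds as extra feature lags).
Samples from minutes 0-10 of every subject form the *reference* class;
samples from a later 10-minute window form the *candidate state* class.
A random forest is trained on a stratified random 80/20 split of the
pooled samples and scored on the held-out 20 %; the split/fit/score
cycle is repeated (default 20 times) and accuracies averaged.  As
fatigue deepens, heart rate drifts away from its reference and the two
classes separate, so the mean accuracy per window traces the fatigue
trend over the task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .hrv import HRVSeries

__all__ = [
    "ClassifierConfig",
    "WindowDataset",
    "AccuracyProfile",
    "build_window_dataset",
    "train_eval_once",
    "evaluate_all_windows",
]

#: Seconds per analysis window (10 minutes).
WINDOW_S = 600


@dataclass(frozen=True)
class ClassifierConfig:
    """Random-forest evaluation settings.

    d_features is the number of features drawn per split (d out of the
    D = feature_lags total); None means ceil(sqrt(D)).  With the default
    single-lag feature (one HRV value per sample) D = d = 1.
    """

    n_trees: int = 100
    d_features: int | None = None
    train_fraction: float = 0.8
    n_repeats: int = 20
    feature_lags: int = 1
    seed: int = 0

    def violations(self) -> list[str]:
        """Invariant violations as messages (empty when valid)."""
        out = []
        if self.n_trees < 1:
            out.append("n_trees must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            out.append("train_fraction must lie strictly between 0 and 1")
        if self.n_repeats < 1:
            out.append("n_repeats must be >= 1")
        if self.feature_lags < 1:
            out.append("feature_lags must be >= 1")
        elif not (1 <= self.resolved_d_features() <= self.feature_lags):
            out.append(
                f"d_features={self.resolved_d_features()} must lie in "
                f"[1, D={self.feature_lags}]"
            )
        return out

    def validate(self) -> None:
        violations = self.violations()
        if violations:
            raise ValueError("; ".join(violations))

    def resolved_d_features(self) -> int:
        if self.d_features is None:
            return math.ceil(math.sqrt(self.feature_lags))
        return self.d_features


@dataclass
class WindowDataset:
    """Pooled labelled samples: reference state vs one candidate window."""

    features: np.ndarray  # (n_samples, feature_lags)
    labels: np.ndarray  # 0 = reference, 1 = candidate state
    window_index: int  # 1 = minutes 10-20, ..., 11 = minutes 110-120
    n_reference: int
    n_state: int

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")
        if self.n_reference + self.n_state != len(self.labels):
            raise ValueError("class counts must sum to the sample count")


@dataclass
class AccuracyProfile:
    """Mean classification accuracy per candidate window, plus window-mean HRV."""

    window_indices: np.ndarray  # 1..n_windows
    mean_accuracy: np.ndarray  # %, one per window
    per_repeat: np.ndarray  # (n_windows, n_repeats), %
    mean_v: np.ndarray  # pooled mean HRV index per window

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start_min": 10 * self.window_indices,
                "window_end_min": 10 * (self.window_indices + 1),
                "mean_accuracy_pct": self.mean_accuracy,
                "mean_v": self.mean_v,
            }
        )

    def per_repeat_frame(self) -> pd.DataFrame:
        rows = []
        for wi, accs in zip(self.window_indices, self.per_repeat):
            for r, a in enumerate(accs):
                rows.append(
                    {"window_index": int(wi), "repeat": r, "accuracy_pct": a}
                )
        return pd.DataFrame(rows)


def _lagged_features(v: np.ndarray, lags: int) -> np.ndarray:
    """Per-second feature vectors [v_t, v_{t-1}, ..., v_{t-lags+1}].

    The first lags-1 seconds of a block are padded by repeating the
    block's first value, so each block of length n yields n samples.
    """
    if lags == 1:
        return v[:, None].astype(float)
    padded = np.concatenate([np.full(lags - 1, v[0]), v]).astype(float)
    windows = np.lib.stride_tricks.sliding_window_view(padded, lags)
    return windows[:, ::-1].copy()


def build_window_dataset(
    cohort_hrv: list[HRVSeries],
    window_index: int,
    config: ClassifierConfig | None = None,
) -> WindowDataset:
    """Pool reference and candidate-window samples across a cohort.

    Reference samples come from seconds [0, 600) of every subject and
    candidate-state samples from seconds [600*k, 600*(k+1)) where k is
    ``window_index`` (1 = minutes 10-20).  With 20 subjects this yields
    12,000 samples per class.
    """
    if config is None:
        config = ClassifierConfig()
    config.validate()
    if window_index < 1:
        raise ValueError("window_index must be >= 1 (1 = minutes 10-20)")
    need = WINDOW_S * (window_index + 1)
    ref_feats, state_feats = [], []
    for series in cohort_hrv:
        if len(series.v) < need:
            raise ValueError(
                f"subject {series.subject_id} covers {len(series.v)} s, "
                f"too short for window {window_index} (needs {need} s)"
            )
        ref_feats.append(_lagged_features(series.v[:WINDOW_S], config.feature_lags))
        block = series.v[WINDOW_S * window_index : WINDOW_S * (window_index + 1)]
        state_feats.append(_lagged_features(block, config.feature_lags))
    ref = np.vstack(ref_feats)
    state = np.vstack(state_feats)
    features = np.vstack([ref, state])
    labels = np.concatenate([np.zeros(len(ref), int), np.ones(len(state), int)])
    return WindowDataset(
        features=features,
        labels=labels,
        window_index=window_index,
        n_reference=len(ref),
        n_state=len(state),
    )


def train_eval_once(
    dataset: WindowDataset,
    config: ClassifierConfig | None = None,
    repeat_seed: int = 0,
) -> float:
    """One stratified 80/20 hold-out: fit a forest, return accuracy in %.

    The forest's majority vote over trees is scored on the held-out 20 %.
    Identical (dataset, config, repeat_seed) give identical accuracy.
    """
    if config is None:
        config = ClassifierConfig()
    config.validate()
    if len(np.unique(dataset.labels)) < 2:
        raise ValueError("dataset must contain both classes")
    rs = int(repeat_seed) % (2**32 - 1)
    x_tr, x_va, y_tr, y_va = train_test_split(
        dataset.features,
        dataset.labels,
        train_size=config.train_fraction,
        stratify=dataset.labels,
        random_state=rs,
    )
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.resolved_d_features(),
        random_state=rs,
        n_jobs=1,
    )
    forest.fit(x_tr, y_tr)
    return float(100.0 * forest.score(x_va, y_va))


def evaluate_all_windows(
    cohort_hrv: list[HRVSeries],
    config: ClassifierConfig | None = None,
    n_windows: int | None = None,
) -> AccuracyProfile:
    """Repeated hold-out evaluation of every candidate window.

    For each window k = 1..n_windows (default: as many full 10-min
    windows as the shortest series allows after the reference window,
    11 for a 120-min recording) the forest is evaluated on
    ``config.n_repeats`` independent stratified splits and accuracies
    averaged.  Repeat seeds derive from ``config.seed`` so the whole
    profile is reproducible.  The pooled mean HRV index of each window
    is recorded for the trend/correlation analysis.
    """
    if config is None:
        config = ClassifierConfig()
    config.validate()
    if not cohort_hrv:
        raise ValueError("cohort_hrv must be non-empty")
    max_windows = min(len(s.v) for s in cohort_hrv) // WINDOW_S - 1
    if n_windows is None:
        n_windows = max_windows
    if n_windows < 1 or n_windows > max_windows:
        raise ValueError(
            f"n_windows={n_windows} not supported by the series "
            f"(max {max_windows})"
        )
    seeds = np.random.SeedSequence(config.seed).generate_state(
        n_windows * config.n_repeats
    )
    per_repeat = np.empty((n_windows, config.n_repeats))
    mean_v = np.empty(n_windows)
    indices = np.arange(1, n_windows + 1)
    for j, wi in enumerate(indices):
        dataset = build_window_dataset(cohort_hrv, int(wi), config)
        mean_v[j] = float(
            np.mean(
                np.concatenate(
                    [
                        s.v[WINDOW_S * wi : WINDOW_S * (wi + 1)]
                        for s in cohort_hrv
                    ]
                )
            )
        )
        for r in range(config.n_repeats):
            per_repeat[j, r] = train_eval_once(
                dataset, config, repeat_seed=int(seeds[j * config.n_repeats + r])
            )
    return AccuracyProfile(
        window_indices=indices,
        mean_accuracy=per_repeat.mean(axis=1),
        per_repeat=per_repeat,
        mean_v=mean_v,
    )
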