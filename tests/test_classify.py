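"""Window-dataset construction and random-forest evaluation tests."""

import numpy as np
import pytest

import bcgfatigue as bf
from bcgfatigue.classify import (
    ClassifierConfig,
    WindowDataset,
    _lagged_features,
    build_window_dataset,
    evaluate_all_windows,
    train_eval_once,
)
from bcgfatigue.hrv import HRVSeries


def make_hrv(v, subject="s"):
    v = np.asarray(v, dtype=float)
    return HRVSeries(subject, np.arange(len(v)), v, h_ref=72.0)


def synthetic_hrv_cohort(n_subjects, n_seconds, shift=0.0, noise=0.03, seed=0):
    """Reference-like v around 1 with an optional late-block mean shift."""
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        v = 1.0 + rng.normal(0, noise, n_seconds)
        v[600:] += shift
        cohort.append(make_hrv(v, f"S{i}"))
    return cohort


class TestLaggedFeatures:
    def test_single_lag_is_column_vector(self):
        x = _lagged_features(np.arange(5.0), 1)
        assert x.shape == (5, 1)

    def test_lag_padding_repeats_block_start(self):
        x = _lagged_features(np.array([10.0, 11.0, 12.0, 13.0]), 3)
        assert x.shape == (4, 3)
        np.testing.assert_array_equal(x[0], [10.0, 10.0, 10.0])
        np.testing.assert_array_equal(x[2], [12.0, 11.0, 10.0])


class TestBuildWindowDataset:
    def test_pooled_cohort_sample_counts(self):
        cohort = synthetic_hrv_cohort(20, 1800)
        ds = build_window_dataset(cohort, 1)
        assert ds.n_reference == 12_000
        assert ds.n_state == 12_000

    def test_single_subject_counts(self):
        ds = build_window_dataset([make_hrv(np.ones(1200))], 1)
        assert ds.n_reference == 600 and ds.n_state == 600
        assert set(np.unique(ds.labels)) == {0, 1}

    def test_lagged_feature_dimension(self):
        cohort = synthetic_hrv_cohort(2, 1800)
        ds = build_window_dataset(cohort, 1, ClassifierConfig(feature_lags=5))
        assert ds.features.shape[1] == 5

    def test_short_series_rejected_naming_subject(self):
        cohort = [make_hrv(np.ones(1800), "SA"), make_hrv(np.ones(900), "SB")]
        with pytest.raises(ValueError, match="SB"):
            build_window_dataset(cohort, 1)

    def test_window_index_validated(self):
        with pytest.raises(ValueError, match="window_index"):
            build_window_dataset([make_hrv(np.ones(1800))], 0)


class TestTrainEvalOnce:
    def test_separable_point_masses_give_perfect_accuracy(self):
        ds = build_window_dataset(
            [make_hrv(np.r_[np.ones(600), np.full(600, 16.0)])], 1
        )
        assert train_eval_once(ds, ClassifierConfig(n_trees=10), 0) == 100.0

    def test_repeat_seed_determinism(self):
        cohort = synthetic_hrv_cohort(2, 1200, shift=0.05)
        ds = build_window_dataset(cohort, 1)
        cfg = ClassifierConfig(n_trees=20)
        a = train_eval_once(ds, cfg, repeat_seed=7)
        b = train_eval_once(ds, cfg, repeat_seed=7)
        assert a == b
        c = train_eval_once(ds, cfg, repeat_seed=8)
        assert a != c  # different split, generically different accuracy

    def test_single_class_rejected(self):
        ds = WindowDataset(
            features=np.ones((10, 1)),
            labels=np.zeros(10, int),
            window_index=1,
            n_reference=10,
            n_state=0,
        )
        with pytest.raises(ValueError, match="both classes"):
            train_eval_once(ds, ClassifierConfig(n_trees=5), 0)

    def test_config_invariants_enforced(self):
        ds = build_window_dataset([make_hrv(np.ones(1200))], 1)
        with pytest.raises(ValueError, match="train_fraction"):
            train_eval_once(ds, ClassifierConfig(train_fraction=1.2), 0)
        with pytest.raises(ValueError, match="d_features"):
            train_eval_once(ds, ClassifierConfig(feature_lags=2, d_features=5), 0)


class TestEvaluateAllWindows:
    def test_window_count_follows_duration(self):
        cohort = synthetic_hrv_cohort(3, 1800, shift=0.05)  # 30 min -> 2 windows
        cfg = ClassifierConfig(n_trees=10, n_repeats=2)
        profile = evaluate_all_windows(cohort, cfg)
        assert list(profile.window_indices) == [1, 2]
        assert profile.per_repeat.shape == (2, 2)

    def test_reported_mean_is_exact_repeat_average(self):
        cohort = synthetic_hrv_cohort(2, 1800, shift=0.08)
        cfg = ClassifierConfig(n_trees=10, n_repeats=3)
        profile = evaluate_all_windows(cohort, cfg)
        np.testing.assert_array_equal(
            profile.mean_accuracy, profile.per_repeat.mean(axis=1)
        )
        assert np.all((profile.per_repeat >= 0) & (profile.per_repeat <= 100))

    def test_master_seed_determines_profile(self):
        cohort = synthetic_hrv_cohort(2, 1800, shift=0.05)
        cfg = ClassifierConfig(n_trees=10, n_repeats=2, seed=5)
        a = evaluate_all_windows(cohort, cfg)
        b = evaluate_all_windows(cohort, cfg)
        np.testing.assert_array_equal(a.per_repeat, b.per_repeat)
        np.testing.assert_array_equal(a.mean_v, b.mean_v)

    def test_larger_shift_never_less_separable(self):
        # effect-size monotonicity at small scale: bigger mean shift,
        # higher final-window accuracy (averaged over cohort seeds)
        cfg = ClassifierConfig(n_trees=20, n_repeats=2, seed=0)
        accs = []
        for shift in (0.0, 0.1, 0.4):
            per_seed = []
            for seed in range(3):
                cohort = synthetic_hrv_cohort(2, 1200, shift=shift, seed=seed)
                per_seed.append(evaluate_all_windows(cohort, cfg).mean_accuracy[-1])
            accs.append(np.mean(per_seed))
        assert accs[0] <= accs[1] + 3 and accs[1] <= accs[2] + 3
        assert accs[2] > accs[0]
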