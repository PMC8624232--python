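"""Generator tests: beat morphology, timing ground truth, determinism."""

import numpy as np
import pytest
from scipy import signal as sps

import bcgfatigue as bf
from bcgfatigue.synthetic import WAVES, cohort_subject_seeds


class TestBeatTemplate:
    def test_default_satisfies_morphology_invariants(self, template):
        amp = template.wave_amplitudes
        assert all(amp["J"] > abs(amp[w]) for w in WAVES if w != "J")
        assert all(amp[w] < 0 for w in ("I", "K", "M"))
        assert all(amp[w] > 0 for w in ("H", "L", "N"))
        offs = [template.wave_offsets[w] for w in WAVES]
        assert offs == sorted(offs)

    def test_rendered_beat_peaks_at_j_offset(self, template):
        phase = np.linspace(0, 1, 2000, endpoint=False)
        beat = template.render(phase)
        peak_phase = phase[np.argmax(beat)]
        assert abs(peak_phase - template.wave_offsets["J"]) < 0.02

    def test_fundamental_dominates_harmonics(self, template):
        # required for spectrum-peak HR readout: |c1| > |c_k| for k >= 2
        assert template.fundamental_dominance() > 1.0

    def test_periodic_train_beat_count_at_75_bpm(self, quiet_profile):
        rec = bf.simulate_bcg(quiet_profile(75.0), duration=60.0, seed=0)
        peaks, _ = sps.find_peaks(rec.samples, height=0.5 * rec.samples.max())
        assert abs(len(peaks) - 75) <= 1

    @pytest.mark.parametrize("bad_wave,field,value", [
        ("J", "wave_amplitudes", 0.2),      # J no longer dominant
        ("I", "wave_amplitudes", 0.3),      # trough made positive
        ("H", "wave_offsets", 0.9),         # order broken
    ])
    def test_invalid_templates_rejected(self, template, bad_wave, field, value):
        kwargs = {
            "wave_amplitudes": dict(template.wave_amplitudes),
            "wave_offsets": dict(template.wave_offsets),
            "wave_widths": dict(template.wave_widths),
        }
        kwargs[field][bad_wave] = value
        with pytest.raises(ValueError):
            bf.BeatTemplate(**kwargs)


class TestSimulateBcg:
    def test_deterministic_period_gives_exact_beat_count(self, quiet_profile):
        rec = bf.simulate_bcg(quiet_profile(72.0), duration=60.0, seed=0)
        assert abs(len(rec.truth_beat_times) - 72) <= 1

    def test_seed_determinism_is_bitwise(self):
        prof = bf.SubjectProfile("s", baseline_hr=75.0)
        a = bf.simulate_bcg(prof, duration=30.0, seed=42)
        b = bf.simulate_bcg(prof, duration=30.0, seed=42)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.truth_beat_times, b.truth_beat_times)

    def test_different_seeds_differ(self):
        prof = bf.SubjectProfile("s", baseline_hr=75.0)
        a = bf.simulate_bcg(prof, duration=30.0, seed=1)
        b = bf.simulate_bcg(prof, duration=30.0, seed=2)
        assert not np.array_equal(a.samples, b.samples)

    def test_linear_drift_reaches_stated_endpoint(self):
        prof = bf.SubjectProfile("s", baseline_hr=80.0, drift_fraction=0.1,
                                 hr_jitter_sd=0.0, noise_sd=0.0)
        rec = bf.simulate_bcg(prof, duration=7200.0, seed=0)
        assert rec.truth_hr[-60:].mean() == pytest.approx(72.0, abs=0.2)

    def test_truth_shapes_and_monotone_beats(self, quiet_profile):
        rec = bf.simulate_bcg(quiet_profile(72.0), duration=45.5, seed=0)
        assert len(rec.samples) == round(45.5 * 10)
        assert len(rec.truth_hr) == 45
        gaps = np.diff(rec.truth_beat_times)
        assert np.all(gaps > 0)
        assert np.all((gaps >= 60 / 180) & (gaps <= 60 / 40))

    def test_beat_count_matches_hr_integral(self):
        # conservation: #beats in [0,T] ~= integral HR(t)/60 dt, within 1
        prof = bf.SubjectProfile("s", baseline_hr=70.0, drift_fraction=0.2,
                                 hr_jitter_sd=0.0, noise_sd=0.0)
        rec = bf.simulate_bcg(prof, duration=600.0, seed=0)
        tt = np.linspace(0, 600.0, 10_000)
        expected = np.trapezoid(70.0 * (1 - 0.2 * tt / 600.0) / 60.0, tt)
        assert abs(len(rec.truth_beat_times) - expected) <= 1.5

    def test_drifting_truth_hr_is_nonincreasing_per_minute(self):
        prof = bf.SubjectProfile("s", baseline_hr=75.0, drift_fraction=0.1)
        rec = bf.simulate_bcg(prof, duration=1200.0, seed=3)
        per_min = rec.truth_hr.reshape(-1, 60).mean(axis=1)
        assert np.all(np.diff(per_min) <= 0)

    @pytest.mark.parametrize("kwargs,match", [
        (dict(duration=-5.0), "duration"),
        (dict(sampling_rate=4.0), "Nyquist|2.5 Hz"),
    ])
    def test_invalid_arguments_rejected(self, kwargs, match):
        prof = bf.SubjectProfile("s")
        with pytest.raises(ValueError, match=match):
            bf.simulate_bcg(prof, **kwargs)

    def test_profile_range_validation(self):
        with pytest.raises(ValueError, match="operating range"):
            bf.SubjectProfile("s", baseline_hr=200.0)
        with pytest.raises(ValueError, match="drift_fraction"):
            bf.SubjectProfile("s", drift_fraction=0.7)


class TestSimulateCohort:
    def test_study_scale_cohort_shapes(self, drifting_cohort):
        assert len(drifting_cohort) == 20
        assert all(len(r.samples) == 72_000 for r in drifting_cohort)
        assert all(r.sampling_rate == 10.0 for r in drifting_cohort)

    def test_single_subject_cohort(self):
        recs = bf.simulate_cohort(n_subjects=1, duration=60.0, seed=0)
        assert len(recs) == 1

    def test_rejects_empty_cohort(self):
        with pytest.raises(ValueError, match="n_subjects"):
            bf.simulate_cohort(n_subjects=0)

    def test_subject_reproducible_in_isolation(self):
        # subject 5 regenerated from its derived seed alone
        recs = bf.simulate_cohort(n_subjects=6, duration=30.0, seed=99)
        seed5 = int(cohort_subject_seeds(99, 6)[5])
        solo = bf.simulate_bcg(recs[5].profile, duration=30.0, seed=seed5)
        np.testing.assert_array_equal(solo.samples, recs[5].samples)


def test_record_csv_roundtrip(tmp_path, quiet_profile):
    rec = bf.simulate_bcg(quiet_profile(70.0), duration=20.0, seed=0)
    from bcgfatigue.synthetic import read_record, write_record

    write_record(rec, tmp_path)
    back = read_record(tmp_path, "quiet")
    np.testing.assert_allclose(back.samples, rec.samples, atol=1e-6)
    np.testing.assert_allclose(back.truth_beat_times, rec.truth_beat_times, atol=1e-6)
    assert back.profile == rec.profile
    assert back.seed == rec.seed
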