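"""Synthetic ballistocardiogram (BCG) generation with known ground truth.

A BCG records the recoil of the body to cardiac ejection.  One cardiac
cycle shows the stereotyped G, H, I, J, K, L, M, N wave sequence: small
pre-systolic deflections (G, H), the dominant positive J peak flanked by
the I and K troughs (systole), and the smaller diastolic L, M, N waves.
The generator renders each beat as a sum of signed Gaussian bumps placed
at fixed fractions of the cardiac cycle, drives the beat-to-beat interval
from a prescribed instantaneous heart-rate trajectory, and superimposes a
sub-cardiac respiration sinusoid plus white sensor noise.

Mental fatigue is emulated as a slow linear decline of heart rate over
the task (the direction reported for sustained cognitive load); the
fractional decline over the full recording is the ``drift_fraction``
parameter.  Every record carries its ground truth (J-peak times and the
per-second heart-rate trend) so downstream estimators can be scored
exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WAVES",
    "BeatTemplate",
    "SubjectProfile",
    "BCGRecord",
    "make_default_template",
    "simulate_bcg",
    "simulate_cohort",
    "default_profile_sampler",
    "write_record",
    "read_record",
]

#: Canonical BCG wave names in within-cycle order.
WAVES = ("G", "H", "I", "J", "K", "L", "M", "N")

#: Physiological operating range of the heart-rate sensor (beats/min).
HR_MIN, HR_MAX = 40.0, 180.0


@dataclass(frozen=True)
class BeatTemplate:
    """One cardiac cycle of BCG morphology as signed Gaussian bumps.

    Amplitudes are relative (J peak = 1 by convention), offsets and widths
    are fractions of the cardiac cycle, so the same template serves every
    heart rate: the waveform stretches with the beat interval.
    """

    wave_amplitudes: dict[str, float]
    wave_offsets: dict[str, float]
    wave_widths: dict[str, float]

    def __post_init__(self) -> None:
        for name, d in (
            ("wave_amplitudes", self.wave_amplitudes),
            ("wave_offsets", self.wave_offsets),
            ("wave_widths", self.wave_widths),
        ):
            missing = set(WAVES) - set(d)
            if missing:
                raise ValueError(f"{name} missing waves: {sorted(missing)}")
        amp = self.wave_amplitudes
        if any(amp["J"] <= abs(amp[w]) for w in WAVES if w != "J"):
            raise ValueError("J must be the maximum-amplitude wave")
        for w in ("I", "K", "M"):
            if amp[w] >= 0:
                raise ValueError(f"wave {w} is a trough and must be negative")
        for w in ("H", "L", "N"):
            if amp[w] <= 0:
                raise ValueError(f"wave {w} is a peak and must be positive")
        offs = [self.wave_offsets[w] for w in WAVES]
        if not all(0.0 <= o < 1.0 for o in offs):
            raise ValueError("wave offsets must lie in [0, 1)")
        if not all(a < b for a, b in zip(offs, offs[1:])):
            raise ValueError("wave offsets must increase in G..N order")
        if any(self.wave_widths[w] <= 0 for w in WAVES):
            raise ValueError("wave widths must be positive")

    def render(self, phase: np.ndarray) -> np.ndarray:
        """Evaluate the beat shape at cycle fractions ``phase`` in [0, 1)."""
        phase = np.asarray(phase, dtype=float)
        out = np.zeros_like(phase)
        for w in WAVES:
            a = self.wave_amplitudes[w]
            mu = self.wave_offsets[w]
            sd = self.wave_widths[w]
            out += a * np.exp(-0.5 * ((phase - mu) / sd) ** 2)
        return out

    def fundamental_dominance(self, n_harmonics: int = 10, n_grid: int = 4096) -> float:
        """Ratio |c1| / max|c_k|, k=2..n_harmonics, of the periodic beat.

        For spectrum-peak heart-rate estimation to read the beat frequency
        (rather than a harmonic) this ratio must exceed 1.
        """
        shape = self.render(np.arange(n_grid) / n_grid)
        c = np.fft.rfft(shape - shape.mean()) / n_grid
        mags = np.abs(c)
        return float(mags[1] / mags[2 : n_harmonics + 1].max())


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject generator parameters.

    baseline_hr
        Resting heart rate at task start, beats/min; must sit inside the
        sensor's 40-180 beats/min operating range.
    drift_fraction
        Fractional heart-rate decline over the full task (0.10 = 10 %
        lower at the end), the fatigue stand-in.
    hr_jitter_sd
        Beat-to-beat heart-rate variability, beats/min.
    noise_sd
        White sensor-noise amplitude relative to the J peak.
    respiration_amp, respiration_freq
        Amplitude (relative) and frequency (Hz) of the slow baseline
        oscillation; the default frequency sits below the cardiac
        passband so the band-pass filter must remove it.
    """

    subject_id: str
    baseline_hr: float = 72.0
    drift_fraction: float = 0.1
    hr_jitter_sd: float = 2.5
    noise_sd: float = 0.1
    respiration_amp: float = 0.3
    respiration_freq: float = 0.25

    def __post_init__(self) -> None:
        if not (HR_MIN <= self.baseline_hr <= HR_MAX):
            raise ValueError(
                f"baseline_hr {self.baseline_hr} outside the sensor operating "
                f"range [{HR_MIN:g}, {HR_MAX:g}] beats/min"
            )
        if not (0.0 <= self.drift_fraction < 0.5):
            raise ValueError("drift_fraction must lie in [0, 0.5)")
        if self.hr_jitter_sd < 0 or self.noise_sd < 0:
            raise ValueError("hr_jitter_sd and noise_sd must be non-negative")
        if self.respiration_freq <= 0:
            raise ValueError("respiration_freq must be positive")


@dataclass
class BCGRecord:
    """A simulated single-channel BCG recording plus its ground truth."""

    samples: np.ndarray
    sampling_rate: float
    duration: float
    subject_id: str
    truth_beat_times: np.ndarray  # J-peak times, s
    truth_hr: np.ndarray  # per-second heart-rate trend, beats/min
    profile: SubjectProfile | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        expected = int(round(self.duration * self.sampling_rate))
        if len(self.samples) != expected:
            raise ValueError(
                f"samples has length {len(self.samples)}, expected "
                f"duration*sampling_rate = {expected}"
            )


def make_default_template() -> BeatTemplate:
    """Default beat morphology: dominant J, I/K/M troughs, H/L/N peaks.

    Widths are chosen broad enough that the fundamental of a periodic beat
    train dominates all harmonics, so the power-spectrum peak of the
    band-passed signal sits at the beat frequency.
    """
    return BeatTemplate(
        wave_amplitudes={
            "G": 0.10, "H": 0.28, "I": -0.32, "J": 1.00,
            "K": -0.38, "L": 0.30, "M": -0.22, "N": 0.16,
        },
        wave_offsets={
            "G": 0.06, "H": 0.16, "I": 0.26, "J": 0.34,
            "K": 0.43, "L": 0.56, "M": 0.68, "N": 0.80,
        },
        wave_widths={
            "G": 0.035, "H": 0.045, "I": 0.035, "J": 0.075,
            "K": 0.045, "L": 0.070, "M": 0.070, "N": 0.060,
        },
    )


def _hr_trend(t: np.ndarray | float, profile: SubjectProfile, duration: float) -> np.ndarray:
    """Deterministic instantaneous heart rate at time t (beats/min)."""
    hr = profile.baseline_hr * (1.0 - profile.drift_fraction * np.asarray(t, float) / duration)
    return np.clip(hr, HR_MIN, HR_MAX)


def simulate_bcg(
    profile: SubjectProfile,
    template: BeatTemplate | None = None,
    duration: float = 7200.0,
    sampling_rate: float = 10.0,
    seed: int = 0,
) -> BCGRecord:
    """Simulate one subject's BCG recording.

    Beat intervals follow the instantaneous trajectory
    ``HR(t) = baseline_hr * (1 - drift_fraction * t/duration)`` with
    independent Gaussian beat-to-beat jitter (sd ``hr_jitter_sd``),
    clipped to the 40-180 beats/min sensor range.  The waveform is the
    per-beat template train plus a respiration sinusoid and white noise.
    Identical ``(profile, seed)`` give bitwise-identical output.

    ``truth_hr`` stores the noise-free trend HR(t) once per second;
    ``truth_beat_times`` stores the realised J-peak times including
    jitter.
    """
    if duration <= 0:
        raise ValueError("duration must be positive (seconds)")
    if sampling_rate < 5.0:
        raise ValueError(
            "sampling_rate must be at least 5 Hz to support the 2.5 Hz "
            "upper edge of the cardiac band (Nyquist constraint)"
        )
    if template is None:
        template = make_default_template()

    rng = np.random.default_rng(seed)

    # Beat start times: sequential draw of jittered instantaneous HR.
    starts: list[float] = []
    intervals: list[float] = []
    t = 0.0
    while t < duration:
        hr = float(_hr_trend(t, profile, duration))
        if profile.hr_jitter_sd > 0:
            hr += profile.hr_jitter_sd * rng.standard_normal()
        hr = min(max(hr, HR_MIN), HR_MAX)
        dt = 60.0 / hr
        starts.append(t)
        intervals.append(dt)
        t += dt
    beat_starts = np.asarray(starts)
    beat_intervals = np.asarray(intervals)

    n = int(round(duration * sampling_rate))
    tt = np.arange(n) / sampling_rate
    idx = np.searchsorted(beat_starts, tt, side="right") - 1
    phase = (tt - beat_starts[idx]) / beat_intervals[idx]
    samples = template.render(phase)

    if profile.respiration_amp > 0:
        samples = samples + profile.respiration_amp * np.sin(
            2.0 * np.pi * profile.respiration_freq * tt
        )
    if profile.noise_sd > 0:
        samples = samples + profile.noise_sd * rng.standard_normal(n)

    j_off = template.wave_offsets["J"]
    j_times = beat_starts + j_off * beat_intervals
    j_times = j_times[j_times < duration]

    secs = np.arange(int(np.floor(duration)))
    truth_hr = _hr_trend(secs + 0.5, profile, duration)

    return BCGRecord(
        samples=samples,
        sampling_rate=sampling_rate,
        duration=duration,
        subject_id=profile.subject_id,
        truth_beat_times=j_times,
        truth_hr=truth_hr,
        profile=profile,
        seed=seed,
    )


def default_profile_sampler(
    index: int, rng: np.random.Generator, drift_fraction: float = 0.1
) -> SubjectProfile:
    """Draw a plausible seated young-adult profile for cohort subject `index`.

    Baseline heart rate is uniform on 62-88 beats/min, respiration on
    0.20-0.30 Hz (12-18 breaths/min); beat-to-beat jitter and sensor
    noise are held at the class defaults.
    """
    return SubjectProfile(
        subject_id=f"S{index + 1:02d}",
        baseline_hr=float(rng.uniform(62.0, 88.0)),
        drift_fraction=drift_fraction,
        respiration_freq=float(rng.uniform(0.20, 0.30)),
    )


def cohort_subject_seeds(master_seed: int, n_subjects: int) -> np.ndarray:
    """Per-subject waveform seeds derived from the master seed.

    Exposed so that any one subject's record can be regenerated in
    isolation: ``simulate_bcg(profile, seed=cohort_subject_seeds(m, n)[i])``.
    """
    return np.random.SeedSequence(master_seed).generate_state(n_subjects)


def simulate_cohort(
    n_subjects: int = 20,
    duration: float = 7200.0,
    profile_sampler=None,
    seed: int = 0,
    sampling_rate: float = 10.0,
    template: BeatTemplate | None = None,
    drift_fraction: float = 0.1,
) -> list[BCGRecord]:
    """Simulate a cohort of subjects performing the 120-min task.

    Defaults mirror the study layout: 20 subjects, 7200 s at 10 Hz, a 10 %
    heart-rate decline over the task.  ``profile_sampler(index, rng)``
    overrides the default profile draw; subject waveform seeds derive
    deterministically from ``seed`` (see :func:`cohort_subject_seeds`) and
    profile draws use an independent stream, so the whole cohort is
    reproducible from the one master seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    if profile_sampler is None:
        def profile_sampler(i, rng):  # noqa: ANN001 - local default
            return default_profile_sampler(i, rng, drift_fraction=drift_fraction)

    subject_seeds = cohort_subject_seeds(seed, n_subjects)
    profile_rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    records = []
    for i in range(n_subjects):
        profile = profile_sampler(i, profile_rng)
        records.append(
            simulate_bcg(
                profile,
                template=template,
                duration=duration,
                sampling_rate=sampling_rate,
                seed=int(subject_seeds[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# CSV interfaces


def write_record(record: BCGRecord, directory: str | Path) -> dict[str, Path]:
    """Write a record as CSV files plus a JSON sidecar; returns the paths.

    Layout per subject: ``<id>_bcg.csv`` (time_s,amplitude),
    ``<id>_beats.csv`` (beat_time_s), ``<id>_truth_hr.csv``
    (second,hr_bpm), ``<id>_meta.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = record.subject_id
    paths = {
        "bcg": directory / f"{sid}_bcg.csv",
        "beats": directory / f"{sid}_beats.csv",
        "truth_hr": directory / f"{sid}_truth_hr.csv",
        "meta": directory / f"{sid}_meta.json",
    }
    tt = np.arange(len(record.samples)) / record.sampling_rate
    pd.DataFrame({"time_s": tt, "amplitude": record.samples}).to_csv(
        paths["bcg"], index=False, float_format="%.6f"
    )
    pd.DataFrame({"beat_time_s": record.truth_beat_times}).to_csv(
        paths["beats"], index=False, float_format="%.6f"
    )
    pd.DataFrame(
        {"second": np.arange(len(record.truth_hr)), "hr_bpm": record.truth_hr}
    ).to_csv(paths["truth_hr"], index=False, float_format="%.6f")
    meta = {
        "subject_id": sid,
        "sampling_rate": record.sampling_rate,
        "duration": record.duration,
        "seed": record.seed,
        "profile": dataclasses.asdict(record.profile) if record.profile else None,
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return paths


def read_record(directory: str | Path, subject_id: str) -> BCGRecord:
    """Read a record previously written by :func:`write_record`."""
    directory = Path(directory)
    meta = json.loads((directory / f"{subject_id}_meta.json").read_text())
    bcg = pd.read_csv(directory / f"{subject_id}_bcg.csv")
    beats = pd.read_csv(directory / f"{subject_id}_beats.csv")
    truth = pd.read_csv(directory / f"{subject_id}_truth_hr.csv")
    profile = SubjectProfile(**meta["profile"]) if meta["profile"] else None
    return BCGRecord(
        samples=bcg["amplitude"].to_numpy(),
        sampling_rate=meta["sampling_rate"],
        duration=meta["duration"],
        subject_id=subject_id,
        truth_beat_times=beats["beat_time_s"].to_numpy(),
        truth_hr=truth["hr_bpm"].to_numpy(),
        profile=profile,
        seed=meta["seed"],
    )
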