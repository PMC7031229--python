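"""Seeded synthetic 12-lead ECG generator.

Beats are sums of Gaussian bumps (P, Q, R, S, T) placed on a jittered RR
grid; the 12 leads are fixed scaled/signed copies of a single template so
lead II carries canonical polarity.  Each rhythm group gets the morphology
that defines it clinically:

* ``SR``  — 60-100 BPM, regular RR, P waves present;
* ``SB``  — <= 60 BPM, regular RR, P waves present;
* ``GSVT`` — > 100 BPM, regular RR;
* ``AFIB`` — irregularly irregular RR, no P waves, replaced by a 6-8 Hz
  low-amplitude fibrillatory oscillation.

Noise is added separately as the three contamination sources handled by the
denoising stage: a power-line sinusoid (50-60 Hz), sub-0.5 Hz baseline
wander, and white Gaussian noise.  Everything is deterministic for a fixed
seed; per-record seeds are spawned from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ECGRecord, LEAD_NAMES, MachineMeasurements

#: Per-lead gain applied to the lead II template.  Signs/magnitudes are
#: loosely modelled on normal-axis limb/precordial projections; magnitudes
#: stay >= 0.4 so R peaks remain prominent on every lead.
LEAD_GAINS = {
    "I": 0.6, "II": 1.0, "III": 0.5, "aVR": -0.7, "aVL": 0.4, "aVF": 0.8,
    "V1": -0.5, "V2": 0.6, "V3": 0.8, "V4": 0.9, "V5": 0.85, "V6": 0.7,
}

#: Table 6-style age distributions (mean, SD) per group.
_AGE_DIST = {"SB": (58.4, 14.0), "SR": (54.4, 16.2),
             "AFIB": (73.1, 11.3), "GSVT": (55.0, 20.0)}


class ConfigurationError(ValueError):
    pass


@dataclass
class RhythmParams:
    """Generator knobs for one rhythm class.

    ``rr_jitter`` is the coefficient of variation of the RR intervals;
    amplitudes are in the template's relative units (R peak = 1).
    """

    group: str
    heart_rate: float = 75.0
    rr_jitter: float = 0.03
    p_wave_present: bool = True
    p_amplitude: float = 0.15
    fibrillatory_wave_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ConfigurationError("heart_rate must be positive")
        if self.rr_jitter < 0:
            raise ConfigurationError("rr_jitter must be non-negative")


#: Heart-rate sampling ranges per group (BPM, uniform).
_RATE_RANGES = {"SR": (60.0, 100.0), "SB": (42.0, 60.0),
                "GSVT": (105.0, 170.0), "AFIB": (70.0, 140.0)}


def default_rhythm_params(group: str, rng: np.random.Generator) -> RhythmParams:
    """Draw class-typical parameters for one record."""
    lo, hi = _RATE_RANGES[group]
    rate = float(rng.uniform(lo, hi))
    if group == "AFIB":
        return RhythmParams(group=group, heart_rate=rate, rr_jitter=0.25,
                            p_wave_present=False, p_amplitude=0.0,
                            fibrillatory_wave_amplitude=0.05)
    return RhythmParams(group=group, heart_rate=rate, rr_jitter=0.03,
                        p_wave_present=True, p_amplitude=0.15)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive contamination: power line + baseline wander + white noise."""

    powerline_hz: float = 50.0
    powerline_amp: float = 0.0
    baseline_hz: float = 0.3
    baseline_amp: float = 0.0
    gaussian_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_hz >= 0.5:
            raise ConfigurationError(
                f"baseline wander frequency must be < 0.5 Hz, "
                f"got {self.baseline_hz}")
        if min(self.powerline_amp, self.baseline_amp, self.gaussian_sd) < 0:
            raise ConfigurationError("noise amplitudes must be non-negative")


@dataclass
class GroundTruth:
    """Fiducial times (seconds) of the noiseless template."""

    r_times: np.ndarray
    p_times: np.ndarray
    q_times: np.ndarray
    s_times: np.ndarray
    t_times: np.ndarray
    rr_intervals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rr_intervals is None:
            self.rr_intervals = np.diff(self.r_times)


def _gauss(t: np.ndarray, center: float, sd: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / sd) ** 2)


def generate_record(params: RhythmParams, seed: int, fs: float = 500.0,
                    duration: float = 10.0,
                    record_id: str | None = None) -> tuple[ECGRecord, GroundTruth]:
    """Generate one noiseless 12-lead record with known fiducials.

    Machine-measurement metadata (ventricular rate, QRS count, ...) is
    computed from the ground truth so machine-feature groups are exercisable
    on synthetic data.
    """
    rr_mean = 60.0 / params.heart_rate
    if duration < 2 * rr_mean:
        raise ConfigurationError(
            f"duration {duration}s holds fewer than 2 beats at "
            f"{params.heart_rate} BPM")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration * fs))) / fs

    # RR grid: jittered multiplicative deviations, truncated away from zero
    n_beats_max = int(np.ceil(duration / rr_mean)) + 3
    devs = np.clip(1.0 + params.rr_jitter * rng.standard_normal(n_beats_max),
                   0.4, 2.5)
    rr = rr_mean * devs
    beat_times = float(rng.uniform(0.1, 0.1 + rr_mean)) + np.concatenate(
        ([0.0], np.cumsum(rr)))
    # keep every QRS inside the record; P/T tails may spill past the edges
    beat_times = beat_times[(beat_times > 0.1) & (beat_times < duration - 0.1)]

    # Interval scale: compress wave offsets at fast rates so beats don't fuse
    c = float(np.clip(rr_mean / 0.8, 0.5, 1.0))
    p_off, q_off, s_off, t_off = -0.17 * c, -0.05 * c, 0.05 * c, 0.30 * c
    p_sd, q_sd, r_sd, s_sd, t_sd = 0.025 * c, 0.012, 0.012, 0.012, 0.06 * c

    template = np.zeros_like(t)
    for tb in beat_times:
        template += _gauss(t, tb + q_off, q_sd, -0.10)
        template += _gauss(t, tb, r_sd, 1.0)
        template += _gauss(t, tb + s_off, s_sd, -0.20)
        template += _gauss(t, tb + t_off, t_sd, 0.25)
        if params.p_wave_present:
            template += _gauss(t, tb + p_off, p_sd, params.p_amplitude)
    if params.fibrillatory_wave_amplitude > 0:
        f_fib = rng.uniform(6.0, 8.0)
        phase = rng.uniform(0, 2 * np.pi)
        template += params.fibrillatory_wave_amplitude * np.sin(
            2 * np.pi * f_fib * t + phase)

    signal = np.column_stack([LEAD_GAINS[name] * template
                              for name in LEAD_NAMES])

    def _inside(times: np.ndarray) -> np.ndarray:
        return times[(times >= 0) & (times < duration)]

    truth = GroundTruth(
        r_times=beat_times,
        p_times=(_inside(beat_times + p_off) if params.p_wave_present
                 else np.empty(0)),
        q_times=beat_times + q_off,
        s_times=beat_times + s_off,
        t_times=_inside(beat_times + t_off),
    )

    mean_rr = float(np.mean(truth.rr_intervals)) if len(truth.rr_intervals) else rr_mean
    vrate = 60.0 / mean_rr
    arate = vrate if params.group != "AFIB" else float(rng.uniform(300, 450))
    first = beat_times[0]
    machine = MachineMeasurements(
        ventricular_rate=round(vrate, 1),
        atrial_rate=round(arate, 1),
        qrs_duration=round((s_off - q_off + 4 * r_sd) * 1000, 1),
        qt_interval=round((t_off - q_off + 2 * t_sd) * 1000, 1),
        r_axis=round(float(rng.normal(55, 15)), 1),
        t_axis=round(float(rng.normal(45, 15)), 1),
        qrs_count=len(beat_times),
        q_onset=int(round((first + q_off - 2 * q_sd) * fs)),
        q_offset=int(round((first + s_off + 2 * s_sd) * fs)),
    )
    record = ECGRecord(
        signal=signal, fs=fs,
        record_id=record_id or f"{params.group}_{seed}",
        rhythm_raw=params.group, machine=machine)
    return record, truth


def add_noise(record: ECGRecord, spec: NoiseSpec, seed: int) -> ECGRecord:
    """Add power-line, baseline-wander and Gaussian noise to every lead.

    The contamination is purely additive, so given ``spec`` and ``seed`` it
    can be regenerated and subtracted exactly.
    """
    rng = np.random.default_rng(seed)
    n, n_leads = record.signal.shape
    t = np.arange(n) / record.fs
    noisy = record.signal.copy()
    for j in range(n_leads):
        noisy[:, j] += spec.powerline_amp * np.sin(
            2 * np.pi * spec.powerline_hz * t + rng.uniform(0, 2 * np.pi))
        noisy[:, j] += spec.baseline_amp * np.sin(
            2 * np.pi * spec.baseline_hz * t + rng.uniform(0, 2 * np.pi))
        if spec.gaussian_sd > 0:
            noisy[:, j] += spec.gaussian_sd * rng.standard_normal(n)
    return record.replace_signal(noisy)


def generate_dataset(n_per_class: int,
                     class_params: dict[str, RhythmParams] | None = None,
                     noise: NoiseSpec | None = None,
                     seed: int = 0, fs: float = 500.0, duration: float = 10.0,
                     ) -> tuple[list[ECGRecord], list[str]]:
    """Generate a balanced labelled dataset of 4 x ``n_per_class`` records.

    Per-record seeds are spawned from ``seed`` so any record can be
    regenerated independently.  Ages and sexes are sampled per group and
    recorded in the metadata.  Returns records and their group labels.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    groups = ("SB", "AFIB", "GSVT", "SR")
    records: list[ECGRecord] = []
    labels: list[str] = []
    children = np.random.SeedSequence(seed).spawn(len(groups) * n_per_class)
    i = 0
    for group in groups:
        for k in range(n_per_class):
            ss = children[i]
            i += 1
            rec_seed = int(ss.generate_state(1)[0] % (2 ** 31))
            rng = np.random.default_rng(rec_seed)
            params = (class_params[group] if class_params is not None
                      else default_rhythm_params(group, rng))
            rec, _ = generate_record(params, seed=rec_seed + 1, fs=fs,
                                     duration=duration,
                                     record_id=f"{group}_{k:04d}")
            mu, sd = _AGE_DIST[group]
            rec.age = float(np.clip(round(rng.normal(mu, sd)), 18, 95))
            rec.sex = "male" if rng.uniform() < 0.6 else "female"
            if noise is not None:
                rec = add_noise(rec, noise, seed=rec_seed + 2)
            records.append(rec)
            labels.append(group)
    return records, labels
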