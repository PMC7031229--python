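import numpy as np
import pytest

from ecgrhythm.synth import NoiseSpec, RhythmParams, add_noise, generate_record


@pytest.fixture(scope="session")
def sr_record():
    """Clean sinus-rhythm record at 75 BPM with ground truth."""
    return generate_record(RhythmParams(group="SR", heart_rate=75.0),
                           seed=1, fs=500.0, duration=10.0)


@pytest.fixture(scope="session")
def afib_record():
    """Clean atrial-fibrillation record: irregular RR, no P waves."""
    params = RhythmParams(group="AFIB", heart_rate=90.0, rr_jitter=0.25,
                          p_wave_present=False, p_amplitude=0.0,
                          fibrillatory_wave_amplitude=0.05)
    return generate_record(params, seed=2, fs=500.0, duration=10.0)


@pytest.fixture(scope="session")
def standard_noise():
    """The contamination used by the denoising benchmarks."""
    return NoiseSpec(powerline_hz=50.0, powerline_amp=0.1,
                     baseline_hz=0.3, baseline_amp=0.3, gaussian_sd=0.05)


@pytest.fixture(scope="session")
def noisy_sr(sr_record, standard_noise):
    clean, truth = sr_record
    return clean, add_noise(clean, standard_noise, seed=11), truth


@pytest.fixture(scope="session")
def blobs_fixture():
    """Linearly separable-ish 4-class 2-feature blobs, fixed seed."""
    from sklearn.datasets import make_blobs
    from sklearn.model_selection import train_test_split
    X, y = make_blobs(n_samples=200, centers=4, cluster_std=2.5,
                      random_state=7)
    return train_test_split(X, y, test_size=0.5, random_state=7, stratify=y)


@pytest.fixture(scope="session")
def classified_extrema(sr_record):
    """Lead II extrema of the clean SR record, QRS-classified."""
    from ecgrhythm.fiducials import classify_qrs, detect_extrema
    record, _ = sr_record
    es = detect_extrema(record.lead("II"), record.fs, lead="II")
    return classify_qrs(es, record.fs)


def make_extrema(specs, fs=500.0, lead="II"):
    """Hand-build an ExtremaSet from (time, kind, klass, h, w, p) tuples."""
    from ecgrhythm.fiducials import Extremum, ExtremaSet

    es = ExtremaSet(lead=lead, fs=fs)
    for time, kind, klass, h, w, p in specs:
        es.extrema.append(Extremum(index=int(round(time * fs)), time=time,
                                   kind=kind, height=h, width=w,
                                   prominence=p, klass=klass))
    es.r_indices = [e.index for e in es.extrema if e.klass == "QRS"]
    return es
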