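"""Reading and writing 12-lead ECG records and their metadata.

Records are plain CSV tables: a header row of lead names followed by one
numeric row per sample.  Per-record metadata (demographics, rhythm label and
the nine ECG-machine measurements) lives in a sidecar CSV keyed by
``record_id``.  This module also owns the clinical label merge that collapses
the eleven raw rhythm acronyms into the four analysis groups used for
classification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical lead order.  Lead II is the rhythm lead used for RR intervals.
LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")

#: The four analysis groups.
RHYTHM_GROUPS = ("SB", "AFIB", "GSVT", "SR")

#: Raw 11-rhythm vocabulary -> analysis group.
#
# AFIB and AFL merge because the two frequently coexist clinically; all
# tachycardias of supraventricular origin (including sinus tachycardia)
# collapse into GSVT; sinus irregularity joins sinus rhythm.
RHYTHM_MERGE_MAP = {
    "SB": "SB",
    "AFIB": "AFIB",
    "AFL": "AFIB",
    "ST": "GSVT",
    "SVT": "GSVT",
    "AT": "GSVT",
    "AVNRT": "GSVT",
    "AVRT": "GSVT",
    "WAP": "GSVT",
    "SR": "SR",
    "SI": "SR",
    # group labels pass through unchanged, so merged datasets (and the
    # synthetic generator, which emits group labels) round-trip idempotently
    "GSVT": "GSVT",
}

MACHINE_FIELDS = (
    "ventricular_rate", "atrial_rate", "qrs_duration", "qt_interval",
    "r_axis", "t_axis", "qrs_count", "q_onset", "q_offset",
)


class ECGFormatError(ValueError):
    """Raised when an on-disk record violates the 12-lead CSV contract."""


class RhythmVocabularyError(ValueError):
    """Raised for a rhythm acronym outside the 11-acronym vocabulary."""


@dataclass(frozen=True)
class MachineMeasurements:
    """The nine measurements an ECG machine reports for one record.

    Rates are beats per minute, durations/intervals milliseconds, axes
    degrees, ``q_onset``/``q_offset`` sample indices.
    """

    ventricular_rate: float
    atrial_rate: float
    qrs_duration: float
    qt_interval: float
    r_axis: float
    t_axis: float
    qrs_count: int
    q_onset: int
    q_offset: int

    def __post_init__(self) -> None:
        for name in ("ventricular_rate", "atrial_rate",
                     "qrs_duration", "qt_interval"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.q_onset > self.q_offset:
            raise ValueError("q_onset must not exceed q_offset")

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in MACHINE_FIELDS}


@dataclass
class ECGRecord:
    """One 12-lead recording plus its metadata.

    ``signal`` has shape ``(n_samples, 12)`` with columns in ``LEAD_NAMES``
    order; sample indices are 0-based and time in seconds is ``index / fs``.
    """

    signal: np.ndarray
    fs: float
    record_id: str = "record"
    age: float | None = None
    sex: str | None = None
    rhythm_raw: str | None = None
    machine: MachineMeasurements | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.ndim != 2 or self.signal.shape[1] != len(LEAD_NAMES):
            raise ECGFormatError(
                f"expected {len(LEAD_NAMES)} leads, observed "
                f"{self.signal.shape[1] if self.signal.ndim == 2 else 'non-2D'}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        return self.signal[:, LEAD_NAMES.index(name)]

    def replace_signal(self, signal: np.ndarray) -> "ECGRecord":
        return dataclasses.replace(self, signal=np.asarray(signal, float))


def merge_rhythm_label(rhythm_raw: str) -> str:
    """Map a raw rhythm acronym onto one of the four analysis groups.

    SB stays alone; AFIB absorbs AFL; GSVT collects every supraventricular
    tachycardia (ST, SVT, AT, AVNRT, AVRT, WAP); SR absorbs SI.
    """
    try:
        return RHYTHM_MERGE_MAP[rhythm_raw]
    except KeyError:
        raise RhythmVocabularyError(
            f"unknown rhythm acronym {rhythm_raw!r}; valid inputs: "
            f"{sorted(RHYTHM_MERGE_MAP)}"
        ) from None


def read_ecg_csv(path: str | Path, metadata: pd.Series | dict | None = None,
                 fs: float = 500.0) -> ECGRecord:
    """Read one 12-lead record from CSV.

    Parameters
    ----------
    path
        CSV with a header of 12 lead names and one numeric row per sample.
    metadata
        Optional sidecar row (see :func:`read_metadata_csv`) supplying
        ``fs``, demographics, rhythm label and machine measurements.
    fs
        Sampling rate used when the metadata does not carry one (Hz).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] != len(LEAD_NAMES):
        raise ECGFormatError(
            f"expected {len(LEAD_NAMES)} leads, observed {df.shape[1]} "
            f"columns in {path.name}"
        )
    try:
        signal = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for i, row in enumerate(df.itertuples(index=False)):
            for v in row:
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ECGFormatError(
                        f"non-numeric cell in row {i} of {path.name}: {v!r}"
                    ) from None
        raise

    kwargs: dict = {"record_id": path.stem, "fs": fs}
    if metadata is not None:
        meta = dict(metadata)
        kwargs["fs"] = float(meta.get("fs", fs))
        kwargs["record_id"] = str(meta.get("record_id", path.stem))
        if meta.get("age") is not None and not pd.isna(meta.get("age")):
            kwargs["age"] = float(meta["age"])
        if meta.get("sex") is not None and not pd.isna(meta.get("sex")):
            kwargs["sex"] = str(meta["sex"])
        if meta.get("rhythm") is not None and not pd.isna(meta.get("rhythm")):
            kwargs["rhythm_raw"] = str(meta["rhythm"])
        if all(meta.get(f) is not None and not pd.isna(meta.get(f))
               for f in MACHINE_FIELDS):
            kwargs["machine"] = MachineMeasurements(
                **{f: (int(meta[f]) if f in ("qrs_count", "q_onset", "q_offset")
                       else float(meta[f]))
                   for f in MACHINE_FIELDS})
    return ECGRecord(signal=signal, **kwargs)


def write_ecg_csv(record: ECGRecord, path: str | Path) -> Path:
    """Write a record's signal matrix to CSV at full precision."""
    path = Path(path)
    if not np.all(np.isfinite(record.signal)):
        raise ValueError("refusing to write non-finite samples")
    df = pd.DataFrame(record.signal, columns=list(LEAD_NAMES))
    # repr-based float formatting round-trips float64 exactly
    df.to_csv(path, index=False)
    return path


def metadata_row(record: ECGRecord) -> dict:
    """Flatten a record's metadata into one sidecar-table row."""
    row: dict = {
        "record_id": record.record_id,
        "fs": record.fs,
        "age": record.age,
        "sex": record.sex,
        "rhythm": record.rhythm_raw,
    }
    if record.machine is not None:
        row.update(record.machine.as_dict())
    else:
        row.update({f: None for f in MACHINE_FIELDS})
    return row


def write_metadata_csv(records: list[ECGRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([metadata_row(r) for r in records]).to_csv(path, index=False)
    return path


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    """Read the sidecar metadata table, indexed by record_id."""
    df = pd.read_csv(path, dtype={"record_id": str})
    return df.set_index("record_id", drop=False)
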