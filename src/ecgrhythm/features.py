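"""Feature engineering: extrema summaries and 100-bin frequency features.

Eleven feature groups of increasing richness are assembled from three
building blocks:

1. the nine ECG-machine measurements plus demographics (age, sex);
2. lead-wise summary statistics — RR mean/variance/count (lead II only) and
   mean/variance of height, width and prominence for each of the three
   extremum classes (QRS, non-QRS peaks, valleys);
3. empirical frequency distributions (EFDs): per lead, 100-bin histograms
   of (a) the three attributes for the three classes (9 x 100), (b) the
   signed location differences for the six pairwise class combinations
   (6 x 100), and (c) the three difference-over-time-difference ratios for
   the six combinations (18 x 100) — 3300 frequencies per lead.

Every histogram spans [min, max] of its own series, so each record
contributes exactly 100 integers per variable regardless of how many
extrema pairs it has.  Pair differences use the earlier-minus-later
convention; pairs with zero time difference are excluded.  Empty classes
produce zero-filled summaries and histograms so vectors keep a fixed,
globally stable schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fiducials import ExtremaSet, QRS, NONQRS, VALLEY, rr_intervals
from .io import ECGRecord, LEAD_NAMES, MACHINE_FIELDS

log = logging.getLogger(__name__)

N_BINS = 100

CLASSES = (QRS, NONQRS, VALLEY)
ATTRIBUTES = ("height", "width", "prominence")

#: The six pairwise class combinations, in a fixed order.
COMBINATIONS = (
    (QRS, QRS), (NONQRS, NONQRS), (VALLEY, VALLEY),
    (QRS, NONQRS), (QRS, VALLEY), (NONQRS, VALLEY),
)

#: Expected vector lengths per group (demographics included).
EXPECTED_LENGTHS = {1: 11, 2: 23, 3: 32, 4: 221, 5: 230, 6: 3302,
                    7: 3323, 8: 3332, 9: 39602, 10: 39821}


class MissingMetadataError(ValueError):
    pass


@dataclass
class EmpiricalFrequencyDistribution:
    """A 100-bin histogram of one derived variable series."""

    variable_name: str
    lo: float
    hi: float
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=int)
        if self.frequencies.size != N_BINS:
            raise ValueError(f"expected {N_BINS} bins")


@dataclass
class FeatureVector:
    record_id: str
    group_id: int
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")


def rescale_minmax(record: ECGRecord) -> ECGRecord:
    """Rescale each lead to [0, 1] with the max-min algorithm.

    Constant leads are returned unchanged with a logged notice.  Idempotent.
    """
    out = record.signal.copy()
    for j, name in enumerate(LEAD_NAMES):
        lo, hi = out[:, j].min(), out[:, j].max()
        if hi == lo:
            log.info("rescale_minmax: lead %s is constant; left unchanged",
                     name)
            continue
        out[:, j] = (out[:, j] - lo) / (hi - lo)
    return record.replace_signal(out)


def _mean_var(values: np.ndarray) -> tuple[float, float]:
    """Mean and sample variance (n-1 denominator; 0 when n <= 1)."""
    if values.size == 0:
        return 0.0, 0.0
    if values.size == 1:
        return float(values[0]), 0.0
    return float(np.mean(values)), float(np.var(values, ddof=1))


def attribute_summaries(extrema: ExtremaSet) -> dict[str, float]:
    """Mean and variance of each attribute for each extremum class.

    18 named values per lead; empty classes yield sentinel zeros.
    """
    lead = extrema.lead
    out: dict[str, float] = {}
    for klass in CLASSES:
        members = extrema.of_class(klass)
        for attr in ATTRIBUTES:
            vals = np.array([getattr(e, attr) for e in members])
            mean, var = _mean_var(vals)
            out[f"{lead}_{klass}_{attr}_mean"] = mean
            out[f"{lead}_{klass}_{attr}_var"] = var
    return out


def pairwise_series(extrema: ExtremaSet) -> dict[tuple[str, str], np.ndarray]:
    """Derived-variable series for the six pairwise class combinations.

    For each combination, all unordered pairs are enumerated (within-class:
    i < j; cross-class: the full cross product) and, per pair ordered
    earlier-minus-later, four series are emitted: the location difference
    t_a - t_b (negative by construction) and the ratios delta-height,
    delta-width and delta-prominence over delta-time.  Keys are
    ``(combination_label, variable)`` with variables ``location_diff``,
    ``height_ratio``, ``width_ratio``, ``prominence_ratio``.
    """
    def _arrays(klass: str) -> np.ndarray:
        members = extrema.of_class(klass)
        return np.array([[e.time, e.height, e.width, e.prominence]
                         for e in members]).reshape(-1, 4)

    series: dict[tuple[str, str], np.ndarray] = {}
    for ka, kb in COMBINATIONS:
        label = f"{ka}v{kb}"
        A = _arrays(ka)
        if ka == kb:
            i, j = np.triu_indices(A.shape[0], k=1)
            a, b = A[i], A[j]
        else:
            B = _arrays(kb)
            a = np.repeat(A, B.shape[0], axis=0)
            b = np.tile(B, (A.shape[0], 1))
        # order each pair earlier-minus-later
        swap = a[:, 0] > b[:, 0]
        a, b = np.where(swap[:, None], b, a), np.where(swap[:, None], a, b)
        d = a - b
        keep = d[:, 0] != 0.0          # drop coincident-time pairs
        d = d[keep]
        dt = d[:, 0]
        series[(label, "location_diff")] = dt
        series[(label, "height_ratio")] = d[:, 1] / dt
        series[(label, "width_ratio")] = d[:, 2] / dt
        series[(label, "prominence_ratio")] = d[:, 3] / dt
    return series


def efd(series: np.ndarray,
        variable_name: str = "") -> EmpiricalFrequencyDistribution:
    """100 equal-width bins spanning [min, max] of the series.

    The final bin is right-closed so the frequencies always sum to the
    series length.  An empty series gives all-zero frequencies with
    lo = hi = 0; an all-equal series puts its whole mass in the first bin.
    """
    series = np.asarray(series, float)
    if series.size and not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite entries")
    if series.size == 0:
        return EmpiricalFrequencyDistribution(
            variable_name, 0.0, 0.0, np.zeros(N_BINS, int))
    lo, hi = float(series.min()), float(series.max())
    if lo == hi:
        freqs = np.zeros(N_BINS, int)
        freqs[0] = series.size
        return EmpiricalFrequencyDistribution(variable_name, lo, hi, freqs)
    freqs, _ = np.histogram(series, bins=N_BINS, range=(lo, hi))
    return EmpiricalFrequencyDistribution(variable_name, lo, hi, freqs)


# ---------------------------------------------------------------------------
# feature-group assembly


def _demographics_block(record: ECGRecord) -> dict[str, float]:
    age = float(record.age) if record.age is not None else 0.0
    sex = {"male": 1.0, "female": 0.0}.get(record.sex or "", 0.0)
    return {"age": age, "sex": sex}


def _machine_block(record: ECGRecord) -> dict[str, float]:
    if record.machine is None:
        raise MissingMetadataError(
            f"record {record.record_id}: machine measurements required for "
            "this feature group but absent")
    return {k: float(v) for k, v in record.machine.as_dict().items()}


def _rr_block(extrema_ii: ExtremaSet) -> dict[str, float]:
    rr = rr_intervals(extrema_ii)
    if rr.size == 0:
        log.info("rr features: fewer than 2 R peaks on lead II; "
                 "sentinel zeros emitted")
    mean, var = _mean_var(rr)
    return {"rr_mean": mean if rr.size else 0.0,
            "rr_var": var,
            "rr_count": float(rr.size)}


def _efd_block(extrema: ExtremaSet) -> dict[str, float]:
    """3300 frequency features for one lead: 900 + 600 + 1800."""
    lead = extrema.lead
    out: dict[str, float] = {}

    def emit(name: str, series: np.ndarray) -> None:
        dist = efd(series, name)
        for b, f in enumerate(dist.frequencies):
            out[f"{name}_bin{b:03d}"] = float(f)

    for klass in CLASSES:
        members = extrema.of_class(klass)
        for attr in ATTRIBUTES:
            emit(f"{lead}_{klass}_{attr}",
                 np.array([getattr(e, attr) for e in members]))
    series = pairwise_series(extrema)
    for ka, kb in COMBINATIONS:
        label = f"{ka}v{kb}"
        emit(f"{lead}_{label}_location_diff", series[(label, "location_diff")])
    for var in ("height_ratio", "width_ratio", "prominence_ratio"):
        for ka, kb in COMBINATIONS:
            label = f"{ka}v{kb}"
            emit(f"{lead}_{label}_{var}", series[(label, var)])
    return out


def _union(*blocks: dict[str, float]) -> dict[str, float]:
    """Ordered union; shared names (demographics etc.) counted once."""
    out: dict[str, float] = {}
    for block in blocks:
        for k, v in block.items():
            if k not in out:
                out[k] = v
    return out


def build_features(record: ECGRecord,
                   extrema_by_lead: dict[str, ExtremaSet],
                   group_id: int,
                   g11_count_match: bool = False) -> FeatureVector:
    """Assemble one record's feature vector for a feature group (1-11).

    Groups 1/3/5/8 (and 11) include the machine measurements and raise
    :class:`MissingMetadataError` if they are absent.  Demographics appear
    in every group and are de-duplicated under union semantics.  Group 11
    defaults to the union of groups 3 and 9; ``g11_count_match`` switches to
    the union of groups 5 and 9 (an alternative composition whose length is
    39,830 rather than 39,632).
    """
    if group_id not in range(1, 12):
        raise ValueError(f"group_id must be 1..11, got {group_id}")
    demo = _demographics_block(record)
    need_ii = group_id in (2, 3, 4, 5, 6, 7, 8, 9, 10, 11)
    if need_ii and "II" not in extrema_by_lead:
        raise ValueError("lead II extrema required for this group")

    def g1() -> dict[str, float]:
        return _union(_machine_block(record), demo)

    def g2() -> dict[str, float]:
        return _union(_rr_block(extrema_by_lead["II"]),
                      attribute_summaries(extrema_by_lead["II"]), demo)

    def g4() -> dict[str, float]:
        blocks = [_rr_block(extrema_by_lead["II"])]
        for lead in LEAD_NAMES:
            blocks.append(attribute_summaries(extrema_by_lead[lead]))
        blocks.append(demo)
        return _union(*blocks)

    def g6() -> dict[str, float]:
        return _union(_efd_block(extrema_by_lead["II"]), demo)

    def g9() -> dict[str, float]:
        blocks = [_efd_block(extrema_by_lead[lead]) for lead in LEAD_NAMES]
        blocks.append(demo)
        return _union(*blocks)

    builders = {
        1: g1,
        2: g2,
        3: lambda: _union(g1(), g2()),
        4: g4,
        5: lambda: _union(g1(), g4()),
        6: g6,
        7: lambda: _union(g2(), g6()),
        8: lambda: _union(g1(), g2(), g6()),
        9: g9,
        10: lambda: _union(g4(), g9()),
        11: (lambda: _union(g1(), g4(), g9())) if g11_count_match
        else (lambda: _union(g1(), g2(), g9())),
    }
    feats = builders[group_id]()
    expected = EXPECTED_LENGTHS.get(group_id)
    if expected is not None and len(feats) != expected:
        raise AssertionError(
            f"group {group_id}: built {len(feats)} features, "
            f"expected {expected}")
    return FeatureVector(record_id=record.record_id, group_id=group_id,
                         names=list(feats), values=np.array(list(feats.values())))


def extract_record_features(record: ECGRecord, group_id: int,
                            rescale: bool = True,
                            min_prominence: float = 0.0,
                            g11_count_match: bool = False,
                            **qrs_kwargs) -> FeatureVector:
    """Extrema detection + classification + feature assembly for one record.

    Only the leads a group needs are processed (lead II for groups 2/3/6/7/8,
    all twelve for 4/5/9/10/11, none for group 1).
    """
    from .fiducials import classify_qrs, detect_extrema

    if rescale:
        record = rescale_minmax(record)
    if group_id == 1:
        leads: tuple[str, ...] = ()
    elif group_id in (2, 3, 6, 7, 8):
        leads = ("II",)
    else:
        leads = LEAD_NAMES
    extrema: dict[str, ExtremaSet] = {}
    for lead in leads:
        es = detect_extrema(record.lead(lead), record.fs, lead=lead,
                            min_prominence=min_prominence)
        extrema[lead] = classify_qrs(es, record.fs, **qrs_kwargs)
    if group_id != 1 and "II" not in extrema:
        es = detect_extrema(record.lead("II"), record.fs, lead="II",
                            min_prominence=min_prominence)
        extrema["II"] = classify_qrs(es, record.fs, **qrs_kwargs)
    return build_features(record, extrema, group_id,
                          g11_count_match=g11_count_match)


def feature_matrix(records: list[ECGRecord], group_id: int,
                   rescale: bool = True, g11_count_match: bool = False,
                   **kwargs) -> pd.DataFrame:
    """Feature table (one row per record) for a list of records."""
    rows = []
    index = []
    names: list[str] | None = None
    for rec in records:
        fv = extract_record_features(rec, group_id, rescale=rescale,
                                     g11_count_match=g11_count_match,
                                     **kwargs)
        if names is None:
            names = fv.names
        elif names != fv.names:
            raise AssertionError("feature schema differs across records")
        rows.append(fv.values)
        index.append(rec.record_id)
    return pd.DataFrame(np.vstack(rows), index=index, columns=names)
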