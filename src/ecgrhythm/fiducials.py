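"""Peak/valley detection and attribute measurement.

Each local maximum (peak) and local minimum (valley) of a lead carries three
attributes:

* **height** — the signed sample value at the extremum;
* **prominence** — the vertical distance from the extremum to its lowest
  enclosing contour line: on each side, walk to the nearest strictly higher
  sample and record the minimum encountered; the contour sits at the higher
  of the two side minima.  A side that reaches the record edge without
  meeting a higher sample imposes no constraint (the edge is treated as an
  impassable wall), so the tallest peak's prominence is its height above the
  record minimum;
* **width** — the horizontal extent (seconds) at half prominence, located by
  linear interpolation of the level crossings.

Peaks are then partitioned into QRS and non-QRS sets: R peaks are the
prominent peaks surviving a 200 ms refractory rule, and any peak within
60 ms of an R peak belongs to the QRS complex.  Valleys form their own
class.  RR intervals are the successive differences of R-peak times and are
only computed on lead II.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

QRS, NONQRS, VALLEY = "QRS", "NONQRS", "VALLEY"


@dataclass
class Extremum:
    index: int
    time: float
    kind: str                  # "peak" | "valley"
    height: float              # signed sample value
    width: float               # seconds, at half prominence
    prominence: float
    klass: str | None = None   # QRS | NONQRS | VALLEY


@dataclass
class ExtremaSet:
    lead: str
    fs: float
    extrema: list[Extremum] = field(default_factory=list)
    r_indices: list[int] = field(default_factory=list)  # R-peak sample indices

    @property
    def peaks(self) -> list[Extremum]:
        return [e for e in self.extrema if e.kind == "peak"]

    @property
    def valleys(self) -> list[Extremum]:
        return [e for e in self.extrema if e.kind == "valley"]

    def of_class(self, klass: str) -> list[Extremum]:
        return [e for e in self.extrema if e.klass == klass]

    @property
    def r_times(self) -> np.ndarray:
        return np.asarray(self.r_indices, float) / self.fs


def _prominences(y: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Prominence of each peak of ``y`` under the walls-at-edges convention."""
    n = y.size
    proms = np.empty(peaks.size)
    for a, p in enumerate(peaks):
        h = y[p]
        left_min, left_bounded = np.inf, False
        j = p - 1
        run_min = np.inf
        while j >= 0:
            if y[j] > h:
                left_bounded = True
                break
            run_min = min(run_min, y[j])
            j -= 1
        left_min = run_min
        right_min, right_bounded = np.inf, False
        j = p + 1
        run_min = np.inf
        while j < n:
            if y[j] > h:
                right_bounded = True
                break
            run_min = min(run_min, y[j])
            j += 1
        right_min = run_min
        bases = []
        if left_bounded:
            bases.append(left_min)
        if right_bounded:
            bases.append(right_min)
        if bases:
            base = max(bases)
        else:
            # tallest peak: contour descends to the record minimum
            base = min(left_min, right_min)
        proms[a] = h - base
    return proms


def _half_prom_widths(y: np.ndarray, peaks: np.ndarray,
                      proms: np.ndarray, fs: float) -> np.ndarray:
    """Width at half prominence, crossings located by linear interpolation."""
    n = y.size
    widths = np.empty(peaks.size)
    for a, p in enumerate(peaks):
        ref = y[p] - proms[a] / 2.0
        j = p
        while j > 0 and y[j - 1] > ref:
            j -= 1
        if j == 0 or y[j] == y[j - 1]:
            left = float(j)
        else:
            left = j - (y[j] - ref) / (y[j] - y[j - 1])
        j = p
        while j < n - 1 and y[j + 1] > ref:
            j += 1
        if j == n - 1 or y[j] == y[j + 1]:
            right = float(j)
        else:
            right = j + (y[j] - ref) / (y[j] - y[j + 1])
        widths[a] = max(right - left, 0.5) / fs
    return widths


def detect_extrema(signal: np.ndarray, fs: float, lead: str = "II",
                   min_prominence: float = 0.0) -> ExtremaSet:
    """Detect local maxima and minima with height, width and prominence.

    Valleys are measured on the negated signal (their height stays the
    signed raw value); extrema whose prominence does not exceed
    ``min_prominence`` are discarded.
    """
    x = np.asarray(signal, float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")

    out: list[Extremum] = []
    for kind, y in (("peak", x), ("valley", -x)):
        locs, _ = find_peaks(y)
        proms = _prominences(y, locs)
        widths = _half_prom_widths(y, locs, proms, fs)
        keep = proms > max(min_prominence, 0.0)
        for i, p, w in zip(locs[keep], proms[keep], widths[keep]):
            out.append(Extremum(index=int(i), time=i / fs, kind=kind,
                                height=float(x[i]), width=float(w),
                                prominence=float(p)))
    out.sort(key=lambda e: (e.index, e.kind))
    return ExtremaSet(lead=lead, fs=fs, extrema=out)


def classify_qrs(extrema: ExtremaSet, fs: float | None = None,
                 prominence_factor: float = 0.5, top_n: int = 10,
                 min_r_prominence: float = 0.3,
                 refractory_s: float = 0.2,
                 qrs_window_s: float = 0.06) -> ExtremaSet:
    """Partition extrema into QRS peaks, non-QRS peaks and valleys.

    R candidates must exceed ``max(prominence_factor * median prominence of
    the top_n most prominent peaks, min_r_prominence)``; among candidates
    closer than ``refractory_s`` the more prominent wins.  Peaks within
    ``qrs_window_s`` of a surviving R peak are QRS, the rest non-QRS; all
    valleys form the valley class.  The absolute floor keeps records that
    only contain P/T-scale undulations from being assigned spurious QRS
    complexes.
    """
    fs = fs or extrema.fs
    peaks = extrema.peaks
    for v in extrema.valleys:
        v.klass = VALLEY
    extrema.r_indices = []
    if not peaks:
        return extrema

    proms = np.array([p.prominence for p in peaks])
    top = np.sort(proms)[::-1][:min(top_n, proms.size)]
    threshold = max(prominence_factor * float(np.median(top)),
                    min_r_prominence)
    candidates = [p for p in peaks if p.prominence >= threshold]

    # refractory suppression: greedy by descending prominence
    accepted: list[Extremum] = []
    for p in sorted(candidates, key=lambda e: -e.prominence):
        if all(abs(p.time - a.time) >= refractory_s for a in accepted):
            accepted.append(p)
    accepted.sort(key=lambda e: e.index)
    extrema.r_indices = [p.index for p in accepted]

    r_times = np.array([p.time for p in accepted])
    for p in peaks:
        near_r = r_times.size > 0 and np.min(
            np.abs(r_times - p.time)) <= qrs_window_s
        p.klass = QRS if near_r else NONQRS
    return extrema


def rr_intervals(extrema: ExtremaSet) -> np.ndarray:
    """Successive R-peak time differences (seconds) for one lead.

    Fewer than two R peaks yield an empty array; downstream features fall
    back to sentinel zeros.
    """
    times = extrema.r_times
    if times.size < 2:
        return np.empty(0)
    return np.diff(times)
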