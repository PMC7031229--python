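"""Three-stage ECG noise reduction.

The stages run in a fixed order per lead:

1. zero-phase Butterworth low-pass (default 50 Hz cut-off, order 4,
   forward-backward so fiducial timing is undistorted) for high-frequency
   and power-line noise;
2. robust LOESS baseline estimation and subtraction for sub-0.5 Hz wander
   (locally weighted quadratic regression with tricube weights, iteratively
   reweighted with bisquare weights so QRS spikes do not drag the baseline);
3. non-local-means (NLM) smoothing of the remainder, with the smoothing
   bandwidth tied to a robust noise-level estimate.

The noise level sigma is estimated from second-difference local residuals

    D(l) = (2 x(l) - x(l-1) - x(l+1)) / sqrt(6),
    sigma_hat = 1.4826 * median(|D - median(D)|),

the sqrt(6) normalisation making the residual SD equal the SD of white
noise riding on a smooth signal.  NLM then averages samples whose
surrounding patches look alike,

    S(i) = 1/Z(i) * sum_j w(i,j) x(j),
    w(i,j) = exp(- sum_delta [x(i+d) - x(j+d)]^2 / (2 L lambda^2)),

with lambda = 1.5 * sigma_hat by default, patch half-width 10 (L = 21
samples), and the search ranging over the whole record (ECG beats repeat,
so distant beats are the best donors); a windowed search is available for
speed.  Patches truncated by the record edge renormalise by the number of
samples actually compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import ECGRecord, LEAD_NAMES

log = logging.getLogger(__name__)

STAGE_ORDER = ("butterworth", "loess", "nlm")


@dataclass(frozen=True)
class NLMParams:
    """Non-local-means knobs.

    ``lambda_factor`` multiplies the estimated noise SD to give the
    smoothing bandwidth lambda; ``patch_half_width`` P gives a patch of
    L = 2P+1 samples; ``search_mode`` "full" compares every sample pair,
    "windowed" restricts donors to +/- ``search_half_width`` samples.
    """

    lambda_factor: float = 1.5
    patch_half_width: int = 10
    search_mode: str = "full"
    search_half_width: int = 500

    def __post_init__(self) -> None:
        if self.lambda_factor <= 0:
            raise ValueError("lambda_factor must be positive")
        if self.patch_half_width < 1:
            raise ValueError("patch_half_width must be >= 1")
        if self.search_mode not in ("full", "windowed"):
            raise ValueError("search_mode must be 'full' or 'windowed'")


@dataclass
class DenoiseReport:
    """Per-lead noise estimates and stage provenance for one record."""

    sigma_hat: dict[str, float]
    stage_order: tuple[str, ...] = STAGE_ORDER
    stages: dict[str, np.ndarray] = field(default_factory=dict)


def butterworth_lowpass(x: np.ndarray, fs: float, cutoff: float = 50.0,
                        order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass via forward-backward filtering."""
    x = np.asarray(x, float)
    if not 0 < cutoff < fs / 2:
        raise ValueError(
            f"cutoff must lie in (0, fs/2) = (0, {fs / 2}), got {cutoff}")
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def loess_baseline_remove(x: np.ndarray, fs: float, span: float = 0.2,
                          robust_iterations: int = 5,
                          eval_points: int = 250,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and subtract the baseline with robust quadratic LOESS.

    Parameters
    ----------
    x, fs
        Signal and sampling rate.
    span
        Smoothing window as a fraction of the record length.  The default
        0.2 (a 2 s window on a 10 s record) lets the quadratic smoother
        track respiration-band wander up to ~0.5 Hz while leaving beat-scale
        structure to the robustifying weights.
    robust_iterations
        Bisquare reweighting passes that de-weight outlying samples (QRS
        spikes).  0 gives plain (linear-operator) LOESS.
    eval_points
        The local fits are evaluated on a grid of at most this many points
        and interpolated; the baseline is band-limited far below the grid
        spacing so this is lossless in practice.

    Returns
    -------
    (detrended, baseline), both the length of ``x``.
    """
    x = np.asarray(x, float)
    n = x.size
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    w = max(int(np.ceil(span * n)), 3)
    if w < 3 or n < 3:
        raise ValueError("span too small: window must hold >= 3 points")
    w = min(w, n)

    m = min(eval_points, n)
    eval_idx = np.unique(np.round(np.linspace(0, n - 1, m)).astype(int))
    starts = np.clip(eval_idx - w // 2, 0, n - w)
    cols = starts[:, None] + np.arange(w)[None, :]        # (m, w)
    u = (cols - eval_idx[:, None]).astype(float)          # local abscissa
    dmax = np.abs(u).max(axis=1, keepdims=True)
    tri = np.clip(1 - (np.abs(u) / dmax) ** 3, 0, None) ** 3
    y = x[cols]

    # precompute the polynomial basis once; only the weights change across
    # robustifying iterations
    u_pow = [np.ones_like(u), u, u * u]
    u_pow += [u_pow[2] * u, u_pow[2] * u_pow[2]]          # u^3, u^4
    u_pow_y = [p * y for p in u_pow[:3]]

    robust_w = np.ones(n)
    baseline_grid = np.zeros(eval_idx.size)
    for it in range(robust_iterations + 1):
        wt = tri * robust_w[cols]
        # batched weighted quadratic fit: solve 3x3 normal equations per row
        powers = [np.sum(wt * up, axis=1) for up in u_pow]
        rhs = [np.sum(wt * upy, axis=1) for upy in u_pow_y]
        A = np.stack([np.stack([powers[i + j] for j in range(3)], axis=-1)
                      for i in range(3)], axis=-2)
        b = np.stack(rhs, axis=-1)[..., None]             # (m, 3, 1)
        # ridge jitter guards rank-deficient windows (constant weights etc.)
        A = A + 1e-12 * np.eye(3)
        beta = np.linalg.solve(A, b)[..., 0]
        baseline_grid = beta[:, 0]                        # value at u = 0
        if it == robust_iterations:
            break
        baseline = np.interp(np.arange(n), eval_idx, baseline_grid)
        resid = x - baseline
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        robust_w = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2

    baseline = np.interp(np.arange(n), eval_idx, baseline_grid)
    return x - baseline, baseline


def estimate_noise_sigma(x: np.ndarray) -> float:
    """Robust white-noise SD estimate from normalised second differences."""
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to estimate noise")
    d = (2.0 * x[1:-1] - x[:-2] - x[2:]) / np.sqrt(6.0)
    return float(1.4826 * np.median(np.abs(d - np.median(d))))


def nlm_smooth(x: np.ndarray, params: NLMParams = NLMParams(),
               sigma_hat: float | None = None) -> np.ndarray:
    """Non-local-means smoothing of a 1-D signal.

    Every output sample is a convex combination of input samples; the
    self-weight w(i,i) = exp(0) = 1 before normalisation, so the output is
    always bounded by the input's range.  ``sigma_hat = 0`` (noise-free
    input) degenerates lambda to 0; the signal is returned unchanged with a
    logged notice.
    """
    x = np.asarray(x, float)
    n = x.size
    if sigma_hat is None:
        sigma_hat = estimate_noise_sigma(x)
    lam = params.lambda_factor * sigma_hat
    if lam <= 0:
        log.info("nlm_smooth: estimated noise level is 0; returning input")
        return x.copy()
    P = params.patch_half_width
    L = 2 * P + 1
    if n < L:
        raise ValueError(f"signal length {n} shorter than patch length {L}")

    inv_two_lam2 = 1.0 / (2.0 * lam * lam)
    num = x.copy()            # self-weight exp(0) = 1
    den = np.ones(n)
    max_shift = n - 1 if params.search_mode == "full" else min(
        params.search_half_width, n - 1)

    for k in range(1, max_shift + 1):
        m = n - k
        if m < 1:
            break
        d2 = (x[:m] - x[k:]) ** 2          # d2[i] = (x[i] - x[i+k])^2
        c = np.concatenate(([0.0], np.cumsum(d2)))
        idx = np.arange(m)
        hi = np.minimum(idx + P + 1, m)
        lo = np.maximum(idx - P, 0)
        ssd = c[hi] - c[lo]
        cnt = (hi - lo).astype(float)      # truncated patches renormalise
        wgt = np.exp(-ssd * inv_two_lam2 / cnt)
        num[:m] += wgt * x[k:]
        den[:m] += wgt
        num[k:] += wgt * x[:m]
        den[k:] += wgt

    return num / den


def denoise_record(record: ECGRecord, params: NLMParams = NLMParams(),
                   cutoff: float = 50.0, order: int = 4,
                   span: float = 0.2, robust_iterations: int = 5,
                   keep_stages: bool = False,
                   ) -> tuple[ECGRecord, DenoiseReport]:
    """Run the three denoising stages on every lead of a record.

    The noise SD feeding NLM is estimated per lead after the first two
    stages, when the residual noise is closest to white.
    """
    out = np.empty_like(record.signal)
    sigma: dict[str, float] = {}
    stages: dict[str, np.ndarray] = {}
    post_bw = np.empty_like(record.signal)
    post_loess = np.empty_like(record.signal)
    for j, name in enumerate(LEAD_NAMES):
        bw = butterworth_lowpass(record.signal[:, j], record.fs,
                                 cutoff=cutoff, order=order)
        detrended, _ = loess_baseline_remove(
            bw, record.fs, span=span, robust_iterations=robust_iterations)
        s = estimate_noise_sigma(detrended)
        sigma[name] = s
        out[:, j] = nlm_smooth(detrended, params, sigma_hat=s)
        if keep_stages:
            post_bw[:, j] = bw
            post_loess[:, j] = detrended
    if keep_stages:
        stages = {"butterworth": post_bw, "loess": post_loess,
                  "nlm": out.copy()}
    report = DenoiseReport(sigma_hat=sigma, stage_order=STAGE_ORDER,
                           stages=stages)
    return record.replace_signal(out), report
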