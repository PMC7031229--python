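# Methods

## Scope and model of the data

The package classifies the rhythm of a 10-second, 12-lead ECG sampled at
500 Hz into four groups: SB, AFIB, GSVT and SR. The raw clinical label
vocabulary has eleven rhythms; they merge hierarchically (AFL joins AFIB
because the two conditions commonly coexist; all supraventricular
tachycardias — ST, SVT, AT, AVNRT, AVRT, WAP — join GSVT; SI joins SR).
Sinus tachycardia's assignment to GSVT is the composition under which the
per-rhythm cohort frequencies reproduce the published per-group totals
(6,208 + 542 + 133 + 16 + 7 + 7 = 6,913); the merge map treats group labels
themselves as fixed points so merged data round-trips.

Sample indices are 0-based, time is `index / fs` seconds, windows are
half-open. Lead order is fixed to I, II, III, aVR, aVL, aVF, V1–V6; lead II
is the rhythm lead: RR intervals are computed there only. The on-disk lead
ordering is a package convention, not a property of the source data format.

## Synthetic generator

Each beat is a sum of Gaussian bumps (P, Q, R, S, T) on a jittered RR grid;
the 12 leads are fixed scaled/signed copies of one template (gains chosen
with magnitude ≥ 0.4 so R peaks stay prominent on every lead). Group
morphology follows the clinical definitions: SR 60–100 BPM with P waves and
low RR jitter; SB ≤ 60 BPM; GSVT > 100 BPM; AFIB has no P waves, an
irregularly irregular RR grid (RR coefficient of variation 0.25), and a
6–8 Hz low-amplitude fibrillatory oscillation in their place. Wave offsets
and widths default to physiologic orders (P ≈ 50 ms wide and small, QRS
large and narrow, T ≈ 120 ms and medium), compressed at fast rates so beats
do not fuse. Machine-measurement metadata (ventricular rate, QRS count,
intervals, axes) is computed from the ground-truth fiducials so the
machine-feature group is exercisable synthetically; ages are drawn per
group around the published cohort means.

Noise is additive and three-component — a power-line sinusoid (50–60 Hz),
a sub-0.5 Hz baseline sinusoid, and white Gaussian noise — matching the
three contamination sources the denoiser addresses. What the generator does
**not** emulate: electrophysiologically realistic vectorcardiographic lead
projections, morphology classes beyond rhythm (PVC/RBBB/LBBB/APC), muscle
artifact, electrode motion, or between-subject morphology variability.
Consequently, passing benchmarks here demonstrates the pipeline's
correctness and its sensitivity to rhythm-defining structure (rate,
regularity, P-wave presence), not clinical-grade accuracy on hospital data.

## Denoising

1. **Butterworth low-pass**, cut-off 50 Hz, order 4, applied
   forward–backward (`sosfiltfilt`) so the response is zero-phase; phase
   distortion would shift fiducials and corrupt every downstream timing
   feature. The order is a package choice (standard ECG practice); both
   cut-off and order are parameters.
2. **Robust LOESS baseline removal.** The baseline is a locally weighted
   quadratic regression of the signal on time with tricube weights and
   five bisquare robustifying iterations (QRS complexes act as outliers
   and must not drag the baseline). The default span is 0.2 of the record:
   calibrated on pure sub-0.5 Hz wander, a 2 s quadratic window tracks a
   0.3 Hz component to residual RMS ≈ 0.013 (a 3 s window leaves 0.17),
   while beat-scale structure is protected by the robust weights. Local
   fits are evaluated on a ≤ 250-point grid and linearly interpolated —
   the baseline is band-limited far below the grid spacing, so this is
   numerically lossless; with robustification disabled the smoother is an
   exactly linear operator.
3. **Non-local means.** Each sample is replaced by a weighted average of
   all samples whose surrounding patches look alike, with Gaussian weights
   `exp(-ssd / (2 L λ²))` over patches of half-width 10 (L = 21 samples)
   and λ = 1.5 σ̂. σ̂ is the MAD-based estimate over normalised second
   differences `(2x(l) − x(l−1) − x(l+1))/√6`, whose √6 normalisation makes
   the residual SD equal the white-noise SD on a smooth signal; the median
   is robust to the QRS spikes, so all interior samples are used rather
   than a hand-picked homogeneous region. σ̂ is estimated per lead, after
   the first two stages, where the residual noise is closest to white.
   The search defaults to the full record (repeated beats are the best
   donors); a windowed search (± a configurable number of samples) trades a
   little accuracy for an order of magnitude of speed and is used by the
   end-to-end pipeline. Patches truncated at record edges renormalise by
   the number of samples actually compared. σ̂ = 0 degenerates λ and the
   stage becomes the identity (logged).

Known limitation: at λ = 1.5 σ, features whose amplitude is below roughly
2λ are partially flattened toward baseline, because their patches are
indistinguishable from flat signal at that bandwidth. On raw noise of
SD 0.05 this caps NLM-alone MSE reduction near 40% (R peaks themselves
reach 90%+). In the three-stage pipeline σ̂ is measured after low-pass
filtering and is several times smaller, so the effect vanishes and the
composite benchmark reduces MSE by ~95%.

## Fiducials and attributes

Peaks are local maxima, valleys local minima (detected on the negated
signal). Each extremum carries:

* **height** — the signed sample value;
* **prominence** — height minus the lowest enclosing contour line. On each
  side the search walks to the nearest strictly higher sample, recording
  the minimum met; the contour is the higher of the two side minima. A side
  that reaches the record edge without meeting a higher sample imposes no
  constraint (the edge is an impassable wall), so the tallest peak's
  prominence is its height above the record minimum. For interior peaks
  this coincides exactly with `scipy.signal.peak_prominences`, which is
  used as an independent oracle in the tests; the boundary convention
  differs deliberately so that the invariant "prominence of the global
  maximum = height − record minimum" holds.
* **width** — horizontal extent at half prominence, crossings located by
  linear interpolation, clamped at record edges.

QRS classification is a package design (the partitioning rule is not
specified by the method description): R candidates must exceed
`max(0.5 × median prominence of the top-10 peaks, 0.3)` — the relative
term adapts to amplitude scale, the absolute floor prevents records
containing only P/T-scale undulations from acquiring spurious QRS labels —
and candidates within 200 ms resolve to the more prominent (refractory
rule). Peaks within ±60 ms of a surviving R peak are QRS; remaining peaks
are non-QRS; valleys are their own class (Q and S dips are therefore
valleys, matching the three-subset partition). Validated against generator
ground truth: sensitivity and precision 1.0 at ±2 samples on clean records.

## Features

Empirical frequency distributions are 100 equal-width bins spanning
[min, max] of each record's own series (per-record ranges follow the
method's construction; a global-range mode is not provided because vector
lengths, not bin alignment, are the published contract). The last bin is
right-closed so counts always sum to the series length; an empty series
yields all zeros, a degenerate range puts all mass in the first bin.
Pair enumeration covers *all* unordered pairs (within-class i < j;
cross-class full product), differences use the earlier-minus-later
convention (location differences are therefore negative), and pairs with
zero time difference are excluded. Variances are sample variances (n−1),
zero for singletons. Empty classes produce sentinel zeros so every vector
has a fixed, globally stable schema regardless of input. Demographics
(age; sex encoded female = 0, male = 1) join every group, and union
compositions de-duplicate shared names — the published group counts
(11, 23, 32, 221, 230, 3302, 3323, 3332, 39602, 39821) reconcile exactly
under these conventions.

Group 11 is ambiguous in its source: its description ("groups 3 and 9")
yields 39,632 features, its printed count (39,830) matches groups 5 and 9.
The default builds the described composition; `g11_count_match=True`
builds the count-matching one. Neither is asserted as the original intent,
and group 11 is excluded from count-based checks.

Min–max rescaling maps each lead to [0, 1]; constant leads pass through
with a logged notice. Rescaling is on by default in the pipeline and makes
features invariant to per-lead offset and gain.

## Gradient boosting

The K-class booster follows the classic multinomial gradient boosting
recipe: residuals are `r_ik = y_ik − p_k(x)` under the softmax link
(the score-to-probability map is implemented as a proper softmax with
max-subtraction stabilisation); per iteration and class an exact greedy
least-squares tree is fit to the residuals; each leaf gets the one-step
value `γ = ((K−1)/K) Σr / Σ|r|(1−|r|)`, guarded to 0 when the denominator
falls below 1e-12 (pure leaves); updates are shrunk by a learning rate.
Shrinkage and row subsampling are not part of the minimal printed recipe
but are standard and are tuned in the published hyperparameter grid, so
they exist as parameters (subsampling draws rows without replacement per
(iteration, class) from one seeded stream). Scores start at the constant
model f_k0 = 0 (uniform prior); a class-log-prior start is available.
Splits use midpoint thresholds with ties broken toward the lowest feature
index, and an optional per-split feature subsample (`max_features`).
Determinism is tree-by-tree for a fixed seed.

With K = 2 the construction reduces to binomial boosting: the two
per-class residual vectors are exact negatives, so (without subsampling)
the two trees per iteration mirror each other and the model is equivalent
to a single booster on the score difference — asserted in the tests.
Training deviance is non-increasing at full subsample and modest learning
rate; on separable fixtures test accuracy matches scikit-learn's
gradient boosting within 2 points at matched hyperparameters.

## Evaluation protocol

Per-class F1 = 2PR/(P+R) (0 when the denominator vanishes); the selection
criterion is the support-weighted mean `Σ F1_j N_j / Σ N_j` with N_j the
true-class supports, so classes absent from a fold carry no weight. Micro
F1 equals accuracy in single-label classification. The stated protocol
"10-fold cross-validation with 20% testing data" is internally
inconsistent (true 10-fold implies 10% test); the package implements 10
stratified seeded shuffle-splits at 80/20 — honouring the more specific
printed fractions — with classical stratified k-fold available as a mode.
Stratification itself is a package default; whether the original folds
were stratified is unstated.

The registry's 19 base algorithms delegate to scikit-learn (xgboost for
EGBT); only the gradient-boosting classifier described above is
implemented from scratch, and the scikit-learn booster remains available
independently as a cross-check. The shipped grid file mirrors the
published hyperparameter table verbatim; option spellings that newer
library versions renamed (`max_features='auto'`, GBT `loss='deviance'`,
SGD `loss='log'`) are translated at estimator construction.

## Study conditions of the end-to-end benchmark

The demonstration dataset is 100 records per group (n = 400), 10 s at
500 Hz, with noise amplitudes power-line 0.1, baseline 0.3, Gaussian 0.03
(relative to an R amplitude of 1). The pipeline denoises with windowed NLM
(search half-width 300 samples), extracts group-8 features with rescaling,
and cross-validates the from-scratch booster (50 iterations, depth 3,
learning rate 0.1, `max_features='sqrt'`) over 10 stratified 80/20 splits.
These sizes are the package's chosen demonstration scale; the machinery
accepts arbitrary n, full-search NLM, and the full grid file.

## Numerical choices and degenerate inputs

* LOESS normal equations get a 1e-12 ridge jitter against rank-deficient
  windows; the robust scale uses `6 × median |residual|` bisquare.
* `estimate_noise_sigma` needs ≥ 3 samples; constant or linear inputs give
  exactly 0.
* EFD of an empty series: zeros with lo = hi = 0.
* Records with fewer than two detected R peaks emit RR sentinel zeros with
  a logged notice rather than failing.
* Prediction ties break toward the lowest class index.
* Per-record seeds spawn from the master seed via `SeedSequence`, so any
  record regenerates independently and full-pipeline outputs are
  byte-identical across runs at a fixed seed.

## Known limitations

* Synthetic-only validation — see the generator section for what that does
  and does not show.
* The NLM low-amplitude flattening discussed above.
* Beat-level windowing for external beat-annotated databases ("two RR
  intervals around each heartbeat") is out of scope; so are wavelet/Fourier
  feature extraction and second-order (Newton) boosting variants, which are
  reachable through the registry's xgboost engine instead.
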