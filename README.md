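# ecgrhythm

Multi-stage classification of cardiac rhythm from 10-second, 12-lead ECGs
(500 Hz), for researchers building or benchmarking arrhythmia classifiers.
The package implements a complete scheme — three-stage denoising, an
interpretable peak/valley feature extraction method, and multiclass
gradient boosting with grid search and weighted-F1 model selection — and
ships a seeded synthetic ECG generator so every stage is testable without
any clinical data download.

## The method

**Labels.** Eleven clinical rhythm labels merge into four analysis groups:
SB (sinus bradycardia), AFIB (atrial fibrillation + atrial flutter), GSVT
(supraventricular tachycardias, including sinus tachycardia), and SR
(sinus rhythm + sinus irregularity).

**Denoising** runs three stages per lead:

1. zero-phase Butterworth low-pass (50 Hz, order 4) for high-frequency and
   power-line noise;
2. robust LOESS (locally weighted quadratic regression, bisquare
   reweighting) to remove sub-0.5 Hz baseline wander;
3. non-local means: `S(i) = Z(i)^-1 Σ_j w(i,j) D(j)` with patch weights
   `w(i,j) = exp(-Σ_δ [D(i+δ) - D(j+δ)]² / (2 L_Δ λ²))`, where
   `λ = 1.5 σ̂` and the noise level is the MAD estimate
   `σ̂ = 1.4826 · median(|D - median(D)|)` over normalised
   second-difference residuals.

**Features.** Local maxima and minima of each lead carry three attributes
(height, width at half prominence, prominence — the drop to the lowest
enclosing contour line). Peaks split into QRS vs non-QRS; valleys form a
third class. Eleven feature groups combine machine measurements,
demographics, RR-interval statistics (lead II), per-class attribute
summaries, and 100-bin empirical frequency distributions of attributes,
pairwise location differences, and difference-over-time ratios across the
six class combinations — up to 39,821 features per record.

**Classifier.** A from-scratch K-class gradient-boosted tree ensemble:
per iteration and class a regression tree is fit to the softmax residuals
`r_ik = y_ik - p_k(x_i)`, each leaf receives
`γ = ((K-1)/K) Σr / Σ|r|(1-|r|)`, and scores update with shrinkage.
A registry exposes 19 standard algorithms (scikit-learn / xgboost) plus
ensemble and multiclass-decomposition strategies for comparison studies;
model selection maximises the support-weighted mean F1
(`Σ_j F1_j N_j / Σ_j N_j`) over 10 stratified 80/20 splits.

## Worked example

```python
import ecgrhythm as er
from ecgrhythm.synth import RhythmParams, NoiseSpec
import numpy as np

params = RhythmParams(group="SR", heart_rate=75.0)
clean, truth = er.generate_record(params, seed=1)       # 5000 x 12 at 500 Hz
noisy = er.add_noise(clean, NoiseSpec(powerline_amp=0.1,
                                      baseline_amp=0.3,
                                      gaussian_sd=0.05), seed=11)
denoised, report = er.denoise_record(noisy)
print(round(report.sigma_hat["II"], 4))                 # 0.0077
before = np.mean((noisy.signal - clean.signal) ** 2)
after = np.mean((denoised.signal - clean.signal) ** 2)
print(f"MSE reduction: {100 * (1 - after / before):.1f}%")   # 94.7%

fv = er.extract_record_features(denoised, group_id=8)
print(len(fv.names))                                    # 3332
```

The printed `sigma_hat` is the per-lead noise SD estimated after the first
two stages (small, because the low-pass already removed most white noise);
the MSE reduction is measured against the known clean signal; 3332 is the
group-8 feature count (machine measurements + lead II summaries + lead II
frequency distributions + demographics).

End to end from a shell:

```bash
ecgrhythm run --seed 1 --out results/study
# mean weighted F1 = 0.989
```

This simulates 400 labelled records (100 per rhythm group), denoises them,
extracts group-8 features, and cross-validates the boosted-tree classifier
over 10 stratified 80/20 splits; the weighted F1 is the support-weighted
mean of per-class F1 scores on the held-out splits.

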