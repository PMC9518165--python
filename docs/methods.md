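# Methods

This note documents the models, conventions and design choices behind
`laughpd`, in the order the pipeline runs.

## Signal front end

**Pre-emphasis.** A first-order FIR high-pass, y(n) = x(n) − k·x(n−1),
with y(0) = x(0) (zero pre-history). Default k = 0.97, the midpoint of
the commonly used 0.95–0.98 range; any k in (0, 1) is accepted. The
filter offsets the −6 dB/octave glottal spectral tilt so higher formants
contribute to the cepstrum.

**Framing.** 25 ms windows with 10 ms *overlap* — i.e. a 15 ms hop.
Overlap (not hop) is the configured quantity; both readings of
"10 ms" exist in the speech literature, and the overlap reading is the
one adopted here (configurable via `FramingConfig`). A trailing segment
shorter than one window is discarded rather than padded, so every frame
is full length and the local-stationarity assumption applies uniformly.
Each frame is multiplied by a symmetric Hanning window.

**Power spectra.** Frames are zero-padded to the 512-point DFT and the
one-sided power |X(j)|², j = 0..256, is kept. At 16 kHz this gives
31.25 Hz bins; the 512-point size is also the grid on which the
reference filter-center table lives (every tabulated Mel center is a
multiple of 31.25 Hz).

## Filter banks

All three banks use M = 26 triangular filters on 0–8 kHz.

**Mel.** 28 points equally spaced on the Mel scale
(1125·ln(1 + f/700)) are unwarped to Hz; the 26 interior points are
snapped to the DFT-bin grid. The snap rule is *peak-weight snapping*:
the snapped center is the bin that carries the maximum weight of the
continuous triangle spanning the two neighboring points (ties to the
lower bin). For symmetric triangles this is nearest-bin rounding, but a
triangle whose rising slope is shallower than its falling slope can
peak, after discretization, at the bin above the nearest one — this
happens exactly once in the default bank (filter 9) and peak-weight
snapping reproduces the full reference center table, which nearest-bin
rounding does not. Triangles then span adjacent snapped centers with
unit peak at the center.

**Human-Factor (HFCC).** Centers as published in the packaged reference
table; each triangle extends center ± ERB/2 where
ERB(f_c) = 6.23f² + 93.39f + 28.52 Hz with f_c expressed in kHz. The
printed form of this polynomial with f_c in Hz is dimensionally
meaningless (it would give ~4·10⁸ Hz at 8 kHz), so the canonical
Moore–Glasberg kHz convention is used. An `erb_scale` factor (default
1.0) widens the triangles if desired. Low-frequency HFCC filters are
much narrower than their Mel counterparts, which is the defining
property of the variant.

**Bark (BFCC).** Centers from the reference table; triangles span
adjacent centers as for Mel. The Bark map is
13·atan(0.00076·f) + 3.5·atan((f/7500)²), inverted numerically by
bisection where needed.

For the default configuration the HFCC and Bark center frequencies are
taken from a packaged 26×3 reference table rather than re-derived: the
constructive equal-spacing rule reproduces the Mel column exactly but
deviates from the tabulated HFCC/Bark columns (by up to eight bins for
Bark), and the procedure that produced those columns is not otherwise
recoverable. For non-default filter counts or ranges the constructive
rule (Mel spacing for HFCC, Bark spacing for BFCC) is used and should be
treated as an approximation. One tabulated HFCC center (filter 24,
5537.50 Hz) is not a bin multiple; it is kept verbatim.

## Cepstra and pooling

Filter energies are floored at 1e−10 before log10 so silent frames do
not produce −inf. The cepstrum is
c_n = Σ_{m=1..M} log10 s(m) · cos(π n (m − 0.5) / M) for n = 1..13.
The n = 0 term is a pure log-energy sum and is excluded: with it the
features would encode recording gain, and loudness is deliberately not a
feature. Δ tracks are central differences (c(t+1) − c(t−1))/2 with edge
replication (the difference is undefined at the first and last frame
otherwise); ΔΔ applies the same operator twice.

Pooling uses the sample mean, sample SD (n−1 denominator), sample
skewness (g₁) and non-excess kurtosis (normal → 3) of each coefficient
track over the frames. "SD" is the dispersion of the coefficient across
frames, not the standard error of its mean — the standard error would
shrink with laugh duration and confound bout length with pathology.
Zero-variance tracks get skew = kurt = 0 by convention. The full
selection is 3 streams × 4 moments × 13 coefficients = 156 components;
a mean+SD selection gives the 78-component variant. Feature tables are
CSV with `stream.statistic.coefficient` headers plus
clip/subject/class/sex metadata columns.

## MVN cohort augmentation

Per (class, sex) group, `fit_cohort_model` stores the componentwise
sample mean and variance of the group's feature vectors;
`sample_cohort` draws independent normals with that mean and diagonal
covariance. Diagonal covariance is the default because the generator is
defined by per-feature variances; full-covariance fitting/sampling is
available behind a flag (`full_cov=True`) but with 156 dimensions it
needs far more source laughs than a desk-scale study provides. Models
are fitted per class×sex by default; pooling per class is a caller
choice. Sampled vectors have no subject of their own: for grouped CV
they are assigned pseudo-subject blocks of consecutive draws
(`block_size`), a documented stand-in for true subject structure.

## Waveform simulator

`synthesize_laugh` renders a laugh bout as 3–6 voiced bursts (120–260 ms)
separated by 80–180 ms gaps. Each burst is a glottal pulse train whose
cycle periods carry multiplicative jitter and whose pulse amplitudes
carry shimmer; pulses drive two all-pole resonators (700 and 1400 Hz,
bandwidths 90/150 Hz) and a Hanning envelope shapes the burst.
Aspiration noise (the same resonators, tripled bandwidth) is mixed at
`breath_noise_db` relative to the voiced RMS. F0 declines within bursts
and across the bout in proportion to `f0_var`.

The class contrast is a single scalar: `effect_size` interpolates
linearly from the healthy endpoint (jitter 1%, shimmer 4%, noise
−25 dB, bandwidth scale 1.0, f0_var 0.15) to a dysarthria-like endpoint
(jitter 5%, shimmer 14%, noise −12 dB, bandwidth scale 1.9, f0_var
0.06): more cycle-level perturbation and breath noise, smeared
articulation, flattened prosody. `make_synthetic_study` builds a
balanced class×sex cohort in which every subject draws a base F0 once
(so laughs within a subject correlate and subject-wise CV is
meaningful) plus per-subject offsets on the perturbation axes, so the
classes are overlapping distributions rather than point masses. The
endpoint magnitudes and subject spreads are calibrated so the default
`effect_size = 0.6` produces random-forest accuracy in the mid-80s on a
120-laugh study — a deliberate emulation of the reported operating
range, not a fit to any acoustic corpus.

In `pitch_matched` mode the pitch-moving axes (f0_var, jitter) stay at
the healthy values for both classes and subject base F0s are *paired*
across classes (subject i of each class shares one draw), so per-clip
pitch statistics are matched by construction and any residual
classification signal must be spectral. This is the constructed null
behind the pitch-ablation negative control.

What the simulator does **not** model: realistic laugh phonetics
(vowel quality, inhalation phases), disease progression or medication
state, room acoustics, or microphone variation. Passing tests therefore
demonstrate that the pipeline detects the *kinds* of acoustic change
dysarthria produces at controlled effect sizes — not clinical
performance on real laughter.

## Pitch estimation

Frame-wise F0 via the normalized autocorrelation peak (40 ms frames,
10 ms hop, 80–600 Hz search range, parabolic lag interpolation).
A frame is voiced when the peak exceeds 0.6 — a deliberately strict
threshold, because marginal frames are where octave and noise errors
live. Per-clip pitch statistics (mean, SD, min, max of F0) are computed
over the voiced frames whose RMS reaches the 60th percentile of voiced
frames, i.e. the burst centers: which *edge* frames survive the voicing
gate depends on noise floor and spectral shape, and including them would
let non-pitch factors contaminate nominally-pitch statistics. The
voicing fraction itself is excluded from the pitch statistics for the
same reason.

## Classification and evaluation

Folds partition *subjects*: distinct subject ids are shuffled by seed
and dealt round-robin into k folds, so all records of a subject share a
fold. k = 1 is rejected (no training segment).

Per fold, the training-fold mean/SD standardize both splits for the
distance- and margin-based families (kNN, SVM); random forests are
scale-invariant and skip standardization. Families: RF with 100
unpruned trees and √156 features per split; kNN with Euclidean
distance; SVC or ν-SVC (ν = 0.5) with linear, 3rd-degree polynomial and
RBF kernels. Continuous PD scores are the tree-vote fraction (RF), the
neighbor-class fraction (kNN) and the decision value (SVM); ties (even
kNN votes, zero SVM margin) resolve toward PD, the clinically
conservative direction. Validation predictions from all folds are
pooled into one confusion matrix (pooled-prediction metrics rather than
per-fold averaging); AR is the pooled correct fraction ×100, and
per-class rates follow the TPR/TNR convention (tp_rate + fn_rate = 1).
MCC returns 0 when any marginal is empty. ROC is a threshold sweep over
unique pooled scores with trapezoidal AUC, which equals the
tie-corrected Mann–Whitney concordance.

## Study orchestration

`run_study` chains everything: simulate, extract per bank, fit and
sample cohorts, then evaluate the moment grid (each moment alone, then
incrementally mean → +SD → +skew → +kurt, per stream and combined), the
six-kernel SVM grid, and a per-bank summary. The grid is generated
programmatically from `FeatureSelection` subsets, so the tabular report
structure is a view over one run. All randomness derives from the
single study seed via `SeedSequence`; the JSON report is byte-identical
across reruns of one config, and the manifest (config hash, seed,
version, sizes) suffices to regenerate every number.

## Numerical and scale choices

- Energy floor 1e−10 before log10; feature matrices are rejected if
  non-finite.
- Bisection inverse of the Bark map: 60 halvings on [0, 16 kHz],
  sub-µHz resolution.
- Statistical checks in the test suite run at sizes chosen to make
  their tolerances meaningful at desk scale: null calibration with
  1,500 vectors/class under 10-fold CV (0.03 on AUC ≈ 2.8 null SEs),
  dose-response on 5,000 vectors/class under 2-fold CV over a 5-point
  Mahalanobis-separation grid (0, 1, 2, 3, 5; d = 5 has Bayes error
  ≈ 0.6%), cohort-moment recovery at 10,000 draws, and the ablation and
  leakage experiments on studies of 192 and 144 laughs.

## Known limitations

- The acoustic simulator is a perturbation harness; none of its
  parameters were fitted to recorded laughter.
- Diagonal-covariance augmentation ignores inter-feature correlation,
  which real cepstral moments certainly have; augmented-cohort
  accuracies are therefore optimistic relative to cohorts with
  correlated noise.
- Grouped CV on augmented cohorts uses pseudo-blocks, not subjects;
  conclusions about subject-level generalization come only from the
  waveform path.
- Pitch statistics depend on the autocorrelation estimator's voicing
  decisions; they are a negative control here, not a validated F0
  measurement method for pathological voices.
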