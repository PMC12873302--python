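# Methods

`fcstack` implements a subject-level classification pipeline for resting-state
EEG functional connectivity, together with a synthetic cohort generator that
lets every stage be exercised without access to clinical data. This note
documents the models, the numerical choices, and what the synthetic studies
do and do not demonstrate.

## Pipeline overview

Input is a cohort of subjects, each with preprocessed EEG cut into
non-overlapping 5-second epochs (19 channels at 500 Hz for the clinical
montage the pipeline targets). The stages are:

1. **Band decomposition.** Each epoch is filtered into delta (0.5–4 Hz),
   theta (4–8 Hz), alpha (8–14 Hz), beta (14–30 Hz), and gamma (30–45 Hz)
   with a 4th-order Butterworth band-pass applied forward–backward
   (`scipy.signal.sosfiltfilt`). Zero-phase application was chosen because
   the phase-coupling metrics (PLV, wPLV) would be confounded by a causal
   filter's frequency-dependent group delay; the cost is that the first and
   last ~0.5 s of an epoch can carry edge transients.
2. **Connectivity extraction.** Twelve pairwise metrics per band produce one
   symmetric channels × channels matrix per epoch (60 feature keys over the
   five bands), each projected onto the SPD cone.
3. **Base classification.** One FgMDM classifier per (band, metric) key,
   under an SPD geometry chosen from affine-invariant Riemannian,
   log-Euclidean, or Euclidean (log-Euclidean by default: in practice it
   performs on par with the affine-invariant metric at a fraction of the
   cost).
4. **Stacking.** A class-distinctiveness filter retains the top half of the
   keys; stratified 5-fold subject-grouped cross-validation produces
   out-of-fold epoch probabilities; these are averaged per subject; greedy
   forward selection picks the keys whose elastic-net meta-classifier
   maximizes internal cross-validated subject ROC-AUC; the final elastic-net
   logistic regression (α = 1, L1-ratio λ = 0.15) maps the subject-level
   probability vector to one positive-class probability per subject.
5. **Evaluation.** Leave-one-subject-out cross-validation refits the entire
   stack per fold; accuracy, sensitivity, specificity, F1 and ROC-AUC are
   computed from the pooled subject probabilities at a 0.5 threshold, with a
   DeLong test of AUC against 0.5.

## Connectivity metrics

With X, Y two band-limited channels of one epoch:

- **Cov / Corr** — biased sample covariance E[(X−EX)(Y−EY)] and Pearson
  correlation.
- **XCov / XCorr** — the signed value of the cross-covariance sequence at
  the lag maximizing its absolute value, and its normalization by
  √(Var X · Var Y). The sequence is estimated *circularly* (FFT periodogram
  convention, biased 1/N normalization): every lag then averages N products,
  so a time-shifted copy of a channel is recovered with coefficient 1 at the
  true lag, and Cauchy–Schwarz keeps |XCorr| ≤ 1 at every lag. A linear
  (zero-padded) estimator would attenuate the peak by (N−k)/N and weight
  long lags by very few samples.
- **CSD / Coh** — Welch cross-spectra (1-s Hann segments, 50% overlap; nine
  segments per 5-s epoch), aggregated as the arithmetic mean over the
  frequency bins inside the band: band-mean |S_XY| for CSD, band-mean
  |S_XY|²/(S_XX·S_YY) for coherence. Welch averaging keeps the null
  coherence of independent channels well below 1 (≈ 1/#segments), which a
  single-segment estimate would not.
- **MI / ECC** — plug-in histogram mutual information in bits,
  MI = H(X) + H(Y) − H(X,Y), with the entropy correlation coefficient
  ECC = MI/√(H(X)·H(Y)). Bin edges follow the Freedman–Diaconis rule
  computed per subject from that subject's pooled band-limited samples per
  channel and shared across the subject's epochs, so within-subject epochs
  are binned identically; an IQR of zero falls back to Sturges' rule with a
  warning. The joint histogram is computed once per unordered pair, making
  the matrix exactly symmetric. The MI diagonal is H(X); ECC's diagonal
  is 1.
- **AECov / AECorr / PLV / wPLV** — from the Hilbert analytic signal per
  channel: covariance/correlation of the amplitude envelopes, the
  phase-locking value |E[e^{i(arg X_H − arg Y_H)}]|, and its
  amplitude-weighted variant |E[|X_H||Y_H| e^{iΔφ}]| / E[|X_H||Y_H|]. The
  analytic signal is computed per epoch, consistent with per-epoch
  filtering.

**SPD projection.** Several metrics (XCov at a maximizing lag, band-mean
coherence, PLV, MI, …) are not guaranteed positive definite. Every matrix is
passed through an eigenvalue-clipping projection: symmetrize, eigendecompose,
raise eigenvalues below ε = 1e-10 to ε. For symmetric input and ε = 0 this is
the Frobenius-nearest positive semidefinite matrix; matrices already
satisfying the constraint pass through unchanged.

## SPD geometry and FgMDM

Three distances between SPD matrices C₁, C₂:

- affine-invariant Riemannian: d_R = ‖log(C₁^{-1/2} C₂ C₁^{-1/2})‖_F,
- log-Euclidean: d_L = ‖log C₂ − log C₁‖_F,
- Euclidean: d_E = ‖C₂ − C₁‖_F.

Means follow their metric: arithmetic for Euclidean, exp of the mean of logs
for log-Euclidean, and the Karcher mean for the affine-invariant metric
(fixed-point iteration initialized at the log-Euclidean mean, unit step, at
most 50 iterations, stopping when the tangent-gradient norm falls below
1e-8). Tangent vectors use the half-vectorization with √2-scaled
off-diagonals, which makes the tangent norm equal the manifold distance for
all three metrics and the inverse map exact.

The FgMDM classifier (1) maps training matrices to the tangent space at
their weighted manifold mean, (2) runs Fisher's Discriminant Analysis there
and reconstructs each vector from its projection onto the (classes − 1)
discriminant directions (geodesic filtering), (3) maps back to the manifold
and recomputes class means, and (4) assigns new samples to the nearest class
mean, with probabilities softmax(−d²) — continuous, order-preserving with
the nearest-mean rule, and exactly ½/½ for equidistant samples. Because the
tangent dimension n(n+1)/2 usually exceeds the number of training subjects,
the within-class scatter is shrunk toward a scaled identity,
(1−γ)S_W + γ·tr(S_W)/d·I with γ = 0.1 by default. Sample weights — inverse
epoch count per subject, so every subject contributes equally — propagate
into the reference mean, the scatter matrices, and the class means.

## Stacking details

- **Filter.** Class distinctiveness of a key is d(m₁, m₂) / (½(σ₁ + σ₂)):
  the distance between class means over the average within-class mean
  distance to the own class mean, all under the classifier's metric and with
  the same inverse-epoch weights. The top ⌈n/2⌉ keys are retained; ties
  break lexicographically. Scores are always computed within the training
  fold only.
- **Out-of-fold probabilities.** Subjects (not epochs) are stratified into
  5 folds; every epoch is scored by a model whose training fold excluded its
  subject. Only the positive-class probability is kept.
- **Wrapper.** Greedy forward selection on the subject-level table; each
  candidate set is scored by mean subject ROC-AUC over an internal
  stratified 5-fold split, stopping when no candidate strictly improves the
  score. At least one key is always selected — an empty meta-model is not a
  classifier.
- **Meta.** Elastic-net logistic regression in the standard
  parameterization (total penalty strength α = 1, L1 fraction λ = 0.15,
  sklearn saga with C = 1/α), unpenalized intercept. Two numerical
  refinements matter for honest cross-validated evaluation:
  - coefficients left below 1e-8 by the solver are snapped to exact zero;
  - the intercept is replaced by its exact 1-D maximum-likelihood value
    given the final coefficients (closed form when all coefficients are
    zero, otherwise a bracketed root of the monotone weighted mean-residual
    equation);
  - the meta stage weights the two classes to equal total mass (subjects
    stay uniform within class).

  Without these, a fully regularized-away model predicts a constant whose
  value tracks the training fold's class prior; under leave-one-subject-out
  pooling that prior is the complement of the held-out label, so pure noise
  is converted into a deterministic anti-ranking (pooled null AUC of 0
  instead of 0.5). With them, zero-coefficient folds emit exactly 0.5 and
  pooled ties score as chance.

## Evaluation

Sensitivity is the recall of the positive class; F1 = 2PR/(P+R); ROC-AUC is
the Mann–Whitney rank statistic with ties credited ½. The DeLong test
compares AUC against 0.5 using the placement-value variance; when that
variance vanishes at perfect separation the test falls back to the
Mann–Whitney null variance (m+n+1)/(12mn), which is the correct variance
under the hypothesis being tested; the fully tied case returns p = 1 with a
warning. Classifier diversity uses normalized disagreement
D_ij = N_{ŷᵢ≠ŷⱼ} / (N(1 − Accuracy_ij)) with Accuracy_ij the accuracy of the
averaged-probability two-model ensemble at threshold 0.5, and D = 0 when the
classifiers agree everywhere; hierarchical clustering of D uses average
linkage with a flat cut at 75% of the maximum disagreement. Demographic
group comparisons reconstruct the one-way ANOVA from per-group n/mean/SD
(exact when the summaries are exact) and use the chi-square test of
independence without continuity correction.

Fig-2-style per-key scores, pairwise ensembles, and the diversity analysis
run on stratified 5-fold subject CV; headline performance uses LOSOCV.

## Synthetic cohorts

Each epoch is a sum of five band-limited unit-variance Gaussian sources plus
white sensor noise (SD 0.5), scaled by one log-normal per-subject gain
(σ = 0.2). Group structure enters only through (a) the alpha-band mixing
weight c — every channel's alpha source is √c·shared + √(1−c)·independent,
so the expected off-diagonal alpha-band correlation is ≈ c and the implied
channel covariance (1−c)I + c11ᵀ is positive definite for c ∈ [0, 1) — and
(b) a multiplier on delta-source variance. Default group parameters mirror
the clinical cohort the pipeline targets: 36/23/29 subjects (AD/FTD/HC) with
reduced alpha coupling in the patient groups (0.2/0.3 vs 0.5) and increased
delta power in AD (×1.5); demographics are drawn from the published
group-wise age/MMSE means and SDs and sex proportions, and epoch counts per
subject are uniform on [60, 250], matching 5-s epochs cut from 5–21-minute
recordings.

What the generator does *not* emulate: volume conduction and electrode
geometry, non-Gaussian or nonstationary dynamics, artifacts, within-subject
autocorrelation across epochs, or any spatial structure beyond the one
shared source. Consequently, passing the synthetic studies shows that the
pipeline recovers linear band-specific coupling differences and is calibrated
under a null — not that clinical effect sizes are attainable.

## Calibration and recovery studies

The reference experiments (`fcstack.experiments`) run at a reduced scale
chosen so a complete study is minutes on one core: 8 channels, two bands and
two-to-three metrics per study, 15–20 subjects per group, 20–34 epochs per
subject. The generative structure is unchanged by the reduction.

- **Null calibration** (20 cohorts, no group difference): mean pooled
  LOSOCV subject AUC should sit in [0.40, 0.60] and DeLong p < 0.05 should
  occur at roughly the nominal rate (≤ 3/20).
- **Signal recovery** (20 seeds, alpha coupling 0.1 vs 0.7): the
  (alpha, Cov) and (alpha, Corr) base classifiers should reach subject-level
  out-of-fold AUC ≥ 0.9 while gamma-band classifiers stay below 0.7.

`scripts/acceptance.py` recomputes both studies plus the clinical table's
demographic statistics from scratch and writes the numbers as JSON.

## Known limitations

- Only binary problems are exercised end to end; FDA supports classes − 1
  directions generically, but the stacking and evaluation layers assume two
  classes.
- Probabilities from FgMDM (softmax of negative squared distances) and from
  the heavily regularized meta model are rankings, not calibrated
  posteriors.
- The circular cross-covariance estimator assumes per-epoch stationarity;
  true lags near half the epoch length would alias.
- The EDF/BIDS import path picks channels by 10–20 names and epochs the
  continuous signal; it assumes the recording is already cleaned and
  re-referenced.
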