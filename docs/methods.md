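# Methods

## Trial timeline and the synthetic cohort

Time 0 is the onset of the feedback period. The online decoder's relay
delay places the feedback display/stimulation at +0.5 s; the
motor-imagery instruction ends at −2.0 s, so the 300 ms baseline window
is [−2.3, −2.0] s and the default epoch span [−2.3, 1.5] s covers both
the baseline and the full analysis window. The sample grid is anchored
on integer multiples of 1/fs (fs = 256 Hz), which makes the half-open
[0, 1.5) s window exactly 384 samples and the ×16 decimation exactly 24
bins per channel.

Each synthetic trial is:

- **pink noise** — Gaussian 1/f noise, `noise_sd` = 1.5 µV per channel
  (spectrum shaped in the frequency domain, DC removed);
- **a motor-imagery contaminant** — a sinusoid with per-trial random
  frequency in 8–12 Hz and random phase, amplitude `alpha_amp` = 2 µV.
  It lies entirely inside the low-pass filter's stopband, so it tests
  the filter rather than the classifier;
- **the ErrP template**, added only when the trial's feedback is
  incorrect: two Gaussian lobes (negative at +0.25 s after the display,
  −6 µV; positive at +0.45 s, +5 µV; width 0.05 s), scaled per channel
  by a fronto-central topography peaked at FCz/Cz. The topography is
  deliberately non-uniform so the surface Laplacian retains the
  deflection (a spatially uniform component would be cancelled).

Feedback correctness is Bernoulli with `error_rate` = 0.2568, matching
the 74.32 % online accuracy of the stimulation-feedback group (0.34
reproduces the 66 % of the visual group). Labels follow the merged-foot
rule: hand trials are correct iff the feedback limb matches; foot-imagery
trials are correct if either foot was stimulated.

**Covariate shift.** Each subject applies `gain * (M(s) @ data) + offset`
with `M(s) = (1−s) I + (s/C) 11^T`, plus a latency jitter added to the
template lobes at generation. Defaults (`default_shifts`): gains
log-uniform in [0.5, 2.0], offsets Gaussian (1.5 µV), jitter Gaussian
with a 60 ms scale, mixing 0.15. The jitter scale matters: component
latencies across subjects vary by tens of milliseconds, i.e. about one
62.5 ms decimation bin, which is what genuinely breaks a classifier
trained on pooled raw features. The DC offset, by contrast, is removed
exactly by baseline correction and is kept only for realism of the raw
traces.

These noise/shift defaults were fixed once, by anchoring the pipeline's
operating range to the study-scale behavior (baseline arm well below the
transport arm, both far from ceiling); they are not per-test knobs.

**What a green test does not establish.** The generator produces
Gaussian, stationary noise with a single shared template shape; real
EEG has non-Gaussian artifacts (EMG, blinks), per-subject template
*shapes*, and session drift. Green tests show the pipeline recovers the
structure it assumes, not that it reaches any particular performance on
recorded data.

**Seeding.** One master seed; each subject's stream derives from
(seed, CRC32(subject_id)), so cohorts are bit-reproducible and subjects
are independent.

## Preprocessing

- **FIR design.** `scipy.signal.remez`, passband [0, 6] Hz, stopband
  [8, 128] Hz, default 301 taps. 257 taps reach only 39.8 dB stopband
  attenuation, and reweighting the bands to pass 40 dB pushes the DC
  gain outside 1 ± 0.01; 301 taps give 45.2 dB with DC gain 0.9946. The
  achieved attenuation is measured from the frequency response and
  stored on the `FilterSpec`; designs below 40 dB warn rather than fail.
- **Filtering** is single-pass FFT convolution with symmetric odd-length
  taps in 'same' mode, i.e. exact group-delay compensation, preserving
  the equiripple magnitude response (forward–backward filtering would
  square it).
- **Laplacian neighborhoods.** Cz − mean(C1, FCz, C2, CPz) as
  prescribed; FCz and CPz use their nearest recorded 10–20 neighbors
  (FCz: Fz, FC3, FC4, Cz; CPz: Cz, CP3, CP4, Pz). Configurable via
  `LaplacianMontage`.
- **Stage order.** Low-pass → Laplacian → baseline correction →
  [0, 1.5) window → decimate. Baseline correction must precede window
  extraction because the baseline segment lies before the window. The
  order is fixed and regression-tested; correcting after decimation is
  *not* equivalent (the baseline mean would be estimated from 5 samples
  instead of 77).
- **Decimation** keeps indices 0, 16, 32, … (no bin averaging); the 0–6
  Hz filter has already removed everything that could alias.

## Optimal transport

The coupling solves entropic OT with a class/column group penalty:

    min <tau, J> + lambda * sum tau log tau
                 + eta * sum_j sum_c ||tau(I_c, j)||_1 ** (1/2)

- **Cost scale.** `lambda` = 1 and `eta` = 10 are interpreted on a
  unit-median cost: the decoding layer divides each fold's squared-
  Euclidean cost matrix by its median before solving. On raw microvolt
  features the median cost is O(10^3) and the stated weights would be
  vacuous.
- **Group penalty.** The per-class *l2* column norm, under entropic
  smoothing (where every entry stays strictly positive), has a
  class-constant majorization gradient at uniform spread
  (1/sqrt(N_c)) — it biases every column toward the larger class and
  never concentrates. The implemented penalty is therefore the concave
  lp–l1 form `||tau(I_c, j)||_1^(1/2)`, whose
  majorization–minimization weights `(1/2) m_c(j)^(-1/2)` make classes
  that already carry mass in a column cheaper, concentrating each column
  within one class as `eta` grows. Measured column purity is monotone in
  `eta` (0.74 → 0.99 on a two-cluster toy); `eta = 0` reduces exactly to
  plain Sinkhorn.
- **Semisupervised mode** adds a large cost penalty on source–target
  pairs with different labels (target labels steer the coupling only;
  the classifier never sees them). Unsupervised mode uses source labels
  alone.
- **Numerics.** Plain Sinkhorn scaling switches to the log-domain
  (log-sum-exp) iteration when `lambda` is small relative to the median
  cost or the cost spread would underflow `exp(-J/lambda)`; the MM outer
  loop always uses the log-domain solver because near-empty groups get
  near-infinite weights. Returned plans are rounded onto the transport
  polytope (row/column scaling plus a nonnegative rank-one repair), so
  marginals are exact to float precision even when the fixed point
  stalls at the ~1e-5 float64 floor that tiny `lambda` induces; the
  `converged` flag still reports the scaling iteration's own tolerance.
- **Barycentric mapping** is the source→target direction
  `diag(tau 1)^(-1) tau F_t`. The alternative printed transposed form is
  dimensionally inconsistent as written; the target→source reading was
  implemented and benchmarked during development and performed no
  better, so the standard direction stands.
- `exact_ot_oracle` (scipy HiGHS LP) is a test-only oracle for the
  unregularized problem on instances up to 400 cells.

## Decoding and evaluation

Leave-one-subject-out: the held-out subject is the target, the rest are
pooled as the source (per-subject transport exists as a development
variant; pooling is the default). The classifier suite delegates to
scikit-learn with fixed published hyperparameters — random forest
(100 trees, Gini, bootstrap) as the primary decoder; shrinkage LDA
(lsqr/Ledoit–Wolf), logistic regression (C = 1000, tol 1e-4, lbfgs),
linear SVM (hinge, C = 1), bagged LDA (100 learners) and AdaBoost
(100 depth-1 trees, lr 1.0) as comparisons. Headline metrics are
positive-class (`incorrect`) precision/recall/F1; a support-weighted F1
is also recorded because near-equal published precision/recall/F1
triples suggest an averaged report.

Paired pipeline comparisons use a two-tailed Wilcoxon signed-rank test:
zero differences dropped, exact null distribution by dynamic programming
over sign assignments for n ≤ 25 (midranks doubled to stay integer),
normal approximation with tie correction beyond.

**Known limitation.** On the default shifted cohort the *semisupervised*
transport arm beats the pooled baseline uniformly (all 8 subjects,
exact p = 0.0078 at seed 0). The *unsupervised* arm raises the cohort
mean on every seed examined but not uniformly per subject: without
target labels the group-sparse coupling assigns only ~60 % of target
columns to the correct class under the 3:1 class imbalance, so subjects
whose baseline is already strong are sometimes degraded, and the exact
n = 8 signed-rank test then stays above 0.05. The corresponding
acceptance test is left failing rather than weakened.

## ERP statistics

Grand averages pool trials across subjects (per-subject averaging is
available as a flag); the Kruskal–Wallis p-series is computed per
timepoint with tie correction and the chi-square (1 df) approximation,
all-tied timepoints reporting p = 1 with a warning. No multiple-testing
correction is applied by default, matching the per-timepoint display
convention; a Benjamini–Hochberg option can be layered on the returned
p-series. On null-template cohorts the fraction of significant
timepoints sits near the nominal 5 %, with a wide sampling band because
pink-noise timepoints are autocorrelated.
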