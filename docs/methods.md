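# Methods

This note documents the models, algorithms and numerical conventions the
package implements, the choices made where the design was genuinely
open, and what the synthetic validation does and does not establish.

## Problem setting

Resting-state EEG carries a well-replicated spectral signature of
Alzheimer's disease: as severity increases, alpha-band (8–13 Hz) power
falls and theta/delta power rises. The pipeline turns this into a
classification problem over three groups — neurotypical, mild AD,
moderate AD — recorded on a 20-site 10-20 montage at 200 Hz and analysed
in 8-second trial windows. Each trial is band-pass filtered, decomposed
by empirical mode decomposition (EMD) into 7 intrinsic mode functions
(IMFs) plus a residual per channel, reduced to one scalar feature per
component, and classified; five diagnostic contrasts ("issues") are
evaluated under two cross-validation schemes.

## Synthetic cohort generator

Clinical EEG of this kind is not publicly available, so the package
ships a generator that reproduces the *statistical* structure the
analysis depends on, and nothing more.

Per subject, each channel is a mixture

    x(t) = sqrt(c) * s_common(t) + sqrt(1 - c) * s_indiv(t),   c = 0.30,

where both sources are built as

    s(t) = sum_b sqrt(w_b) * u_b(t) + g * n_bg(t).

`u_b` is unit-average-power Gaussian noise band-limited (FFT masking) to
band `b` (delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30 Hz), `w_b` its
relative *power* weight, and `n_bg` unit-power 1/f^β background noise
(β = 1, flat below 0.5 Hz, no DC), scaled so the structured-to-background
power ratio is `snr_db` (default 20 dB — high enough that measured band
power tracks the configured weights within a few percent; at much lower
SNR the 1/f background, which loads delta preferentially, would distort
the weight ratios).

Default class contrasts follow the canonical AD shift with monotone
orderings: alpha weights 3/2/1 and theta weights 1/2/3 across
neurotypical/mild/moderate; delta and beta are 1 for all classes. Band
weights get a per-subject multiplicative jitter of ±10% (uniform,
seeded) so subject-grouped cross-validation is non-trivial. All
randomness flows from `numpy.random.SeedSequence(seed, spawn_key=(class,
subject))`: cohorts are bit-reproducible and subjects are independent
streams.

What the generator does *not* model: dipole geometry and volume
conduction, artifacts (blinks, EMG), non-stationarity within a
recording, age/medication covariates, realistic channel covariance
beyond a single common source. Consequently, passing results here
demonstrate that the pipeline is implemented correctly and can recover
class-conditional spectral structure at realistic SNR — not that it
would reach the same numbers on clinical recordings.

### The null cohort

`null_cohort_spec` produces the label-uninformative counterpart of any
cohort spec: flat class profiles *and* zero subject jitter. Both must be
removed for a valid chance-level control, because subject jitter is
label-correlated even when class profiles are identical — every subject
belongs to exactly one class, so under pooled-trial k-fold a classifier
can memorize subject signatures and map them to labels. We measured
35–40% three-class accuracy on jittered zero-contrast cohorts versus
the ~33% chance level; that is genuine subject leakage, not an
implementation artifact, and it motivates the subject-grouped scheme.

## Pre-processing

An elliptic IIR band-pass, 0.1–60 Hz, designed as cascaded second-order
sections (the direct-form polynomial is ill-conditioned with a band edge
at 0.001 of Nyquist). Design parameters the source analysis left open
are fixed at: prototype order 4 (band-pass order 8), 0.1 dB passband
ripple, 40 dB stopband attenuation — mild ripple with a realizable
transition near 0.1 Hz at fs = 200 Hz. The filter is applied
forward-backward (zero phase) with even reflection padding, so the
envelope timing that EMD depends on is not skewed; the effective
magnitude response is the square of the single-pass response. Epochs are
cut contiguously from sample zero; a trailing remainder shorter than one
epoch is discarded.

## Empirical mode decomposition

Sifting follows the classical scheme: locate interior extrema,
interpolate maxima and minima separately with natural cubic splines,
subtract the envelope mean, repeat. Conventions, all deterministic:

* **Extrema / plateaus.** An interior sample is an extremum if it
  strictly exceeds (or falls below) its neighbours; a plateau bounded by
  a rise and fall counts once, at its midpoint rounded down. This keeps
  the decomposition stable on 16-bit-quantized data where ties are
  common.
* **Boundary handling.** The two extrema nearest each end are mirrored
  about the endpoint before the spline fit, suppressing end swings that
  otherwise corrupt short epochs.
* **Spline fallback.** Fewer than 4 knots → linear interpolation.
* **Stopping rule.** Sifting of one IMF stops when the Cauchy criterion
  SD = Σ(h_prev − h_new)² / Σ h_prev² drops below 0.2, or after 10
  iterations (classical defaults). The IMF condition — extrema and
  zero-crossing counts differing by at most one — is *recorded* per IMF
  (`IMFSet.condition_met`) rather than enforced: for the first IMF of
  broadband noise the counts still differ by 2–3 after 10 sifts, so
  enforcement would simply always exhaust the budget.
* **Fixed width.** Exactly 7 IMFs are always returned; if the residual
  becomes monotone earlier, remaining slots are zero-filled and flagged
  as placeholders so every trial yields a constant-width feature vector.
  The telescoping construction guarantees Σ IMFs + residual equals the
  input to round-off regardless.

Envelope ordering (upper ≥ lower) holds at each envelope's own knots by
interpolation and almost everywhere else; natural-spline overshoot can
invert the pair locally between knots, which is inherent to
spline-envelope EMD and left as-is.

## Feature operators

One scalar per component (7 IMFs + residual), stacked channel-major into
a `n_channels × 8` row per trial; feature types are never concatenated —
each is classified on its own. For a component x(1..N):

| name   | definition | degenerate rule |
|--------|------------|-----------------|
| energy | Σ x(n)²    | — |
| lbp    | ln(Σ x(n)² / N) | all-zero → ln(1e−12), floor |
| norm   | √(Σ x(n)²) | — |
| ppv    | max − min  | — |
| zcr    | (1/N) Σ \|sgn(x_n) − sgn(x_{n−1})\|, sgn(0)=+1 | — |
| mf     | Σ f_j P_j / Σ P_j on a rectangular-window periodogram | zero power → 0 |
| apen   | φ^e(r) − φ^{e+1}(r), see below | zero SD → 0 |

Approximate entropy uses embedding dimension e = 2 and tolerance
r = 0.2 × SD(x) (the dominant convention in the ApEn literature; the
source analysis states neither), Chebyshev distance by default with
Euclidean available, self-matches included (the Heaviside step is 1 at
zero distance, so every correlation integral is positive and logs are
defined), natural logarithms. Making r proportional to SD renders apen
exactly invariant to amplitude scaling, which the suite asserts.

Mean frequency uses a full-length rectangular-window periodogram — exact
for bin-aligned tones (an 8 s window gives 0.125 Hz bins, so 10 Hz sits
in one bin). zcr is kept as the literal normalized sign-difference sum
(range [0, 2)); any monotone rescaling is irrelevant to classifiers.
The norm includes the square root (it is the Euclidean norm, the square
root of the energy) — the suite asserts norm² = energy.

## Classifiers

Six configurations, evaluated uniformly behind one `fit_predict`
surface with z-score standardization fit on the training fold only:

* **lda** — linear discriminant analysis, empirical priors
  (scikit-learn).
* **svm** — linear-kernel SVC, max 1000 iterations (scikit-learn).
* **adaboost_tree** — AdaBoost over decision trees, 100 learners,
  learning rate 0.01 (scikit-learn). Named for what it is; ensembles of
  this configuration are sometimes loosely called "random forest" but
  the boosting method is what is implemented.
* **ann** — 1 hidden layer × 10 logistic units, softmax output, trained
  full-batch with Adam on a mean-absolute-error objective plus L2
  penalty (a portable approximation of Bayesian-regularized training),
  100 epochs, lr 0.01 (numpy, in-package).
* **rnn** — Elman network, hidden delays 1:2, 10 tanh units, linear
  readout, same objective; the 160-wide feature row is presented as a
  length-8 sequence of 20-channel slices (component index as time).
* **cnn** — two blocks of (same-padded conv, batch norm, leaky ReLU,
  dropout 0.25), 96 filters, two dense layers, softmax/cross-entropy,
  Adam with mini-batches of 64. The nominal 11×11 filter cannot fit the
  20×8 channels × components map, so the kernel is clamped to the
  largest odd size that fits (9×7) — a documented deviation forced by
  the input topology.

The three networks are deliberately small numpy implementations: the
feature matrices here are hundreds of rows × 160 columns, and a
framework dependency is not warranted. Their training is deterministic
given (data, config, seed).

## Cross-validation and metrics

* **kfold** (default k = 10): stratified by class at the trial level.
  Trials of one subject can appear on both sides of a split; this
  subject leakage is retained deliberately — it is what pooling trials
  means — and quantified by comparison with the grouped scheme.
* **loso**: within each class, subjects are partitioned into
  `round(1/holdout_fraction)` groups (default 20% → grouped 5-fold);
  no subject crosses the train/test boundary. A fraction of
  `1/n_subjects` gives literal leave-one-subject-out.

Binary metrics are percentage precision TP/(TP+FP), recall TP/(TP+FN),
accuracy (TP+TN)/total, with the disease class positive. The
three-class issue reports macro-averaged one-vs-rest precision and
recall and trace accuracy (the binary formulas do not generalize
uniquely; macro averaging is the standard unweighted choice).
Fold metrics are averaged unweighted. A training fold with a single
class is skipped and counted, never silently averaged; undefined
precision (no positive predictions) scores 0 and is flagged.

## Validation strategy and problem sizes

The suite validates by construction and by oracle, at sizes chosen to
keep a full run inside a few minutes on one core:

* formula-level oracles: each feature operator against an independent
  direct evaluation on 1,000 seeded components (ApEn against an O(N²)
  double-loop oracle at N = 200);
* EMD: exact reconstruction on 1,000 seeded 1,600-sample epochs;
  two-tone (2 Hz + 20 Hz) separation with r ≥ 0.95 per tone;
* filter: response evaluated at 10/30/90 Hz against the design contract;
* end-to-end: a 5-subjects/class × 20-trials cohort must reach ≥ 90%
  three-class accuracy with EMD + log band power + LDA under 10-fold,
  while the null cohort's mean accuracy over 3 replicates must sit
  inside the 95% binomial band around 1/3 (single CV runs have
  super-binomial variance because fold predictions share training data,
  so a mean over replicates is the stable null statistic);
* scheme ordering: pooled k-fold accuracy ≥ subject-grouped accuracy on
  average over 15 cohort replicates at 28 trials/subject — the leakage
  direction expected whenever subjects carry stable signatures.

## Known limitations

* EDF support is plain EDF, one sampling rate, no annotations; 16-bit
  quantization bounds round-trip accuracy by one step of each channel's
  physical range.
* The sifting defaults (SD 0.2, 10 sifts) favour speed and determinism;
  mode mixing between close frequencies is untreated (no ensemble EMD).
* The CNN/RNN/ANN are faithful small-scale implementations, not tuned
  deep models; at their nominal sizes (96 filters) the CNN is slow on
  large cohorts and is exercised at reduced size in routine testing.
* Synthetic validation bounds what can be claimed about clinical data;
  see the generator section.
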