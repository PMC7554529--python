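# Methods

## Problem and data model

The package decodes left- vs right-hand motor imagery (MI) from
trial-structured 3-channel bipolar EEG (C3, Cz, C4) sampled at 250 Hz.
A trial spans 8 s: fixation 0–3 s, cue at 3 s, imagery 3–7 s.  Trials are
grouped into five sessions per subject; sessions 1–3 are calibration
recordings, sessions 4–5 evaluation recordings.  Two protocols are
supported: intra-subject (train 1–3, test 4–5) and inter-subject
leave-one-subject-out (train on all five sessions of every other
subject, test on the held-out subject's sessions 4–5).  Splits are
deterministic; no shuffling happens at the split layer, and an identity
audit asserts that no held-out trial reaches a training batch.

## Synthetic EEG generator

The generator emulates exactly the statistical structure the decoder
exploits, nothing more:

- **Background**: Gaussian noise spectrally shaped to 1/f^`noise_exponent`
  (default exponent 1.0), unit RMS, DC removed.  This is the standard
  coarse model of resting EEG background spectra.
- **Rhythms**: each channel carries independent mu and beta oscillations —
  amplitude-modulated sinusoids at 10 Hz and 22 Hz with per-trial random
  phase, ±1 Hz center-frequency jitter and a slow (0.2–0.6 Hz, depth 0.3)
  amplitude modulation.  The beta amplitude is half the mu amplitude
  (beta rhythms are typically weaker).  The combined oscillatory RMS is
  `snr` times the noise RMS (default `snr` = 1.0).
- **ERD**: during the imagery interval the oscillation amplitude of the
  channel contralateral to the imagined hand (C4 for left, C3 for right)
  is multiplied by √(1 − `erd_depth`), i.e. band power drops by
  `erd_depth`.  The gain ramps with 250 ms raised cosines at either edge
  so the first/last analysis windows see no step discontinuity.
  Default `erd_depth` = 0.5 — a mid-range value for healthy subjects;
  no quantitative depth is published for the reference recordings, so the
  default is chosen for testability, not fidelity to any individual.
- **Subjects**: per-subject ERD depth is drawn once, lognormally around
  the configured value with log-sd `subject_shift_sd` (default 0.1),
  clipped to [0, 1].  Sessions are exactly class-balanced; per-session
  trial counts may differ (e.g. 140/140/140/160/160 mimics a
  competition-shaped subject with 420 training and 320 test trials).
- **Determinism**: a single integer seed fixes everything via spawned
  per-subject substreams.

Not modeled: volume conduction, ocular/muscular artifacts, ERS rebound
after imagery, feedback-dependent non-stationarity across sessions, and
channel covariance.  Consequently, passing the recovery tests shows the
*pipeline* is sound (images carry the class signal, the CNN finds it, the
metrics report it); it says nothing about accuracy levels attainable on
real recordings, where the effect is weaker and confounded.

## Input images

Eleven 2-s windows per trial (200 ms hop over 3–7 s, window end times
5.0–7.0 s; half-open sample ranges, segment k starting at sample
750 + 50k at 250 Hz).  Per window and channel: magnitude STFT with a
64-sample symmetric Hamming taper, 50-sample overlap (hop 14), 512 FFT
points → 257 bins × 32 frames, implemented as an explicit strided
windowed rFFT (no centering or padding conventions hidden in a library
call) and verified against a brute-force DFT oracle to 1e-9.

Band rows for [f_lo, f_hi] are bins floor(f_lo·n_fft/fs) ..
ceil(f_hi·n_fft/fs) inclusive — the one simple rule that yields 20 rows
for 4–13 Hz and 41 rows for 13–32 Hz at fs = 250, n_fft = 512.  The beta
block is cubic-spline interpolated along frequency onto 20 evenly spaced
points per time column (small negative overshoots are clipped to zero so
the image stays a magnitude), and stacked under the theta–alpha block;
channels stack depthwise → 40×32×3.

Scaling choices the method definition leaves open, exposed as
configuration:
magnitude (not power, not dB) spectrograms, and per-image min–max
normalization to [0, 1] before the CNN (`normalize="none"` available).
Bounded inputs stabilize the small-batch training; a constant image maps
to zeros.

## Architectures and training

Declarative specs (conv block / Mega Block / pooling stages) are traced
symbolically before any allocation.  Conventions: same-padded stride-1
convolutions, ceil-mode 3×3 stride-2 max pooling (overhang padded with
−inf), valid 8×8 stride-1 average pooling.  These are the only
conventions under which the flattened feature size is 192 for the
intra-subject stack and 108 for the Mega Block stack, for every repeat
setting 1–5 (repeats never change spatial dims).  Repeat counts outside
1..5 are rejected.

The numeric model is plain numpy (im2col convolutions, channel-wise
batch norm with ε = 1e-5 and 0.9-momentum running statistics, exact ReLU,
softmax head) with hand-written backward passes validated by central
difference gradient checks.  float32 by default; float64 available for
oracle-grade tests.  Weight init is uniform with 1/√fan_in bounds (no particular
scheme is prescribed by the method); biases start at zero.

`count_parameters` uses the convention *every tensor the optimizer
updates*: conv kernels + biases, batch-norm scale + offset, dense
weights + biases, and emits a per-layer audit table.  Under this (or any
obvious variant — drop biases, drop BN) the intra-subject network counts
24,194 parameters, not the published 23,269; the audit is documented
rather than forced into agreement.

Optimizers implement the two-line momentum update (no dampening, no
Nesterov) and Adam with standard bias correction, ε = 1e-8 added to the
bias-corrected √v̂.  Both are functional (params in, params out) so
single steps are testable against hand iteration to 1e-12.  The training
loop uses seeded shuffled mini-batches, L2 weight decay applied to conv
and dense kernels only (added as λw to the gradient, 0.5λ‖w‖² to the
reported loss), a piecewise-constant learning-rate schedule (drop by
`lr_drop_factor` every `lr_drop_period` epochs), and a monitoring-only
validation split of up to 500 segment images (capped at 20 % of the
data; no early stopping).  All 11 windows of a training trial inherit
the trial's label, multiplying 420 trials into 4,620 training instances.
A non-finite loss aborts with epoch/batch diagnostics.

## Hyperparameter search

Minimization over a box: Mega Block repeat count 1..5 (one integer tied
across the three blocks — every published per-subject setting uses equal
repeats), learning rate [1e-6, 1e-2] and L2 [1e-10, 1e-2] on log axes,
momentum [0.6, 0.98]; budget 30 evaluations, the first 5 from a seeded
Sobol design.  The GP is a Matérn-5/2 with ML-fitted amplitude and
length scale on the unit cube (jitter escalation 1e-10 → 1e-6 on
Cholesky failure).  Acquisitions: closed-form EI below the incumbent
posterior mean (σ = 0 handled as the deterministic limit) and PI with a
margin defaulting to the residual noise scale (σ = 0 degenerates to a
0/1 step).  The next point maximizes the acquisition over ≥1000 seeded
uniform candidates; integer axes round half-up.  A failing objective is
recorded at the worst value observed so far and the search continues;
the returned optimum is the argmin of *observed* values.  The objective
used by the pipeline is the validation misclassification rate of a
training run — the conventional choice where none is prescribed.

## Metrics

CA_gross = 100·(correct windows)/(trials × 11).  CA_ST counts a trial
correct iff ≥6 of its 11 windows are correct (11 is odd, so the majority
rule needs no tie-break).  CA_opt is the maximum column-wise accuracy
over the 11 decoding instants, ties resolving to the earliest instant
(lowest feedback latency).  Cohen's κ uses the two-class
confusion-matrix definition with marginal-product chance agreement;
degenerate single-class inputs return 0 with a warning.  κ is computed
per window instance for the gross view and per trial-majority label for
the single-trial view.  Method comparisons use the exact two-sided
Wilcoxon signed-rank test (zero differences dropped; identical vectors
give p = 1), appropriate at the n = 9 subjects scale.

## Problem sizes for the bundled experiments

The acceptance-level recovery experiment uses 3 subjects × 5 sessions ×
40 trials at `erd_depth` 0.7 (and 0 for the null control), 6 Adam epochs,
batch 50, lr 1e-3, Architecture-1 intra and Architecture-2 with repeats
(1,1,1) inter — the smallest schedule that trains to convergence on the
synthetic task, keeping a full four-run sweep within a few minutes on a
single CPU.  The chance bounds are exact binomial quantiles for the
80-trial test sets.  Unit and property tests use 2 subjects × 5 sessions
× 6 trials and toy architectures.

## Known limitations

- The numpy CNN targets clarity and testability; it is single-threaded
  matmul-bound and not meant for datasets beyond the desk scale.
- GDF reading follows the competition IV-2b event conventions
  (768 trial start, 769/770 cues, cue at 3 s) and keeps trials carrying
  rejection markers; it is exercised only for its error contract in CI
  since no recording ships with the package.
- The generator's lognormal subject-variability model and the default
  `snr`/`erd_depth` are plausibility choices, not fitted to any corpus.
- Batch-norm inference uses running statistics; with very few training
  batches these can lag the batch statistics and cost a little test
  accuracy.
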