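# Methods

## Signal model

The simulator emulates a standard SSVEP benchmark recording: 8 channels
(P7, P3, Pz, P4, P8, O1, Oz, O2) at 250 Hz, 4 s epochs, stimulus frequencies
{6, 8, 9, 10} Hz, 20 runs × 4 frequencies = 80 labeled trials per session.

Each trial is *signal + noise*:

- **Signal.** Channel `c` carries
  `gain_c · Σ_{h=1..H} (1/h) · sin(2π h f t + φ_h)`.
  The `1/h` amplitude decay encodes that SSVEP harmonics are weaker than the
  fundamental; the exact profile is not critical and any decaying profile
  exercises the decoders.  The per-channel gains
  (O* ≈ 0.9–1.0, P* ≈ 0.3–0.5) concentrate amplitude occipitally, as volume
  conduction of a visual-cortex source does.  The harmonic phases `φ_h` have
  a per-frequency mean (drawn once per seed) plus a per-run Gaussian jitter
  of standard deviation `phase_jitter_rad` (default 0.1 rad): SSVEPs are
  largely phase-locked to the stimulus, and the across-run phase consistency
  is exactly what the training-based decoders (MsetCCA, CFA, MLR, L1-MCCA)
  exploit, so it is an explicit knob.
- **Noise.** `1/f^α` Gaussian background (default α = 1, the canonical EEG
  spectral slope), built as `√m · shared + √(1−m) · independent` colored
  components with mixing `m = 0.5`, so channels are spatially correlated the
  way volume-conducted background EEG is — decoders that exploit multichannel
  structure are only meaningfully compared against correlated noise.
- **SNR.** The noise is scaled per trial so that the signal/noise power ratio
  on the reference channel Oz equals `10^(snr_db/10)` exactly.  The default
  operating point is −8 dB, a realistic single-trial SSVEP regime (per-trial
  oscillatory power well below the broadband background).  `snr_db = -inf`
  is the noise-only convention (signal amplitude forced to zero), used for
  chance-level testing.

Preprocessing mirrors standard practice: zero-phase 4th-order Butterworth
band-pass 4–45 Hz (applied forward–backward, preserving the harmonic phase
structure), bipolar/monopolar montage derivation (`anode − cathode` or the
anode row unchanged), and onset-anchored analysis windows (samples
`[0, w·Fs)`); trials are simulated in steady state from t = 0, with no
stimulus-onset transient.

Determinism: every trial's random stream is keyed on
`(seed, frequency, run)`, so identical configurations are byte-identical
after serialization, independent of generation order.

## Decoder implementation notes

- **References.** `Y_i` rows are unit-amplitude sine/cosine pairs for
  harmonics 1..N at `t = 1/Fs … n/Fs`; N defaults to 2 for CCA, LASSO and
  L1-MCCA.  A `reference_shape="square"` switch replaces each row by its
  sign, for the square-wave reading of the flicker waveform; the harmonic
  form is the default.
- **CCA** is computed by the numerically stable whitening route (orthonormal
  bases of the centered row spaces via SVD; canonical correlations are the
  singular values of `Qx'Qy`), with singular values below `1e-10·σ_max`
  truncated — the pseudoinverse path for rank-deficient covariances, which
  warns.  All covariances center signals in time first.  Weight signs are
  fixed by making the first nonzero element positive.
- **LASSO** minimizes the objective exactly as written,
  `‖y−Xβ‖₂² + λ‖β‖₁` (no ½ factor; solver penalties are scaled
  accordingly).  The solver is ADMM with one cached `p×p` inverse per penalty
  parameter, residual-balancing adaptation of the ADMM penalty, optional warm
  starting, and duality-gap termination (default 1e-9, certifying the 1e-8
  contract on well-conditioned data).  On the decoders' nearly collinear
  designs (condition numbers up to ~1e7) the residual-scaling gap estimate
  has a float64 round-off floor; the solver therefore also accepts an exact
  ADMM fixed point, or a stalled best-gap within 100× tolerance, and raises
  on genuine non-convergence.  Design columns are not variance-standardized
  (references are already unit amplitude); a switch is provided.
- **L1-MCCA** alternates L1-penalized least squares over `(v, w1, w3)` with
  all three penalties 0.02.  Renormalizing a LASSO iterate to the unit sphere
  is not a descent step for the constrained objective, so every coordinate
  update is safeguarded: the renormalized LASSO candidate competes with the
  exact norm-constrained least-squares minimizer (trust-region secular
  equation) and is accepted only if it lowers the objective.  Two starts are
  swept — the deterministic uniform `1/√dim` initialization (v solved first)
  plus one seeded random start — keeping the lower objective; sweeps stop on
  sufficient decrease < 1e-6 or at 200 sweeps; an all-zero solution triggers
  up to 5 fresh seeded starts before erroring.  On tensors with no coherent
  component the landscape is genuinely multimodal and no alternating scheme
  reliably finds the global optimum; the oracle-bound tests therefore use
  coherent toy instances, the regime the method is designed for.
- **MsetCCA** builds the full `R` and block-diagonal `S` covariance block
  matrices, ridge-regularizes `S` (by `1e-8·trace/dim`, with a warning) when
  nearly singular — which happens at very high SNR, where the trials are
  spatially rank-1 — and keeps only the leading eigenvector, since the
  optimized reference stacks exactly one canonical variable per trial.
  Filters are rescaled to the MAXVAR normalization constraint.
- **CFA.** The factorization algorithm is the largest interpretive choice:
  the shared temporal basis is estimated as the top right-singular subspace
  of the per-trial-centered trials stacked along channel rows — the best
  shared low-rank temporal fit, deterministic, with the individual parts as
  residuals.  `C_common` defaults to 1.  Multichannel test windows score each
  channel row against the basis and sum squared norms, reducing exactly to
  the single-vector rule when C = 1 (the headline one-channel use case).
- **MLR** uses M-column one-of-M coding (the pseudoinverse absorbs the rank
  redundancy), truncates singular values below `1e-10·σ_max`, and classifies
  by majority vote of the 5 nearest projected training points.
- **Tie-breaking** everywhere: the lowest frequency wins and the tie is
  recorded on the prediction record — reproducible and diagnostically
  visible.

## Evaluation and statistics

Leave-one-run-out cross-validation: each of the `n_runs` runs serves once as
the test fold; training-based decoders are refitted per fold on the remaining
runs' windows of the same length.  Hyperparameters (λ's, `C_common`, k) are
fixed constants, never tuned inside folds — tuning on the test fold would
bias the comparison optimistically.

The field-standard per-class statistics are `Pr = TP/(TP+FP)`,
`Se = TP/(TP+FN)`, `F = 2·Pr·Se/(Pr+Se)`; a class with no predicted or no
actual positives gets F = 0 and a degeneracy flag.  The headline score per
condition is the **unweighted macro average** across the four classes:
classes are balanced by design, making macro and pooled micro averages agree
in expectation, and the per-class values are always retained in the report.

McNemar's test uses only the discordant counts `b` (A correct, B wrong) and
`c` (the reverse): exact two-sided binomial when `b + c < 25` (with at most
80 matched trials discordant pairs are few, and the chi-square approximation
is unreliable there), otherwise the continuity-corrected chi-square
`(|b−c|−1)²/(b+c)` with 1 df.  The significance level is a knob, default
α = 0.05 (0.1 is sometimes preferred for small samples to avoid missing true
differences; both are supported).  `b + c = 0` yields p = 1 and no winner.
No multiple-comparison correction is applied to the pairwise win counts.
Montage-by-method marginal modelling (e.g. GEE) is out of scope: the pipeline
exports the long-format per-trial prediction records such a routine would
consume.

## What the synthetic benchmark shows — and what it does not

The generator reproduces the *statistical contract* each decoder relies on:
harmonic structure at the gazed frequency, occipital topography, across-run
phase consistency, spatially correlated 1/f background, calibrated SNR.
Passing tests therefore demonstrate algorithmic correctness and the expected
qualitative behaviour (perfect recovery at high SNR, chance level on noise,
degradation with shorter windows and fewer channels).

They do not certify real-data rankings.  Two gaps matter most:

1. The simulated waveform is a finite harmonic sum — when the decoders'
   references use the same number of harmonics, CCA's analytic template is
   essentially a matched filter and is hard to beat.  The low-channel
   demonstration regime therefore simulates 4 signal harmonics against
   2-harmonic references with phase jitter 0 and −2 dB SNR, giving the
   trained methods something real to learn.  In that regime CFA clearly
   outperforms CCA at sub-2-s windows (e.g. macro F 0.91 vs 0.81 at 0.5 s,
   0.99 vs 0.93 at 1 s, seed 1), echoing the short-window advantage of
   common-feature references reported on real recordings.
2. Real EEG carries trial-consistent non-stationarities, artifacts and
   subject idiosyncrasies that sample-hungry discriminative methods (MLR)
   exploit; a stationary harmonic-plus-1/f simulation under-serves them, and
   MLR's single-channel short-window scores here are accordingly modest.
   No leadfield/forward model, eye-blink or EMG artifacts are simulated.

A related caveat for the chance-level suite: within one seed the 80
leave-one-run-out predictions share 19/20 of their training data across
folds, so they are not independent draws; the pooled deviation from 0.25 can
modestly exceed the i.i.d. binomial width even for a perfectly calibrated
decoder.

## Numerical choices and problem sizes

- Filter: Butterworth order 4, `sosfiltfilt`; band edges validated against
  Nyquist.
- CCA/MLR rank truncation: `1e-10·σ_max`; CCA correlations clipped to [0, 1].
- LASSO: duality-gap target 1e-9 (scale-aware floor `1e-10·(‖y‖²+1)`),
  100 000 iteration cap.
- L1-MCCA: sweep tolerance 1e-6, 200-sweep cap, 2 starts.
- MsetCCA ridge: `1e-8·trace/dim` on near-singular `S`.
- Test-suite problem sizes: the perfect-recovery and chance-level suites run
  the full 20-run, 80-prediction leave-one-run-out protocol; oracle checks
  use 50 random instances; CFA recovery uses 50 seeds of 10 trials × 4
  channels × 200 samples.  The whole suite completes in a few minutes on one
  CPU, the acceptance script likewise.
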