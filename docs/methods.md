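# Methods

## The pipeline at a glance

One cell × one behavior (contraction or ciliary reversal) contributes a
60-trial binary response series recorded under 0.1-Hz mechanical
stimulation.  The analysis proceeds strictly per cell and per behavior —
cells are never pooled before the statistics stage:

1. **Embedding.**  The series is transformed into its 58 overlapping 3-bit
   windows (sequential-series embedding, step 1).  Each window is a serial
   behavioral strategy, id = big-endian value of the triplet; one strategy
   state spans 30 s (three 10-s inter-stimulus intervals).  The embedding
   is invertible (overlap-consistency), which the property tests assert.
2. **Distributions.**  At every window two distributions over the 8
   strategies are formed: *planned* — products of per-position
   Beta(1,1)-posterior-mean response probabilities computed from trials
   before the current one — and *executed* — add-1-smoothed cumulative
   strategy frequencies up to and including the current window.
3. **Engine metrics.**  Per window, the executed strategy's planned and
   executed probabilities give single-probability entropy terms
   H(p) = −p log₂ p, converted to Boltzmann entropy S = H·k_B·ln 2.  Work,
   power, efficiency, COP, fidelity and cycle type follow the definitions
   in the README.  Undefined ratios (W = 0, S_planned = 0) propagate as
   NaN and are excluded pairwise downstream — never silently zeroed.
4. **Error thresholds.**  The flip-averaged threshold S_sn replaces each
   position's expected probability x_i by f_i = 1 − x_i in turn and
   averages the three single-flip entropy terms.  Executed entropies are
   compared per strategy against these thresholds via two-tailed paired
   t-tests over group-mean window series.
5. **Statistics.**  Split-plot ANOVAs (group × metric; occurrence-weighted
   group × strategy difference scores), one-way simple comparisons,
   paired t-tests, lag-advanced F comparisons and quadratic trend fits.

## The synthetic-cohort generator

No public recordings exist, so cohorts are simulated.  The generator
emulates exactly the features the analysis relies on:

- **Dual-process learning.**  Per-trial response probability follows a
  single-exponential approach to an asymptote,
  q_n = p_asym + (p_init − p_asym)·e^{−(n−1)/τ}; sensitization when
  p_asym > p_init, habituation otherwise.  This is the simplest generative
  form consistent with "exponential response increment/decrement".
- **Responsiveness strata.**  Cells are classified by realized response
  frequency to the first five stimuli (0–0.2 low, 0.4–0.6 medium, 0.8–1.0
  high).  Stratum membership is enforced by rejection sampling (retry
  budget 1000) because it is defined on realized responses, not
  parameters; a cell that cannot be placed raises a stratum-infeasible
  error naming the stratum.
- **Study design defaults.**  Contraction strata n = 14/16/10
  (low/medium/high), reversal strata n = 17/23 (medium/high); no
  low-reversal stratum is generated by default because none was observed.
  Contraction and reversal series of one cell are independent.
- **Parameter defaults.**  Sensitizing cells draw p_asym ~ U(0.85, 0.98),
  habituating cells p_asym ~ U(0.02, 0.15), τ ~ U(5, 15) trials.
  Low-stratum cells sensitize, high-stratum cells habituate, medium cells
  do either with probability ½.  Rationale: recorded cohorts reach
  near-deterministic signalling (near-perfect modal fidelity) by the end
  of testing, which requires asymptotes near the extremes and time
  constants well inside the 60-trial session.  These defaults are the
  study conditions; they were fixed once and are not tuned per analysis.
- **Determinism.**  All randomness derives from the master seed through
  named substreams (CRC-keyed per cell, behavior and retry attempt), so a
  cohort regenerates bit-identically, and any single series regenerates
  from its ground-truth row alone.

What the generator does *not* emulate: continuous-time behavior, abnormal
body-shape exclusions, inter-behavior correlations within a cell (an
anticorrelation knob exists but is off), or any intracellular Ca²⁺
mechanism.  Passing tests therefore validate the computational pipeline
and its statistical behavior under the assumed learning model, not claims
about real recordings.

## Estimator and numerical choices

- **"Bayesian probabilities".**  The planned/executed estimators above are
  the package's own choice of proper Bayesian point estimates (rule of
  succession; add-α smoothing).  They keep every probability strictly
  positive — required by the entropy logarithms — and make planning and
  execution genuinely different stages.  Priors and smoothing (defaults
  Beta(1,1), α = 1) are config-exposed.
- **Power denominator.**  Windows advance one stimulus at a time, so
  P = ΔW/Δt uses Δt = one inter-stimulus interval (10 s) by default; the
  30-s state period is available via `dt_mode: period`.
- **Flip probability f.**  f_i = 1 − x_i (the position's expected
  probability replaced by its complement) is the only parameter-free
  reading of "a bit-flip introduced at each location"; it reduces to zero
  threshold for deterministic plans.  A constant-f override is available.
- **Modal ties** break toward the strategy whose first occurrence is
  earliest — deterministic and data-driven.
- **Degenerate statistics.**  Zero-difference paired samples resolve to
  "no difference" (t = 0, p = 1); constant non-zero differences are
  flagged degenerate; zero-variance series flag the lag-advanced F rather
  than dividing by zero.  An all-constant ANOVA returns F = 0, p = 1.
- **Channel capacity** pairs the argmax-planned strategy with the executed
  strategy per window; the prefix-maximal mutual information is reported
  (the alternative Shannon-capacity reading of "maximum over source
  distributions" is not guessed as canonical).
- **Multiple testing**: none by default (matching the original battery);
  a Benjamini–Hochberg toggle can be applied downstream by the caller.

## Known limitations

- **Mid-range entropy regime.**  With cumulative estimators over a
  58-window session, planned and executed probabilities stay in the
  mid-range (the cumulative posterior of a learning cell converges to its
  running average, not its asymptote; the smoothed frequency is bounded by
  (1+n)/(8+n)).  In that regime the per-strategy entropy term is near its
  maximum while flip thresholds — entropies of smaller flipped products —
  are lower, so executed entropies typically *exceed* the thresholds even
  in the noiseless limit p_E ≡ p_P (at x = 0.9 uniform,
  H(0.729) = 0.331 > mean-flip H(0.081) = 0.294).  Below-threshold
  behavior requires an extreme-concentration regime (probabilities ≥ 0.95
  or ≤ 0.015) that these estimators cannot reach within 58 windows.  The
  threshold comparison is still computed and reported exactly as defined;
  its verdicts on synthetic cohorts should be read with this in mind.
- **Lag-advanced F is conservative.**  The variance-ratio compares a
  57-point subseries against the 58-point series that contains it; the
  two sample variances are computed on nested data, so under an i.i.d.
  null the ratio concentrates near 1 and the nominal F(56, 57) reference
  almost never rejects (type-I error ≈ 0).  The statistic is provided for
  completeness with the documented df convention; `trend_f` (regression
  slope F, df (1, m − 2)) is the calibrated test of "improvement with
  time" and is reported alongside it everywhere.
- **Problem sizes.**  Default analyses use the 40-cell × 2-behavior study
  design; simulation-based checks use 10–20 cohorts, 10⁵ Monte-Carlo
  channel trials and 10³–2×10³ null replicates — sizes at which binomial
  Monte-Carlo error is well below the asserted tolerances.
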