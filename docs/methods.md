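# Methods

## Pipeline model

A recording is reduced in four steps, each a pure function with an explicit
contract:

1. **Fixation events.** Input is either a vendor fixation table or raw gaze
   samples. For raw samples an I-VT classifier is used: the velocity between
   consecutive valid samples is Euclidean displacement over Δt (per second,
   in input units; a `px_per_degree` factor converts to deg/s on request),
   runs of sub-threshold velocities form candidate fixations, and a
   candidate's duration is last-minus-first member time plus one sample
   period (the median Δt of the recording), so that an n-sample fixation at a
   uniform rate spans n sample periods. Candidates shorter than the minimum
   duration are dropped. Defaults are the common mobile-tracker event
   detector settings: 40 °/s threshold, 50 ms minimum. Invalid samples split
   candidates — a blink never bridges two fixations — and no velocity
   smoothing is applied by default (a centred moving-average width is exposed
   for noisy data). No merge step joins nearby fixations; vendor detectors
   differ here and we deliberately implement none rather than guess one.

2. **AOI letters.** Each fixation is mapped to the single uppercase letter of
   the first scheme region containing its position; everything else becomes
   the whitespace letter (default `W`). Rectangle membership is half-open
   ([x0,x1) × [y0,y1)) so abutting regions cannot both claim an edge point;
   polygon membership counts the boundary as inside. Scheme order resolves
   overlaps. Geometry is user-supplied: AOI definitions are scene-specific
   and there is no meaningful default.

3. **Dwell strings.** Maximal runs of equal letters collapse to one position
   carrying the run's summed duration and fixation count. The collapsed
   string therefore never repeats a letter adjacently, which is what makes
   k = 1 counts equal dwell counts, k = 2 counts equal transition counts, and
   restricts the reachable k-mer space to n·(n−1)^(k−1) patterns. Whitespace
   is retained in the string; analyses that want task-AOI-only patterns
   restrict the alphabet downstream, which drops every pattern containing an
   excluded letter and renormalises the surviving relative frequencies.
   The mean fixation duration averages over all fixations including
   whitespace by default (an `exclude_letter` switch exists because
   conventions differ).

4. **k-mer tables.** All overlapping windows at stride 1. The relative
   frequency of a pattern divides its mean count across the analysed trials
   by the sum of mean counts of all same-k patterns; at group level,
   per-participant mean counts are first averaged across participants and
   then normalised (the reported `sem` is instead the dispersion of
   per-participant relative frequencies, which answers the
   between-participant variability question the pooled point estimate
   cannot). Patterns with relative frequency strictly above the threshold
   (default 1%) are "relevant" and carried into trends and statistics.

## Trends and statistics

Per participant and pattern, the per-trial occurrence counts (raw counts, not
relative frequencies — group-curve magnitudes are then directly
interpretable as occurrences per trial) are regressed on the mean-centred
1-based trial index by OLS. Centring makes the intercept the fitted value at
the mean trial, which for OLS is exactly the participant's average count, so
between-group intercept comparisons measure average pattern occurrence while
slope comparisons measure learning rate. Trials are assumed equally spaced
and unweighted; no trial is dropped.

The battery, applied to novice groups only (an expert group is a reference
plateau, not an inference population, and typically has too few members):

- **Levene's test** (classic, mean-centred; Brown–Forsythe median-centring
  behind a flag) as the equal-variance precondition check, p > 0.05 passing.
- **Paired t** of first-vs-last-trial counts per group:
  t = mean(d)/(SD(d)/√n) on d = first − last, df = n − 1, two-sided p, and
  effect size r = √(t²/(t²+df)). Reports carry r at 4 decimals plus a
  3-decimal *truncated* companion, since published tables in this literature
  truncate rather than round. Zero-spread differences are reported as
  not-available rather than as a fabricated statistic.
- **Two-group one-way ANOVA** of per-participant slopes and of centred
  intercepts between the two novice groups, emitted as a full df/SS/MS/F/p
  table row per effect together with the global mean of the pooled values.
  No multiple-testing correction is applied by default, matching common
  practice in this design; the p-values are reported raw so any correction
  can be applied downstream.

All p-values are two-sided and significance flags use α = 0.05.

## The synthetic cohort generator

The generator emulates a repeated-assembly training study and is the test
bed for the whole pipeline. Each trial string is sampled from a first-order
Markov chain over the letters A (building area), B (bricks), C (manual),
W (whitespace) with zero diagonal — the simplest process that produces
collapsed strings directly and reproduces the 2-mer/4-mer phenomenology of
interest. Two chains define the behavioural endpoints:

- *novice*: attention routed through the manual (A→C 0.60, C→B 0.55,
  B→A 0.55 dominant), giving frequent ACB/BAC/CBA cycles and CAC
  manual-checking;
- *expert*: bricks↔building-area alternation (A→B 0.90, B→A 0.92), giving
  ABAB/BABA dominance with rare manual glances.

Learning follows an exponential saturation: on trial t the kernel is the
convex mix with expert weight w(t) = 1 − e^(−λ(t−1)), so trial 1 is pure
novice behaviour and the chain approaches the expert reference as practice
accumulates — the "decreasing increments" shape of a classical learning
curve. Defaults, chosen once to mirror a plausible 30-person study: two
novice groups of 14 (degrees of freedom 13 in the paired tests), λ = 0.40
for the simpler-stimulus group and 0.25 for the complex-stimulus group
(w(8) ≈ 0.94 vs 0.83, so the simpler task is learned faster, which is what
the slope/intercept ANOVA should detect), 2 experts sampled from the pure
expert chain for all trials, 8 trials. Collapsed string lengths are Poisson
with mean interpolating 100 (novice trial 1; ~110 for the complex stimulus)
down to 55 (expert) along the same w(t), matching the observation that early
novice scanpaths are longer and more meandering. Per-fixation durations are
lognormal (μ = 5.7, σ = 0.55 on the ms log-scale; median ≈ 300 ms), start
times cumulate with a 30 ms saccade gap. One seed governs everything;
participant substreams derive deterministically from (seed, group index,
participant index), so cohorts are bit-reproducible.

The ground-truth record carries the per-trial mixed kernels and the
chain-derived expected k-mer relative frequencies
P(a₀…a_{k−1}) = π(a₀)·∏P(aᵢ→aᵢ₊₁) under the stationary distribution π,
which empirical window frequencies approach for long strings.

What the generator does **not** emulate: raw gaze kinematics (saccade
velocity profiles, blinks — detector tests use hand-built sample streams),
higher-order sequential dependence, per-participant heterogeneity in
learning rate, task times and use errors. Passing tests therefore show the
*machinery* recovers planted sequence dynamics; they do not validate any
behavioural claim about real assembly tasks.

## Numerical choices and degenerate inputs

- Relevance threshold is a strict inequality (> 1%), so a pattern at exactly
  the threshold is excluded.
- Relative-frequency maps with an all-zero total are returned empty rather
  than dividing by zero; Σ rel_freq = 1 within 1e−12 otherwise.
- Trend fits need ≥ 2 trials (FitError below); residual variance uses the
  n − 2 denominator and is 0 for n = 2 where the line interpolates.
- SEM with a single contributor is NaN (sample SD undefined), not 0.
- Paired t with zero-spread differences and two-group ANOVA with zero
  within-group variance at equal means raise DegenerateDataError; the
  pipeline reports such cells as not-available. Zero within-variance with
  unequal means yields F = ∞, p = 0.
- Kernel rows must sum to 1 within 1e−9 with an exactly-zero diagonal; the
  stationary distribution comes from the unit left eigenvector, normalised.
- Fixation-table parsing reports the first offending line number for
  non-numeric time fields; missing required columns name the column.

## Problem sizes used in the checks

The test suite and acceptance script run entirely on generated data at the
study's own scale: default cohorts of 30 participants × 8 trials
(240 sequences, strings of ~55–110 letters), 20-cohort replicates for
direction-recovery checks, 100–200 participant cohorts for null (λ = 0)
calibration, and 200 × 400-letter strings for chain-expectation checks. The
full suite completes in well under a minute on a single CPU.

## Known limitations

- First-order Markov simulation cannot represent strategies with longer
  memory (e.g. a strict ACB→ACB cycle without its 2-step factorisation).
- The I-VT detector implements no fixation merging and no dispersion
  criterion; vendor outputs will differ in edge cases.
- Group-level relative-frequency SEM pairs a pooled point estimate with a
  per-participant dispersion measure (see above); the two use slightly
  different weightings when participants contribute unequal trial counts.
- The ANOVA layer assumes exactly two novice groups for the slope/intercept
  comparison; more groups would need the general one-way table.
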