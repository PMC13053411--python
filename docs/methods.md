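# Methods

This note documents the models, numerical choices, and open design decisions
behind the package. Everything quantitative stated here is computed by the
test suite or the acceptance script; nothing is asserted from data the
package cannot generate.

## Task designs and schedule construction

Schedules are built by **exact composition**: at the printed trial counts the
per-condition counts are the largest-remainder integer apportionment of the
stated proportions, and only the trial *order* is randomized. This makes
condition counts testable (160 cued trials always yield 112 valid / 32
invalid / 16 neutral) and matches how such experiments are actually
programmed. Non-integer per-location quotas (32 infrequent trials over 5
locations → 6.4) become the most-even partition {7,7,6,6,6}, with the +1
cells chosen by the participant seed so no location is systematically
favored.

Array locations are indexed 0..N−1 clockwise from the 12 o'clock position;
in the eight-item cued design, indices 0 and 4 are the vertical meridian and
are never used for targets or distractors (the cues reference left/right
sides only). The six-item design shares one frequent location between the
target and distractor manipulations; the four-item design draws distinct
frequent target and distractor locations per participant.

One stated probability table is internally inconsistent for the six-item
design: a 50% frequent target location cannot coexist with ~17% in *each* of
five other locations. We implement 10% per infrequent location (an even 50%
split over five); in the four-item design 50/3 ≈ 16.7% per infrequent
location is consistent and is used as stated.

Extinction blocks present a distractor on 100% of trials with fully
randomized locations; baseline blocks use a 50% distractor rate. In
target-location learning (TLL) blocks the distractor (50% of trials) is
balanced *within* each target condition so the presence contrast is
orthogonal to the frequency contrast.

## Generative model of behavior

Each participant carries latent condition effects (cue validity cost,
target-location frequency cost, distractor-location frequency cost, and
distractor-presence cost per block type) drawn once from a multivariate
normal with configurable means, between-subject SDs, and a correlation
matrix (validated symmetric PSD; a PSD-safe eigenvalue factor handles
singular cases such as ρ = 1). Trial RT is

    RT = baseline + Σ applicable latent effects + Normal(0, σ_within),

an additive-normal model chosen because the reference sensitivity analysis
for this design assumes exactly that structure (normal latent traits plus
normal trial noise); RT is floored at 1 ms and a draw beyond the 2,225-ms
response deadline becomes a non-response. Accuracy is Bernoulli with a
logistic model, log-odds = baseline − Σ effects, so condition effects compose
additively on a bounded scale (the source analyses report accuracy effects
only as percentage differences, which pins no particular link function; the
logit keeps probabilities valid at extreme parameter values).

Defaults: baseline RT 800 ± 80 ms between participants, σ_within = 200 ms,
baseline accuracy 0.90, lapse rate 0.02. The lapse process replaces a trial
with a fast guess (uniform 80–240 ms), an invalid key press, or a
non-response with equal probability; its default magnitude produces the
~1–2% accuracy-stage exclusion rates typical of online samples and ensures
the trial filters are exercised. Within-subject trial SDs are *not*
published quantities for this paradigm; 200 ms is a realistic choice for
~900-ms online RTs, and the package treats it as a free simulator parameter
throughout. The same caveat applies to between-subject SDs: the
`example_population` values are reconstructions from group standard errors
(se·√n, net of the trial-noise share), documented as such.

Per-participant randomness derives from
`SeedSequence(master_seed, spawn_key=(participant_id, k))` with k = 0 for
latent draws, 1 for trial noise, 2 for design randomization, so any
participant's data are independent of how many others are simulated, and the
trial CSV is byte-identical under a fixed master seed.

What the simulator does **not** model: learning dynamics within a block
(condition effects are stationary, so acquisition curves and extinction decay
are absent — the carryover analysis on simulated data therefore tests the
null machinery, not learning itself), sequential dependencies (post-error
slowing, priming), RT skew (a lognormal option would change distributional
shape but not the mean-difference analyses the pipeline runs), and
speed–accuracy coupling. Passing tests on simulated data show the *analysis
chain* is correct and calibrated, not that real behavior satisfies these
assumptions.

## Trial and participant exclusion

The accuracy-analysis set removes trials with no response, an invalid key, or
an RT *outside* 250–2,225 ms — bounds inclusive, so a 250-ms trial survives.
The RT-analysis set additionally removes incorrect trials; it is always a
subset of the accuracy set and filtering is idempotent. Participant
screening excludes anyone with block accuracy below 70% or mean block RT
outside 250–1,500 ms on two consecutive blocks; both statistics are computed
over responded trials (whether the original protocol restricted the RT band
to correct trials is not stated; all responded trials is the implemented
reading). Screening can be disabled to reproduce the relaxed replication
protocol.

## Effect scores and group tests

Scores are differences of per-participant condition means (simple arithmetic
means of surviving trials, no trimming), oriented so a positive RT score is
the cost of the unlikely/invalid/distractor-present condition: invalid −
valid, infrequent − frequent, present − absent. The source material defines
the frequency effect once in the opposite order but normalizes and tabulates
it as infrequent − frequent; the latter is adopted throughout so positive RT
effects mean facilitation by the likely condition. The normalized score
(c₂ − c₁)/(c₂ + c₁) is dimensionless, antisymmetric, and bounded in (−1, 1)
for positive inputs; a zero denominator yields a missing value with a
warning, and a participant lacking either condition gets a missing (never
zero) score. Group tests are two-sided one-sample t tests with Bonferroni
correction p·m capped at 1; the family size m is a configuration value
because the original family definitions live in footnotes that are not fully
recoverable.

Carryover analysis relabels extinction trials by whether the target (after
TLL) or distractor (after DLL) occupies the previously learned frequent
location, optionally restricted to the first half of each participant's
trials in the subset, and then reuses the ordinary effect-score and paired
test machinery.

## Permutation split-half reliability

Each split partitions every participant's trials at random into two halves,
computes the effect score per half, Pearson-correlates the two half-score
vectors across participants, and applies the Spearman–Brown correction
2r/(1+r); 5,000 splits give a distribution whose mean is the reliability
estimate and whose empirical 2.5/97.5 percentiles classify the measure
(reliable iff the interval excludes zero).

Design choices:

- **Stratified splitting** (each condition halved separately) is the default:
  it is the only construction that guarantees both halves contain both
  conditions so every half-score is defined. Joint splitting of the pooled
  trials is available behind a flag for comparison; halves that lose a
  condition produce missing scores and that participant drops out of the
  split's correlation.
- **Odd cell counts**: the extra trial joins a uniformly chosen half,
  independently per split, so neither half is systematically longer.
- **No clamping** of the correction: negative half-correlations pass through
  2r/(1+r) unchanged (null measures legitimately produce negative corrected
  means); r_half = −1 is undefined and propagates as missing.
- Participants with fewer than two usable trials in a required condition are
  dropped from the analysis with a warning.

The engine is vectorized across splits (per participant-condition cell, one
uniform matrix → argsort → prefix-cumsum half means), which keeps 5,000
splits at realistic trial counts under a second per measure.

## Bayesian correlation inference

The Bayes factor uses the exact sampling density of the Pearson correlation
for bivariate-normal data, reduced to the sufficient statistics (r, n). The
density ratio against ρ = 0,

    (1 − ρ²)^((n−1)/2) (1 − ρr)^(3/2−n)
        · ₂F₁(½, ½; n − ½; (1+ρr)/2) / ₂F₁(½, ½; n − ½; ½),

is integrated against a stretched Beta(1/κ, 1/κ) prior on (−1, 1). κ = 1/3
(a Beta(3,3)-shaped prior, the "medium" default of the standard R
implementation of this test) is the package default; it reproduces the
published BF₁₀ values for this paradigm at two decimals when r is taken at
full precision from the published t statistics. Only the two-sided prior is
implemented. The integrand is evaluated in log space, its peak located on a
grid and factored out, and the two subintervals around the peak integrated
adaptively; non-convergence raises an error with diagnostics rather than
falling back silently. The result is stable to well beyond four significant
figures under doubling of a fixed-order quadrature (tested).

Evidence labels: the default band table follows the usage in the source
analyses — anecdotal (1–3), substantial (3–10), very strong (10–100),
decisive (>100), mirrored via 1/BF₁₀ for evidence toward the null. This
differs from the classic Jeffreys table (which splits 10–30 "strong" from
30–100 "very strong"); the classic table ships as an alternative constant
and the cut points are configurable.

Correlations between individual-difference measures are only run when both
measures' split-half classifications are reliable; an override flag
reproduces the replication-study protocol of testing anyway, and the gate's
outcome is recorded (`both_reliable` / `gate_overridden` / `not_run`).

## Monte Carlo sensitivity

Each iteration draws n participants' latent trait pairs from a bivariate
normal with correlation R0 and the stated between-SDs, simulates
n_trials_per_condition (default 105) noisy trials per condition per measure,
averages them into observed difference scores, computes the sample
correlation, and evaluates BF₁₀. The reported proportion of iterations with
BF₁₀ ≤ threshold estimates the probability of obtaining that degree of null
evidence despite a true correlation. Because the within-subject SDs behind
the published runs are not printed, published iteration counts (e.g. 1 in
1,000) are qualitative benchmarks, not pin-point reproducible; the package's
acceptance check instead verifies the near-zero rate at negligible trial
noise.

## Colorimetry

ΔE is the CIE 1976 Euclidean distance in L\*a\*b\*. The sRGB → XYZ → Lab
conversion uses the long-standing rounded reference constants (4-decimal sRGB
matrix, D65 white 95.047/100/108.883 for the 2° observer, 0.04045 companding
threshold, 0.008856/7.787 Lab knee). This specific constant set is the
pinned convention: it reproduces the published distractor-color distances
(82.6272 orange–grey, 82.6159 green–grey) at four decimals, whereas
higher-precision constant sets shift ΔE in the second decimal. A side effect
of the rounded matrix is that reference white sits ~0.01 off the exact
neutral axis.

## Problem sizes in the test suite

Calibration tests use 50 participants × 100 trials/condition × 500 splits
(reliability classification, 100 replicates), 93 participants × 105+
trials/condition (parameter recovery of the latent correlation structure,
100 replicates), and 1,000 iterations at n = 27 for sensitivity — sizes
chosen to match the studied designs while keeping each property's Monte
Carlo error far below its assertion margin. Parameter recovery checks that
observed correlations fall in Fisher-z 95% intervals around the
noise-attenuated model-implied values; the attenuation accounts for the
distractor-location frequency latent leaking into the DLL capture score with
weight ½ (present trials are half frequent-location), and for realized
post-filter trial counts.

## Known limitations

- Stationary effects mean no within-block learning or extinction dynamics;
  carryover analyses on simulated data exercise only the null path.
- Test–retest (across-session) reliability is out of scope.
- The Bonferroni family sizes of the original analyses are configuration,
  not reproduced constants.
- Whether the original split-half analysis stratified splits by condition is
  not documented; stratified is the default here, joint splitting a flag.
- Accuracy latents share the RT latents' correlation matrix but are drawn
  independently of the RT latents; cross-measure (RT↔accuracy) latent
  correlations are not modeled.
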