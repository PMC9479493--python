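# Methods

## Model and assumptions

The simulated outcome is a tract-averaged FA summary of the corticospinal
tract. Each subject's true FA is assumed to decline *linearly* over the
study window, with a subject-specific slope drawn from a single Gaussian
law; controls do not decline at all (slope exactly 0, with zero
between-subject slope variance). Every scan observes the current true
value plus independent, homoscedastic Gaussian measurement error with
standard deviation SEM, identical for patients and controls and constant
over time. A design consists of a baseline session and exactly one
follow-up session, each with `m` scans averaged into the session value;
the analysis statistic is the per-subject change score (follow-up session
mean − baseline session mean), compared between groups by a two-sided
independent-samples t-test.

These assumptions are strong in known ways: linearity is only plausible
over windows of a few months; measurement error in patients with advanced
disease is likely larger than in the healthy test-retest cohort that
calibrates the SEM; and a change-score t-test discards within-session
scan-level information that a mixed model could weight.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| patient group | 0.326 ± 0.018 | FA | cross-sectional CST FA, ALS cohort (n = 80) |
| control group | 0.339 ± 0.023 | FA | cross-sectional CST FA, healthy cohort (n = 50) |
| rate | 2.0 (0.5 / 3.5) | %/yr | annual FA decline of patients; slow / intermediate / fast progressor scenarios |
| CV | 67 | % | between-subject coefficient of variation of the decline rate |
| SEM | 0.00054 / 0.00134 | FA | per-scan error SD: low / high measurement uncertainty protocols |
| t | 30–180 (default 90) | days | baseline-to-follow-up interval; outside this range the code warns |
| m | 1–3 (default 1) | scans | scans per session, averaged |
| n | default 20 | subjects | per-group sample size |
| alpha | 0.05 | — | two-sided significance level |
| iterations | 2000 | — | Monte Carlo replications per power estimate |

Percentage anchoring: the annual decline percentage is converted to FA
units/year against the *patient group mean* (anchor 0.326), not each
subject's own baseline, because a single group-level Gaussian slope law is
only well-defined with a group-level anchor; the subject-anchored variant
is available (`anchoring="subject"`) and differs negligibly at these
parameter scales. Years are 365 days. The decline is encoded as a
negative slope; the power analysis is sign-symmetric.

The group baseline SD (0.018–0.023) is treated as the spread of *true*
baselines, with per-scan error added on top. Since the SEM (≤ 0.00134) is
an order of magnitude smaller than the group SD, the distinction between
"true" and "measured" baseline spread is conceptually real but numerically
negligible here.

## Reliability side (ICC and SEM)

Test-retest reliability is quantified by ICC(A,1): single rater, two-way
model, absolute agreement, computed from the two-way ANOVA mean squares,
with the standard F-approximation confidence interval. Absolute agreement
(rather than consistency) charges systematic occasion shifts against
reliability, which is the right convention when the "rater" is the
scanner. Qualitative bands use half-open intervals with boundaries
assigned upward (0.50 → moderate, 0.75 → good, 0.90 → excellent), since
the conventional printed ranges overlap at their endpoints. Because a
confidence interval can straddle a band boundary, the `icc` command
reports the band of the point estimate *and* of both CI endpoints rather
than guessing which one is meant.

The SEM formula's radical extent is ambiguous in its usual compact
printing; the default reading is

    SEM = sqrt( TSS/(k-1) * ICC * (1 - ICC) ),

chosen because it yields FA (not FA²) units; the literal product form is
available as `variant="product"`. Both readings give SEM = 0 at ICC = 0,
which is physically implausible (a useless measurement has *large* error);
the formula is meaningful only in the high-ICC regime where it is used.
Negative ICC estimates are reported unclamped and classified "poor"; only
the SEM factor truncates the ICC into [0, 1].

## Numerical and design choices

- **t-test flavor.** Pooled-variance Student's test by default; group
  sizes are equal by design, which makes the pooled test robust to the
  real variance difference between patients (slope variability) and
  controls (measurement error only). Welch is available (`test="welch"`).
- **Change scores, not slopes.** With exactly two sessions, per-subject
  least-squares slopes are an affine rescaling of the change score and
  yield the identical t-test.
- **Vectorized engine and common random numbers.** `estimate_power`
  simulates all iterations as arrays. Randomness is split into named
  substreams (one per random component and per scan index, derived from
  the master seed via `SeedSequence` spawn keys) with the subject axis
  leading. Consequently draws are shared across scenarios that differ
  only in n (prefix property), m (extra scans use extra streams), t or
  rate (slope/error streams unchanged), so power comparisons along those
  axes are not masked by Monte Carlo noise, and power is *exactly*
  invariant in m when SEM = 0. The baseline FA level cancels
  algebraically in the change score, so it is not drawn in this engine
  under group anchoring; `run_iteration` is the per-subject reference
  path and draws everything.
- **Sample-size search.** Power is evaluated at every n on a step-1 grid
  (common random numbers across n), the power-vs-n curve is smoothed by
  isotonic regression, and the smallest n whose smoothed power reaches
  the target is returned. At 2000 iterations the Monte Carlo SE near
  power 0.8 is ≈ 0.009, enough to cause non-monotone jitter that the
  smoothing removes; an unreachable target is an explicit "not reached"
  result, never a clamp.
- **Significance** is strict (`p < alpha`); immaterial for continuous
  p-values. Degenerate configurations (SEM = 0 with no decline) raise
  rather than returning a meaningless answer.
- FA values are not clipped to [0, 1]: excursions outside the physical
  range are impossible at these parameter scales and clipping would bias
  the Gaussian model.

## Independent checks

A closed-form oracle computes approximate power from the noncentral t
distribution (noncentrality `delta / sqrt((v_pat + v_ctl)/n)` with
`delta = |mu_beta| t/365`, `v_pat = sigma_beta² (t/365)² + 2 SEM²/m`,
`v_ctl = 2 SEM²/m`, df = 2n − 2). The test suite requires the Monte Carlo
estimate to track this oracle within 3 combined binomial standard errors
over a 24-scenario grid, and the sample-size search to land within ±2 of
the oracle's inversion. The ICC implementation is checked against a
brute-force loop-written ANOVA oracle to 1e-10 on random small matrices
and against `pingouin.intraclass_corr` (point estimate and CI).

## What the synthetic data do and do not show

The retest fixture generator and the cohort simulator reproduce exactly
the model above — Gaussian random effects, Gaussian homoscedastic noise,
complete designs, no dropout. Passing tests therefore demonstrate the
statistical machinery is correct *under the model*, not that real
longitudinal FA data satisfy it: real studies face nonlinearity,
patient-specific error inflation, missed visits and scanner drift, none
of which are simulated. Sample sizes from this tool are best read as
optimistic lower bounds for real studies.

## Problem sizes

Power estimates use 2000 iterations (the design default). The sample-size
searches scan n = 3…100 at 2000 iterations per n; the whole acceptance
recomputation runs in a few seconds on one core thanks to the vectorized
engine. Moment-matching tests use 1e5 draws.
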