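# dtipower

Monte Carlo power and sample-size planning for **longitudinal diffusion
tensor imaging (DTI) group studies in amyotrophic lateral sclerosis
(ALS)**.

Tract-averaged fractional anisotropy (FA) of the corticospinal tract
declines as ALS progresses, which makes it a candidate imaging biomarker —
but the annual decline (0.5–3.5 % of baseline FA) is small relative to
both between-subject variability and per-scan measurement error. This
package answers the design questions such a study faces: *how many
subjects per group, how long between baseline and follow-up, and how many
scans per session are needed to detect the decline with adequate
statistical power?*

## Model

Each subject *i*'s true FA follows a linear trajectory with Gaussian
random effects,

```
FA(t)_i   = FA0_i + beta_i * t
FAhat(t)_i = FA(t)_i + eps,            eps  ~ N(0, SEM)  per scan
FA0_i  ~ N(mu_g, sigma_g)              (group-specific baseline)
beta_i ~ N(mu_beta, sigma_beta)        (patients; controls: beta = 0)
mu_beta    = -(rate%/100) * FA_anchor  per year
sigma_beta = (CV%/100) * |mu_beta|
```

A study design observes each subject at baseline and at one follow-up `t`
days later, with `m` scans per session averaged into the session value.
The per-subject change score (follow-up mean − baseline mean) is compared
between `n` patients and `n` controls with a two-sided pooled-variance
t-test; **power is the fraction of significant iterations over 2000
Monte Carlo replications**. The per-scan noise SD (SEM) is derived from
test-retest reliability via the intraclass correlation,
ICC(A,1) — two-way model, single rater, absolute agreement — as
`SEM = sqrt(TSS/(k-1) * ICC * (1-ICC))`, with TSS the within-subject sum
of squares over `k` repeated measurements.

Packaged defaults encode the cohort estimates the simulations are built
around: patients FA 0.326 ± 0.018 (n = 80), controls 0.339 ± 0.023
(n = 50), per-scan SEM 0.00054 (low uncertainty, ICC 0.97) or 0.00134
(high uncertainty, ICC 0.91), decline CV 67 %, alpha 0.05.

## Worked example

Power for an intermediate decline (2.0 %/yr), low measurement
uncertainty, a 30-day follow-up, **two scans per session** and 20
subjects per group:

```
$ dtipower power --rate-percent 2.0 --sem 0.00054 --t-days 30 -m 2 -n 20 --seed 1
power=0.7915
n_significant=1583
iterations=2000
mc_standard_error=0.009083714823793183
```

1583 of 2000 simulated studies detect the group difference at
alpha = 0.05, i.e. power ≈ 0.79 ± 0.009 — at the 0.8 design threshold.
With a single scan per session the same design needs ≈ 35 subjects per
group; the second scan buys that back. The required sample size for a
target power comes from the `samplesize` search (common random numbers
across `n`, isotonic smoothing of the power curve):

```
$ dtipower samplesize --rate-percent 2.0 --sem 0.00134 --t-days 60 -m 2 --seed 1
n_min=29
```

The same machinery is available as a library
(`dtipower.estimate_power`, `dtipower.min_sample_size`,
`dtipower.power_grid`), and `dtipower icc` / `dtipower simulate-retest`
handle the reliability side (ICC with 95 % CI, SEM, qualitative band)
from test-retest CSV tables.

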