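"""Monte Carlo power estimation for two-group longitudinal FA comparisons.

One iteration simulates n patients (declining FA, subject-specific slopes)
and n controls (no decline), observes each subject at baseline and at one
follow-up session with m scans per session, forms per-subject change scores
and compares the groups with a two-sided independent-samples t-test.  Power
is the fraction of significant iterations.

Randomness is organized as named component streams derived from the
scenario seed (one stream per random component and per scan index, with the
subject axis leading), so that draws are *common random numbers* across
scenarios that differ only in n, m, t or the decline rate: power
comparisons along those axes are then not masked by Monte Carlo noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

from .exceptions import DegenerateDataError, InvalidInputError
from .trajectory import (
    DAYS_PER_YEAR,
    DecreaseModel,
    ErrorModel,
    GroupDistribution,
    draw_subject,
    observe_session,
    subject_change,
)

__all__ = [
    "Scenario",
    "PowerEstimate",
    "two_sample_t",
    "run_iteration",
    "estimate_power",
    "analytic_power_oracle",
    "simulate_change_scores",
]

#: Time-interval range (days) covered by the underlying simulation study.
STUDIED_T_RANGE = (30.0, 180.0)

# spawn-key component ids for the named random streams
_KEY_PAT_SLOPE = 0
_KEY_PAT_BASE = 1
_KEY_ERR = 2  # (_KEY_ERR, group, session, scan)
_GROUP_PAT, _GROUP_CTL = 0, 1
_SESSION_BASE, _SESSION_FU = 0, 1


@dataclass(frozen=True)
class Scenario:
    """Full parameterization of one simulated two-group longitudinal design."""

    patient_group: GroupDistribution
    control_group: GroupDistribution
    decrease: DecreaseModel
    error: ErrorModel
    t_days: float
    m: int
    n_per_group: int
    alpha: float = 0.05
    iterations: int = 2000
    seed: int = 0
    anchoring: str = "group"
    test: str = "student"

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise InvalidInputError(f"n_per_group must be >= 2, got {self.n_per_group}")
        if not (0.0 < self.alpha < 1.0):
            raise InvalidInputError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.iterations < 1:
            raise InvalidInputError(f"iterations must be >= 1, got {self.iterations}")
        if self.m < 1:
            raise InvalidInputError(f"m must be >= 1, got {self.m}")
        if self.t_days <= 0.0:
            raise InvalidInputError(f"t_days must be > 0, got {self.t_days}")
        if self.seed < 0:
            raise InvalidInputError(f"seed must be non-negative, got {self.seed}")
        if self.anchoring not in ("group", "subject"):
            raise InvalidInputError(f"anchoring must be 'group' or 'subject', got {self.anchoring!r}")
        if self.test not in ("student", "welch"):
            raise InvalidInputError(f"test must be 'student' or 'welch', got {self.test!r}")
        if not (STUDIED_T_RANGE[0] <= self.t_days <= STUDIED_T_RANGE[1]):
            warnings.warn(
                f"t_days={self.t_days} lies outside the studied 30-180 day range; "
                "results are extrapolations of the linear-decline model",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class PowerEstimate:
    """Monte Carlo power estimate with its binomial standard error."""

    power: float
    n_significant: int
    iterations: int
    mc_standard_error: float
    seed: int


def two_sample_t(
    changes_a: Sequence[float],
    changes_b: Sequence[float],
    welch: bool = False,
) -> float:
    """Two-sided p-value of the independent-samples t-test on change scores.

    Pooled-variance (Student) by default; ``welch=True`` switches to the
    Welch unequal-variance form.
    """
    a = np.asarray(changes_a, dtype=float)
    b = np.asarray(changes_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each group needs at least 2 change scores")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise DegenerateDataError(
            "both groups have zero variance in their change scores; "
            "the t statistic is undefined"
        )
    res = scipy.stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)


def _stream(seed: int, key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _scan_error_mean(
    scenario: Scenario, group: int, session: int, n: int
) -> np.ndarray | float:
    """Mean of the m per-scan errors, shape (n, iterations); 0.0 when SEM = 0.

    One stream per scan index, so results at m scans share the first m
    streams with results at m' > m scans (common random numbers in m); the
    subject axis leads so smaller n is a prefix of larger n.
    """
    sem = scenario.error.sem
    if sem == 0.0:
        return 0.0
    shape = (n, scenario.iterations)
    total = np.zeros(shape)
    for j in range(scenario.m):
        z = _stream(scenario.seed, (_KEY_ERR, group, session, j)).standard_normal(shape)
        total += z
    return sem * total / scenario.m


def simulate_change_scores(
    scenario: Scenario, n: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject change scores for all iterations at once.

    Returns (patients, controls), each of shape (n, iterations).  The true
    baseline level cancels exactly in the change score (follow-up session
    mean minus baseline session mean), so under group anchoring only slopes
    and scan errors are drawn; under subject anchoring the patient baselines
    are drawn because they set the per-subject decline.
    """
    if n is None:
        n = scenario.n_per_group
    it = scenario.iterations
    t_years = scenario.t_days / DAYS_PER_YEAR
    dec = scenario.decrease

    if dec.annual_rate_percent == 0.0:
        slopes = np.zeros((n, it))
    else:
        z = _stream(scenario.seed, (_KEY_PAT_SLOPE,)).standard_normal((n, it))
        if scenario.anchoring == "group":
            slopes = dec.mu_slope + dec.sigma_slope * z
        else:
            zb = _stream(scenario.seed, (_KEY_PAT_BASE,)).standard_normal((n, it))
            base = scenario.patient_group.mean_fa + scenario.patient_group.sd_fa * zb
            mu = -(dec.annual_rate_percent / 100.0) * base
            slopes = mu + (dec.cv_percent / 100.0) * np.abs(mu) * z

    pat = (
        slopes * t_years
        + _scan_error_mean(scenario, _GROUP_PAT, _SESSION_FU, n)
        - _scan_error_mean(scenario, _GROUP_PAT, _SESSION_BASE, n)
    )
    ctl = np.zeros((n, it)) + (
        _scan_error_mean(scenario, _GROUP_CTL, _SESSION_FU, n)
        - _scan_error_mean(scenario, _GROUP_CTL, _SESSION_BASE, n)
    )
    return pat, ctl


def _t_pvalues(a: np.ndarray, b: np.ndarray, welch: bool = False) -> np.ndarray:
    """Vectorized two-sided independent-t p-values, one per iteration column."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    if welch:
        se2a, se2b = va / na, vb / nb
        denom2 = se2a + se2b
        with np.errstate(divide="ignore", invalid="ignore"):
            df = denom2**2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
            tstat = (ma - mb) / np.sqrt(denom2)
    else:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return 2.0 * scipy.stats.t.sf(np.abs(tstat), df)


def run_iteration(scenario: Scenario, rng: np.random.Generator) -> float:
    """One Monte Carlo iteration, subject by subject; returns the p-value.

    Draws each subject's baseline and slope, observes the baseline and the
    follow-up session with m scans each, forms change scores and runs the
    group comparison.  This is the faithful per-subject path; power
    estimation uses the algebraically equivalent vectorized engine.
    """
    error = scenario.error
    no_decline = DecreaseModel(0.0, 0.0, scenario.decrease.anchor_fa)

    def _group_changes(group: GroupDistribution, decrease: DecreaseModel) -> list[float]:
        changes = []
        for _ in range(scenario.n_per_group):
            subj = draw_subject(group, decrease, rng, anchoring=scenario.anchoring)
            base = observe_session(subj, 0.0, scenario.m, error, rng)
            fu = observe_session(subj, scenario.t_days, scenario.m, error, rng)
            changes.append(subject_change(base, fu))
        return changes

    pat = _group_changes(scenario.patient_group, scenario.decrease)
    ctl = _group_changes(scenario.control_group, no_decline)
    return two_sample_t(pat, ctl, welch=scenario.test == "welch")


def estimate_power(scenario: Scenario) -> PowerEstimate:
    """Monte Carlo power: the fraction of significant iterations.

    Deterministic given ``scenario.seed``; an iteration counts as
    significant when its p-value is strictly below ``scenario.alpha``.
    """
    if scenario.error.sem == 0.0 and scenario.decrease.annual_rate_percent == 0.0:
        raise DegenerateDataError(
            "with SEM = 0 and no decline every change score is exactly 0; "
            "the group comparison is undefined"
        )
    pat, ctl = simulate_change_scores(scenario)
    p = _t_pvalues(pat, ctl, welch=scenario.test == "welch")
    n_sig = int(np.count_nonzero(p < scenario.alpha))
    power = n_sig / scenario.iterations
    return PowerEstimate(
        power=power,
        n_significant=n_sig,
        iterations=scenario.iterations,
        mc_standard_error=float(np.sqrt(power * (1.0 - power) / scenario.iterations)),
        seed=scenario.seed,
    )


def analytic_power_oracle(scenario: Scenario, n: int | None = None) -> float:
    """Closed-form approximate power of the two-sample t-test on change scores.

    The change score is Gaussian in both groups: mean difference
    delta = |mu_beta| * t/365, patient variance
    sigma_beta^2 (t/365)^2 + 2 SEM^2 / m and control variance 2 SEM^2 / m.
    Power follows from the noncentral t distribution with noncentrality
    delta / sqrt((v_pat + v_ctl)/n) and 2n - 2 degrees of freedom.  An
    independent check on the Monte Carlo engine, not a replacement for it
    (it assumes the pooled test's equal-variance form).
    """
    if n is None:
        n = scenario.n_per_group
    t_years = scenario.t_days / DAYS_PER_YEAR
    dec = scenario.decrease
    delta = abs(dec.mu_slope) * t_years
    v_pat = dec.sigma_slope**2 * t_years**2 + 2.0 * scenario.error.sem**2 / scenario.m
    v_ctl = 2.0 * scenario.error.sem**2 / scenario.m
    if delta == 0.0:
        return scenario.alpha
    if v_pat + v_ctl == 0.0:
        return 1.0
    df = 2 * n - 2
    nc = delta / np.sqrt((v_pat + v_ctl) / n)
    t_crit = scipy.stats.t.ppf(1.0 - scenario.alpha / 2.0, df)
    return float(
        scipy.stats.nct.sf(t_crit, df, nc) + scipy.stats.nct.cdf(-t_crit, df, nc)
    )
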