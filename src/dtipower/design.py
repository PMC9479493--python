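"""Study-design utilities: sample-size search, scan-repetition trade-offs
and scenario-grid sweeps.

The sample-size search evaluates power on a step-1 grid of n with common
random numbers (smaller cohorts are prefixes of larger ones, so the whole
curve shares one set of draws), smooths the curve with isotonic regression
to remove Monte Carlo jitter, and thresholds at the power target.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .exceptions import InvalidInputError, SampleSizeNotReachedError
from .power import (
    Scenario,
    _t_pvalues,
    estimate_power,
    simulate_change_scores,
)
from .trajectory import DecreaseModel, ErrorModel

__all__ = [
    "DesignQuery",
    "SampleSizeResult",
    "PowerGridRow",
    "GridSpec",
    "min_sample_size",
    "sample_size_reduction",
    "power_grid",
]


@dataclass(frozen=True)
class DesignQuery:
    """A sample-size question: scenario template plus target and search bounds.

    ``scenario_template.n_per_group`` is ignored; the search scans
    n = n_min .. n_max in steps of 1.
    """

    scenario_template: Scenario
    power_target: float = 0.8
    n_min: int = 3
    n_max: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.power_target < 1.0):
            raise InvalidInputError(f"power_target must be in (0, 1), got {self.power_target}")
        if not (2 <= self.n_min <= self.n_max):
            raise InvalidInputError(
                f"need 2 <= n_min <= n_max, got n_min={self.n_min}, n_max={self.n_max}"
            )


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a sample-size search.

    ``n`` is the smallest per-group size whose isotonically smoothed power
    reaches the target, or None if the target is not reached within the
    bounds (``reached`` False).  ``curve`` holds the raw and smoothed power
    at every scanned n.
    """

    n: int | None
    reached: bool
    power_target: float
    curve: pd.DataFrame


@dataclass(frozen=True)
class PowerGridRow:
    """One cell of a power grid sweep."""

    annual_rate_percent: float
    sem: float
    t_days: float
    m: int
    n_per_group: int
    power: float
    mc_standard_error: float
    seed: int


@dataclass(frozen=True)
class GridSpec:
    """Cartesian sweep specification; every cell reuses the same master seed
    so that slices of the grid are comparable under common random numbers."""

    scenario_template: Scenario
    rates: Sequence[float]
    sems: Sequence[float]
    t_days_values: Sequence[float]
    m_values: Sequence[int]
    n_values: Sequence[int]

    def __post_init__(self) -> None:
        for name, vals in (
            ("rates", self.rates),
            ("sems", self.sems),
            ("t_days_values", self.t_days_values),
            ("m_values", self.m_values),
            ("n_values", self.n_values),
        ):
            if len(list(vals)) == 0:
                raise InvalidInputError(f"grid dimension {name!r} is empty")


def power_curve(query: DesignQuery) -> pd.DataFrame:
    """Power at every n in [n_min, n_max] under common random numbers.

    Simulates the full cohort once at n_max and reuses prefixes for smaller
    n, then fits a monotone (isotonic) regression to the raw powers.
    Columns: n, power, power_smoothed, mc_standard_error.
    """
    template = replace(query.scenario_template, n_per_group=query.n_max)
    pat, ctl = simulate_change_scores(template)
    welch = template.test == "welch"
    ns = np.arange(query.n_min, query.n_max + 1)
    powers = np.empty(ns.size)
    for i, n in enumerate(ns):
        p = _t_pvalues(pat[:n], ctl[:n], welch=welch)
        powers[i] = np.count_nonzero(p < template.alpha) / template.iterations
    smoothed = IsotonicRegression(increasing=True).fit_transform(ns, powers)
    mc_se = np.sqrt(powers * (1.0 - powers) / template.iterations)
    return pd.DataFrame(
        {
            "n": ns,
            "power": powers,
            "power_smoothed": smoothed,
            "mc_standard_error": mc_se,
        }
    )


def min_sample_size(query: DesignQuery) -> SampleSizeResult:
    """Smallest per-group n whose smoothed power reaches the target.

    Returns an explicit not-reached result (``n=None``) when even n_max
    falls short; the caller decides whether that is an error.
    """
    curve = power_curve(query)
    hit = curve.loc[curve["power_smoothed"] >= query.power_target, "n"]
    if hit.empty:
        return SampleSizeResult(n=None, reached=False, power_target=query.power_target, curve=curve)
    return SampleSizeResult(
        n=int(hit.iloc[0]), reached=True, power_target=query.power_target, curve=curve
    )


def sample_size_reduction(query: DesignQuery, m_from: int, m_to: int) -> float:
    """Percent reduction in required sample size when changing scans/session.

    100 * (n_min(m_from) - n_min(m_to)) / n_min(m_from).  Positive when the
    extra scans shrink the required cohort.  Both searches share the query's
    seed, hence common random numbers.
    """
    if m_from == m_to:
        raise InvalidInputError("m_from and m_to must differ")
    results = {}
    for m in (m_from, m_to):
        q = replace(query, scenario_template=replace(query.scenario_template, m=m))
        res = min_sample_size(q)
        if not res.reached:
            raise SampleSizeNotReachedError(
                f"power target {query.power_target} not reached within "
                f"n <= {query.n_max} at m={m}; reduction is not computable"
            )
        results[m] = res.n
    return 100.0 * (results[m_from] - results[m_to]) / results[m_from]


def power_grid(spec: GridSpec) -> list[PowerGridRow]:
    """Estimate power on the full Cartesian grid, one row per cell.

    Iteration order (row order) is rates x sems x t_days x m x n.  Every
    cell runs with the template's master seed, so the output is
    deterministic and slices along any axis are CRN-comparable.
    """
    template = spec.scenario_template
    rows: list[PowerGridRow] = []
    for rate, sem, t_days, m, n in itertools.product(
        spec.rates, spec.sems, spec.t_days_values, spec.m_values, spec.n_values
    ):
        scenario = replace(
            template,
            decrease=DecreaseModel(rate, template.decrease.cv_percent, template.decrease.anchor_fa),
            error=ErrorModel(sem),
            t_days=t_days,
            m=m,
            n_per_group=n,
        )
        est = estimate_power(scenario)
        rows.append(
            PowerGridRow(
                annual_rate_percent=rate,
                sem=sem,
                t_days=t_days,
                m=m,
                n_per_group=n,
                power=est.power,
                mc_standard_error=est.mc_standard_error,
                seed=scenario.seed,
            )
        )
    return rows
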