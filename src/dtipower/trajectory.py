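"""Subject-level model of longitudinal FA with per-scan measurement noise.

A subject's true tract-averaged FA declines linearly,

    FA(t) = FA_0 + beta * t,

with a subject-specific slope beta (a Gaussian random effect) and a true
baseline FA_0 drawn from the group's cross-sectional distribution.  Every
scan observes the current true value plus independent Gaussian measurement
error with standard deviation SEM; a session of m scans is summarized by
its arithmetic mean, and the per-subject longitudinal change is the
follow-up session mean minus the baseline session mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "DAYS_PER_YEAR",
    "GroupDistribution",
    "DecreaseModel",
    "ErrorModel",
    "SubjectState",
    "SessionObservation",
    "draw_subject",
    "observe_session",
    "session_mean",
    "subject_change",
]

#: Calendar-year length used to convert annual decline rates to per-day slopes.
DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class GroupDistribution:
    """Cross-sectional FA distribution of one study group (mean, SD in FA units)."""

    mean_fa: float
    sd_fa: float

    def __post_init__(self) -> None:
        if not (0.0 < self.mean_fa < 1.0):
            raise InvalidInputError(f"mean_fa must be in (0, 1), got {self.mean_fa}")
        if self.sd_fa <= 0.0:
            raise InvalidInputError(f"sd_fa must be positive, got {self.sd_fa}")


@dataclass(frozen=True)
class DecreaseModel:
    """Annual FA decline of the patient group, as a percentage of ``anchor_fa``.

    ``annual_rate_percent`` is the group-mean decline in %/year (0 encodes
    no decline); ``cv_percent`` is the between-subject coefficient of
    variation of the decline rate.  The slope random effect is

        beta_i ~ N(mu_beta, sigma_beta),
        mu_beta    = -(annual_rate_percent / 100) * anchor_fa   [FA / year]
        sigma_beta = (cv_percent / 100) * |mu_beta|

    anchored at a group-level FA so that all subjects share one Gaussian
    slope law.  A rate of exactly 0 yields slope 0 with no variability.
    """

    annual_rate_percent: float
    cv_percent: float
    anchor_fa: float

    def __post_init__(self) -> None:
        if self.annual_rate_percent < 0.0:
            raise InvalidInputError(
                f"annual_rate_percent must be >= 0, got {self.annual_rate_percent}"
            )
        if self.cv_percent < 0.0:
            raise InvalidInputError(f"cv_percent must be >= 0, got {self.cv_percent}")
        if not (0.0 < self.anchor_fa < 1.0):
            raise InvalidInputError(f"anchor_fa must be in (0, 1), got {self.anchor_fa}")

    @property
    def mu_slope(self) -> float:
        """Group-mean slope in FA units per year (negative for decline)."""
        return -(self.annual_rate_percent / 100.0) * self.anchor_fa

    @property
    def sigma_slope(self) -> float:
        """Between-subject SD of the slope in FA units per year."""
        return (self.cv_percent / 100.0) * abs(self.mu_slope)


@dataclass(frozen=True)
class ErrorModel:
    """Per-scan measurement-error model: each scan adds N(0, sem) noise."""

    sem: float

    def __post_init__(self) -> None:
        if self.sem < 0.0:
            raise InvalidInputError(f"sem must be >= 0, got {self.sem}")


@dataclass(frozen=True)
class SubjectState:
    """Latent state of one synthetic subject: true baseline FA and slope (FA/yr)."""

    true_baseline_fa: float
    slope: float


@dataclass(frozen=True)
class SessionObservation:
    """One scanning session: days since baseline and the m measured FA values."""

    t_days: float
    scans: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.t_days < 0.0:
            raise InvalidInputError(f"t_days must be >= 0, got {self.t_days}")
        if len(self.scans) < 1:
            raise InvalidInputError("a session needs at least one scan")

    @property
    def m(self) -> int:
        return len(self.scans)


def draw_subject(
    group: GroupDistribution,
    decrease: DecreaseModel,
    rng: np.random.Generator,
    anchoring: str = "group",
) -> SubjectState:
    """Draw one subject's true baseline and slope.

    ``anchoring="group"`` (default) applies the percentage decline to the
    group-level anchor FA; ``anchoring="subject"`` re-anchors the decline at
    the subject's own drawn baseline, so faster-declining slopes attach to
    higher-FA subjects.
    """
    baseline = rng.normal(group.mean_fa, group.sd_fa)
    if decrease.annual_rate_percent == 0.0:
        slope = 0.0
    elif anchoring == "group":
        slope = rng.normal(decrease.mu_slope, decrease.sigma_slope)
    elif anchoring == "subject":
        mu = -(decrease.annual_rate_percent / 100.0) * baseline
        slope = rng.normal(mu, (decrease.cv_percent / 100.0) * abs(mu))
    else:
        raise InvalidInputError(f"anchoring must be 'group' or 'subject', got {anchoring!r}")
    return SubjectState(true_baseline_fa=float(baseline), slope=float(slope))


def observe_session(
    subject: SubjectState,
    t_days: float,
    m: int,
    error: ErrorModel,
    rng: np.random.Generator,
) -> SessionObservation:
    """Measure a subject m times at ``t_days`` after baseline.

    The true FA at the session is ``true_baseline_fa + slope * t_days/365``;
    each scan adds an independent N(0, sem) error.
    """
    if m < 1:
        raise InvalidInputError(f"m must be >= 1, got {m}")
    if t_days < 0.0:
        raise InvalidInputError(f"t_days must be >= 0, got {t_days}")
    true_value = subject.true_baseline_fa + subject.slope * t_days / DAYS_PER_YEAR
    scans = true_value + rng.normal(0.0, error.sem, size=m)
    return SessionObservation(t_days=float(t_days), scans=tuple(float(s) for s in scans))


def session_mean(obs: SessionObservation) -> float:
    """Arithmetic mean of the session's scans."""
    return float(np.mean(obs.scans))


def subject_change(baseline: SessionObservation, followup: SessionObservation) -> float:
    """Per-subject longitudinal FA change: follow-up mean minus baseline mean."""
    if baseline.t_days != 0.0:
        raise InvalidInputError(f"baseline session must be at t_days=0, got {baseline.t_days}")
    if followup.t_days <= baseline.t_days:
        raise InvalidInputError("follow-up session must be strictly after baseline")
    return session_mean(followup) - session_mean(baseline)
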