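"""Test-retest reliability of a scalar imaging metric.

Quantifies how reproducible a tract-averaged fractional-anisotropy (FA)
summary is when the same subject is scanned repeatedly on the same scanner.
The estimand is the single-rater, absolute-agreement intraclass correlation
from a two-way model — ICC(A,1) in the McGraw–Wong taxonomy — together with
its F-approximation confidence interval and the standard error of
measurement (SEM) that downstream simulations use as the per-scan noise
standard deviation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .exceptions import DegenerateDataError, InvalidInputError

__all__ = [
    "TestRetestMatrix",
    "IccResult",
    "ReliabilityBand",
    "compute_icc",
    "compute_sem",
    "classify_reliability",
    "generate_retest_fixture",
]


@dataclass(frozen=True)
class TestRetestMatrix:
    """Complete subjects x occasions grid of a scalar FA summary.

    Rows are subjects, columns are measurement occasions.  The design must
    be complete: at least two subjects, at least two occasions, every cell
    finite.  Missing cells are rejected rather than imputed.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise InvalidInputError(
                f"test-retest matrix must be 2-D (subjects x occasions), got ndim={arr.ndim}"
            )
        if arr.shape[0] < 2:
            raise InvalidInputError("need at least 2 subjects")
        if arr.shape[1] < 2:
            raise InvalidInputError("need at least 2 measurement occasions")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("all cells must be finite; missing values are not supported")
        object.__setattr__(self, "values", arr)

    @property
    def n_subj(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class IccResult:
    """ICC(A,1) point estimate with CI, ANOVA components and the derived SEM.

    Mean squares are in squared FA units; ``sem`` is in FA units.
    ``tss_within`` is the total within-subject sum of squares
    (sum over subjects of squared deviations from each subject's mean).
    """

    icc: float
    ci_low: float
    ci_high: float
    n_subj: int
    k: int
    ms_between_subjects: float
    ms_between_measurements: float
    ms_error: float
    tss_within: float
    sem: float
    confidence: float = field(default=0.95)


class ReliabilityBand(str, enum.Enum):
    """Qualitative reliability bands for an ICC point value.

    Half-open intervals, boundary assigned upward: poor [-inf, 0.50),
    moderate [0.50, 0.75), good [0.75, 0.90), excellent [0.90, 1].
    """

    POOR = "poor"
    MODERATE = "moderate"
    GOOD = "good"
    EXCELLENT = "excellent"


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float, float]:
    """Two-way (subject x occasion) ANOVA decomposition without replication.

    Returns (ms_rows, ms_cols, ms_error, tss_within).
    """
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    tss_within = max(ss_total - ss_rows, 0.0)
    return ms_rows, ms_cols, ms_err, tss_within


def compute_icc(
    matrix: TestRetestMatrix,
    confidence: float = 0.95,
    sem_variant: str = "sqrt",
) -> IccResult:
    """Single-rater absolute-agreement ICC from a two-way model, ICC(A,1).

    The point estimate is

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR, MSC, MSE the between-subject, between-occasion and residual
    mean squares.  The confidence interval uses the standard F-distribution
    approximation for this ICC form.  Absolute agreement charges any
    systematic shift between occasions (a scanner drift, say) against the
    reliability, unlike the consistency-type coefficient.

    Negative estimates are returned as-is (classified "poor"); the SEM
    stored on the result uses the ICC truncated into [0, 1].

    Raises
    ------
    DegenerateDataError
        If every cell is identical (no variance to apportion).
    """
    if not (0.0 < confidence < 1.0):
        raise InvalidInputError(f"confidence must be in (0, 1), got {confidence}")
    x = matrix.values
    n, k = x.shape
    if np.ptp(x) == 0.0:
        raise DegenerateDataError(
            "all cells identical: total variance is zero, so the ICC is undefined "
            "(no between-subject spread to compare the measurement error against)"
        )
    msr, msc, mse, tss_within = _anova_mean_squares(x)
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    alpha = 1.0 - confidence
    if tss_within == 0.0:
        # no within-subject variance at all: perfectly reliable, CI collapses
        ci_low = ci_high = 1.0
    else:
        a = n * (1.0 + (k - 1) * icc) - k * icc
        if mse > 0.0:
            # Satterthwaite df of the denominator mean square
            fc = msc / mse
            vn = (k - 1) * (n - 1) * (k * icc * fc + a) ** 2
            vd = (n - 1) * k**2 * icc**2 * fc**2 + a**2
            v = vn / vd
        else:
            # MSE -> 0 limit (fc -> inf): v -> k - 1
            v = k - 1
        f_u = scipy.stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_l = scipy.stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        ci_low = (
            n * (msr - f_u * mse)
            / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        ci_high = (
            n * (f_l * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
        )
    sem = compute_sem(tss_within, k, float(np.clip(icc, 0.0, 1.0)), variant=sem_variant)
    return IccResult(
        icc=float(icc),
        ci_low=float(min(ci_low, icc)),
        ci_high=float(max(ci_high, icc)),
        n_subj=n,
        k=k,
        ms_between_subjects=float(msr),
        ms_between_measurements=float(msc),
        ms_error=float(mse),
        tss_within=float(tss_within),
        sem=float(sem),
        confidence=confidence,
    )


def compute_sem(tss_within: float, k: int, icc: float, variant: str = "sqrt") -> float:
    """Standard error of measurement from the within-subject sum of squares.

    ``variant="sqrt"`` (default) reads the radical as covering the whole
    product, which keeps the result in FA units:

        SEM = sqrt( TSS/(k-1) * ICC * (1 - ICC) )

    ``variant="product"`` is the literal no-radical product
    ``TSS/(k-1) * ICC * (1-ICC)`` (squared-FA units), kept for comparison.
    Both vanish at ICC = 0 and ICC = 1.
    """
    if k < 2:
        raise InvalidInputError(f"k must be >= 2, got {k}")
    if tss_within < 0:
        raise InvalidInputError(f"tss_within must be non-negative, got {tss_within}")
    if not (0.0 <= icc <= 1.0):
        raise InvalidInputError(f"icc must lie in [0, 1] for the SEM formula, got {icc}")
    core = tss_within / (k - 1) * icc * (1.0 - icc)
    if variant == "sqrt":
        return float(np.sqrt(core))
    if variant == "product":
        return float(core)
    raise InvalidInputError(f"unknown SEM variant {variant!r}; use 'sqrt' or 'product'")


def classify_reliability(icc: float) -> ReliabilityBand:
    """Map an ICC point value to its conventional qualitative band."""
    if not np.isfinite(icc):
        raise InvalidInputError(f"icc must be finite, got {icc}")
    if icc < 0.50:
        return ReliabilityBand.POOR
    if icc < 0.75:
        return ReliabilityBand.MODERATE
    if icc < 0.90:
        return ReliabilityBand.GOOD
    return ReliabilityBand.EXCELLENT


def generate_retest_fixture(
    n_subj: int,
    k: int,
    between_sd: float,
    error_sd: float,
    grand_mean: float = 0.33,
    seed: int = 0,
) -> TestRetestMatrix:
    """Synthetic test-retest table with known variance components.

    Each subject's true value is drawn from N(grand_mean, between_sd); each
    cell adds independent N(0, error_sd) measurement noise, so the
    population ICC is between_sd^2 / (between_sd^2 + error_sd^2).  Used both
    as a test fixture and for ICC parameter-recovery studies.
    """
    if n_subj < 2 or k < 2:
        raise InvalidInputError(f"need n_subj >= 2 and k >= 2, got {n_subj} x {k}")
    if between_sd < 0 or error_sd < 0:
        raise InvalidInputError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    true = grand_mean + between_sd * rng.standard_normal(n_subj)
    values = true[:, None] + error_sd * rng.standard_normal((n_subj, k))
    return TestRetestMatrix(values)
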