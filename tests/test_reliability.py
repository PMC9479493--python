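"""Reliability module: ICC(A,1), its CI, the SEM and the fixture generator."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dtipower as dp
from dtipower.exceptions import DegenerateDataError, InvalidInputError


def icc_a1_oracle(x):
    """Brute-force two-way ANOVA ICC(A,1): mean squares by direct summation.

    Written independently of the implementation; plain Python loops only.
    """
    x = [[float(v) for v in row] for row in x]
    n = len(x)
    k = len(x[0])
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_total = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def _random_matrix(seed, n=None, k=None):
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(2, 7))
    k = k or int(rng.integers(2, 5))
    return 0.33 + 0.02 * rng.standard_normal(n)[:, None] + 0.006 * rng.standard_normal((n, k))


class TestComputeIcc:
    def test_perfect_agreement_gives_icc_one(self):
        m = dp.TestRetestMatrix([[0.30, 0.30], [0.32, 0.32], [0.34, 0.34], [0.36, 0.36]])
        res = dp.compute_icc(m)
        assert res.icc == pytest.approx(1.0)
        assert res.ci_low == res.ci_high == 1.0
        assert res.sem == 0.0

    def test_matches_hand_computed_anova(self):
        rows = [[0.30, 0.31], [0.32, 0.33], [0.34, 0.33], [0.36, 0.38]]
        res = dp.compute_icc(dp.TestRetestMatrix(rows))
        assert res.icc == pytest.approx(icc_a1_oracle(rows), abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_bruteforce_oracle_on_random_small_matrices(self, seed):
        x = _random_matrix(seed)
        res = dp.compute_icc(dp.TestRetestMatrix(x))
        assert res.icc == pytest.approx(icc_a1_oracle(x), abs=1e-10)
        assert res.ci_low <= res.icc <= res.ci_high

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), shift=st.floats(-0.5, 0.5))
    def test_invariant_under_common_constant_shift(self, seed, shift):
        x = _random_matrix(seed)
        a = dp.compute_icc(dp.TestRetestMatrix(x))
        b = dp.compute_icc(dp.TestRetestMatrix(x + shift))
        assert b.icc == pytest.approx(a.icc, abs=1e-9)

    def test_absolute_agreement_penalizes_systematic_occasion_shift(self):
        # occasion 2 = occasion 1 + c with c large vs between-subject spread:
        # the absolute-agreement ICC must fall below the consistency ICC
        base = np.array([0.30, 0.32, 0.34, 0.36])
        x = np.column_stack([base, base + 0.05])
        res = dp.compute_icc(dp.TestRetestMatrix(x))
        msr, msc, mse = res.ms_between_subjects, res.ms_between_measurements, res.ms_error
        icc_consistency = (msr - mse) / (msr + (res.k - 1) * mse)
        assert res.icc < icc_consistency

    def test_matches_pingouin_point_and_ci(self):
        pg = pytest.importorskip("pingouin")
        x = _random_matrix(11, n=8, k=3)
        res = dp.compute_icc(dp.TestRetestMatrix(x))
        n, k = x.shape
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(n), k),
                "occ": np.tile(np.arange(k), n),
                "y": x.ravel(),
            }
        )
        row = pg.intraclass_corr(df, "subj", "occ", "y").set_index("Type").loc["ICC(A,1)"]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-10)
        lo, hi = row["CI95"]
        assert res.ci_low == pytest.approx(lo, abs=5e-3)
        assert res.ci_high == pytest.approx(hi, abs=5e-3)

    def test_all_identical_cells_is_degenerate(self):
        with pytest.raises(DegenerateDataError, match="total variance"):
            dp.compute_icc(dp.TestRetestMatrix(np.full((4, 2), 0.3)))

    @pytest.mark.parametrize("shape", [(1, 3), (4, 1)])
    def test_too_few_subjects_or_occasions_rejected(self, shape):
        with pytest.raises(InvalidInputError):
            dp.TestRetestMatrix(np.zeros(shape))

    def test_nonfinite_cells_rejected(self):
        with pytest.raises(InvalidInputError):
            dp.TestRetestMatrix([[0.3, np.nan], [0.31, 0.32]])


class TestComputeSem:
    @pytest.mark.parametrize("icc", [0.0, 1.0])
    def test_vanishes_at_icc_extremes(self, icc):
        assert dp.compute_sem(0.01, 2, icc) == 0.0
        assert dp.compute_sem(0.01, 2, icc, variant="product") == 0.0

    def test_hand_arithmetic_example(self):
        # sqrt(0.001 / (2-1) * 0.9 * 0.1)
        expected = math.sqrt(0.001 * 0.9 * 0.1)
        assert dp.compute_sem(0.001, 2, 0.9) == pytest.approx(expected, rel=1e-12)
        assert dp.compute_sem(0.001, 2, 0.9, variant="product") == pytest.approx(
            0.001 * 0.9 * 0.1, rel=1e-12
        )

    def test_icc_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            dp.compute_sem(0.001, 2, 1.2)
        with pytest.raises(InvalidInputError):
            dp.compute_sem(0.001, 2, -0.1)


class TestClassifyReliability:
    @pytest.mark.parametrize(
        "icc,band",
        [
            (0.97, dp.ReliabilityBand.EXCELLENT),
            (0.91, dp.ReliabilityBand.EXCELLENT),
            (0.90, dp.ReliabilityBand.EXCELLENT),
            (0.75, dp.ReliabilityBand.GOOD),
            (0.50, dp.ReliabilityBand.MODERATE),
            (0.40, dp.ReliabilityBand.POOR),
            (-0.2, dp.ReliabilityBand.POOR),
        ],
    )
    def test_bands_with_upward_boundaries(self, icc, band):
        assert dp.classify_reliability(icc) is band


class TestGenerateRetestFixture:
    def test_shape_contract(self):
        m = dp.generate_retest_fixture(5, 3, 0.02, 0.005, seed=0)
        assert m.values.shape == (5, 3)

    def test_zero_error_gives_perfect_icc(self):
        m = dp.generate_retest_fixture(10, 2, 0.02, 0.0, seed=3)
        assert dp.compute_icc(m).icc == pytest.approx(1.0)

    def test_variance_component_identity_recovered(self):
        # population ICC = 0.018^2 / (0.018^2 + 0.006^2) = 0.9
        m = dp.generate_retest_fixture(200, 2, between_sd=0.018, error_sd=0.006, seed=42)
        res = dp.compute_icc(m)
        assert res.ci_low <= 0.9 <= res.ci_high

    def test_parameter_recovery_improves_with_sample_size(self):
        # mean estimated ICC over replicate fixtures approaches the
        # variance-component value as n_subj grows
        target = 0.018**2 / (0.018**2 + 0.006**2)
        est = [
            dp.compute_icc(
                dp.generate_retest_fixture(500, 2, 0.018, 0.006, seed=s)
            ).icc
            for s in range(20)
        ]
        assert np.mean(est) == pytest.approx(target, abs=0.01)

    def test_reproducible_and_validating(self):
        a = dp.generate_retest_fixture(6, 2, 0.02, 0.003, seed=9)
        b = dp.generate_retest_fixture(6, 2, 0.02, 0.003, seed=9)
        assert np.array_equal(a.values, b.values)
        with pytest.raises(InvalidInputError):
            dp.generate_retest_fixture(1, 2, 0.02, 0.003)
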