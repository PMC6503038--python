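"""Rate estimators, one-sample tests, ICC mean squares, annualized volume
change and BH-FDR — each checked against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from brainage import (
    DataValidationError,
    StatisticsError,
    annual_bag_change,
    annual_volume_change,
    fdr_adjust,
    group_rate_test,
    icc,
)

# ---------------------------------------------------------------- oracles ----


def bh_oracle(p):
    """Step-up BH from first principles: q_(i) = min_{j >= i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = min(1.0, running)
    return q


def icc_oracle(m, form):
    """Explicit two-way ANOVA sums computed with python loops."""
    n, k = m.shape
    grand = sum(sum(row) for row in m) / (n * k)
    row_means = [sum(row) / k for row in m]
    col_means = [sum(m[i][j] for i in range(n)) / n for j in range(k)]
    ssb = k * sum((rm - grand) ** 2 for rm in row_means)
    ssw = sum((m[i][j] - row_means[i]) ** 2 for i in range(n) for j in range(k))
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sse = ssw - ssc
    bms = ssb / (n - 1)
    wms = ssw / (n * (k - 1))
    ems = sse / ((n - 1) * (k - 1))
    if form == "oneway_single":
        return (bms - wms) / (bms + (k - 1) * wms)
    return (bms - ems) / (bms + (k - 1) * ems)


def t_oracle(x):
    """One-sample t-test against 0 via the t CDF (regularized beta)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    t = x.mean() / (x.std(ddof=1) / np.sqrt(n))
    df = n - 1
    p = special.betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, p


# ------------------------------------------------------------------ rates ----


class TestAnnualBagChange:
    def test_two_sessions(self):
        assert annual_bag_change([(30.0, 2.0), (35.0, 4.0)]) == pytest.approx(0.4)

    def test_longest_interval_ignores_middle_sessions(self):
        rate = annual_bag_change([(30.0, 1.0), (32.0, 1.5), (34.4, 2.8)])
        assert rate == pytest.approx(1.8 / 4.4)

    def test_constant_bag_is_zero(self):
        assert annual_bag_change([(30.0, 1.3), (33.0, 1.3)]) == 0.0

    def test_exact_slope_for_affine_trajectories(self):
        ages = [30.0, 31.5, 34.0, 36.2]
        bag = [0.7 * a - 10 for a in ages]
        assert annual_bag_change(list(zip(ages, bag))) == pytest.approx(0.7, abs=1e-12)
        assert annual_bag_change(list(zip(ages, bag)), "slope") == pytest.approx(0.7, abs=1e-12)

    def test_single_session_excluded(self):
        with pytest.raises(DataValidationError, match="2 sessions"):
            annual_bag_change([(30.0, 1.0)])


class TestGroupRateTest:
    def test_degenerate_zero_variance(self):
        with pytest.warns(UserWarning, match="machine epsilon"):
            mean, se, t, p = group_rate_test([1.0, 1.0, 1.0, 1.0])
        assert (mean, se) == (1.0, 0.0)
        assert p < np.finfo(float).eps

    def test_published_rate_statistics(self):
        # n = 68 rates with mean 0.41 and SE 0.15 -> t ~ 2.73, p ~ 0.008
        rng = np.random.default_rng(3)
        x = rng.normal(size=68)
        x = (x - x.mean()) / x.std(ddof=1)  # exact mean 0, sd 1
        rates = 0.41 + x * (0.15 * np.sqrt(68))
        mean, se, t, p = group_rate_test(rates)
        assert mean == pytest.approx(0.41, abs=1e-12)
        assert se == pytest.approx(0.15, abs=1e-12)
        assert t == pytest.approx(0.41 / 0.15, abs=1e-10)
        assert p == pytest.approx(0.0081, abs=0.0005)

    def test_symmetric_rates_null(self):
        mean, se, t, p = group_rate_test([-1.0, 1.0, -2.0, 2.0])
        assert (mean, t, p) == (0.0, 0.0, 1.0)

    def test_small_sample_rejected(self):
        with pytest.raises(StatisticsError, match="n >= 3"):
            group_rate_test([0.1, 0.2])

    def test_matches_t_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            x = rng.normal(rng.normal(), rng.uniform(0.5, 2), size=rng.integers(3, 40))
            _, _, t, p = group_rate_test(x)
            t0, p0 = t_oracle(x)
            assert abs(t - t0) < 1e-10 and abs(p - p0) < 1e-10


# -------------------------------------------------------------------- icc ----


class TestIcc:
    def test_identical_columns_is_one(self):
        m = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
        assert icc(m, "oneway_single") == pytest.approx(1.0)
        assert icc(m, "twoway_consistency_single") == pytest.approx(1.0)

    def test_hand_computed_3x2_matrix(self):
        # rows [[1,2],[3,4],[5,6]]: BMS = 8, WMS = 0.5, EMS = 0
        m = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert icc(m, "twoway_consistency_single") == pytest.approx(1.0)
        assert icc(m, "oneway_single") == pytest.approx((8 - 0.5) / (8 + 0.5))

    def test_constant_matrix_undefined(self):
        with pytest.raises(StatisticsError, match="constant"):
            icc(np.ones((4, 3)))

    def test_rows_with_missing_sessions_dropped(self):
        m = np.array([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0], [2.0, 2.5]])
        complete = m[[0, 2, 3]]
        assert icc(m) == icc(complete)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n, k = rng.integers(2, 8), rng.integers(2, 5)
            m = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * rng.uniform(0, 3)
            for form in ("oneway_single", "twoway_consistency_single"):
                assert icc(m, form) == pytest.approx(icc_oracle(m, form), abs=1e-10)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(9)
        for _ in range(20):
            n, k = 12, 3
            m = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 2
            long = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(n), k),
                    "rater": np.tile(np.arange(k), n),
                    "score": m.ravel(),
                }
            )
            table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
            icc1 = table.set_index("Type").loc["ICC(1,1)", "ICC"]
            icc3 = table.set_index("Type").loc["ICC(C,1)", "ICC"]
            assert icc(m, "oneway_single") == pytest.approx(icc1, abs=1e-8)
            assert icc(m, "twoway_consistency_single") == pytest.approx(icc3, abs=1e-8)

    def test_variance_ratio_recovery(self):
        # between/(between+within) = 0.94 at 500 subjects x 3 sessions
        from brainage.workflows import reliability_icc_sim

        value = reliability_icc_sim(0.94, 500, 3, seed=77)
        assert value == pytest.approx(0.94, abs=0.02)


# ----------------------------------------------------------------- volume ----


class TestAnnualVolumeChange:
    def test_published_arithmetic_anchor(self):
        assert annual_volume_change([(40.0, 1_000_000.0), (41.0, 997_000.0)]) == pytest.approx(-0.30)

    def test_constant_volume(self):
        assert annual_volume_change([(40.0, 1e6), (42.0, 1e6)]) == 0.0

    def test_two_year_interval_annualized(self):
        assert annual_volume_change([(40.0, 1e6), (42.0, 0.994e6)]) == pytest.approx(-0.30)

    def test_consecutive_estimator(self):
        sessions = [(40.0, 1e6), (41.0, 0.997e6), (42.0, 0.994009e6)]
        assert annual_volume_change(sessions, "consecutive") == pytest.approx(-0.30, abs=1e-6)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(DataValidationError, match="positive"):
            annual_volume_change([(40.0, 1e6), (41.0, -5.0)])


# -------------------------------------------------------------------- fdr ----


class TestFdrAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.5]), [0.5])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 30))
            q = fdr_adjust(p)
            assert np.all(q >= p) and np.all(q <= 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 25))
            np.testing.assert_allclose(fdr_adjust(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_p_named_by_index(self):
        with pytest.raises(DataValidationError, match="2"):
            fdr_adjust([0.1, 0.2, 1.5])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_bh_properties_hold_for_arbitrary_p_vectors(self, p):
        q = fdr_adjust(p)
        assert np.all(q >= np.asarray(p)) and np.all(q <= 1.0)
        # BH preserves the ordering of the p-values
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(
        st.tuples(st.floats(20.0, 60.0), st.floats(-30.0, 30.0)),
        min_size=2,
        max_size=6,
        unique_by=lambda s: round(s[0], 3),
    )
)
def test_rate_uses_only_first_and_last_sessions(sessions):
    ordered = sorted(sessions)
    expected = (ordered[-1][1] - ordered[0][1]) / (ordered[-1][0] - ordered[0][0])
    assert annual_bag_change(sessions) == pytest.approx(expected, rel=1e-9, abs=1e-9)


# --------------------------------------------------- estimator properties ----


def test_rate_estimator_is_unbiased_under_noise():
    # 200 synthetic cohorts of 68 patients: endpoint rates with scan noise
    # recover the injected 0.41 years/year with bias < 0.05
    rng = np.random.default_rng(15)
    means = []
    for _ in range(200):
        t = rng.uniform(3.5, 5.5, 68)
        bag0 = rng.normal(0, 6, 68)
        noise = rng.normal(0, 3, (68, 2))
        rates = ((bag0 + 0.41 * t + noise[:, 1]) - (bag0 + noise[:, 0])) / t
        means.append(rates.mean())
    assert abs(np.mean(means) - 0.41) < 0.05


def test_rate_test_type_one_error_calibrated():
    # statistical calibration of the one-sample test itself under iid nulls
    rng = np.random.default_rng(16)
    rejections = 0
    reps = 500
    for _ in range(reps):
        rates = rng.normal(0, 1, 30)
        _, _, _, p = group_rate_test(rates)
        rejections += p < 0.05
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(rejections / reps - 0.05) < 2 * se + 1e-9
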