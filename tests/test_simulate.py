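"""Generator contracts: closed-form moments, determinism, latent-truth
consistency and configuration validation."""

import io

import numpy as np
import pandas as pd
import pytest

from brainage import (
    REGION_LABELS,
    ConfigurationError,
    GeneratorConfig,
    generate_case_control,
    generate_longitudinal_patients,
    generate_scanner_pairs,
    generate_training_cohort,
)
from brainage.longitudinal import annual_volume_change


def zero_noise_config(**kw):
    n_feat = 7 * kw.get("features_per_region", 2)
    base = dict(
        n_train_hc=30,
        n_test_hc=10,
        n_ms=10,
        features_per_region=2,
        feature_intercepts=np.full(n_feat, 100.0),
        age_slopes=np.full(n_feat, -1.0),
        sex_effects=np.zeros(n_feat),
        feature_noise_sd=np.zeros(n_feat),
        subject_random_sd=0.0,
        scanner_offsets={"scanner_3T": 0.0, "scanner_1p5T": 0.0},
    )
    base.update(kw)
    return GeneratorConfig(**base)


def csv_bytes(table) -> bytes:
    buf = io.StringIO()
    table.data.to_csv(buf, index=False)
    return buf.getvalue().encode()


class TestTrainingCohort:
    def test_zero_noise_features_equal_100_minus_age(self):
        table = generate_training_cohort(zero_noise_config(), seed=3)
        expected = np.tile(100.0 - table.data["age"].to_numpy()[:, None], (1, 14))
        np.testing.assert_allclose(table.features.to_numpy(), expected, rtol=0, atol=1e-10)

    def test_feature_means_match_closed_form(self):
        cfg = GeneratorConfig(n_train_hc=500)
        table = generate_training_cohort(cfg, seed=11)
        lo, hi = cfg.train_age_range
        mean_age = (lo + hi) / 2.0
        var_age = (hi - lo) ** 2 / 12.0
        p = cfg.female_fraction
        for j in [0, 17, 40, 83]:  # spot-check features across regions/kinds
            a, b, c = cfg.feature_intercepts[j], cfg.age_slopes[j], cfg.sex_effects[j]
            sigma = cfg.feature_noise_sd[j]
            expected = a + b * mean_age + c * p
            var = (
                b**2 * (var_age + cfg.subject_random_sd**2)
                + c**2 * p * (1 - p)
                + sigma**2
            )
            se = np.sqrt(var / cfg.n_train_hc)
            observed = table.data[cfg.feature_names[j]].mean()
            assert abs(observed - expected) < 3 * se

    def test_moment_recovery_mean_and_sd(self):
        # empirical mean/SD over 1e4 draws match the closed forms within 4 SE
        cfg = GeneratorConfig(n_train_hc=10_000)
        table = generate_training_cohort(cfg, seed=29)
        lo, hi = cfg.train_age_range
        var_age = (hi - lo) ** 2 / 12.0
        p = cfg.female_fraction
        n = cfg.n_train_hc
        for j in [5, 50]:
            a, b, c = cfg.feature_intercepts[j], cfg.age_slopes[j], cfg.sex_effects[j]
            var = (
                b**2 * (var_age + cfg.subject_random_sd**2)
                + c**2 * p * (1 - p)
                + cfg.feature_noise_sd[j] ** 2
            )
            x = table.data[cfg.feature_names[j]]
            assert abs(x.mean() - (a + b * (lo + hi) / 2 + c * p)) < 4 * np.sqrt(var / n)
            # SE of the sample SD ~ sd / sqrt(2(n-1)) for roughly normal data
            assert abs(x.std() - np.sqrt(var)) < 4 * np.sqrt(var / (2 * (n - 1)))

    def test_same_seed_is_byte_identical(self):
        cfg = GeneratorConfig(n_train_hc=40)
        t1 = generate_training_cohort(cfg, seed=13)
        t2 = generate_training_cohort(cfg, seed=13)
        assert csv_bytes(t1) == csv_bytes(t2)

    def test_adding_subjects_preserves_existing_ones(self):
        small = generate_case_control(GeneratorConfig(n_test_hc=0, n_ms=10), seed=13)
        large = generate_case_control(GeneratorConfig(n_test_hc=0, n_ms=25), seed=13)
        pd.testing.assert_frame_equal(small.data, large.data.iloc[: len(small.data)])

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="n_train_hc"):
            generate_training_cohort(GeneratorConfig(n_train_hc=0), seed=1)
        with pytest.raises(ConfigurationError, match="female_fraction"):
            generate_training_cohort(GeneratorConfig(female_fraction=1.5), seed=1)
        with pytest.raises(ConfigurationError, match="gap_sd"):
            generate_case_control(GeneratorConfig(gap_sd=-1.0), seed=1)


class TestCaseControl:
    def test_null_config_gives_equal_group_means(self):
        cfg = GeneratorConfig(
            n_test_hc=400, n_ms=400, gap_offset_global=0.0, gap_sd=0.0,
            wmll_gap_correlation=0.0,
        )
        table = generate_case_control(cfg, seed=17)
        hc = table.data["group"] == "HC"
        for j in [0, 45]:
            name = cfg.feature_names[j]
            a = table.data.loc[hc, name]
            b = table.data.loc[~hc, name]
            se = np.sqrt(a.var() / len(a) + b.var() / len(b))
            assert abs(a.mean() - b.mean()) < 4 * se

    def test_mean_latent_gap_matches_configured_offset(self):
        cfg = GeneratorConfig(n_test_hc=0, n_ms=200)
        table = generate_case_control(cfg, seed=19)
        # feature-count-weighted global gap = mean over equal-sized regions
        gaps = table.latent["ba_global"] - table.data["age"] - table.latent["u"]
        se = cfg.gap_sd / np.sqrt(cfg.n_ms)
        assert abs(gaps.mean() - 4.4) < 3 * se
        # regional structure: subcortical/cerebellar offset exceeds the rest
        sc = table.latent["ba_subcortical_cerebellar"] - table.latent["ba_frontal"]
        np.testing.assert_allclose(sc, 6.2 - 4.1, atol=1e-10)

    def test_no_controls_is_allowed(self):
        table = generate_case_control(GeneratorConfig(n_test_hc=0, n_ms=5), seed=2)
        assert set(table.data["group"]) == {"MS"}
        assert len(table.data) == 5

    def test_wmll_correlates_with_latent_gap(self):
        cfg = GeneratorConfig(n_test_hc=0, n_ms=2000)
        table = generate_case_control(cfg, seed=23)
        r = np.corrcoef(table.latent["gap_dev"], table.data["wmll_mm3"])[0, 1]
        assert abs(r - 0.46) < 0.05


class TestLongitudinal:
    def test_zero_acceleration_keeps_latent_gap_constant(self):
        cfg = GeneratorConfig(n_ms=20, acceleration=0.0)
        table = generate_longitudinal_patients(cfg, seed=7)
        gap = table.latent["ba_global"] - table.data["age"]
        spread = gap.groupby(table.data["subject_id"]).agg(np.ptp)
        np.testing.assert_allclose(spread, 0.0, atol=1e-10)

    def test_latent_truth_recomputes_exactly(self):
        cfg = GeneratorConfig(n_ms=15)
        table = generate_longitudinal_patients(cfg, seed=31)
        lat, d = table.latent, table.data
        for region in REGION_LABELS:
            # same term grouping as the documented generative formula
            expected = (d["age"] + lat["u"]) + (
                (cfg.gap_offset_region[region] + lat["gap_dev"])
                + lat["delta"] * lat["t_since_first"]
            )
            np.testing.assert_array_equal(lat[f"ba_{region}"], expected)

    def test_zero_noise_atrophy_is_exactly_rate(self):
        cfg = zero_noise_config(n_ms=8, atrophy_rate=-0.30, atrophy_rate_sd=0.0)
        table = generate_longitudinal_patients(cfg, seed=41)
        for _, grp in table.data.groupby("subject_id"):
            grp = grp.sort_values("session")
            rate = annual_volume_change(zip(grp["age"], grp["brain_volume_mm3"]))
            assert rate == pytest.approx(-0.30, abs=1e-12)
            # volume one year after baseline is 0.997x baseline
            v0 = grp["brain_volume_mm3"].iloc[0]
            assert v0 * (1 - 0.003) == pytest.approx(v0 * (1 + (-0.30 / 100) * 1.0))

    def test_visit_structure(self):
        cfg = GeneratorConfig(n_ms=30, n_visits=3)
        table = generate_longitudinal_patients(cfg, seed=43)
        counts = table.data.groupby("subject_id").size()
        assert (counts == 3).all()
        assert set(table.data["scanner"]) == {cfg.longitudinal_scanner}
        total = table.data.groupby("subject_id")["age"].agg(np.ptp)
        assert abs(total.mean() - 4.4) < 3 * 0.4 / np.sqrt(30)

    def test_two_visits_required(self):
        with pytest.raises(ConfigurationError, match="n_visits"):
            generate_longitudinal_patients(GeneratorConfig(n_ms=5, n_visits=1), seed=1)


class TestScannerPairs:
    def test_paired_scans_differ_only_by_scanner_shift_and_noise(self):
        cfg = zero_noise_config(
            n_ms=6, scanner_offsets={"scanner_3T": 0.0, "scanner_1p5T": 3.0}
        )
        table = generate_scanner_pairs(cfg, seed=3, n_subjects=6)
        d = table.data.sort_values(["subject_id", "session"])
        f = cfg.feature_names[0]
        first = d.groupby("subject_id")[f].first()
        second = d.groupby("subject_id")[f].last()
        # slope -1 per year, +3-year shift on the second scanner; ages differ
        # by the tiny nominal session spacing
        np.testing.assert_allclose(second - first, -3.0 - 0.01, atol=1e-9)
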