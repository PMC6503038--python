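"""Configuration objects for the synthetic cohort generator, model training
and the end-to-end pipeline.

The generator emulates the structure of a morphometric (FreeSurfer-style)
case-control and longitudinal MS study: a large healthy training cohort
spanning adolescence to old age, a single-scanner cross-sectional
case-control set, and a second-scanner longitudinal patient set with up to
three visits over roughly 4.4 years.  Every scan carries named thickness /
area / volume features grouped into seven coarse regions, plus total brain
volume and white-matter lesion load (WMLL).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

#: The seven coarse region labels every feature is assigned to.
REGION_LABELS: tuple[str, ...] = (
    "occipital",
    "frontal",
    "temporal",
    "parietal",
    "cingulate",
    "insula",
    "subcortical_cerebellar",
)

#: Morphometric measure kinds, cycled over the features of each region.
MEASURE_KINDS: tuple[str, ...] = ("thickness", "area", "volume")

MEASURE_UNITS: dict[str, str] = {
    "thickness": "mm",
    "area": "mm2",
    "volume": "mm3",
}

# Disease gap offsets per region, expressed relative to the global offset so
# that a feature-count-weighted average over the 7 regions equals the global
# offset exactly.  Subcortical/cerebellar carries the largest excess
# (6.2 vs 4.4 years globally at the defaults).
_REGION_GAP_PROFILE: dict[str, float] = {
    "occipital": 4.1 / 4.4,
    "frontal": 4.1 / 4.4,
    "temporal": 4.1 / 4.4,
    "parietal": 4.1 / 4.4,
    "cingulate": 4.1 / 4.4,
    "insula": 4.1 / 4.4,
    "subcortical_cerebellar": 6.2 / 4.4,
}


@dataclass(frozen=True)
class ClinicalCovariateSpec:
    """A synthetic clinical covariate drawn per patient.

    The covariate is Gaussian with the given mean/SD and a configurable
    correlation with the patient's latent brain-age-gap deviation.
    """

    name: str
    mean: float
    sd: float
    gap_correlation: float = 0.0


def default_gap_offsets(gap_offset_global: float) -> dict[str, float]:
    """Per-region disease offsets scaled proportionally from the global one.

    At the default global offset of 4.4 years this yields 6.2 years for the
    subcortical/cerebellar region and 4.1 years elsewhere; a zero global
    offset yields zero everywhere (a true null).
    """
    return {r: gap_offset_global * p for r, p in _REGION_GAP_PROFILE.items()}


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort's latent brain-age
    process.

    Each feature ``f`` of a scan is generated as

        x_f = a_f + b_f * (BA_region + scanner_offset) + c_f * 1[sex=F] + eps_f

    where ``BA_region`` is the latent regional brain age of the scan,
    ``eps_f ~ N(0, sigma_f)``, and the scanner offset is an additive shift in
    years on the latent-age input.  Latent brain age is chronological age
    plus a subject-level deviation ``u_i ~ N(0, subject_random_sd)``; MS
    patients additionally carry a per-region disease offset plus a shared
    subject deviation ``gamma_i ~ N(0, gap_sd)``, and in the longitudinal
    cohort an acceleration of ``acceleration`` years per year of follow-up.
    """

    # cohort sizes
    n_train_hc: int = 800
    n_test_hc: int = 200
    n_ms: int = 200

    # demographics
    train_age_range: tuple[float, float] = (12.0, 95.0)
    test_age_range: tuple[float, float] = (21.0, 49.0)
    female_fraction: float = 0.71

    # longitudinal design
    n_visits: int = 3
    followup_years: float = 4.4
    followup_sd: float = 0.4

    # feature model
    features_per_region: int = 12
    feature_intercepts: np.ndarray | None = None  # a_f
    age_slopes: np.ndarray | None = None  # b_f, units per year
    sex_effects: np.ndarray | None = None  # c_f, additive for sex == F
    feature_noise_sd: np.ndarray | None = None  # sigma_f

    # latent brain-age process
    subject_random_sd: float = 3.5  # years
    gap_offset_global: float = 4.4  # years
    gap_offset_region: dict[str, float] | None = None
    gap_sd: float = 6.0  # years
    acceleration: float = 0.41  # years of brain age per year of follow-up

    # scanners
    test_scanner: str = "scanner_3T"
    longitudinal_scanner: str = "scanner_1p5T"
    scanner_offsets: dict[str, float] = field(
        default_factory=lambda: {"scanner_3T": 0.0, "scanner_1p5T": 3.0}
    )

    # global brain volume & lesion load
    brain_volume_mean: float = 1_150_000.0  # mm3
    brain_volume_sd: float = 100_000.0  # mm3 between subjects
    brain_volume_sex_effect: float = -120_000.0  # additive for sex == F
    atrophy_rate: float = -0.30  # % of baseline volume per year
    atrophy_rate_sd: float = 0.53  # between-patient SD of the annual rate
    wmll_baseline: float = 4000.0  # mm3
    wmll_sd: float = 1500.0  # mm3 between patients
    wmll_annual_change: float = 504.0  # mm3 per year
    wmll_annual_sd: float = 28.0  # between-patient SD of the annual change
    wmll_gap_correlation: float = 0.46

    # clinical covariates (patients only)
    clinical_covariate_specs: list[ClinicalCovariateSpec] = field(
        default_factory=lambda: [ClinicalCovariateSpec("disability_score", 2.0, 1.0, 0.0)]
    )

    # seed for the *feature population* (a_f, b_f, c_f, sigma_f defaults);
    # per-table sampling seeds are passed to the generator functions.
    seed: int = 20190430

    def __post_init__(self) -> None:
        if self.gap_offset_region is None:
            self.gap_offset_region = default_gap_offsets(self.gap_offset_global)
        if (
            self.feature_intercepts is None
            or self.age_slopes is None
            or self.sex_effects is None
            or self.feature_noise_sd is None
        ):
            params = default_feature_params(self.features_per_region, self.seed)
            if self.feature_intercepts is None:
                self.feature_intercepts = params["a"]
            if self.age_slopes is None:
                self.age_slopes = params["b"]
            if self.sex_effects is None:
                self.sex_effects = params["c"]
            if self.feature_noise_sd is None:
                self.feature_noise_sd = params["sigma"]
        for name in ("feature_intercepts", "age_slopes", "sex_effects", "feature_noise_sd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.n_features,):
                raise ConfigurationError(
                    f"{name}: expected {self.n_features} values "
                    f"({len(REGION_LABELS)} regions x {self.features_per_region} "
                    f"features), got shape {arr.shape}"
                )
            setattr(self, name, arr)

    # -- derived structure ---------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.features_per_region * len(REGION_LABELS)

    @property
    def feature_names(self) -> list[str]:
        return [
            f"{region}_{MEASURE_KINDS[i % len(MEASURE_KINDS)]}_{i:02d}"
            for region in REGION_LABELS
            for i in range(self.features_per_region)
        ]

    @property
    def feature_regions(self) -> list[str]:
        return [region for region in REGION_LABELS for _ in range(self.features_per_region)]

    @property
    def feature_measures(self) -> list[str]:
        return [
            MEASURE_KINDS[i % len(MEASURE_KINDS)]
            for _ in REGION_LABELS
            for i in range(self.features_per_region)
        ]

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first invalid field."""
        if self.n_train_hc < 1:
            raise ConfigurationError("n_train_hc must be >= 1")
        if self.n_test_hc < 0:
            raise ConfigurationError("n_test_hc must be >= 0")
        if self.n_ms < 0:
            raise ConfigurationError("n_ms must be >= 0")
        if self.features_per_region < 1:
            raise ConfigurationError("features_per_region must be >= 1")
        if self.n_visits < 1:
            raise ConfigurationError("n_visits must be >= 1")
        for name in ("train_age_range", "test_age_range"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigurationError(f"{name} must be an ordered finite (low, high) pair")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must lie in [0, 1]")
        for name in (
            "subject_random_sd",
            "gap_sd",
            "followup_sd",
            "atrophy_rate_sd",
            "wmll_baseline",
            "wmll_sd",
            "wmll_annual_sd",
            "brain_volume_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.brain_volume_mean <= 0:
            raise ConfigurationError("brain_volume_mean must be > 0")
        if not -1.0 <= self.wmll_gap_correlation <= 1.0:
            raise ConfigurationError("wmll_gap_correlation must lie in [-1, 1]")
        if set(self.gap_offset_region) != set(REGION_LABELS):
            raise ConfigurationError(
                "gap_offset_region must provide exactly the region labels "
                f"{sorted(REGION_LABELS)}"
            )
        if np.any(self.feature_noise_sd < 0):
            raise ConfigurationError("feature_noise_sd entries must be >= 0")
        for scanner in (self.test_scanner, self.longitudinal_scanner):
            if scanner not in self.scanner_offsets:
                raise ConfigurationError(f"scanner_offsets is missing an entry for '{scanner}'")
        for spec in self.clinical_covariate_specs:
            if spec.sd < 0:
                raise ConfigurationError(f"clinical covariate '{spec.name}': sd must be >= 0")
            if not -1.0 <= spec.gap_correlation <= 1.0:
                raise ConfigurationError(
                    f"clinical covariate '{spec.name}': gap_correlation must lie in [-1, 1]"
                )

    def replace(self, **changes) -> "GeneratorConfig":
        """Return a copy with the given fields replaced.

        Feature parameters are regenerated when ``features_per_region`` or
        ``seed`` change (unless explicitly supplied), and regional gap
        offsets track ``gap_offset_global`` the same way.
        """
        if "features_per_region" in changes or "seed" in changes:
            for name in ("feature_intercepts", "age_slopes", "sex_effects", "feature_noise_sd"):
                changes.setdefault(name, None)
        if "gap_offset_global" in changes:
            changes.setdefault("gap_offset_region", None)
        return dataclasses.replace(self, **changes)


def default_feature_params(features_per_region: int, seed: int) -> dict[str, np.ndarray]:
    """Draw the default per-feature population parameters.

    Each synthetic feature stands in for roughly a dozen real morphometric
    features (84 synthetic vs ~1,100 real), so per-feature noise is scaled
    down accordingly: the noise expressed in years of latent age
    (sigma_f / |b_f|) is drawn uniformly from 10-25 years, preserving the
    information content of the full real feature set.
    """
    n = features_per_region * len(REGION_LABELS)
    rng = np.random.default_rng([seed, 0xFEA7])
    kinds = [
        MEASURE_KINDS[i % len(MEASURE_KINDS)]
        for _ in REGION_LABELS
        for i in range(features_per_region)
    ]
    a = np.empty(n)
    b = np.empty(n)
    c = np.empty(n)
    noise_years = rng.uniform(10.0, 25.0, size=n)
    for i, kind in enumerate(kinds):
        if kind == "thickness":
            b[i] = -rng.uniform(0.002, 0.006)
            a[i] = rng.uniform(2.2, 3.0) + abs(b[i]) * 95.0
            c[i] = b[i] * rng.normal(0.0, 2.0)
        elif kind == "area":
            b[i] = -rng.uniform(0.5, 3.0)
            a[i] = rng.uniform(500.0, 3000.0) + abs(b[i]) * 95.0
            c[i] = b[i] * rng.normal(8.0, 3.0)
        else:  # volume
            b[i] = -rng.uniform(5.0, 30.0)
            a[i] = rng.uniform(3000.0, 15000.0) + abs(b[i]) * 95.0
            c[i] = b[i] * rng.normal(8.0, 3.0)
    sigma = np.abs(b) * noise_years
    return {"a": a, "b": b, "c": c, "sigma": sigma}


@dataclass
class CVSettings:
    """Cross-validation settings for brain-age model training.

    ``outer_folds`` controls the out-of-fold performance report (set to 0 to
    skip it); ``inner_folds`` and ``early_stopping_rounds`` control the
    nested loop that picks the number of boosting rounds.
    """

    outer_folds: int = 10
    inner_folds: int = 5
    early_stopping_rounds: int = 50
    max_rounds: int = 4000

    def validate(self) -> None:
        if self.outer_folds not in (0,) and self.outer_folds < 2:
            raise ConfigurationError("outer_folds must be 0 (skip report) or >= 2")
        if self.inner_folds < 2:
            raise ConfigurationError("inner_folds must be >= 2")
        if self.early_stopping_rounds < 1:
            raise ConfigurationError("early_stopping_rounds must be >= 1")
        if self.max_rounds < 1:
            raise ConfigurationError("max_rounds must be >= 1")
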