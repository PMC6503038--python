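"""Synthetic cohort generators with a known latent brain-age process.

Three cohorts mirror the structure of a typical case-control + longitudinal
morphometric MS study:

* a healthy training cohort spanning ages 12-95 for fitting brain-age models,
* a single-scanner cross-sectional case-control set (healthy controls and
  MS patients, one visit each),
* a second-scanner longitudinal patient set with ``n_visits`` visits over a
  follow-up of about 4.4 years, declining brain volume and growing lesion
  load.

All randomness is drawn from per-subject substreams keyed by a stable hash
of the subject id, so enlarging a cohort never perturbs previously generated
subjects, and the same (config, seed) pair always yields byte-identical
tables.  The per-subject draw order is part of that determinism contract.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .config import MEASURE_UNITS, REGION_LABELS, GeneratorConfig
from .exceptions import ConfigurationError
from .features import METADATA_COLUMNS, FeatureTable

__all__ = [
    "generate_training_cohort",
    "generate_case_control",
    "generate_longitudinal_patients",
    "generate_scanner_pairs",
]


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Deterministic per-subject random stream (stable under cohort growth)."""
    digest = hashlib.blake2b(subject_id.encode(), digest_size=8).digest()
    return np.random.default_rng([int(seed), int.from_bytes(digest, "little")])


def feature_metadata(config: GeneratorConfig) -> pd.DataFrame:
    meta = pd.DataFrame(
        {
            "feature": config.feature_names,
            "region": config.feature_regions,
            "measure": config.feature_measures,
        }
    )
    meta["unit"] = meta["measure"].map(MEASURE_UNITS)
    return meta.set_index("feature")


def _scan_features(
    config: GeneratorConfig,
    rng: np.random.Generator,
    ba_by_region: dict[str, float],
    scanner_offset: float,
    is_female: bool,
) -> np.ndarray:
    """x_f = a_f + b_f * (BA_region(f) + scanner_offset) + c_f * 1[F] + eps_f."""
    ba_f = np.array([ba_by_region[r] for r in config.feature_regions])
    x = (
        config.feature_intercepts
        + config.age_slopes * (ba_f + scanner_offset)
        + config.sex_effects * float(is_female)
    )
    return x + rng.normal(0.0, 1.0, size=config.n_features) * config.feature_noise_sd


def _correlated(rng: np.random.Generator, z_anchor: float, rho: float) -> float:
    """A standard-normal draw with correlation ``rho`` to ``z_anchor``."""
    return rho * z_anchor + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal()


def _baseline_volume(config: GeneratorConfig, rng: np.random.Generator, age: float, is_female: bool) -> float:
    # mild cross-sectional age decline; within-subject decline is governed by
    # atrophy_rate in the longitudinal generator
    vol = (
        config.brain_volume_mean
        + config.brain_volume_sex_effect * float(is_female)
        - 2000.0 * (age - 45.0)
        + rng.normal(0.0, config.brain_volume_sd)
    )
    return max(vol, 0.2 * config.brain_volume_mean)


def _make_table(config: GeneratorConfig, rows: list[dict], latent_rows: list[dict]) -> FeatureTable:
    clinical = [s.name for s in config.clinical_covariate_specs]
    columns = list(METADATA_COLUMNS) + clinical + config.feature_names
    data = pd.DataFrame(rows, columns=columns)
    latent_cols = (
        ["subject_id", "session", "u", "gap_dev", "delta", "t_since_first", "atrophy_rate", "ba_global"]
        + [f"ba_{r}" for r in REGION_LABELS]
    )
    latent = pd.DataFrame(latent_rows, columns=latent_cols)
    return FeatureTable(data=data, feature_meta=feature_metadata(config), latent=latent)


def _regional_ba(
    config: GeneratorConfig, age: float, u: float, gap_dev: float, is_ms: bool, delta_t: float, delta: float
) -> dict[str, float]:
    ba = {}
    for r in REGION_LABELS:
        disease = (config.gap_offset_region[r] + gap_dev + delta * delta_t) if is_ms else 0.0
        ba[r] = age + u + disease
    return ba


def _emit_scan(
    config: GeneratorConfig,
    rng: np.random.Generator,
    rows: list[dict],
    latent_rows: list[dict],
    *,
    subject_id: str,
    session: int,
    age: float,
    sex: str,
    scanner: str,
    group: str,
    u: float,
    gap_dev: float,
    delta: float,
    t: float,
    brain_volume: float,
    wmll: float,
    clinical: dict[str, float],
    atrophy_rate: float,
) -> None:
    is_ms = group == "MS"
    ba = _regional_ba(config, age, u, gap_dev if is_ms else 0.0, is_ms, t, delta)
    offset = config.scanner_offsets.get(scanner, 0.0)
    x = _scan_features(config, rng, ba, offset, sex == "F")
    row = {
        "subject_id": subject_id,
        "session": session,
        "age": age,
        "sex": sex,
        "scanner": scanner,
        "group": group,
        "brain_volume_mm3": brain_volume,
        "wmll_mm3": wmll,
    }
    row.update(clinical)
    row.update(dict(zip(config.feature_names, x)))
    rows.append(row)
    lat = {
        "subject_id": subject_id,
        "session": session,
        "u": u,
        "gap_dev": gap_dev if is_ms else 0.0,
        "delta": delta if is_ms else 0.0,
        "t_since_first": t,
        "atrophy_rate": atrophy_rate,
        "ba_global": float(np.mean(list(ba.values()))),
    }
    lat.update({f"ba_{r}": ba[r] for r in REGION_LABELS})
    latent_rows.append(lat)


def generate_training_cohort(config: GeneratorConfig, seed: int) -> FeatureTable:
    """Single-visit healthy cohort spanning ``train_age_range`` for model
    training.

    Latent brain age is ``age + u`` with ``u ~ N(0, subject_random_sd)``;
    features follow the linear-Gaussian model of :class:`GeneratorConfig`.
    """
    config.validate()
    rows: list[dict] = []
    latent: list[dict] = []
    clinical_nan = {s.name: np.nan for s in config.clinical_covariate_specs}
    for i in range(config.n_train_hc):
        sid = f"train_{i:05d}"
        rng = _subject_rng(seed, sid)
        age = rng.uniform(*config.train_age_range)
        sex = "F" if rng.random() < config.female_fraction else "M"
        u = rng.normal(0.0, config.subject_random_sd)
        vol = _baseline_volume(config, rng, age, sex == "F")
        _emit_scan(
            config, rng, rows, latent,
            subject_id=sid, session=1, age=age, sex=sex,
            scanner="scanner_train", group="HC",
            u=u, gap_dev=0.0, delta=0.0, t=0.0,
            brain_volume=vol, wmll=0.0, clinical=clinical_nan,
            atrophy_rate=0.0,
        )
    return _make_table(config, rows, latent)


def _patient_draws(config: GeneratorConfig, rng: np.random.Generator) -> dict:
    """Shared per-patient latent draws, in fixed order."""
    age = rng.uniform(*config.test_age_range)
    sex = "F" if rng.random() < config.female_fraction else "M"
    u = rng.normal(0.0, config.subject_random_sd)
    z_gap = rng.normal()
    gap_dev = config.gap_sd * z_gap
    z_wmll = _correlated(rng, z_gap, config.wmll_gap_correlation)
    wmll = max(0.0, config.wmll_baseline + config.wmll_sd * z_wmll)
    clinical = {
        s.name: s.mean + s.sd * _correlated(rng, z_gap, s.gap_correlation)
        for s in config.clinical_covariate_specs
    }
    return {"age": age, "sex": sex, "u": u, "gap_dev": gap_dev, "wmll": wmll, "clinical": clinical}


def generate_case_control(config: GeneratorConfig, seed: int) -> FeatureTable:
    """Cross-sectional HC + MS cohort, one visit each, on ``test_scanner``.

    MS patients carry per-region disease offsets plus a shared subject
    deviation ``gamma_i ~ N(0, gap_sd)``; lesion load is drawn with the
    configured correlation to ``gamma_i``.
    """
    config.validate()
    rows: list[dict] = []
    latent: list[dict] = []
    clinical_nan = {s.name: np.nan for s in config.clinical_covariate_specs}
    for i in range(config.n_test_hc):
        sid = f"hc_{i:05d}"
        rng = _subject_rng(seed, sid)
        age = rng.uniform(*config.test_age_range)
        sex = "F" if rng.random() < config.female_fraction else "M"
        u = rng.normal(0.0, config.subject_random_sd)
        vol = _baseline_volume(config, rng, age, sex == "F")
        _emit_scan(
            config, rng, rows, latent,
            subject_id=sid, session=1, age=age, sex=sex,
            scanner=config.test_scanner, group="HC",
            u=u, gap_dev=0.0, delta=0.0, t=0.0,
            brain_volume=vol, wmll=0.0, clinical=clinical_nan,
            atrophy_rate=0.0,
        )
    for i in range(config.n_ms):
        sid = f"ms_{i:05d}"
        rng = _subject_rng(seed, sid)
        d = _patient_draws(config, rng)
        vol = _baseline_volume(config, rng, d["age"], d["sex"] == "F")
        _emit_scan(
            config, rng, rows, latent,
            subject_id=sid, session=1, age=d["age"], sex=d["sex"],
            scanner=config.test_scanner, group="MS",
            u=d["u"], gap_dev=d["gap_dev"], delta=0.0, t=0.0,
            brain_volume=vol, wmll=d["wmll"], clinical=d["clinical"],
            atrophy_rate=0.0,
        )
    return _make_table(config, rows, latent)


def generate_longitudinal_patients(config: GeneratorConfig, seed: int) -> FeatureTable:
    """Longitudinal MS cohort: ``n_ms`` patients x ``n_visits`` visits on
    ``longitudinal_scanner``.

    Latent brain age at visit j is ``age_ij + u_i + offset_r + gamma_i +
    acceleration * t_ij`` (t in years since the first visit). Brain volume
    declines linearly at a per-patient annual rate drawn from
    ``N(atrophy_rate, atrophy_rate_sd)`` percent of baseline per year, and
    lesion load grows at a per-patient rate from
    ``N(wmll_annual_change, wmll_annual_sd)``.
    """
    config.validate()
    if config.n_visits < 2:
        raise ConfigurationError("n_visits must be >= 2 for a longitudinal cohort")
    rows: list[dict] = []
    latent: list[dict] = []
    for i in range(config.n_ms):
        sid = f"lms_{i:05d}"
        rng = _subject_rng(seed, sid)
        d = _patient_draws(config, rng)
        total = max(0.5, rng.normal(config.followup_years, config.followup_sd))
        if config.n_visits == 2:
            times = np.array([0.0, total])
        else:
            inner = np.sort(rng.uniform(0.15, 0.85, size=config.n_visits - 2)) * total
            times = np.concatenate([[0.0], inner, [total]])
        atrophy = rng.normal(config.atrophy_rate, config.atrophy_rate_sd)
        wmll_rate = rng.normal(config.wmll_annual_change, config.wmll_annual_sd)
        vol0 = _baseline_volume(config, rng, d["age"], d["sex"] == "F")
        for j, t in enumerate(times, start=1):
            _emit_scan(
                config, rng, rows, latent,
                subject_id=sid, session=j, age=d["age"] + t, sex=d["sex"],
                scanner=config.longitudinal_scanner, group="MS",
                u=d["u"], gap_dev=d["gap_dev"], delta=config.acceleration, t=float(t),
                brain_volume=vol0 * (1.0 + atrophy / 100.0 * t),
                wmll=max(0.0, d["wmll"] + wmll_rate * t),
                clinical=d["clinical"],
                atrophy_rate=atrophy,
            )
    return _make_table(config, rows, latent)


def generate_scanner_pairs(config: GeneratorConfig, seed: int, n_subjects: int = 58) -> FeatureTable:
    """Patients scanned back-to-back on both scanners (sessions 1 and 2).

    The two scans share every latent quantity; only the scanner's additive
    shift on the latent-age input (and fresh feature noise) differs, so the
    true scanner effect on brain-age estimates is known from the config.
    """
    config.validate()
    rows: list[dict] = []
    latent: list[dict] = []
    eps_age = 0.01  # session 2 nominally later so session order matches age order
    for i in range(n_subjects):
        sid = f"pair_{i:05d}"
        rng = _subject_rng(seed, sid)
        d = _patient_draws(config, rng)
        vol = _baseline_volume(config, rng, d["age"], d["sex"] == "F")
        for j, scanner in enumerate((config.test_scanner, config.longitudinal_scanner), start=1):
            _emit_scan(
                config, rng, rows, latent,
                subject_id=sid, session=j, age=d["age"] + (j - 1) * eps_age, sex=d["sex"],
                scanner=scanner, group="MS",
                u=d["u"], gap_dev=d["gap_dev"], delta=0.0, t=0.0,
                brain_volume=vol, wmll=d["wmll"], clinical=d["clinical"],
                atrophy_rate=0.0,
            )
    return _make_table(config, rows, latent)
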