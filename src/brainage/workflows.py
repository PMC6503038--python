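"""High-level study workflows: train-once / simulate-many recovery runs.

These helpers chain the generator, the brain-age models and the BAG
statistics the way the full study design does, and are shared by the
pipeline driver, the acceptance script and the recovery tests:

* ``case_control_replicate`` — simulate an HC/MS case-control set, predict,
  residualize on HC and compute the covariate-adjusted group difference and
  Cohen's D, globally and per regional model;
* ``longitudinal_rate_replicate`` — simulate a longitudinal patient cohort,
  pool it with an HC reference from the other scanner, run the full
  residualize + scanner-adjust chain and return the group mean annual BAG
  rate;
* ``reliability_icc_sim`` — a pure test-retest variance-components
  simulation for ICC recovery;
* ``null_rejection_rates`` — type-I error calibration of the rate and
  case-control tests under a generator with every effect zeroed.
"""

from __future__ import annotations

import warnings

import numpy as np

from .associations import case_control_compare, cohens_d
from .bag import adjust_scanner, build_bag_table
from .config import CVSettings, GeneratorConfig
from .features import FeatureTable
from .longitudinal import group_rate_test, icc, subject_rates
from .model import BrainAgeModel, predict_brain_age, train_brain_age
from .simulate import generate_case_control, generate_longitudinal_patients, generate_training_cohort


def derive_seed(master: int, *tags: int | str) -> int:
    """A stable sub-seed (< 2^31) derived from a master seed and tags."""
    entropy = [int(master) & 0x7FFFFFFF]
    for t in tags:
        entropy.append(sum(ord(c) for c in t) if isinstance(t, str) else int(t))
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31 - 1))


def train_study_models(
    config: GeneratorConfig,
    seed: int,
    regions: tuple[str, ...] = ("global", "subcortical_cerebellar"),
    cv: CVSettings | None = None,
    params: dict | None = None,
    training: FeatureTable | None = None,
) -> dict[str, BrainAgeModel]:
    """Generate the healthy training cohort (unless given) and fit one
    brain-age model per requested region."""
    if training is None:
        training = generate_training_cohort(config, derive_seed(seed, "train-cohort"))
    cv = cv or CVSettings(outer_folds=0)
    return {
        region: train_brain_age(training, region, cv=cv, seed=derive_seed(seed, "fit", region), params=params)
        for region in regions
    }


def case_control_replicate(
    models: dict[str, BrainAgeModel],
    config: GeneratorConfig,
    seed: int,
) -> dict[str, dict[str, float]]:
    """One simulated case-control analysis per regional model.

    Returns per region: covariate-adjusted BAG difference, Cohen's D on
    residualized BAG, and the group-coefficient p-value.
    """
    table = generate_case_control(config, seed)
    out: dict[str, dict[str, float]] = {}
    for region, model in models.items():
        pred = predict_brain_age(model, table)
        bt = build_bag_table(table, pred, region=region)
        bt = adjust_scanner(bt, config.test_scanner)
        cmp = case_control_compare(bt, region=region)
        out[region] = {
            "adjusted_difference": cmp.adjusted_difference,
            "cohens_d": cmp.cohens_d,
            "p": cmp.p,
        }
    return out


def longitudinal_rate_replicate(
    model: BrainAgeModel,
    config: GeneratorConfig,
    seed: int,
    n_patients: int = 68,
    reference: FeatureTable | None = None,
) -> dict[str, float]:
    """One simulated longitudinal analysis with the global model.

    The patient cohort (second scanner) is pooled with a cross-sectional HC
    reference (first scanner); BAG is residualized on the HC rows, scanner
    adjusted, and summarized as the group mean annual rate of change.
    """
    long_cfg = config.replace(n_ms=n_patients)
    patients = generate_longitudinal_patients(long_cfg, seed)
    if reference is None:
        reference = generate_case_control(config.replace(n_ms=0), derive_seed(seed, "hc-ref"))
    combined = reference.concat(patients)
    pred = predict_brain_age(model, combined)
    bt = build_bag_table(combined, pred, region=model.region)
    with warnings.catch_warnings():
        # no dual-scanned subjects here: the scanner coefficient is
        # confounded with the group offset, which annual rates are
        # invariant to (additive per-scanner shifts cancel within subject)
        warnings.simplefilter("ignore", UserWarning)
        bt = adjust_scanner(bt, config.test_scanner)
    rates = subject_rates(bt)
    mean, se, t, p = group_rate_test(rates["rate"])
    return {"mean_rate": mean, "se": se, "t": t, "p": p, "n": float(len(rates))}


def reliability_icc_sim(
    reliability: float,
    n_subjects: int,
    n_sessions: int,
    seed: int,
    form: str = "twoway_consistency_single",
    total_sd: float = 6.0,
) -> float:
    """Test-retest simulation: y_ij = u_i + e_ij with the between/total
    variance ratio set to ``reliability``; returns the estimated ICC."""
    rng = np.random.default_rng(seed)
    sigma_b = total_sd * np.sqrt(reliability)
    sigma_e = total_sd * np.sqrt(1.0 - reliability)
    u = rng.normal(0.0, sigma_b, size=n_subjects)
    y = u[:, None] + rng.normal(0.0, sigma_e, size=(n_subjects, n_sessions))
    return icc(y, form)


def null_config(config: GeneratorConfig) -> GeneratorConfig:
    """The generator's null: no disease offset, no acceleration, no
    lesion-gap coupling."""
    return config.replace(gap_offset_global=0.0, acceleration=0.0, wmll_gap_correlation=0.0)


def null_rejection_rates(
    model: BrainAgeModel,
    config: GeneratorConfig,
    seed: int,
    n_reps: int = 500,
    alpha: float = 0.05,
    n_cc: tuple[int, int] = (30, 30),
    n_long: int = 20,
    n_visits: int = 2,
) -> dict[str, float]:
    """Empirical type-I error of the case-control and rate tests under the
    generator null, at reduced cohort sizes."""
    base = null_config(config)
    cc_cfg = base.replace(n_test_hc=n_cc[0], n_ms=n_cc[1])
    long_cfg = base.replace(n_ms=n_long, n_visits=n_visits)
    # one fixed HC reference for the rate pipeline: fitting the bias model on
    # the small patient cohort itself would correlate the residuals and
    # distort the test's size
    reference = generate_case_control(base.replace(n_ms=0), derive_seed(seed, "null-ref"))
    rej_cc = 0
    rej_rate = 0
    for rep in range(n_reps):
        table = generate_case_control(cc_cfg, derive_seed(seed, "null-cc", rep))
        pred = predict_brain_age(model, table)
        bt = build_bag_table(table, pred)
        if case_control_compare(bt).p < alpha:
            rej_cc += 1

        patients = generate_longitudinal_patients(long_cfg, derive_seed(seed, "null-long", rep))
        combined = reference.concat(patients)
        pred = predict_brain_age(model, combined)
        bt = build_bag_table(combined, pred)
        rates = subject_rates(bt)
        _, _, _, p = group_rate_test(rates["rate"])
        if p < alpha:
            rej_rate += 1
    return {"case_control": rej_cc / n_reps, "rate": rej_rate / n_reps}
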