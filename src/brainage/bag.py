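"""Brain age gap (BAG) computation, age-bias residualization, and scanner
adjustment.

BAG is predicted minus chronological age (positive = older-appearing brain).
Because regression-based age prediction is biased along the age axis, BAG is
residualized against age, age^2 and sex with coefficients fitted on a
reference sample (healthy controls by default) and applied to every row, so
disease effects are not absorbed into the bias model.  When scans from more
than one scanner are pooled, each non-reference scanner's additive effect on
residualized BAG is estimated from a linear mixed-effects model (random
intercept per subject, age/age^2/sex as covariates) and subtracted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DataValidationError, StatisticsError
from .features import FeatureTable

logger = logging.getLogger(__name__)

#: Columns carried from a feature table into a BagTable when present.
_CARRY_COLUMNS = ("brain_volume_mm3", "wmll_mm3")


def compute_bag(predicted_age, age):
    """Raw brain age gap: predicted_age - age, in years.

    Accepts scalars or aligned arrays; positive values indicate an
    older-appearing brain.
    """
    predicted_age = np.asarray(predicted_age, dtype=float)
    age = np.asarray(age, dtype=float)
    if not (np.all(np.isfinite(predicted_age)) and np.all(np.isfinite(age))):
        raise DataValidationError("compute_bag requires finite predicted_age and age")
    out = predicted_age - age
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ResidualizationModel:
    """OLS bias model  bag ~ 1 + (age - c) + (age - c)^2 + sex  fitted on a
    reference sample; ``c`` is the reference mean age (centering reduces the
    collinearity between the linear and quadratic terms)."""

    beta0: float
    beta_age: float
    beta_age2: float
    beta_sex: float
    age_center: float
    sex_dropped: bool = False

    def fitted(self, age, sex01) -> np.ndarray:
        ac = np.asarray(age, dtype=float) - self.age_center
        return (
            self.beta0
            + self.beta_age * ac
            + self.beta_age2 * ac**2
            + self.beta_sex * np.asarray(sex01, dtype=float)
        )


def _sex01(sex) -> np.ndarray:
    return (np.asarray(sex) == "F").astype(float)  # M=0, F=1


def residualize_bag(bag, age, sex, reference_mask) -> tuple[np.ndarray, ResidualizationModel]:
    """Remove common variance of BAG with age, age^2 and sex.

    The bias regression is fitted on the rows selected by ``reference_mask``
    and its fitted values are subtracted from *all* rows, so group effects in
    non-reference rows survive the correction.
    """
    bag = np.asarray(bag, dtype=float)
    age = np.asarray(age, dtype=float)
    sex01 = _sex01(sex)
    mask = np.asarray(reference_mask, dtype=bool)
    if not (len(bag) == len(age) == len(sex01) == len(mask)):
        raise DataValidationError("bag, age, sex and reference_mask must be aligned")
    if mask.sum() < 4:
        raise DataValidationError(
            f"residualization needs >= 4 reference rows, got {int(mask.sum())}"
        )
    ref_age = age[mask]
    if np.unique(ref_age).size < 2:
        raise StatisticsError(
            "rank-deficient residualization design: reference ages are constant, "
            "so the age and age^2 columns are collinear with the intercept"
        )
    sex_dropped = np.unique(sex01[mask]).size < 2
    if sex_dropped:
        warnings.warn(
            "reference sample contains a single sex; dropping the sex term "
            "from the BAG residualization",
            stacklevel=2,
        )
    center = float(ref_age.mean())
    ac = ref_age - center
    cols = [np.ones(mask.sum()), ac, ac**2]
    if not sex_dropped:
        cols.append(sex01[mask])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StatisticsError(
            "rank-deficient residualization design: the age/age^2/sex columns "
            "are collinear on the reference sample"
        )
    beta, *_ = np.linalg.lstsq(X, bag[mask], rcond=None)
    model = ResidualizationModel(
        beta0=float(beta[0]),
        beta_age=float(beta[1]),
        beta_age2=float(beta[2]),
        beta_sex=0.0 if sex_dropped else float(beta[3]),
        age_center=center,
        sex_dropped=sex_dropped,
    )
    resid = bag - model.fitted(age, sex01)
    _check_reference_orthogonality(resid[mask], age[mask], sex01[mask], sex_dropped)
    return resid, model


def _check_reference_orthogonality(resid, age, sex01, sex_dropped) -> None:
    """Residuals on the reference rows must be uncorrelated with age and
    age^2 (|r| < 1e-8) and mean-balanced across sexes."""
    if np.std(resid) <= 1e-8 * max(1.0, np.std(age)):
        return  # perfectly explained bias: residuals are numerically zero
    for name, covar in (("age", age), ("age^2", age**2)):
        if np.std(covar) == 0:
            continue
        r = np.corrcoef(resid, covar)[0, 1]
        if abs(r) >= 1e-8:
            raise StatisticsError(
                f"residualization failed: |corr(bag_resid, {name})| = {abs(r):.2e} on "
                "the reference sample"
            )
    if not sex_dropped:
        diff = resid[sex01 == 1].mean() - resid[sex01 == 0].mean()
        if abs(diff) >= 1e-8:
            raise StatisticsError(
                f"residualization failed: mean sex difference {diff:.2e} years on "
                "the reference sample"
            )


@dataclass
class BagTable:
    """Per-scan BAG table with residualization and scanner-adjustment
    provenance.

    ``data`` columns: subject_id, session, group, scanner, age, sex,
    predicted_age, bag_raw, bag_resid, bag_adjusted (plus brain volume,
    lesion load and clinical covariates when available).
    """

    data: pd.DataFrame
    region: str
    resid_model: ResidualizationModel
    scanner_coefficients: dict[str, float] = field(default_factory=dict)
    reference_scanner: str | None = None

    def validate(self) -> None:
        d = self.data
        if not np.allclose(
            d["bag_raw"], d["predicted_age"] - d["age"], rtol=0.0, atol=1e-12
        ):
            raise DataValidationError("bag_raw must equal predicted_age - age exactly")


def build_bag_table(
    table: FeatureTable,
    predicted_age,
    reference_mask=None,
    region: str = "global",
) -> BagTable:
    """Assemble a BagTable from a feature table and its predicted ages.

    ``reference_mask`` selects the rows the bias regression is fitted on;
    by default all healthy-control rows (``group == "HC"``).
    """
    d = table.data
    predicted_age = np.asarray(predicted_age, dtype=float)
    if len(predicted_age) != len(d):
        raise DataValidationError("predicted_age must align with the table rows")
    if reference_mask is None:
        reference_mask = (d["group"] == "HC").to_numpy()
    bag_raw = compute_bag(predicted_age, d["age"].to_numpy(dtype=float))
    resid, model = residualize_bag(
        bag_raw, d["age"].to_numpy(dtype=float), d["sex"].to_numpy(), reference_mask
    )
    out = d[["subject_id", "session", "group", "scanner", "age", "sex"]].copy()
    out["predicted_age"] = predicted_age
    out["bag_raw"] = bag_raw
    out["bag_resid"] = resid
    out["bag_adjusted"] = resid
    out["is_reference"] = np.asarray(reference_mask, dtype=bool)
    for col in _CARRY_COLUMNS:
        if col in d.columns:
            out[col] = d[col].to_numpy()
    for col in table.clinical_columns:
        out[col] = d[col].to_numpy()
    bt = BagTable(data=out, region=region, resid_model=model)
    bt.validate()
    return bt


def adjust_scanner(bag_table: BagTable, reference_scanner: str) -> BagTable:
    """Remove additive scanner effects from residualized BAG.

    Fits ``bag_resid ~ scanner + age + age^2 + sex`` with a random intercept
    per subject and subtracts each non-reference scanner's fixed coefficient
    from its rows. A single-scanner table is returned unchanged (with a
    logged notice). Falls back to OLS if the mixed model cannot be fitted.
    """
    d = bag_table.data
    scanners = list(pd.unique(d["scanner"]))
    if len(scanners) < 2:
        logger.info("adjust_scanner: single scanner '%s'; identity transform", scanners[0])
        out = replace(bag_table, scanner_coefficients={}, reference_scanner=scanners[0])
        out.data = d.copy()
        out.data["bag_adjusted"] = out.data["bag_resid"]
        return out
    if reference_scanner not in scanners:
        raise DataValidationError(
            f"reference scanner '{reference_scanner}' not present; scanners: {scanners}"
        )
    dual = d.groupby("subject_id")["scanner"].nunique().max() >= 2
    if not dual:
        warnings.warn(
            "no subject was scanned on more than one scanner; the scanner "
            "coefficient may be confounded with group or cohort differences",
            stacklevel=2,
        )

    others = [s for s in scanners if s != reference_scanner]
    ac = d["age"].to_numpy(dtype=float) - bag_table.resid_model.age_center
    exog = pd.DataFrame({"const": 1.0, "age_c": ac, "age_c2": ac**2, "sex01": _sex01(d["sex"])})
    for s in others:
        exog[f"scanner[{s}]"] = (d["scanner"] == s).astype(float).to_numpy()
    endog = d["bag_resid"].to_numpy(dtype=float)

    coefs: dict[str, float] = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lme = sm.MixedLM(endog, exog, groups=d["subject_id"].to_numpy())
            fit = lme.fit(reml=True)
        params = fit.fe_params
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn(
            "mixed-effects scanner model failed to fit; falling back to OLS",
            stacklevel=2,
        )
        params = sm.OLS(endog, exog).fit().params
    for s in others:
        coefs[s] = float(params[f"scanner[{s}]"])

    shift = d["scanner"].map(lambda s: coefs.get(s, 0.0)).to_numpy(dtype=float)
    out_data = d.copy()
    out_data["bag_adjusted"] = out_data["bag_resid"] - shift
    return replace(
        bag_table,
        data=out_data,
        scanner_coefficients=coefs,
        reference_scanner=reference_scanner,
    )
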