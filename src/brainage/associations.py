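"""Case-control comparisons and clinical/MRI associations.

Covariate-adjusted group differences in BAG (linear model with age, age^2,
sex and, when applicable, scanner), Cohen's D effect sizes on residualized
BAG, and Pearson correlation tables between BAG or annual brain-aging rates
and clinical/MRI variables with Benjamini-Hochberg FDR across the whole
table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .bag import BagTable, _sex01
from .exceptions import DataValidationError, StatisticsError
from .longitudinal import fdr_adjust


def cohens_d(x, y) -> float:
    """Standardized mean difference (mean(x) - mean(y)) / pooled SD."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatisticsError("cohens_d needs >= 2 observations per group")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataValidationError("cohens_d requires finite values")
    n1, n2 = len(x), len(y)
    pooled = np.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0.0:
        raise StatisticsError("cohens_d is undefined: zero pooled standard deviation")
    return float((x.mean() - y.mean()) / pooled)


def pearson_assoc(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value (t transform,
    n - 2 degrees of freedom)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatisticsError("pearson_assoc needs aligned vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataValidationError("pearson_assoc requires finite values")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise StatisticsError("pearson_assoc is undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class GroupComparison:
    """Covariate-adjusted case-control difference for one region."""

    region: str
    adjusted_difference: float  # years, case minus control
    cohens_d: float  # on residualized BAG
    p: float  # two-sided, on the group coefficient
    n_case: int
    n_control: int


@dataclass(frozen=True)
class AssociationResult:
    variable: str
    target: str  # "bag" or "annual_rate"
    region: str
    r: float
    p: float
    q: float
    n: int


def case_control_compare(
    bag_table: BagTable,
    region: str | None = None,
    value_col: str = "bag_adjusted",
    case_group: str = "MS",
    control_group: str = "HC",
) -> GroupComparison:
    """Adjusted group difference in BAG between cases and controls.

    Fits ``bag ~ group + age + age^2 + sex`` (plus scanner indicators when
    more than one scanner is present); the adjusted difference is the group
    coefficient. Cohen's D is computed on residualized BAG.
    """
    d = bag_table.data
    cases = d[d["group"] == case_group]
    controls = d[d["group"] == control_group]
    if len(cases) < 2 or len(controls) < 2:
        raise DataValidationError(
            f"case_control_compare needs >= 2 rows per group; got "
            f"{len(cases)} {case_group} and {len(controls)} {control_group}"
        )
    both = pd.concat([controls, cases])
    ac = both["age"].to_numpy(dtype=float) - bag_table.resid_model.age_center
    exog = pd.DataFrame(
        {
            "const": 1.0,
            "group": (both["group"] == case_group).astype(float).to_numpy(),
            "age_c": ac,
            "age_c2": ac**2,
            "sex01": _sex01(both["sex"].to_numpy()),
        }
    )
    scanners = list(pd.unique(both["scanner"]))
    for s in scanners[1:]:
        exog[f"scanner[{s}]"] = (both["scanner"] == s).astype(float).to_numpy()
    fit = sm.OLS(both[value_col].to_numpy(dtype=float), exog).fit()
    return GroupComparison(
        region=region if region is not None else bag_table.region,
        adjusted_difference=float(fit.params["group"]),
        cohens_d=cohens_d(cases["bag_resid"], controls["bag_resid"]),
        p=float(fit.pvalues["group"]),
        n_case=len(cases),
        n_control=len(controls),
    )


def association_table(
    values: pd.DataFrame,
    covariates: pd.DataFrame,
    target: str = "bag",
) -> list[AssociationResult]:
    """Pearson correlations of per-subject values against covariates.

    ``values`` has one column per region (indexed by subject);
    ``covariates`` has one column per clinical/MRI variable on the same
    index. One test is run per (variable, region) pair with pairwise-complete
    observations; q-values are BH-FDR adjusted across the whole table.
    """
    if covariates.shape[1] == 0:
        raise DataValidationError("association_table needs at least one covariate")
    if values.shape[1] == 0:
        raise DataValidationError("association_table needs at least one region column")
    joined = values.join(covariates, how="inner", lsuffix="", rsuffix="_cov")
    results = []
    for var in covariates.columns:
        for region in values.columns:
            pair = joined[[region, var]].dropna()
            if len(pair) < 3:
                raise DataValidationError(
                    f"covariate '{var}' x region '{region}': fewer than 3 complete pairs"
                )
            r, p = pearson_assoc(pair[region], pair[var])
            results.append(
                AssociationResult(
                    variable=var, target=target, region=region, r=r, p=p, q=np.nan, n=len(pair)
                )
            )
    qvals = fdr_adjust([res.p for res in results])
    return [
        AssociationResult(
            variable=res.variable,
            target=res.target,
            region=res.region,
            r=res.r,
            p=res.p,
            q=float(q),
            n=res.n,
        )
        for res, q in zip(results, qvals)
    ]


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tidy DataFrame view of an association table (variable, region, r, p, q, n)."""
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "target": r.target,
                "region": r.region,
                "r": r.r,
                "p": r.p,
                "q": r.q,
                "n": r.n,
            }
            for r in results
        ]
    )
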