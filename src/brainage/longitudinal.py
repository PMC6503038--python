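"""Longitudinal brain-aging statistics.

Per-subject annual rate of change of the (adjusted) brain age gap, group
one-sample t-tests per region with FDR control, intraclass-correlation
reliability of repeated measurements, and annualized brain-volume / lesion
load change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bag import BagTable
from .exceptions import DataValidationError, StatisticsError

logger = logging.getLogger(__name__)

ICC_FORMS = ("oneway_single", "twoway_consistency_single")


def annual_bag_change(sessions, rate_estimator: str = "endpoints") -> float:
    """Annual change in BAG for one subject, in years per year.

    ``sessions`` is an iterable of (age, bag) pairs. The default estimator
    divides the change between the chronologically first and last sessions
    (the longest available interval) by the elapsed years; intermediate
    sessions are ignored. ``rate_estimator="slope"`` fits a per-subject OLS
    slope over all sessions instead.
    """
    arr = np.asarray(list(sessions), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DataValidationError("sessions must be (age, bag) pairs")
    if len(arr) < 2 or np.unique(arr[:, 0]).size < 2:
        raise DataValidationError(
            "annual_bag_change needs >= 2 sessions at distinct ages; "
            "subjects with fewer usable scans are excluded from rate analyses"
        )
    order = np.argsort(arr[:, 0], kind="stable")
    ages, bags = arr[order, 0], arr[order, 1]
    if rate_estimator == "endpoints":
        return float((bags[-1] - bags[0]) / (ages[-1] - ages[0]))
    if rate_estimator == "slope":
        return float(np.polyfit(ages, bags, 1)[0])
    raise DataValidationError(f"unknown rate_estimator '{rate_estimator}'")


def subject_rates(
    bag_table: BagTable,
    value_col: str = "bag_adjusted",
    rate_estimator: str = "endpoints",
    group: str | None = "MS",
) -> pd.DataFrame:
    """Per-subject annual change in ``value_col``.

    Returns one row per subject with >= 2 usable sessions (columns:
    subject_id, rate, interval, n_sessions); subjects with a single usable
    scan are excluded, never zero-filled, and their count is logged.
    """
    d = bag_table.data
    if group is not None:
        d = d[d["group"] == group]
    rows, excluded = [], 0
    for sid, grp in d.sort_values("session").groupby("subject_id", sort=True):
        ages = grp["age"].to_numpy(dtype=float)
        vals = grp[value_col].to_numpy(dtype=float)
        ok = np.isfinite(ages) & np.isfinite(vals)
        if ok.sum() < 2 or np.unique(ages[ok]).size < 2:
            excluded += 1
            continue
        rate = annual_bag_change(zip(ages[ok], vals[ok]), rate_estimator)
        interval = float(ages[ok].max() - ages[ok].min())
        rows.append(
            {"subject_id": sid, "rate": rate, "interval": interval, "n_sessions": int(ok.sum())}
        )
    if excluded:
        logger.info("subject_rates: excluded %d subjects without longitudinal data", excluded)
    return pd.DataFrame(rows, columns=["subject_id", "rate", "interval", "n_sessions"])


def group_rate_test(rates) -> tuple[float, float, float, float]:
    """One-sample two-sided t-test of per-subject rates against 0.

    Returns (mean, SE, t, p) with SE = sd/sqrt(n) and n-1 degrees of freedom.
    """
    rates = np.asarray(list(rates), dtype=float)
    if len(rates) < 3:
        raise StatisticsError(f"group_rate_test needs n >= 3 rates, got {len(rates)}")
    if not np.all(np.isfinite(rates)):
        raise DataValidationError("group_rate_test requires finite rates")
    mean = float(rates.mean())
    sd = float(rates.std(ddof=1))
    se = sd / np.sqrt(len(rates))
    if sd == 0.0:
        if mean == 0.0:
            return mean, 0.0, 0.0, 1.0
        warnings.warn(
            "zero variance with nonzero mean: p-value below machine epsilon",
            stacklevel=2,
        )
        return mean, 0.0, np.inf, float(np.finfo(float).tiny)
    t, p = stats.ttest_1samp(rates, popmean=0.0)
    return mean, float(se), float(t), float(p)


def icc(measure_matrix, form: str = "twoway_consistency_single") -> float:
    """Intraclass correlation of a subjects x sessions matrix (mean squares).

    ``oneway_single``            ICC(1,1) = (BMS - WMS) / (BMS + (k-1) WMS)
    ``twoway_consistency_single`` ICC(3,1) = (BMS - EMS) / (BMS + (k-1) EMS)

    where BMS, WMS and EMS are the between-subject, within-subject and
    residual (subject x session interaction) mean squares of the two-way
    ANOVA decomposition. Rows containing missing values are dropped (count
    logged); a constant matrix is an error (the ratio is undefined).
    """
    if form not in ICC_FORMS:
        raise DataValidationError(f"unknown ICC form '{form}'; expected one of {ICC_FORMS}")
    m = np.asarray(measure_matrix, dtype=float)
    if m.ndim != 2:
        raise DataValidationError("measure_matrix must be 2-D (subjects x sessions)")
    complete = np.isfinite(m).all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("icc: dropped %d subjects with missing sessions", dropped)
    m = m[complete]
    n, k = m.shape
    if n < 2 or k < 2:
        raise DataValidationError(f"icc needs >= 2 complete subjects and >= 2 sessions, got {n}x{k}")
    if np.ptp(m) == 0.0:
        raise StatisticsError("icc is undefined for a constant matrix")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_between = k * np.sum((row_means - grand) ** 2)
    ss_within = np.sum((m - row_means[:, None]) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = ss_within - ss_cols
    bms = ss_between / (n - 1)
    wms = ss_within / (n * (k - 1))
    ems = ss_err / ((n - 1) * (k - 1))
    if form == "oneway_single":
        denom = bms + (k - 1) * wms
    else:
        denom = bms + (k - 1) * ems
    if denom == 0.0:
        raise StatisticsError("icc is undefined: zero denominator mean squares")
    ms = wms if form == "oneway_single" else ems
    return float((bms - ms) / denom)


def annual_volume_change(sessions, estimator: str = "endpoints") -> float:
    """Annualized percent change in total brain volume for one subject.

    ``sessions`` is an iterable of (age, volume mm^3) pairs. The default
    annualizes the first-to-last relative change,
    100 * (V_last - V_first) / (V_first * (age_last - age_first));
    ``estimator="consecutive"`` averages the annualized change of each
    consecutive visit pair instead.
    """
    arr = np.asarray(list(sessions), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise DataValidationError("annual_volume_change needs >= 2 (age, volume) sessions")
    if np.any(arr[:, 1] <= 0):
        raise DataValidationError("brain volumes must be positive")
    order = np.argsort(arr[:, 0], kind="stable")
    ages, vols = arr[order, 0], arr[order, 1]
    if ages[-1] == ages[0]:
        raise DataValidationError("annual_volume_change needs distinct ages")
    if estimator == "endpoints":
        return float(100.0 * (vols[-1] - vols[0]) / (vols[0] * (ages[-1] - ages[0])))
    if estimator == "consecutive":
        dt = np.diff(ages)
        if np.any(dt == 0):
            raise DataValidationError("consecutive sessions must have distinct ages")
        return float(np.mean(100.0 * np.diff(vols) / (vols[:-1] * dt)))
    raise DataValidationError(f"unknown estimator '{estimator}'")


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving,
    capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    bad = np.where(~((p >= 0) & (p <= 1)))[0]
    if bad.size:
        raise DataValidationError(
            f"p-values outside [0, 1] at indices {bad.tolist()[:5]} (values {p[bad][:5].tolist()})"
        )
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class LongitudinalSummary:
    """Group-level longitudinal results.

    ``rates``: per subject x region annual BAG change; ``region_tests``: per
    region n / mean / SE / t / p / q (FDR across regions); ``reliability``:
    per region ICC of BAG and of predicted age in both forms;
    ``subject_changes``: per subject annualized brain-volume (%/year) and
    lesion-load (mm^3/year) change.
    """

    rates: pd.DataFrame
    region_tests: pd.DataFrame
    reliability: pd.DataFrame
    subject_changes: pd.DataFrame
    icc_form: str
    rate_estimator: str


def _icc_matrix(d: pd.DataFrame, value_col: str) -> np.ndarray:
    wide = d.pivot_table(index="subject_id", columns="session", values=value_col)
    return wide.to_numpy(dtype=float)


def summarize_longitudinal(
    bag_tables: dict[str, BagTable],
    icc_form: str = "twoway_consistency_single",
    rate_estimator: str = "endpoints",
    volume_estimator: str = "endpoints",
    group: str = "MS",
) -> LongitudinalSummary:
    """Full longitudinal summary over per-region BagTables.

    Computes per-subject annual BAG rates per region, one-sample t-tests of
    the rates against 0 with BH-FDR across regions, ICC reliability of
    residualized BAG and predicted age, and per-subject annualized brain
    volume / lesion load changes (taken from the first region's table, which
    carries the scan-level volume columns).
    """
    rate_rows, test_rows, rel_rows = [], [], []
    for region, bt in bag_tables.items():
        r = subject_rates(bt, "bag_adjusted", rate_estimator, group=group)
        r.insert(0, "region", region)
        rate_rows.append(r)
        mean, se, t, p = group_rate_test(r["rate"])
        test_rows.append(
            {"region": region, "n": len(r), "mean_rate": mean, "se": se, "t": t, "p": p}
        )
        d = bt.data[bt.data["group"] == group]
        rel = {"region": region}
        for label, col in (("bag", "bag_adjusted"), ("predicted_age", "predicted_age")):
            mat = _icc_matrix(d, col)
            for form in ICC_FORMS:
                try:
                    rel[f"icc_{label}_{form}"] = icc(mat, form)
                except (DataValidationError, StatisticsError):
                    rel[f"icc_{label}_{form}"] = np.nan
        rel_rows.append(rel)

    region_tests = pd.DataFrame(test_rows)
    region_tests["q"] = fdr_adjust(region_tests["p"])

    first = next(iter(bag_tables.values())).data
    first = first[first["group"] == group]
    change_rows = []
    for sid, grp in first.sort_values("session").groupby("subject_id"):
        row = {"subject_id": sid}
        try:
            row["volume_change_pct_per_year"] = annual_volume_change(
                zip(grp["age"], grp["brain_volume_mm3"]), volume_estimator
            )
        except (DataValidationError, KeyError):
            row["volume_change_pct_per_year"] = np.nan
        if "wmll_mm3" in grp.columns and len(grp) >= 2:
            ages = grp["age"].to_numpy(dtype=float)
            wmll = grp["wmll_mm3"].to_numpy(dtype=float)
            if ages[-1] > ages[0]:
                row["wmll_change_mm3_per_year"] = float(
                    (wmll[-1] - wmll[0]) / (ages[-1] - ages[0])
                )
            else:
                row["wmll_change_mm3_per_year"] = np.nan
        else:
            row["wmll_change_mm3_per_year"] = np.nan
        change_rows.append(row)

    return LongitudinalSummary(
        rates=pd.concat(rate_rows, ignore_index=True) if rate_rows else pd.DataFrame(),
        region_tests=region_tests,
        reliability=pd.DataFrame(rel_rows),
        subject_changes=pd.DataFrame(change_rows),
        icc_form=icc_form,
        rate_estimator=rate_estimator,
    )
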