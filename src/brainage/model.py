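"""Sex-specific gradient-boosted brain-age regressors.

One extreme-gradient-boosting tree ensemble is trained per sex to predict
chronological age from morphometric features, either from the full feature
set ("global") or from one region's features alone.  The number of boosting
rounds is chosen by an inner cross-validation with early stopping; an
optional outer cross-validation produces a pooled out-of-fold performance
report (Pearson r between predicted and true age, pooled across sexes, as is
conventional when a combined accuracy figure is reported for per-sex models).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats
from sklearn.model_selection import KFold

from .config import REGION_LABELS, CVSettings
from .exceptions import ModelError
from .features import SEX_CODES, FeatureTable

#: Boosting hyperparameters; the learning rate is deliberately small and the
#: number of rounds is data-driven. Depth-4 trees with no subsampling keep
#: results reproducible across library versions.
DEFAULT_PARAMS: dict = {
    "objective": "reg:squarederror",
    "eta": 0.01,
    "max_depth": 4,
    "subsample": 1.0,
    "tree_method": "hist",
}


def subset_features_by_region(table: FeatureTable, region: str) -> FeatureTable:
    """Restrict a feature table to one region's features.

    ``"global"`` returns the table unchanged. An unknown region label raises
    an error listing the valid labels; a valid label with no features in the
    table is an error as well (never an empty table).
    """
    if region == "global":
        return table
    if region not in REGION_LABELS:
        raise ModelError(
            f"unknown region '{region}'; valid labels are "
            f"{('global',) + tuple(REGION_LABELS)}"
        )
    names = [f for f in table.feature_names if table.feature_meta.loc[f, "region"] == region]
    if not names:
        raise ModelError(f"region '{region}' has no features in this table")
    return table.subset_features(names)


@dataclass
class CVReport:
    """Out-of-fold performance of the nested cross-validation."""

    pooled_r: float
    per_fold: pd.DataFrame  # columns: sex, fold, n, r
    #: per-sex fold index of every training row (bookkeeping for the
    #: guarantee that no row is scored by a model fitted on its own fold)
    fold_assignments: dict[str, np.ndarray]
    oof_predictions: dict[str, np.ndarray]


@dataclass
class BrainAgeModel:
    """Fitted per-sex brain-age regressors for one region (or "global")."""

    region: str
    boosters: dict[str, xgb.Booster]
    feature_names: list[str]
    hyperparameters: dict
    n_rounds: dict[str, int]
    training_age_range: tuple[float, float]
    cv_report: CVReport | None = None
    seed: int = 0

    # -- persistence ----------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write a versioned on-disk bundle: metadata JSON + per-sex boosters."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "region": self.region,
            "feature_names": self.feature_names,
            "hyperparameters": self.hyperparameters,
            "n_rounds": self.n_rounds,
            "training_age_range": list(self.training_age_range),
            "seed": self.seed,
            "cv_pooled_r": None if self.cv_report is None else self.cv_report.pooled_r,
            "sexes": sorted(self.boosters),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        for sex, booster in self.boosters.items():
            booster.save_model(str(directory / f"booster_{sex}.json"))

    @classmethod
    def load(cls, directory: str | Path) -> "BrainAgeModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        boosters = {}
        for sex in meta["sexes"]:
            booster = xgb.Booster()
            booster.load_model(str(directory / f"booster_{sex}.json"))
            boosters[sex] = booster
        return cls(
            region=meta["region"],
            boosters=boosters,
            feature_names=list(meta["feature_names"]),
            hyperparameters=dict(meta["hyperparameters"]),
            n_rounds={k: int(v) for k, v in meta["n_rounds"].items()},
            training_age_range=tuple(meta["training_age_range"]),
            seed=int(meta["seed"]),
        )


def _sex_seed(seed: int, sex: str) -> int:
    return (int(seed) * 2 + SEX_CODES.index(sex)) % (2**31 - 1)


def _choose_rounds(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    params: dict,
    cv: CVSettings,
    seed: int,
) -> int:
    """Inner CV: number of rounds minimizing held-out squared error."""
    dtrain = xgb.DMatrix(X, label=y, feature_names=feature_names)
    history = xgb.cv(
        params,
        dtrain,
        num_boost_round=cv.max_rounds,
        nfold=cv.inner_folds,
        early_stopping_rounds=cv.early_stopping_rounds,
        seed=seed,
        shuffle=True,
        verbose_eval=False,
    )
    return int(history["test-rmse-mean"].idxmin()) + 1


def _fit_booster(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    params: dict,
    n_rounds: int,
) -> xgb.Booster:
    fit_params = dict(params, base_score=float(np.mean(y)))
    dtrain = xgb.DMatrix(X, label=y, feature_names=feature_names)
    return xgb.train(fit_params, dtrain, num_boost_round=n_rounds)


def train_brain_age(
    train: FeatureTable,
    region: str = "global",
    cv: CVSettings | None = None,
    seed: int = 0,
    params: dict | None = None,
) -> BrainAgeModel:
    """Train per-sex boosted brain-age regressors on a healthy cohort.

    Parameters
    ----------
    train
        Training feature table; must contain both sexes.
    region
        Region label or ``"global"`` (all features).
    cv
        Cross-validation settings. ``cv.outer_folds == 0`` skips the
        out-of-fold performance report; rounds are still chosen by the inner
        loop.
    seed
        Seed for fold shuffling and booster training; retraining with the
        same data and seed reproduces the model and its CV report exactly.
    params
        Optional overrides of :data:`DEFAULT_PARAMS` (e.g. a larger learning
        rate for quick experiments).
    """
    cv = cv or CVSettings()
    cv.validate()
    table = subset_features_by_region(train, region)
    full_params = dict(DEFAULT_PARAMS, seed=int(seed) % (2**31 - 1))
    if params:
        full_params.update(params)

    data = table.data
    by_sex: dict[str, pd.DataFrame] = {}
    min_rows = max(2 * cv.inner_folds, 2 * cv.outer_folds)
    for sex in SEX_CODES:
        rows = data[data["sex"] == sex]
        if len(rows) < min_rows:
            raise ModelError(
                f"sex '{sex}' has only {len(rows)} training rows; "
                f"need at least {min_rows} for {cv.outer_folds}x{cv.inner_folds} nested CV"
            )
        by_sex[sex] = rows
    ages = data["age"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ages)):
        bad = data.loc[~np.isfinite(ages), "subject_id"].tolist()
        raise ModelError(f"non-finite ages for subjects {bad[:5]}")

    feature_names = table.feature_names
    boosters: dict[str, xgb.Booster] = {}
    n_rounds: dict[str, int] = {}
    fold_assignments: dict[str, np.ndarray] = {}
    oof: dict[str, np.ndarray] = {}
    fold_rows = []

    for sex, rows in by_sex.items():
        X = rows[feature_names].to_numpy(dtype=float)
        y = rows["age"].to_numpy(dtype=float)
        sex_seed = _sex_seed(seed, sex)
        inner_params = dict(full_params, seed=sex_seed)

        if cv.outer_folds >= 2:
            kf = KFold(n_splits=cv.outer_folds, shuffle=True, random_state=sex_seed)
            assign = np.empty(len(y), dtype=int)
            preds = np.empty(len(y), dtype=float)
            for fold, (tr, te) in enumerate(kf.split(X)):
                assign[te] = fold
                rounds = _choose_rounds(
                    X[tr], y[tr], feature_names, inner_params, cv, sex_seed + fold
                )
                booster = _fit_booster(X[tr], y[tr], feature_names, inner_params, rounds)
                preds[te] = booster.predict(xgb.DMatrix(X[te], feature_names=feature_names))
                fold_rows.append(
                    {
                        "sex": sex,
                        "fold": fold,
                        "n": len(te),
                        "r": float(stats.pearsonr(preds[te], y[te])[0]) if len(te) >= 3 else np.nan,
                    }
                )
            fold_assignments[sex] = assign
            oof[sex] = preds

        rounds = _choose_rounds(X, y, feature_names, inner_params, cv, sex_seed)
        boosters[sex] = _fit_booster(X, y, feature_names, inner_params, rounds)
        n_rounds[sex] = rounds

    report = None
    if cv.outer_folds >= 2:
        pooled_pred = np.concatenate([oof[s] for s in sorted(oof)])
        pooled_true = np.concatenate(
            [by_sex[s]["age"].to_numpy(dtype=float) for s in sorted(oof)]
        )
        pooled_r = float(stats.pearsonr(pooled_pred, pooled_true)[0])
        report = CVReport(
            pooled_r=pooled_r,
            per_fold=pd.DataFrame(fold_rows),
            fold_assignments=fold_assignments,
            oof_predictions=oof,
        )

    return BrainAgeModel(
        region=region,
        boosters=boosters,
        feature_names=feature_names,
        hyperparameters=full_params,
        n_rounds=n_rounds,
        training_age_range=(float(ages.min()), float(ages.max())),
        cv_report=report,
        seed=seed,
    )


def predict_brain_age(model: BrainAgeModel, table: FeatureTable) -> np.ndarray:
    """Score every scan with its sex's ensemble; output aligned to rows."""
    data = table.data
    missing = [f for f in model.feature_names if f not in data.columns]
    if missing:
        raise ModelError(f"table is missing model features: {missing}")
    bad_sex = set(data["sex"].unique()) - set(model.boosters)
    if bad_sex:
        raise ModelError(
            f"no model for sex codes {sorted(bad_sex)}; trained sexes: {sorted(model.boosters)}"
        )
    out = np.full(len(data), np.nan)
    for sex, booster in model.boosters.items():
        mask = (data["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        X = data.loc[mask, model.feature_names].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            bad = data.loc[mask].loc[~np.isfinite(X).all(axis=1), "subject_id"].tolist()
            raise ModelError(f"non-finite feature values for subjects {bad[:5]}")
        out[mask] = booster.predict(xgb.DMatrix(X, feature_names=model.feature_names))
    return out
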