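"""The FeatureTable container: one row per MRI scan, named morphometric
features plus demographics / scanner / group metadata, and (for synthetic
cohorts) a latent-truth record of the generating brain-age process."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataValidationError

#: Required per-scan metadata columns, in canonical order.
METADATA_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "session",
    "age",
    "sex",
    "scanner",
    "group",
    "brain_volume_mm3",
    "wmll_mm3",
)

SEX_CODES = ("F", "M")
GROUP_CODES = ("HC", "MS")


@dataclass
class FeatureTable:
    """Per-scan morphometric features with metadata.

    Parameters
    ----------
    data
        One row per scan. Must contain :data:`METADATA_COLUMNS`, every
        feature named in ``feature_meta``, and optionally extra clinical
        covariate columns.
    feature_meta
        Indexed by feature name with columns ``region``, ``measure`` and
        ``unit``; defines the feature -> region map used for regional
        brain-age models.
    latent
        Synthetic cohorts only: per-scan latent truth (subject deviation
        ``u``, disease gap deviation, acceleration, time since first visit
        and the latent regional/global brain ages).
    """

    data: pd.DataFrame
    feature_meta: pd.DataFrame
    latent: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -----------------------------------------------------------

    @property
    def feature_names(self) -> list[str]:
        return list(self.feature_meta.index)

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def clinical_columns(self) -> list[str]:
        known = set(METADATA_COLUMNS) | set(self.feature_names)
        return [c for c in self.data.columns if c not in known]

    @property
    def n_scans(self) -> int:
        return len(self.data)

    def regions(self) -> list[str]:
        """Region labels present in the feature metadata, in first-seen order."""
        return list(dict.fromkeys(self.feature_meta["region"]))

    def validate(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise DataValidationError(f"feature table is missing required columns: {missing}")
        for col in ("region", "measure", "unit"):
            if col not in self.feature_meta.columns:
                raise DataValidationError(f"feature metadata is missing the '{col}' column")
        absent = [f for f in self.feature_meta.index if f not in self.data.columns]
        if absent:
            raise DataValidationError(f"features declared in metadata but absent from table: {absent}")
        if self.feature_meta.index.duplicated().any():
            dup = self.feature_meta.index[self.feature_meta.index.duplicated()].tolist()
            raise DataValidationError(f"duplicated feature names in metadata: {dup}")
        bad_sex = set(self.data["sex"].unique()) - set(SEX_CODES)
        if bad_sex:
            raise DataValidationError(f"unknown sex codes {sorted(bad_sex)}; expected {SEX_CODES}")
        keys = self.data[["subject_id", "session"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].to_records(index=False).tolist()
            raise DataValidationError(f"duplicated (subject_id, session) keys: {dup[:5]}")
        if self.n_scans:
            feats = self.features.to_numpy(dtype=float)
            if not np.all(np.isfinite(feats)):
                rows = self.data.loc[
                    ~np.isfinite(feats).all(axis=1), "subject_id"
                ].tolist()
                raise DataValidationError(f"non-finite feature values for subjects {rows[:5]}")
            # within a subject, session order must agree with age order
            by_subj = self.data.sort_values(["subject_id", "session"]).groupby(
                "subject_id", sort=False
            )
            if not bool(by_subj["age"].apply(lambda a: bool(a.is_monotonic_increasing)).all()):
                raise DataValidationError(
                    "within a subject, session indices must increase with age_at_scan"
                )

    # -- manipulation ---------------------------------------------------------

    def subset_features(self, feature_names: list[str]) -> "FeatureTable":
        """Restrict the table to the given features; metadata preserved."""
        unknown = [f for f in feature_names if f not in self.feature_meta.index]
        if unknown:
            raise DataValidationError(f"unknown features: {unknown}")
        keep = [c for c in self.data.columns if c not in self.feature_names] + list(feature_names)
        return FeatureTable(
            data=self.data[keep].copy(),
            feature_meta=self.feature_meta.loc[list(feature_names)].copy(),
            latent=None if self.latent is None else self.latent.copy(),
        )

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        """Stack two tables sharing the same feature metadata."""
        if list(self.feature_meta.index) != list(other.feature_meta.index):
            raise DataValidationError("cannot concatenate tables with different feature sets")
        latent = None
        if self.latent is not None and other.latent is not None:
            latent = pd.concat([self.latent, other.latent], ignore_index=True)
        return FeatureTable(
            data=pd.concat([self.data, other.data], ignore_index=True),
            feature_meta=self.feature_meta.copy(),
            latent=latent,
        )
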