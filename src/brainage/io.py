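"""Readers and writers for feature tables, BAG tables and run manifests.

Feature tables are tidy CSV/TSV (one row per scan) with a feature-metadata
sidecar CSV (feature, region, measure, unit) and, for synthetic cohorts, a
JSON latent-truth sidecar. BAG tables are CSV with a JSON sidecar holding the
residualization and scanner coefficients.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bag import BagTable, ResidualizationModel
from .config import ClinicalCovariateSpec, CVSettings, GeneratorConfig
from .exceptions import DataValidationError
from .features import METADATA_COLUMNS, FeatureTable


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def write_feature_table(table: FeatureTable, directory: str | Path, fmt: str = "csv") -> dict:
    """Write features.<fmt>, feature_meta.csv and latent_truth.json.

    The metadata sidecar maps every non-metadata column: features carry
    (region, measure, unit); clinical covariate columns are declared with
    measure ``"clinical"``. Returns the paths written, keyed by artifact name.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": directory / f"features.{fmt}",
        "feature_meta": directory / "feature_meta.csv",
    }
    table.data.to_csv(paths["features"], sep=_sep(paths["features"]), index=False)
    meta = table.feature_meta.reset_index()
    clinical = pd.DataFrame(
        {"feature": table.clinical_columns, "region": "", "measure": "clinical", "unit": ""}
    )
    pd.concat([meta, clinical], ignore_index=True).to_csv(paths["feature_meta"], index=False)
    if table.latent is not None:
        paths["latent_truth"] = directory / "latent_truth.json"
        paths["latent_truth"].write_text(
            json.dumps(json.loads(table.latent.to_json(orient="split", index=False)))
        )
    return {k: str(v) for k, v in paths.items()}


def read_feature_table(
    path: str | Path, meta_path: str | Path, latent_path: str | Path | None = None
) -> FeatureTable:
    """Read a feature table plus its metadata sidecar (CSV or TSV by
    extension), validating required columns, the feature -> region map and
    key uniqueness. Every non-metadata column must be declared in the
    sidecar, either as a feature or as a clinical covariate."""
    path, meta_path = Path(path), Path(meta_path)
    data = pd.read_csv(path, sep=_sep(path))
    meta = pd.read_csv(meta_path, keep_default_na=False)
    if "feature" not in meta.columns:
        raise DataValidationError("feature metadata must have a 'feature' column")
    meta = meta.set_index("feature")
    missing = [c for c in METADATA_COLUMNS if c not in data.columns]
    if missing:
        raise DataValidationError(f"'{path.name}' is missing required columns: {missing}")
    unmapped = [c for c in data.columns if c not in METADATA_COLUMNS and c not in meta.index]
    if unmapped:
        raise DataValidationError(
            f"columns not mapped by the feature metadata sidecar: {unmapped}"
        )
    feature_meta = meta[meta["measure"] != "clinical"]
    absent = [f for f in feature_meta.index if f not in data.columns]
    if absent:
        raise DataValidationError(f"metadata declares features absent from the table: {absent}")
    latent = None
    if latent_path is not None and Path(latent_path).exists():
        latent = pd.read_json(Path(latent_path), orient="split")
    return FeatureTable(data=data, feature_meta=feature_meta, latent=latent)


def write_bag_table(bag_table: BagTable, directory: str | Path, stem: str = "bag") -> dict:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{stem}.csv"
    json_path = directory / f"{stem}_coefficients.json"
    bag_table.data.to_csv(csv_path, index=False)
    payload = {
        "region": bag_table.region,
        "residualization": dataclasses.asdict(bag_table.resid_model),
        "scanner_coefficients": bag_table.scanner_coefficients,
        "reference_scanner": bag_table.reference_scanner,
    }
    json_path.write_text(json.dumps(payload, indent=2))
    return {"bag": str(csv_path), "coefficients": str(json_path)}


def read_bag_table(csv_path: str | Path, json_path: str | Path) -> BagTable:
    data = pd.read_csv(csv_path)
    payload = json.loads(Path(json_path).read_text())
    return BagTable(
        data=data,
        region=payload["region"],
        resid_model=ResidualizationModel(**payload["residualization"]),
        scanner_coefficients=dict(payload["scanner_coefficients"]),
        reference_scanner=payload["reference_scanner"],
    )


# -- generator / pipeline configuration ---------------------------------------


def generator_config_from_dict(raw: dict) -> GeneratorConfig:
    raw = dict(raw)
    if "clinical_covariate_specs" in raw:
        raw["clinical_covariate_specs"] = [
            ClinicalCovariateSpec(**s) if isinstance(s, dict) else ClinicalCovariateSpec(*s)
            for s in raw["clinical_covariate_specs"]
        ]
    for key in ("train_age_range", "test_age_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    for key in ("feature_intercepts", "age_slopes", "sex_effects", "feature_noise_sd"):
        if key in raw and raw[key] is not None:
            raw[key] = np.asarray(raw[key], dtype=float)
    return GeneratorConfig(**raw)


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Load a GeneratorConfig from a YAML file (missing fields -> defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return generator_config_from_dict(raw.get("generator", raw))


def cv_settings_from_dict(raw: dict) -> CVSettings:
    return CVSettings(**raw)


# -- run manifest --------------------------------------------------------------

#: Required structure of a run manifest; mirrors docs/manifest.schema.json.
MANIFEST_REQUIRED: dict = {
    "schema_version": int,
    "seed": int,
    "package_version": str,
    "stages": list,
}
STAGE_REQUIRED: dict = {"name": str, "seed": int, "outputs": dict, "rows": dict}


def validate_manifest(manifest: dict) -> None:
    """Structural validation of a run manifest against the published schema."""
    for key, typ in MANIFEST_REQUIRED.items():
        if key not in manifest:
            raise DataValidationError(f"manifest is missing key '{key}'")
        if not isinstance(manifest[key], typ):
            raise DataValidationError(f"manifest key '{key}' must be {typ.__name__}")
    for stage in manifest["stages"]:
        for key, typ in STAGE_REQUIRED.items():
            if key not in stage:
                raise DataValidationError(f"manifest stage is missing key '{key}'")
            if not isinstance(stage[key], typ):
                raise DataValidationError(f"manifest stage key '{key}' must be {typ.__name__}")


def write_manifest(manifest: dict, path: str | Path) -> None:
    validate_manifest(manifest)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
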