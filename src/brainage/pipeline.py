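"""Single pipeline driver chaining simulate -> train -> predict -> bag ->
longitudinal -> associate, with file-based stage boundaries and a run
manifest.

Every stage reads its inputs from disk (as written by the previous stage)
and writes its outputs under the run directory, so a failed stage leaves
earlier artifacts intact and a ``FAILED`` marker naming the stage. Rerunning
with an identical configuration reproduces all outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import association_frame, association_table
from .bag import adjust_scanner, build_bag_table
from .config import CVSettings, GeneratorConfig
from .io import (
    cv_settings_from_dict,
    generator_config_from_dict,
    read_bag_table,
    read_feature_table,
    write_bag_table,
    write_feature_table,
    write_manifest,
)
from .longitudinal import summarize_longitudinal
from .model import BrainAgeModel, predict_brain_age, train_brain_age
from .workflows import derive_seed

logger = logging.getLogger(__name__)

STAGES = ("simulate", "train", "predict", "bag", "longitudinal", "associate")


@dataclass
class PipelineConfig:
    """Configuration of an end-to-end synthetic-study run."""

    out_dir: str
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cv: CVSettings = field(default_factory=lambda: CVSettings(outer_folds=0))
    regions: tuple[str, ...] = ("global", "subcortical_cerebellar")
    icc_form: str = "twoway_consistency_single"
    rate_estimator: str = "endpoints"
    fdr_alpha: float = 0.05
    seed: int = 0
    n_longitudinal_patients: int = 68
    model_params: dict | None = None  # overrides of the boosting defaults
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "generator" in raw:
            raw["generator"] = generator_config_from_dict(raw["generator"])
        if "cv" in raw:
            raw["cv"] = cv_settings_from_dict(raw["cv"])
        if "regions" in raw:
            raw["regions"] = tuple(raw["regions"])
        return cls(**raw)


def _stage_marker(out: Path, stage: str) -> None:
    (out / "FAILED").write_text(stage)


def run_pipeline(config: PipelineConfig, start: str = "simulate", stop: str = "associate") -> dict:
    """Run the pipeline stages from ``start`` to ``stop`` inclusive.

    Returns the run manifest. On a stage failure, partial outputs are
    retained, a ``FAILED`` marker names the stage, and the error is
    re-raised.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    i0, i1 = STAGES.index(start), STAGES.index(stop)
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text())
        if manifest_path.exists()
        else {"schema_version": 1, "seed": int(config.seed), "package_version": __version__, "stages": []}
    )
    (out / "FAILED").unlink(missing_ok=True)
    for stage in STAGES[i0 : i1 + 1]:
        t0 = time.time()
        logger.info("[stage:%s] start", stage)
        try:
            outputs, rows = _STAGE_FUNCS[stage](config, out)
        except Exception:
            _stage_marker(out, stage)
            logger.error("[stage:%s] FAILED", stage)
            raise
        manifest["stages"] = [s for s in manifest["stages"] if s["name"] != stage]
        manifest["stages"].append(
            {
                "name": stage,
                "seed": derive_seed(config.seed, stage),
                "outputs": outputs,
                "rows": rows,
                "wall_seconds": round(time.time() - t0, 3),
            }
        )
        logger.info("[stage:%s] done in %.2fs", stage, time.time() - t0)
    manifest["stages"].sort(key=lambda s: STAGES.index(s["name"]))
    write_manifest(manifest, manifest_path)
    return manifest


# -- stages --------------------------------------------------------------------


def _simulate(config: PipelineConfig, out: Path):
    from .simulate import (
        generate_case_control,
        generate_longitudinal_patients,
        generate_training_cohort,
    )

    g = config.generator
    seed = derive_seed(config.seed, "simulate")
    tables = {
        "train": generate_training_cohort(g, derive_seed(seed, "train")),
        "case_control": generate_case_control(g, derive_seed(seed, "cc")),
        "longitudinal": generate_longitudinal_patients(
            g.replace(n_ms=config.n_longitudinal_patients), derive_seed(seed, "long")
        ),
    }
    outputs, rows = {}, {}
    for name, table in tables.items():
        outputs[name] = write_feature_table(table, out / "cohorts" / name)
        rows[name] = int(table.n_scans)
    return outputs, rows


def _cohort(out: Path, name: str):
    d = out / "cohorts" / name
    return read_feature_table(d / "features.csv", d / "feature_meta.csv", d / "latent_truth.json")


def _train(config: PipelineConfig, out: Path):
    training = _cohort(out, "train")
    outputs, rows = {}, {}
    for region in config.regions:
        model = train_brain_age(
            training,
            region,
            cv=config.cv,
            seed=derive_seed(config.seed, "fit", region),
            params=config.model_params,
        )
        model_dir = out / "models" / region
        model.save(model_dir)
        outputs[region] = str(model_dir)
        rows[region] = int(training.n_scans)
    return outputs, rows


def _predict(config: PipelineConfig, out: Path):
    outputs, rows = {}, {}
    for cohort in ("case_control", "longitudinal"):
        table = _cohort(out, cohort)
        preds = table.data[["subject_id", "session"]].copy()
        for region in config.regions:
            model = BrainAgeModel.load(out / "models" / region)
            preds[f"predicted_age_{region}"] = predict_brain_age(model, table)
        path = out / "predictions" / f"{cohort}.csv"
        path.parent.mkdir(parents=True, exist_ok=True)
        preds.to_csv(path, index=False)
        outputs[cohort] = str(path)
        rows[cohort] = len(preds)
    return outputs, rows


def _bag(config: PipelineConfig, out: Path):
    cc = _cohort(out, "case_control")
    longi = _cohort(out, "longitudinal")
    outputs, rows = {}, {}
    for region in config.regions:
        for cohort, table in (("case_control", cc), ("longitudinal", cc.concat(longi))):
            preds = pd.read_csv(out / "predictions" / "case_control.csv")
            if cohort == "longitudinal":
                lp = pd.read_csv(out / "predictions" / "longitudinal.csv")
                hc_mask = cc.data["group"] == "HC"
                preds = pd.concat([preds, lp], ignore_index=True)
                keep = np.concatenate([hc_mask.to_numpy(), np.ones(len(lp), dtype=bool)])
                table = _subset_rows(table, keep)
                preds = preds[keep].reset_index(drop=True)
            bt = build_bag_table(table, preds[f"predicted_age_{region}"].to_numpy(), region=region)
            bt = adjust_scanner(bt, config.generator.test_scanner)
            outputs[f"{region}/{cohort}"] = write_bag_table(
                bt, out / "bag" / region, stem=cohort
            )
            rows[f"{region}/{cohort}"] = len(bt.data)
    return outputs, rows


def _subset_rows(table, keep: np.ndarray):
    from .features import FeatureTable

    return FeatureTable(
        data=table.data[keep].reset_index(drop=True),
        feature_meta=table.feature_meta,
        latent=None if table.latent is None else table.latent[keep].reset_index(drop=True),
    )


def _longitudinal(config: PipelineConfig, out: Path):
    bag_tables = {
        region: read_bag_table(
            out / "bag" / region / "longitudinal.csv",
            out / "bag" / region / "longitudinal_coefficients.json",
        )
        for region in config.regions
    }
    summary = summarize_longitudinal(
        bag_tables, icc_form=config.icc_form, rate_estimator=config.rate_estimator
    )
    d = out / "longitudinal"
    d.mkdir(parents=True, exist_ok=True)
    outputs = {}
    for name, frame in (
        ("rates", summary.rates),
        ("region_tests", summary.region_tests),
        ("reliability", summary.reliability),
        ("subject_changes", summary.subject_changes),
    ):
        path = d / f"{name}.csv"
        frame.to_csv(path, index=False)
        outputs[name] = str(path)
    return outputs, {"subjects": int(summary.subject_changes.shape[0])}


def _associate(config: PipelineConfig, out: Path):
    rates = pd.read_csv(out / "longitudinal" / "rates.csv")
    changes = pd.read_csv(out / "longitudinal" / "subject_changes.csv").set_index("subject_id")
    bag_values = {}
    clinical = None
    for region in config.regions:
        bt = read_bag_table(
            out / "bag" / region / "longitudinal.csv",
            out / "bag" / region / "longitudinal_coefficients.json",
        )
        d = bt.data[bt.data["group"] == "MS"].sort_values("session")
        last = d.groupby("subject_id").tail(1).set_index("subject_id")
        bag_values[region] = last["bag_adjusted"]
        if clinical is None:
            cols = [
                c
                for c in last.columns
                if c
                not in (
                    "session", "group", "scanner", "age", "sex", "predicted_age",
                    "bag_raw", "bag_resid", "bag_adjusted", "is_reference",
                )
            ]
            clinical = last[cols].join(changes, how="left")
    bag_frame = pd.DataFrame(bag_values)
    rate_frame = rates.pivot(index="subject_id", columns="region", values="rate")
    d = out / "associations"
    d.mkdir(parents=True, exist_ok=True)
    outputs = {}
    for target, frame in (("bag", bag_frame), ("annual_rate", rate_frame)):
        results = association_table(frame, clinical, target=target)
        path = d / f"associations_{target}.csv"
        association_frame(results).to_csv(path, index=False)
        outputs[target] = str(path)
    return outputs, {"bag_tests": bag_frame.shape[1] * clinical.shape[1]}


_STAGE_FUNCS = {
    "simulate": _simulate,
    "train": _train,
    "predict": _predict,
    "bag": _bag,
    "longitudinal": _longitudinal,
    "associate": _associate,
}


def pipeline_config_to_yaml(config: PipelineConfig, path: str | Path) -> None:
    """Persist a pipeline configuration (generator arrays included) to YAML."""
    raw = dataclasses.asdict(config)
    gen = raw["generator"]
    for key in ("feature_intercepts", "age_slopes", "sex_effects", "feature_noise_sd"):
        gen[key] = [float(v) for v in gen[key]]
    for key in ("train_age_range", "test_age_range"):
        gen[key] = list(gen[key])
    raw["regions"] = list(raw["regions"])
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
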