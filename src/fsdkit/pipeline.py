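"""End-to-end pipeline: simulate -> classify -> tables -> regress, with a
run manifest for reproducibility.

Each stage writes plain CSV/JSON outputs and reports its effective n
(complete-case counts mirror how the analyses filter). Re-running the
same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .catalog import SymptomCatalog
from .classify import classifications_to_frame, classify, tabulate_system_counts
from .cohort import (CohortSchema, DiseaseCatalog, apply_exclusions,
                     load_cohort, records_to_frame, save_cohort)
from .elastic_net import (build_design_matrix, fit_caseness_model,
                          make_lambda_grid, report_model)
from .errors import ConfigError
from .group_stats import build_comparison_tables
from .specifiers import build_profile, profiles_to_frame, syndrome_count_table
from .symptoms import extract_all, symptoms_to_frame
from .synth import GeneratorConfig, generate

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int
    software_version: str
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    effective_n: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def classify_records(records, catalog: Optional[SymptomCatalog] = None):
    """Run symptom extraction + classification over a cohort.

    Returns (symptoms_by_respondent, classifications) in input order.
    """
    catalog = catalog or SymptomCatalog.default()
    symptoms_by_id = {r.respondent_id: extract_all(r, catalog) for r in records}
    classifications = [classify(symptoms_by_id[r.respondent_id],
                                respondent_id=r.respondent_id)
                       for r in records]
    return symptoms_by_id, classifications


def analysis_frame(records, classifications, profiles=None) -> pd.DataFrame:
    """Covariate frame with subgroup (and optional specifier) columns,
    ready for the comparison-table builders."""
    frame = records_to_frame(records)
    cls = classifications_to_frame(classifications)
    frame = frame.merge(cls[["respondent_id", "is_case", "subgroup",
                             "n_symptoms", "n_systems"]], on="respondent_id")
    if profiles is not None:
        frame = frame.merge(profiles_to_frame(profiles), on="respondent_id")
    return frame


def run_pipeline(config: dict, out_dir, command: str = "pipeline") -> RunManifest:
    """Run the configured stages; any stage error aborts with a
    stage-named message."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(command=command, config_hash=_config_hash(config),
                           seed=seed, software_version=__version__)

    # --- simulate or load ----------------------------------------------
    try:
        if "simulate" in config:
            sim_cfg = dict(config["simulate"])
            sim_cfg.setdefault("seed", seed)
            records, truth = generate(GeneratorConfig(**sim_cfg))
            cohort_path = out_dir / "cohort.csv"
            save_cohort(records, cohort_path)
            truth.to_csv(out_dir / "truth.csv", index=False)
            manifest.outputs["cohort"] = str(cohort_path)
            manifest.outputs["truth"] = str(out_dir / "truth.csv")
        elif "cohort" in config:
            schema = (CohortSchema.from_file(config["schema"])
                      if "schema" in config else None)
            records = load_cohort(config["cohort"], schema)
            manifest.inputs["cohort"] = str(config["cohort"])
        else:
            raise ConfigError("config needs a 'simulate' or 'cohort' section")
    except Exception as exc:
        raise ConfigError(f"stage simulate/load failed: {exc}") from exc

    included, excluded = apply_exclusions(records)
    manifest.effective_n["loaded"] = len(records)
    manifest.effective_n["included"] = len(included)
    manifest.effective_n["excluded"] = len(excluded)
    log.info("exclusions: %d included, %d excluded", len(included), len(excluded))

    # --- classify -------------------------------------------------------
    try:
        catalog = (SymptomCatalog.from_file(config["catalog"])
                   if "catalog" in config else SymptomCatalog.default())
        symptoms_by_id, classifications = classify_records(included, catalog)
    except Exception as exc:
        raise ConfigError(f"stage classify failed: {exc}") from exc

    all_symptoms = [s for rid in symptoms_by_id for s in symptoms_by_id[rid]]
    symptoms_to_frame(all_symptoms).to_csv(out_dir / "symptoms.csv", index=False)
    classifications_to_frame(classifications).to_csv(
        out_dir / "classifications.csv", index=False)
    tabulate_system_counts(classifications).to_csv(
        out_dir / "system_counts.csv", index=False)
    manifest.outputs["symptoms"] = str(out_dir / "symptoms.csv")
    manifest.outputs["classifications"] = str(out_dir / "classifications.csv")
    manifest.outputs["system_counts"] = str(out_dir / "system_counts.csv")
    manifest.effective_n["cases"] = sum(c.is_case for c in classifications)

    # --- specifiers + tables ---------------------------------------------
    try:
        disease_catalog = (DiseaseCatalog.from_file(config["diseases"])
                           if "diseases" in config else DiseaseCatalog.default())
        by_id = {c.respondent_id: c for c in classifications}
        profiles = [build_profile(r, by_id[r.respondent_id], disease_catalog)
                    for r in included]
        profiles_to_frame(profiles).to_csv(out_dir / "profiles.csv", index=False)
        syndrome_count_table(classifications, profiles).to_csv(
            out_dir / "syndrome_counts.csv", index=False)
        frame = analysis_frame(included, classifications, profiles)
        tables = build_comparison_tables(frame)
        tables["continuous"].to_csv(out_dir / "tables_continuous.csv", index=False)
        tables["categorical"].to_csv(out_dir / "tables_categorical.csv", index=False)
    except Exception as exc:
        raise ConfigError(f"stage tables failed: {exc}") from exc
    manifest.outputs["profiles"] = str(out_dir / "profiles.csv")
    manifest.outputs["syndrome_counts"] = str(out_dir / "syndrome_counts.csv")
    manifest.outputs["tables_continuous"] = str(out_dir / "tables_continuous.csv")
    manifest.outputs["tables_categorical"] = str(out_dir / "tables_categorical.csv")

    # --- regression (optional) -------------------------------------------
    if config.get("regress", {}).get("enabled", False):
        try:
            reg_cfg = config["regress"]
            X, y = build_design_matrix(included, classifications, disease_catalog)
            manifest.effective_n["regression"] = len(X)
            lambda_grid = make_lambda_grid(
                X.to_numpy(), y.to_numpy(),
                n_lambda=int(reg_cfg.get("n_lambda", 15)))
            fit = fit_caseness_model(
                X, y, alpha_grid=tuple(reg_cfg.get("alpha_grid", (0.0, 0.5, 1.0))),
                lambda_grid=lambda_grid, seed=seed,
                selection_rule=reg_cfg.get("selection_rule", "lambda_1se"))
            model = {
                "features": list(fit.feature_names),
                "intercept": fit.intercept,
                "coefficients": fit.coefficients.tolist(),
                "odds_ratios": fit.odds_ratios.tolist(),
                "alpha": fit.alpha, "lambda": fit.lambda_,
                "selection_rule": fit.selection_rule,
                "auc_test": fit.auc_test, "seed": seed,
                "cv_path": fit.cv.path.to_dict("records"),
            }
            with open(out_dir / "model.json", "w") as fh:
                json.dump(model, fh, indent=2)
                fh.write("\n")
            report_model(fit).to_csv(out_dir / "model_report.csv", index=False)
        except Exception as exc:
            raise ConfigError(f"stage regress failed: {exc}") from exc
        manifest.outputs["model"] = str(out_dir / "model.json")
        manifest.outputs["model_report"] = str(out_dir / "model_report.csv")

    manifest.write(out_dir / "manifest.json")
    manifest.outputs["manifest"] = str(out_dir / "manifest.json")
    return manifest
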