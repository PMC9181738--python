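"""End-to-end pipeline runs, flowchart assembly and the run manifest.

``run_pipeline`` chains the stages — cohort (synthetic or CSV), study
filters, train/validation split, paired model development, evaluation and
benchmarking — writing every artifact plus a manifest (config hash, seed,
library versions) so a run can be reproduced byte-for-byte.  All randomness
descends from one root seed through named per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmarking import (BootstrapConfig, benchmark_centers,
                           benchmarks_to_frame, default_subgroups,
                           export_forest)
from .development import SelectionConfig
from .evaluation import calibration_belt, roc_auc
from .pipeline import (FilterReport, apply_all_filters, outcome_to_binary,
                       split_train_validation)
from .study import develop_dual_models, prepare_model_frame
from .synthetic import SyntheticConfig, generate_cohort, read_cohort

logger = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    return (int(root_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def flowchart_report(reports) -> FilterReport:
    """Chain stage-wise filter reports into one flowchart; validates counts."""
    out = FilterReport()
    for r in reports:
        out.extend(r)
    return out


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one cohort source)."""

    outdir: str = "dualbench_run"
    seed: int = 0
    input_path: str | None = None
    synthetic: dict | None = None
    completeness_threshold: float = 0.10
    split_fraction: float = 0.85
    selection: dict = field(default_factory=dict)
    bootstrap_B: int = 1000
    stratified_bootstrap: bool = False
    subgroups: list[str] | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of input_path / synthetic must be given")

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(**self.selection)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _evaluate(model, df, y, devel: str) -> dict:
    p = model.predict_risk(df)
    roc = roc_auc(p, y)
    res = {
        "auc": roc.auc,
        "n_events": roc.n_events,
        "n_nonevents": roc.n_nonevents,
        "_roc": roc, "_belt": None,
    }
    try:
        belt = calibration_belt(p, y, devel=devel)
    except ValueError as exc:
        # e.g. an intercept-only model predicts one constant probability
        res.update(calibration_degree=None, calibration_statistic=None,
                   calibration_p_value=None, calibration_note=str(exc))
        logger.warning("calibration belt unavailable: %s", exc)
    else:
        res.update(calibration_degree=belt.degree,
                   calibration_statistic=belt.statistic,
                   calibration_p_value=belt.p_value)
        res["_belt"] = belt
    return res


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full study pipeline; returns the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "dualbench",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "outputs": [],
    }

    def save_csv(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, index=False, **kw)
        manifest["outputs"].append(name)

    # --- cohort ----------------------------------------------------------
    stage = "cohort"
    try:
        if config.synthetic is not None:
            syn = dict(config.synthetic)
            syn.setdefault("seed", stage_seed(config.seed, "synthetic"))
            scfg = SyntheticConfig.from_dict(syn)
            cohort, truth = generate_cohort(scfg)
            save_csv(cohort, "cohort.csv")
            truth.to_json(out / "true_values.json")
            manifest["outputs"].append("true_values.json")
        else:
            cohort = read_cohort(config.input_path)
            truth = None

        # --- filters -----------------------------------------------------
        stage = "filters"
        analysed, report = apply_all_filters(cohort, config.completeness_threshold)
        (out / "flowchart.json").write_text(report.to_json())
        (out / "flowchart.txt").write_text(report.to_text() + "\n")
        manifest["outputs"] += ["flowchart.json", "flowchart.txt"]
        save_csv(analysed, "analysis_cohort.csv")

        # --- split and model development ---------------------------------
        stage = "split"
        analysed = prepare_model_frame(analysed).reset_index(drop=True)
        split = split_train_validation(analysed, config.split_fraction,
                                       stage_seed(config.seed, "split"))
        train = analysed.loc[list(split.training_ids)]
        valid = analysed.loc[list(split.validation_ids)]
        (out / "split.json").write_text(json.dumps({
            "fraction": split.fraction, "seed": split.seed,
            "n_training": len(train), "n_validation": len(valid)}, indent=1))
        manifest["outputs"].append("split.json")

        stage = "model_development"
        sel = config.selection_config()
        y_train = outcome_to_binary(train)
        pre_model, pre_rep, post_model, post_rep = develop_dual_models(
            train, y_train, config=sel)
        pre_model.save(out / "model_pre.json")
        post_model.save(out / "model_post.json")
        (out / "development_reports.json").write_text(json.dumps(
            {"pre": pre_rep.to_dict(), "post": post_rep.to_dict()},
            indent=1, default=str))
        manifest["outputs"] += ["model_pre.json", "model_post.json",
                                "development_reports.json"]

        # --- evaluation ---------------------------------------------------
        stage = "evaluation"
        y_valid = outcome_to_binary(valid)
        evaluation = {}
        for mname, model in (("pre", pre_model), ("post", post_model)):
            for dname, df, yy, devel in (("training", train, y_train, "internal"),
                                         ("validation", valid, y_valid, "external")):
                res = _evaluate(model, df, yy, devel)
                save_csv(res.pop("_roc").curve_frame(), f"roc_{mname}_{dname}.csv")
                belt = res.pop("_belt")
                if belt is not None:
                    save_csv(belt.band_frame(),
                             f"calibration_belt_{mname}_{dname}.csv")
                evaluation[f"{mname}_{dname}"] = res
        (out / "evaluation.json").write_text(json.dumps(evaluation, indent=1))
        manifest["outputs"].append("evaluation.json")

        # --- benchmarking -------------------------------------------------
        stage = "benchmarking"
        sgs = default_subgroups()
        if config.subgroups is not None:
            sgs = [s for s in sgs if s.name in config.subgroups]
        boot = BootstrapConfig(B=config.bootstrap_B,
                               seed=stage_seed(config.seed, "bootstrap"),
                               stratify_by_center=config.stratified_bootstrap)
        benchmarks = benchmark_centers(analysed, pre_model, post_model,
                                       subgroups=sgs, boot=boot)
        save_csv(benchmarks_to_frame(benchmarks), "benchmarks.csv")
        forest = export_forest(benchmarks)
        path = out / "forest.tsv"
        forest.to_csv(path, sep="\t", index=False)
        manifest["outputs"].append("forest.tsv")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed in stage {stage!r} "
            f"(cohort rows at failure: {len(cohort) if 'cohort' in dict(locals()) else 'n/a'})"
        ) from exc

    manifest["flowchart"] = json.loads(report.to_json())
    manifest["evaluation"] = evaluation
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
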