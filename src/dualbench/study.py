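"""Variable dictionaries and the paired-model study protocol.

This module knows the cohort schema: which columns are candidate predictors
for the pre-operative stage (demographics, comorbidity classes, procedure
flags) and which for the post-operative stage (ICU-admission severity
covariates), and in what clinical order categorical levels sit.  It exposes
one call that develops the paired models exactly as the protocol demands:
the pre-operative model by screening + stepwise selection, the
post-operative model by stepwise selection over post-operative candidates
with every pre-operative term forced in.
"""

from __future__ import annotations

import pandas as pd

from .development import (SelectionConfig, VariableDef, build_postop_model,
                          develop_model)
from .synthetic import SEVERITY_PREFIX


def preop_variable_defs() -> list[VariableDef]:
    """Candidate pre-operative variables of the synthetic cohort schema."""
    return [
        VariableDef("age", "continuous"),
        VariableDef("creat_clear", "continuous"),
        VariableDef("sex_male", "binary"),
        VariableDef("nyha", "categorical", ("I", "II-III", "IV"), "I"),
        VariableDef("ef_class", "categorical", (">50", "30-50", "<30"), ">50"),
        VariableDef("urgency", "categorical",
                    ("elective", "deferred", "emergent", "salvage"), "elective"),
        VariableDef("cabg", "binary"),
        VariableDef("avs", "binary"),
        VariableDef("mvp", "binary"),
        VariableDef("mvr", "binary"),
        VariableDef("aorta", "binary"),
        VariableDef("redo", "binary"),
    ]


def postop_variable_defs(cohort: pd.DataFrame) -> list[VariableDef]:
    """Post-operative candidates: the ICU-admission severity columns."""
    cols = sorted(c for c in cohort.columns if c.startswith(SEVERITY_PREFIX))
    return [VariableDef(c, "continuous") for c in cols]


def prepare_model_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add derived modelling columns (0/1 sex flag) without mutating input."""
    df = cohort.copy()
    df["sex_male"] = (df["sex"] == "M").astype(int)
    return df


def develop_dual_models(train: pd.DataFrame, y, *,
                        config: SelectionConfig = SelectionConfig()):
    """Develop the pre- and post-operative models on the training set.

    Returns ``(pre_model, pre_report, post_model, post_report)``.
    """
    pre_model, pre_report = develop_model(
        train, y, preop_variable_defs(), config, stage="pre")
    post_model, post_report = build_postop_model(
        train, y, pre_model, postop_variable_defs(train), config)
    return pre_model, pre_report, post_model, post_report
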