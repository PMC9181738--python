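"""Cohort inclusion/exclusion rules, completeness filtering and data split.

The filters implement the study protocol in a fixed, documented order so the
resulting flowchart is comparable across runs:

1. adults only (age strictly over 16 years)
2. exclusion of Type-B aortic dissection repairs
3. exclusion of patients admitted to the ICU before cardiac surgery
4. first ICU admission only (re-admissions dropped)
5. month-level completeness rule: every record of a (center, month) stratum
   is removed when the stratum's fraction of incomplete records strictly
   exceeds the threshold (default 10%)
6. exclusion of records with a missing hospital outcome

Every filter returns the surviving cohort plus a :class:`FilterReport` whose
counts satisfy in = excluded + out, so composed reports chain into a
flowchart table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column is absent; the message names it."""


@dataclass(frozen=True)
class FilterStep:
    name: str
    n_in: int
    n_excluded: int
    n_out: int

    def __post_init__(self):
        if self.n_in != self.n_excluded + self.n_out:
            raise ValueError(
                f"filter {self.name!r}: {self.n_in} != "
                f"{self.n_excluded} + {self.n_out}"
            )


@dataclass
class FilterReport:
    """Ordered record of filter steps; chains into a study flowchart."""

    steps: list[FilterStep] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        self.steps.append(FilterStep(name, n_in, n_in - n_out, n_out))

    def extend(self, other: "FilterReport") -> None:
        for s in other.steps:
            if self.steps and s.n_in != self.steps[-1].n_out:
                raise ValueError(
                    f"flowchart breach: step {s.name!r} starts at {s.n_in} "
                    f"but previous step left {self.steps[-1].n_out}"
                )
            self.steps.append(s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_in, s.n_excluded, s.n_out) for s in self.steps],
            columns=["filter", "records_in", "records_excluded", "records_out"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_frame().to_dict(orient="records"), indent=2)

    def to_text(self) -> str:
        lines = []
        for s in self.steps:
            lines.append(f"{s.name}: {s.n_in} -> {s.n_out} "
                         f"(excluded {s.n_excluded})")
        return "\n".join(lines)


def _require(cohort: pd.DataFrame, columns) -> None:
    for c in columns:
        if c not in cohort.columns:
            raise SchemaError(f"required column {c!r} missing from cohort")


def apply_inclusion_exclusion(cohort: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the eligibility rules in fixed order; see module docstring."""
    _require(cohort, ["age", "typeB_dissection_repair",
                      "admitted_to_icu_before_surgery", "readmission_index"])
    report = FilterReport()

    out = cohort[cohort["age"] > 16]
    report.add("age over 16 years", len(cohort), len(out))

    prev, out = out, out[out["typeB_dissection_repair"] == 0]
    report.add("no Type-B dissection repair", len(prev), len(out))

    prev, out = out, out[out["admitted_to_icu_before_surgery"] == 0]
    report.add("not in ICU before surgery", len(prev), len(out))

    prev, out = out, out[out["readmission_index"] == 1]
    report.add("first ICU admission only", len(prev), len(out))

    return out.copy(), report


def month_completeness_filter(
    cohort: pd.DataFrame, threshold: float = 0.10
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop whole (center, month) strata with > ``threshold`` incomplete records.

    The comparison is strict: a stratum at exactly the threshold is retained.
    Complete records in a failing stratum are removed with it — the rule
    targets site-level data quality, not individual records.
    """
    _require(cohort, ["complete", "center_id", "admission_year", "admission_month"])
    report = FilterReport()
    if len(cohort) == 0:
        report.add("month completeness (<=10% incomplete)", 0, 0)
        return cohort.copy(), report
    keys = ["center_id", "admission_year", "admission_month"]
    frac = 1.0 - cohort.groupby(keys)["complete"].transform("mean")
    out = cohort[frac <= threshold + 1e-12]
    report.add(f"month completeness (<={threshold:.0%} incomplete)",
               len(cohort), len(out))
    return out.copy(), report


def exclude_missing_outcome(cohort: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Remove records whose hospital outcome is missing."""
    _require(cohort, ["hospital_outcome"])
    report = FilterReport()
    known = cohort["hospital_outcome"].isin(["alive", "dead"])
    out = cohort[known]
    report.add("non-missing hospital outcome", len(cohort), len(out))
    return out.copy(), report


def apply_all_filters(
    cohort: pd.DataFrame, completeness_threshold: float = 0.10
) -> tuple[pd.DataFrame, FilterReport]:
    """Compose all study filters; returns the analysis cohort and the flowchart."""
    out, report = apply_inclusion_exclusion(cohort)
    out, r2 = month_completeness_filter(out, completeness_threshold)
    report.extend(r2)
    out, r3 = exclude_missing_outcome(out)
    report.extend(r3)
    return out, report


@dataclass(frozen=True)
class SplitResult:
    training_ids: tuple
    validation_ids: tuple
    fraction: float
    seed: int


def split_train_validation(
    cohort: pd.DataFrame, fraction: float = 0.85, seed: int = 0
) -> SplitResult:
    """Simple unstratified random split into training and validation rows.

    The training size is ``round(fraction * N)`` (banker's rounding); the
    split is reproducible under ``seed``.  Row labels of ``cohort.index``
    identify membership.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if len(cohort) < 2:
        raise ValueError("cohort must contain at least 2 records to split")
    n = len(cohort)
    n_train = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    idx = cohort.index.to_numpy()
    train = np.sort(idx[perm[:n_train]])
    valid = np.sort(idx[perm[n_train:]])
    return SplitResult(tuple(train.tolist()), tuple(valid.tolist()),
                       fraction, seed)


def outcome_to_binary(cohort: pd.DataFrame) -> np.ndarray:
    """Map hospital_outcome to 0/1; raises if missing outcomes remain."""
    oc = cohort["hospital_outcome"]
    if not oc.isin(["alive", "dead"]).all():
        raise ValueError("cohort still contains missing outcomes; filter first")
    return (oc == "dead").to_numpy(dtype=float)
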