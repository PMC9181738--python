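"""Model terms and design-matrix construction.

A fitted risk model is described by a list of terms; each term knows how to
expand a cohort table into design columns.  Three kinds exist:

* ``LinearTerm`` — a single numeric column (also used for 0/1 flags).
* ``PiecewiseTerm`` — a continuous variable with a piecewise-linear effect on
  the logit, encoded as a hinge basis ``[x, (x-k1)+, (x-k2)+, ...]`` so the
  fitted curve is continuous at the knots.  Zero knots reduce to a plain
  linear term.
* ``CategoricalTerm`` — a categorical variable with (possibly merged) level
  groups, dummy-coded against a reference group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LinearTerm:
    variable: str

    @property
    def name(self) -> str:
        return self.variable

    def columns(self) -> list[str]:
        return [self.variable]

    def build(self, df: pd.DataFrame) -> np.ndarray:
        return df[self.variable].to_numpy(dtype=float)[:, None]

    def to_dict(self) -> dict:
        return {"kind": "linear", "variable": self.variable}


@dataclass(frozen=True)
class PiecewiseTerm:
    variable: str
    knots: tuple[float, ...] = ()

    def __post_init__(self):
        if list(self.knots) != sorted(set(self.knots)):
            raise ValueError(f"knots for {self.variable} must be strictly increasing")

    @property
    def name(self) -> str:
        return self.variable

    def columns(self) -> list[str]:
        return [self.variable] + [f"{self.variable}>{k:g}" for k in self.knots]

    def build(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.variable].to_numpy(dtype=float)
        cols = [x] + [np.maximum(x - k, 0.0) for k in self.knots]
        return np.column_stack(cols)

    def segment_slopes(self, coef: np.ndarray) -> list[float]:
        """Per-segment slopes implied by hinge-basis coefficients."""
        return list(np.cumsum(coef))

    def to_dict(self) -> dict:
        return {"kind": "piecewise", "variable": self.variable,
                "knots": list(self.knots)}


@dataclass(frozen=True)
class CategoricalTerm:
    """Dummy coding of level groups against a reference group.

    ``groups`` maps each raw level to a group label; levels sharing a label
    have been merged and share one coefficient.  The reference group gets no
    column.
    """

    variable: str
    groups: tuple[tuple[str, str], ...]  # (level, group) pairs, order = level order
    reference: str

    @property
    def name(self) -> str:
        return self.variable

    def group_map(self) -> dict[str, str]:
        return dict(self.groups)

    def group_labels(self) -> list[str]:
        """Non-reference group labels in first-appearance order."""
        seen: list[str] = []
        for _, g in self.groups:
            if g != self.reference and g not in seen:
                seen.append(g)
        return seen

    def columns(self) -> list[str]:
        return [f"{self.variable}={g}" for g in self.group_labels()]

    def build(self, df: pd.DataFrame) -> np.ndarray:
        gm = self.group_map()
        vals = df[self.variable].astype(str).map(gm)
        if vals.isna().any():
            unknown = sorted(set(df[self.variable].astype(str)) - set(gm))
            raise ValueError(f"unknown levels for {self.variable}: {unknown}")
        mat = np.column_stack(
            [(vals == g).to_numpy(dtype=float) for g in self.group_labels()]
        )
        return mat

    def to_dict(self) -> dict:
        return {"kind": "categorical", "variable": self.variable,
                "groups": [list(p) for p in self.groups],
                "reference": self.reference}


def term_from_dict(d: dict):
    kind = d["kind"]
    if kind == "linear":
        return LinearTerm(d["variable"])
    if kind == "piecewise":
        return PiecewiseTerm(d["variable"], tuple(d["knots"]))
    if kind == "categorical":
        return CategoricalTerm(d["variable"],
                               tuple(tuple(p) for p in d["groups"]),
                               d["reference"])
    raise ValueError(f"unknown term kind {kind!r}")


def categorical_from_levels(variable: str, levels, reference=None) -> CategoricalTerm:
    levels = [str(l) for l in levels]
    ref = str(reference) if reference is not None else levels[0]
    return CategoricalTerm(variable, tuple((l, l) for l in levels), ref)


@dataclass
class DesignInfo:
    """Design matrix with intercept plus provenance of every column."""

    matrix: np.ndarray
    column_names: list[str] = field(default_factory=list)
    term_slices: dict[str, slice] = field(default_factory=dict)


def build_design(df: pd.DataFrame, terms, intercept: bool = True) -> DesignInfo:
    blocks = []
    names: list[str] = []
    slices: dict[str, slice] = {}
    if intercept:
        blocks.append(np.ones((len(df), 1)))
        names.append("(intercept)")
    for t in terms:
        start = sum(b.shape[1] for b in blocks)
        blocks.append(t.build(df))
        names.extend(t.columns())
        slices[t.name] = slice(start, start + len(t.columns()))
    mat = np.hstack(blocks) if blocks else np.empty((len(df), 0))
    return DesignInfo(matrix=mat, column_names=names, term_slices=slices)
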