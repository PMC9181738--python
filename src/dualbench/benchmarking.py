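"""Center and subgroup benchmarking of intraoperative performance.

For every center (and center × subgroup) the expected numbers of deaths
under the pre-operative and post-operative models, e_pre and e_post, are the
sums of the models' predicted probabilities over the unit's patients; the
intraoperative performance statistic is the relative difference

    d = (e_post - e_pre) / e_pre .

Positive d means predicted mortality increased across surgery.  The 95%
confidence interval is a percentile bootstrap: the whole cohort is resampled
with replacement, both models are re-estimated on each resample (term
structure fixed, coefficients refit), and d is recomputed per unit; the CI
is the 2.5th/97.5th percentile of the replicate values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._glm import GlmError, fit_logistic_array
from .pipeline import outcome_to_binary
from .terms import build_design

logger = logging.getLogger(__name__)


def expected_deaths(probabilities) -> float:
    """Expected number of deaths: the sum of predicted probabilities."""
    p = np.asarray(probabilities, dtype=float)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(p.sum())


def relative_difference(e_pre: float, e_post: float) -> float:
    """d = (e_post - e_pre) / e_pre; requires e_pre > 0."""
    if e_pre <= 0.0:
        raise ZeroDivisionError("relative difference undefined for e_pre <= 0")
    return (e_post - e_pre) / e_pre


@dataclass(frozen=True)
class SubgroupDef:
    """Named deterministic predicate over cohort rows."""

    name: str
    predicate: callable

    def mask(self, cohort: pd.DataFrame) -> np.ndarray:
        m = np.asarray(self.predicate(cohort), dtype=bool)
        if m.shape != (len(cohort),):
            raise ValueError(f"subgroup {self.name!r} predicate returned "
                             "a mask of the wrong length")
        return m


def default_subgroups() -> list[SubgroupDef]:
    """Urgency and procedure subgroups of the study design."""
    return [
        SubgroupDef("elective", lambda df: df["urgency"] == "elective"),
        SubgroupDef("non-elective", lambda df: df["urgency"] != "elective"),
        SubgroupDef("AVS", lambda df: df["avs"] == 1),
        SubgroupDef("MVS", lambda df: (df["mvp"] == 1) | (df["mvr"] == 1)),
        SubgroupDef("MVP", lambda df: df["mvp"] == 1),
        SubgroupDef("MVR", lambda df: df["mvr"] == 1),
        SubgroupDef("CABG", lambda df: df["cabg"] == 1),
        SubgroupDef("AA", lambda df: df["aorta"] == 1),
    ]


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings; B defaults to the protocol's 1000 resamples.

    ``refit_policy='coefficients'`` (default) refits both models' coefficients
    on each resample with the term structure fixed; ``'reselect'`` repeats the
    whole variable-selection protocol per replicate (orders of magnitude
    slower and less stable; requires passing ``reselect`` to
    :func:`benchmark_centers`).
    """

    B: int = 1000
    seed: int = 0
    stratify_by_center: bool = False
    min_usable_fraction: float = 0.80
    refit_policy: str = "coefficients"

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.refit_policy not in ("coefficients", "reselect"):
            raise ValueError("refit_policy must be 'coefficients' or 'reselect'")


@dataclass
class CenterBenchmark:
    unit: str
    center: str
    subgroup: str  # "overall" or subgroup name
    n: int
    e_pre: float
    e_post: float
    d: float
    ci_low: float
    ci_high: float
    B: int
    usable_replicates: int


def _refit_eta(X: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    try:
        fit = fit_logistic_array(X, y, check_rank=False, allow_boundary=True)
    except GlmError:
        return None
    return X @ fit.coef


def benchmark_centers(cohort: pd.DataFrame, preop_model, postop_model,
                      subgroups=None, boot: BootstrapConfig = BootstrapConfig(),
                      reselect=None) -> list[CenterBenchmark]:
    """Benchmark every center overall and within each subgroup.

    Both models must already be fitted; each bootstrap replicate refits
    their coefficients (fixed term structure) on a resample of the whole
    cohort and recomputes d per unit.  Replicates in which a unit has zero
    resampled e_pre (or no patients) contribute a missing value; a CI is
    reported only when at least ``boot.min_usable_fraction`` of replicates
    were usable for that unit.

    With ``boot.refit_policy == 'reselect'``, supply ``reselect(df, y) ->
    (pre_model, post_model)`` (typically the full development protocol); it
    is re-run on every resample.
    """
    if boot.refit_policy == "reselect" and reselect is None:
        raise ValueError("refit_policy='reselect' needs a reselect callable")
    if subgroups is None:
        subgroups = default_subgroups()
    y = outcome_to_binary(cohort)
    n = len(cohort)
    Xpre = build_design(cohort, preop_model.terms_).matrix
    Xpost = build_design(cohort, postop_model.terms_).matrix
    p_pre = expit(Xpre @ preop_model.coef_.to_numpy())
    p_post = expit(Xpost @ postop_model.coef_.to_numpy())

    centers = sorted(cohort["center_id"].astype(str).unique())
    center_arr = cohort["center_id"].astype(str).to_numpy()
    units = []  # (unit label, center, subgroup name, bool mask)
    for c in centers:
        cmask = center_arr == c
        units.append((c, c, "overall", cmask))
        for sg in subgroups:
            m = cmask & sg.mask(cohort)
            if m.sum() == 0:
                warnings.warn(f"unit {c}/{sg.name} has no patients; omitted",
                              stacklevel=2)
                continue
            units.append((f"{c}/{sg.name}", c, sg.name, m))

    point = {}
    for label, c, sgname, m in units:
        e1, e2 = expected_deaths(p_pre[m]), expected_deaths(p_post[m])
        d = relative_difference(e1, e2) if e1 > 0 else float("nan")
        point[label] = (int(m.sum()), e1, e2, d)

    rng = np.random.default_rng(boot.seed)
    reps = {label: [] for label, *_ in units}
    masks = {label: m for label, _, _, m in units}
    center_idx = {c: np.flatnonzero(center_arr == c) for c in centers}
    for _b in range(boot.B):
        if boot.stratify_by_center:
            idx = np.concatenate([
                rng.choice(ix, size=ix.size, replace=True) for ix in
                (center_idx[c] for c in centers)
            ])
        else:
            idx = rng.integers(0, n, n)
        if boot.refit_policy == "reselect":
            sub = cohort.iloc[idx].reset_index(drop=True)
            try:
                m_pre, m_post = reselect(sub, y[idx])
                pp = m_pre.predict_risk(sub)
                qq = m_post.predict_risk(sub)
            except GlmError:
                for label in reps:
                    reps[label].append(np.nan)
                continue
        else:
            eta_pre = _refit_eta(Xpre[idx], y[idx])
            eta_post = _refit_eta(Xpost[idx], y[idx])
            if eta_pre is None or eta_post is None:
                for label in reps:
                    reps[label].append(np.nan)
                continue
            pp, qq = expit(eta_pre), expit(eta_post)
        for label, m in masks.items():
            sel = m[idx]
            e1 = pp[sel].sum()
            if e1 <= 0.0:
                reps[label].append(np.nan)
                continue
            reps[label].append((qq[sel].sum() - e1) / e1)

    out = []
    for label, c, sgname, m in units:
        n_u, e1, e2, d = point[label]
        vals = np.asarray(reps[label], dtype=float)
        usable = int(np.isfinite(vals).sum())
        if usable < boot.min_usable_fraction * boot.B:
            logger.warning("unit %s: only %d/%d usable bootstrap replicates; "
                           "CI withheld", label, usable, boot.B)
            lo = hi = float("nan")
        else:
            lo, hi = np.nanpercentile(vals, [2.5, 97.5])
        if usable < boot.B:
            logger.info("unit %s: %d replicates dropped (zero e_pre)",
                        label, boot.B - usable)
        out.append(CenterBenchmark(label, c, sgname, n_u, e1, e2, d,
                                   float(lo), float(hi), boot.B, usable))
    return out


def benchmarks_to_frame(benchmarks) -> pd.DataFrame:
    return pd.DataFrame([vars(b) for b in benchmarks])


def export_forest(benchmarks, subgroup: str | None = "overall") -> pd.DataFrame:
    """Plot-ready forest table sorted ascending in d.

    ``subgroup=None`` keeps all units; otherwise only the named subgroup
    (default the per-center overall rows).
    """
    if not benchmarks:
        raise ValueError("no benchmarks to export")
    df = benchmarks_to_frame(benchmarks)
    if subgroup is not None:
        df = df[df["subgroup"] == subgroup]
    df = df[["unit", "d", "ci_low", "ci_high", "n", "e_pre", "e_post"]]
    return df.sort_values("d", kind="mergesort").reset_index(drop=True)
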