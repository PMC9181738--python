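"""Risk-model development protocol.

The pre-operative model is built from variables known before surgery; the
post-operative model is built from variables measured at ICU admission with
every pre-operative term forced in regardless of significance, so the pair
stays clinically comparable.  The protocol is:

1. rare-variable screening — a binary variable or categorical level whose
   exposed subgroup has fewer than ``min_patients`` records or fewer than
   ``min_events`` deaths is removed (rare categorical levels are merged into
   the neighbouring level of the declared order);
2. bivariate screening — single-variable logistic fits; candidates with a
   likelihood-ratio p-value above ``p_screen`` (0.25) are discarded;
3. piecewise-linearisation of continuous candidates (see ``transforms``);
4. alternating forward/backward stepwise selection at ``p_select`` (0.01),
   deterministic under ties (smallest p, then lexical term name);
5. merging of categorical levels whose odds ratios are not statistically
   different, constrained to clinically contiguous level groups.

All hypothesis tests are likelihood-ratio tests except the level-merge
contrasts, which are Wald tests on the fitted covariance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from ._glm import (GlmError, SeparationError, fit_logistic_array, lr_test,
                   LogisticFit)
from .terms import (CategoricalTerm, LinearTerm, PiecewiseTerm, build_design,
                    categorical_from_levels, term_from_dict)
from .transforms import PiecewiseLogitTransformer


class StepwiseOscillationError(RuntimeError):
    """Forward/backward selection cycled beyond the iteration cap."""

    def __init__(self, cycling_terms):
        self.cycling_terms = sorted(cycling_terms)
        super().__init__(
            "stepwise selection oscillated; cycling terms: "
            + ", ".join(self.cycling_terms)
        )


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the development protocol (defaults per the study design)."""

    min_patients: int = 100
    min_events: int = 30
    p_screen: float = 0.25
    p_select: float = 0.01
    max_knots: int = 2
    level_merge_p: float = 0.05
    linearity_alpha: float = 0.05
    max_cycles: int = 20

    def __post_init__(self):
        if not (0.0 < self.p_select < self.p_screen < 1.0):
            raise ValueError("require 0 < p_select < p_screen < 1")
        if min(self.min_patients, self.min_events, self.max_cycles) <= 0:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class VariableDef:
    """Entry of the variable dictionary.

    ``vtype`` is one of ``binary`` (0/1 column), ``categorical`` (string
    levels in clinical order) or ``continuous``.  ``merge_groups`` optionally
    lists sets of levels allowed to merge; by default any contiguous block
    of the declared level order may merge.
    """

    name: str
    vtype: str
    levels: tuple[str, ...] = ()
    reference: str | None = None
    merge_groups: tuple[tuple[str, ...], ...] = ()
    level_map: tuple[tuple[str, str], ...] = ()  # raw level -> group label

    def __post_init__(self):
        if self.vtype not in ("binary", "categorical", "continuous"):
            raise ValueError(f"{self.name}: unknown vtype {self.vtype!r}")
        if self.vtype == "categorical" and len(self.levels) < 2:
            raise ValueError(f"{self.name}: categorical needs >= 2 levels")


def fit_logistic(X, y, **kw) -> LogisticFit:
    """Maximum-likelihood logistic regression (see ``dualbench._glm``)."""
    return fit_logistic_array(X, y, **kw)


def fit_terms(df: pd.DataFrame, terms, y) -> tuple:
    """Fit a logistic model for a term list; returns (DesignInfo, LogisticFit)."""
    info = build_design(df, terms)
    fit = fit_logistic_array(info.matrix, y, column_names=info.column_names)
    return info, fit


# ---------------------------------------------------------------------------
# screening


def screen_rare_variables(cohort: pd.DataFrame, variables, y,
                          config: SelectionConfig = SelectionConfig()):
    """Remove rare binary variables and merge rare categorical levels.

    Returns ``(kept, dropped)`` where ``kept`` is a list of
    :class:`VariableDef` (categoricals possibly with reduced level lists)
    and ``dropped`` maps variable names to the reason.
    """
    y = np.asarray(y, dtype=float)
    kept, dropped = [], {}
    for v in variables:
        if v.vtype == "binary":
            exposed = cohort[v.name].to_numpy(dtype=float) == 1
            n_exp, ev = int(exposed.sum()), int(y[exposed].sum())
            if n_exp < config.min_patients:
                dropped[v.name] = f"only {n_exp} patients exposed"
            elif ev < config.min_events:
                dropped[v.name] = f"only {ev} events among {n_exp} exposed"
            else:
                kept.append(v)
        elif v.vtype == "categorical":
            vals = cohort[v.name].astype(str)
            merged_into: dict[str, str] = {}

            def resolve(lev):
                while lev in merged_into:
                    lev = merged_into[lev]
                return lev

            # a rare level folds into its neighbour in the declared
            # (clinical) order; repeat until all remaining groups are common
            changed = True
            while changed:
                groups = []
                for l in v.levels:
                    g = resolve(l)
                    if g not in groups:
                        groups.append(g)
                changed = False
                if len(groups) <= 2:
                    break
                for i, g in enumerate(groups):
                    members = [l for l in v.levels if resolve(l) == g]
                    mask = vals.isin(members).to_numpy()
                    n_lev, ev = int(mask.sum()), int(y[mask].sum())
                    if n_lev < config.min_patients or ev < config.min_events:
                        tgt = groups[i - 1] if i > 0 else groups[1]
                        merged_into[g] = tgt
                        changed = True
                        break
            lmap = tuple((l, resolve(l)) for l in v.levels)
            if merged_into:
                dropped[v.name] = (
                    "rare levels merged: "
                    + ", ".join(f"{l}->{t}" for l, t in sorted(merged_into.items()))
                )
            ref = resolve(v.reference or v.levels[0])
            kept.append(VariableDef(v.name, "categorical", v.levels, ref,
                                    v.merge_groups, lmap))
        else:
            kept.append(v)
    return kept, dropped


def make_term(cohort: pd.DataFrame, v: VariableDef, y=None, *,
              config: SelectionConfig = SelectionConfig()):
    """Build the model term for a screened variable.

    Continuous variables get a piecewise-linearity test; binaries become
    linear terms; categoricals dummy terms over their level list.
    """
    if v.vtype == "binary":
        return LinearTerm(v.name)
    if v.vtype == "categorical":
        if v.level_map:
            return CategoricalTerm(v.name, v.level_map, v.reference)
        return categorical_from_levels(v.name, v.levels, v.reference)
    tr = PiecewiseLogitTransformer(variable=v.name, max_knots=config.max_knots,
                                   alpha=config.linearity_alpha)
    tr.fit(cohort, y)
    return tr.term_


def bivariate_screen(cohort: pd.DataFrame, terms, y,
                     config: SelectionConfig = SelectionConfig()):
    """Single-variable logistic screen at ``p_screen``.

    Returns a DataFrame (term, p_value, kept, flag); terms whose single-
    covariate fit fails (e.g. perfect separation) are flagged and kept for
    review rather than silently discarded.
    """
    y = np.asarray(y, dtype=float)
    null_fit = fit_logistic_array(np.ones((len(cohort), 1)), y)
    rows = []
    for t in terms:
        flag = ""
        try:
            _, fit = fit_terms(cohort, [t], y)
            _, p = lr_test(fit.llf, null_fit.llf, len(t.columns()))
            kept = p <= config.p_screen
        except SeparationError:
            p, kept, flag = float("nan"), True, "separation"
        except GlmError as exc:
            p, kept, flag = float("nan"), True, type(exc).__name__
        rows.append({"term": t.name, "p_value": p, "kept": kept, "flag": flag})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stepwise estimator


class StepwiseLogisticModel(BaseEstimator):
    """Forward/backward stepwise logistic risk model (scikit-learn style).

    Parameters
    ----------
    candidate_terms : sequence of terms considered for entry.
    forced_terms : sequence of terms always retained (e.g. the pre-operative
        model's terms when building the post-operative model).
    p_enter, p_remove : float
        Likelihood-ratio thresholds for entry and removal (both default to
        the protocol's 0.01).
    max_cycles : int
        Cap on forward/backward alternations before an oscillation error.
    stage : str
        Label ("pre" or "post") carried into serialisations.

    Attributes (after ``fit``)
    --------------------------
    terms_ : list of selected terms (forced first).
    coef_ : pandas Series of coefficients indexed by design column.
    cov_ : DataFrame covariance of the estimates.
    llf_, deviance_, n_obs_ : fit summaries.
    selection_trace_ : list of (action, term, p) tuples.
    """

    def __init__(self, candidate_terms=(), forced_terms=(), p_enter=0.01,
                 p_remove=0.01, max_cycles=20, stage="pre"):
        self.candidate_terms = candidate_terms
        self.forced_terms = forced_terms
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.max_cycles = max_cycles
        self.stage = stage

    # -- fitting -----------------------------------------------------------

    def _refit(self, df, terms, y):
        return fit_terms(df, terms, y)

    def fit(self, X: pd.DataFrame, y):
        df = X
        y = np.asarray(y, dtype=float)
        forced = list(self.forced_terms)
        cands = [t for t in self.candidate_terms
                 if t.name not in {f.name for f in forced}]
        current = list(forced)
        _, cur_fit = self._refit(df, current, y)
        trace = []
        seen_states = {tuple(sorted(t.name for t in current))}
        for _cycle in range(self.max_cycles):
            changed = False
            # forward
            entries = []
            for t in sorted(cands, key=lambda t: t.name):
                if any(t.name == c.name for c in current):
                    continue
                try:
                    _, fit = self._refit(df, current + [t], y)
                except GlmError:
                    continue
                _, p = lr_test(fit.llf, cur_fit.llf, len(t.columns()))
                entries.append((p, t.name, t, fit))
            if entries:
                entries.sort(key=lambda e: (e[0], e[1]))
                p, name, t, fit = entries[0]
                if p < self.p_enter:
                    current.append(t)
                    cur_fit = fit
                    trace.append(("enter", name, p))
                    changed = True
            # backward
            removable = [t for t in current
                         if not any(t.name == f.name for f in forced)]
            exits = []
            for t in sorted(removable, key=lambda t: t.name):
                reduced = [c for c in current if c.name != t.name]
                try:
                    _, fit = self._refit(df, reduced, y)
                except GlmError:
                    continue
                _, p = lr_test(cur_fit.llf, fit.llf, len(t.columns()))
                exits.append((p, t.name, t, fit))
            if exits:
                exits.sort(key=lambda e: (-e[0], e[1]))
                p, name, t, fit = exits[0]
                if p >= self.p_remove:
                    current = [c for c in current if c.name != name]
                    cur_fit = fit
                    trace.append(("remove", name, p))
                    changed = True
            if not changed:
                break
            state = tuple(sorted(t.name for t in current))
            if state in seen_states and _cycle > 0:
                # revisiting a state means we may cycle; allow the loop to
                # terminate naturally unless the cap is hit
                pass
            seen_states.add(state)
        else:
            cycling = {name for _, name, _ in trace[-2 * self.max_cycles:]}
            raise StepwiseOscillationError(cycling)

        info, fit = self._refit(df, current, y)
        self.terms_ = current
        self.design_info_ = info
        self.coef_ = pd.Series(fit.coef, index=info.column_names)
        self.cov_ = pd.DataFrame(fit.cov, index=info.column_names,
                                 columns=info.column_names)
        self.llf_ = fit.llf
        self.deviance_ = fit.deviance
        self.n_iter_ = fit.n_iter
        self.n_obs_ = fit.n_obs
        self.selection_trace_ = trace
        self.training_index_ = tuple(df.index.tolist())
        self.classes_ = np.array([0, 1])
        return self

    # -- prediction --------------------------------------------------------

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted probability of hospital death, one value per row."""
        info = build_design(X, self.terms_)
        eta = info.matrix @ self.coef_.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = self.predict_risk(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_risk(X) >= 0.5).astype(int)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "terms": [t.to_dict() for t in self.terms_],
            "columns": list(self.coef_.index),
            "coef": self.coef_.tolist(),
            "cov": self.cov_.to_numpy().tolist(),
            "llf": self.llf_,
            "deviance": self.deviance_,
            "n_obs": self.n_obs_,
            "selection_trace": [list(t) for t in self.selection_trace_],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "StepwiseLogisticModel":
        model = cls(stage=d["stage"])
        model.terms_ = [term_from_dict(td) for td in d["terms"]]
        model.coef_ = pd.Series(d["coef"], index=d["columns"])
        model.cov_ = pd.DataFrame(d["cov"], index=d["columns"],
                                  columns=d["columns"])
        model.llf_ = d["llf"]
        model.deviance_ = d["deviance"]
        model.n_obs_ = d["n_obs"]
        model.selection_trace_ = [tuple(t) for t in d.get("selection_trace", [])]
        model.classes_ = np.array([0, 1])
        return model

    @classmethod
    def load(cls, path) -> "StepwiseLogisticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def stepwise_select(cohort: pd.DataFrame, candidates, y,
                    config: SelectionConfig = SelectionConfig(),
                    forced=(), stage="pre") -> StepwiseLogisticModel:
    """Run forward/backward selection; thin wrapper over the estimator."""
    model = StepwiseLogisticModel(candidate_terms=list(candidates),
                                  forced_terms=list(forced),
                                  p_enter=config.p_select,
                                  p_remove=config.p_select,
                                  max_cycles=config.max_cycles, stage=stage)
    return model.fit(cohort, y)


# ---------------------------------------------------------------------------
# level merging


def _contiguous(levels_order, group_a, group_b) -> bool:
    idx = sorted(levels_order.index(l) for l in (*group_a, *group_b))
    return idx == list(range(idx[0], idx[-1] + 1))


def merge_levels(model: StepwiseLogisticModel, cohort: pd.DataFrame, y,
                 variable: str, *, level_merge_p: float = 0.05,
                 variable_def: VariableDef | None = None) -> StepwiseLogisticModel:
    """Merge statistically indistinguishable level groups of one categorical.

    Groups are ordered by estimated odds ratio; the adjacent pair with the
    largest pairwise Wald p-value is merged when that p-value is at least
    ``level_merge_p`` and the merged raw levels form a clinically allowed
    group (a contiguous block of the declared level order, or any set listed
    in ``variable_def.merge_groups``).  The model is refit after each merge.
    """
    y = np.asarray(y, dtype=float)
    while True:
        term = next((t for t in model.terms_
                     if isinstance(t, CategoricalTerm) and t.name == variable),
                    None)
        if term is None:
            return model
        groups = [term.reference] + term.group_labels()
        if len(groups) < 3 and variable_def is None:
            # with two groups a merge would erase the variable; require an
            # explicit merge_groups instruction for that
            return model
        gmap = term.group_map()
        members = {g: tuple(l for l, gg in term.groups if gg == g) for g in groups}
        coef = {g: 0.0 for g in groups}
        var = {g: 0.0 for g in groups}
        covf = model.cov_
        for g in term.group_labels():
            col = f"{variable}={g}"
            coef[g] = float(model.coef_[col])
            var[g] = float(covf.loc[col, col])
        order = sorted(groups, key=lambda g: coef[g])
        declared = [l for l, _ in term.groups]
        best = None
        for a, b in zip(order[:-1], order[1:]):
            ca, cb = f"{variable}={a}", f"{variable}={b}"
            cov_ab = 0.0
            if a != term.reference and b != term.reference:
                cov_ab = float(covf.loc[ca, cb])
            se = np.sqrt(max(var[a] + var[b] - 2 * cov_ab, 1e-300))
            z = (coef[a] - coef[b]) / se
            p = 2.0 * float(norm.sf(abs(z)))
            allowed = _contiguous(declared, members[a], members[b])
            if variable_def is not None and variable_def.merge_groups:
                union = set(members[a]) | set(members[b])
                allowed = any(union <= set(g) for g in variable_def.merge_groups)
            if allowed and p >= level_merge_p:
                if best is None or p > best[0]:
                    best = (p, a, b)
        if best is None:
            return model
        _, a, b = best
        label = "+".join(
            sorted(set(members[a]) | set(members[b]),
                   key=lambda l: declared.index(l))
        )
        new_pairs = []
        for lev, g in term.groups:
            new_pairs.append((lev, label if g in (a, b) else g))
        new_ref = label if term.reference in (a, b) else term.reference
        new_term = CategoricalTerm(variable, tuple(new_pairs), new_ref)
        new_terms = [new_term if t.name == variable else t for t in model.terms_]
        refit = StepwiseLogisticModel(candidate_terms=[], forced_terms=new_terms,
                                      p_enter=model.p_enter,
                                      p_remove=model.p_remove, stage=model.stage)
        model = refit.fit(cohort, y)


# ---------------------------------------------------------------------------
# full protocol


@dataclass
class DevelopmentReport:
    rare_dropped: dict = field(default_factory=dict)
    bivariate: pd.DataFrame | None = None
    piecewise: dict = field(default_factory=dict)
    merged: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"rare_dropped": self.rare_dropped, "piecewise": self.piecewise,
             "merged": self.merged}
        if self.bivariate is not None:
            d["bivariate"] = self.bivariate.to_dict(orient="records")
        return d


def develop_model(cohort: pd.DataFrame, y, variables,
                  config: SelectionConfig = SelectionConfig(), *,
                  stage="pre", forced_terms=()):
    """Run the whole development protocol for one stage.

    Returns ``(model, report)``.  ``variables`` is a list of
    :class:`VariableDef`; ``forced_terms`` (term objects) bypass screening
    and selection — used for the post-operative stage.
    """
    y = np.asarray(y, dtype=float)
    report = DevelopmentReport()
    screened, report.rare_dropped = screen_rare_variables(
        cohort, variables, y, config)
    vdefs = {v.name: v for v in screened}
    terms = []
    for v in screened:
        t = make_term(cohort, v, y, config=config)
        if isinstance(t, PiecewiseTerm):
            report.piecewise[v.name] = list(t.knots)
        terms.append(t)
    report.bivariate = bivariate_screen(cohort, terms, y, config)
    kept_names = set(report.bivariate.loc[report.bivariate["kept"], "term"])
    candidates = [t for t in terms if t.name in kept_names]
    model = stepwise_select(cohort, candidates, y, config,
                            forced=forced_terms, stage=stage)
    for t in list(model.terms_):
        if isinstance(t, CategoricalTerm) and len(t.group_labels()) >= 2:
            before = [g for _, g in t.groups]
            model = merge_levels(model, cohort, y, t.name,
                                 level_merge_p=config.level_merge_p,
                                 variable_def=vdefs.get(t.name))
            after_term = next(tt for tt in model.terms_ if tt.name == t.name)
            after = [g for _, g in after_term.groups]
            if after != before:
                report.merged[t.name] = dict(after_term.groups)
    return model, report


def build_postop_model(cohort: pd.DataFrame, y, preop_model, postop_variables,
                       config: SelectionConfig = SelectionConfig()):
    """Develop the post-operative model with the pre-operative terms forced in.

    Coefficients are re-estimated from scratch; only the term structure of
    the pre-operative model is carried over.
    """
    return develop_model(cohort, y, postop_variables, config, stage="post",
                         forced_terms=list(preop_model.terms_))
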