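"""Piecewise-linear logit transforms for continuous risk factors.

Risk factors such as age and creatinine clearance rarely act linearly on the
log-odds of death; this module tests linearity and, where it is rejected,
replaces the linear term with a continuous piecewise-linear (hinge) spline.

The knot search scans candidate knots at inner deciles of the variable,
picks the best single-knot model by likelihood, then tries to extend it to
two knots.  Because the knot is chosen to maximise the likelihood, the
likelihood-ratio test against the linear model is Bonferroni-adjusted by the
number of candidate configurations searched; without the adjustment the
nominal 5% gate would reject linearity far too often.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator, TransformerMixin

from ._glm import GlmError, fit_logistic_array
from .terms import PiecewiseTerm


class PiecewiseLogitTransformer(TransformerMixin, BaseEstimator):
    """Select and apply a piecewise-linear logit transform for one variable.

    Parameters
    ----------
    variable : str or None
        Column to transform when fitting on a DataFrame; with array input
        the single column is used.
    max_knots : int, default 2
        Maximum number of knots considered.
    alpha : float, default 0.05
        Significance gate of the (Bonferroni-adjusted) likelihood-ratio test
        of each knot addition; if linearity is not rejected the transform
        has zero knots.
    n_grid : int, default 9
        Number of candidate knots (inner quantiles of the variable).
    min_distinct : int, default 50
        Minimum number of distinct values required of the variable.

    Attributes
    ----------
    knots_ : tuple of float
        Selected knots (possibly empty).
    slopes_ : list of float
        Per-segment slopes of the fitted univariate logit model.
    pvalue_linearity_ : float
        Adjusted p-value of the first knot addition.
    term_ : PiecewiseTerm
        Term usable in a risk model.
    """

    def __init__(self, variable=None, max_knots=2, alpha=0.05, n_grid=9,
                 min_distinct=50):
        self.variable = variable
        self.max_knots = max_knots
        self.alpha = alpha
        self.n_grid = n_grid
        self.min_distinct = min_distinct

    def _column(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.variable is None:
                if X.shape[1] != 1:
                    raise ValueError("specify `variable` for multi-column input")
                return X.iloc[:, 0].to_numpy(float)
            return X[self.variable].to_numpy(float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("array input must have exactly one column")
            X = X[:, 0]
        return X

    @staticmethod
    def _hinge_design(x: np.ndarray, knots) -> np.ndarray:
        cols = [np.ones_like(x), x]
        cols += [np.maximum(x - k, 0.0) for k in knots]
        return np.column_stack(cols)

    def fit(self, X, y):
        x = self._column(X)
        y = np.asarray(y, dtype=float)
        if np.unique(x).size < 2:
            raise ValueError("variable is constant; cannot model its effect")
        if np.unique(x).size < self.min_distinct:
            raise ValueError(
                f"variable has fewer than {self.min_distinct} distinct values"
            )

        qs = np.linspace(0.1, 0.9, self.n_grid)
        grid = np.unique(np.quantile(x, qs))
        # a knot must leave data on both sides
        grid = np.array([k for k in grid if (x < k).sum() >= 10 and (x > k).sum() >= 10])

        def _fit(knots):
            return fit_logistic_array(self._hinge_design(x, knots), y,
                                      check_rank=False)

        fit_lin = _fit(())
        knots: tuple[float, ...] = ()
        best_fit = fit_lin
        self.pvalue_linearity_ = 1.0

        if self.max_knots >= 1 and grid.size:
            cands = [(k,) for k in grid]
            fits = []
            for ks in cands:
                try:
                    fits.append((ks, _fit(ks)))
                except GlmError:
                    continue
            if fits:
                ks1, fit1 = max(fits, key=lambda t: t[1].llf)
                stat = 2.0 * (fit1.llf - fit_lin.llf)
                p_adj = min(1.0, len(fits) * float(chi2.sf(stat, 1)))
                self.pvalue_linearity_ = p_adj
                if p_adj < self.alpha:
                    knots, best_fit = ks1, fit1
                    if self.max_knots >= 2:
                        pairs = [p for p in combinations(grid, 2)]
                        fits2 = []
                        for ks in pairs:
                            try:
                                fits2.append((ks, _fit(ks)))
                            except GlmError:
                                continue
                        if fits2:
                            ks2, fit2 = max(fits2, key=lambda t: t[1].llf)
                            stat2 = 2.0 * (fit2.llf - fit1.llf)
                            p2 = min(1.0, len(fits2) * float(chi2.sf(stat2, 1)))
                            if p2 < self.alpha:
                                knots, best_fit = tuple(ks2), fit2

        self.knots_ = tuple(float(k) for k in knots)
        self.slopes_ = list(np.cumsum(best_fit.coef[1:]))
        name = self.variable if self.variable is not None else "x"
        self.term_ = PiecewiseTerm(name, self.knots_)
        return self

    def transform(self, X) -> np.ndarray:
        x = self._column(X)
        return np.column_stack([x] + [np.maximum(x - k, 0.0) for k in self.knots_])


def fit_piecewise(cohort: pd.DataFrame, variable: str, y, *, max_knots=2,
                  alpha=0.05) -> PiecewiseLogitTransformer:
    """Convenience wrapper: fit the transformer for one cohort column."""
    tr = PiecewiseLogitTransformer(variable=variable, max_knots=max_knots,
                                   alpha=alpha)
    return tr.fit(cohort, y)
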