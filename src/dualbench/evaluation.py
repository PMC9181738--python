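"""Model adequacy: discrimination, calibration and cohort description.

Discrimination is the Mann–Whitney concordance (AUC of the ROC curve).
Calibration uses a polynomial recalibration belt and test: the logit of the
predicted probability enters a logistic model as a polynomial whose degree
is chosen by forward likelihood-ratio selection, the belt is the confidence
region of the fitted recalibration curve, and the test compares the selected
polynomial against the identity line.  Because the degree is selected on the
same data, the null distribution of the test statistic is not a plain
chi-square: it is the convolution of a chi-square base term with one
truncated chi-square(1) term per accepted degree increment (each accepted
increment was conditioned to exceed the selection threshold).  The same
conditional distribution supplies the belt's critical values.

``devel="external"`` evaluates a model on data it was not fit on (degree
selection starts at 1, base df 2).  ``devel="internal"`` evaluates on the
training data, where the degree-1 recalibration is exactly the identity by
the ML score equations, so selection starts at degree 2 with base df 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import logit as _logit
from scipy.stats import chi2, chi2_contingency, mannwhitneyu
from sklearn.metrics import roc_auc_score, roc_curve

from ._glm import fit_logistic_array, log_likelihood


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_events: int
    n_nonevents: int

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr,
                             "threshold": self.thresholds})


def roc_auc(probabilities, outcomes) -> ROCResult:
    """ROC analysis; AUC is the tie-corrected Mann–Whitney concordance."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n_ev, n_non = int(y.sum()), int((1 - y).sum())
    if n_ev == 0 or n_non == 0:
        raise ValueError("ROC undefined: need at least one event and one non-event")
    auc = float(roc_auc_score(y, p))
    fpr, tpr, thr = roc_curve(y, p)
    return ROCResult(auc, fpr, tpr, thr, n_ev, n_non)


# ---------------------------------------------------------------------------
# calibration belt


@dataclass
class CalibrationBeltResult:
    degree: int
    statistic: float
    p_value: float
    band: pd.DataFrame  # columns: probability, lower_<cl>, upper_<cl>
    n: int
    devel: str

    def band_frame(self) -> pd.DataFrame:
        return self.band


_SELECTION_GRID_MAX = 140.0
_SELECTION_GRID_STEP = 0.01


@lru_cache(maxsize=32)
def _conditional_distribution(df0: int, k: int, thresh: float):
    """Grid survival function of B + sum of k truncated chi2(1) increments."""
    grid = np.arange(0.0, _SELECTION_GRID_MAX, _SELECTION_GRID_STEP)
    dens = np.diff(chi2.cdf(np.append(grid, grid[-1] + _SELECTION_GRID_STEP), df0))
    if k > 0:
        tr = np.diff(chi2.cdf(np.append(grid, grid[-1] + _SELECTION_GRID_STEP), 1))
        tr[grid <= thresh] = 0.0
        tr = tr / tr.sum()
        for _ in range(k):
            dens = np.convolve(dens, tr)[: len(grid)]
    cdf = np.cumsum(dens)
    return grid, np.clip(cdf, 0.0, 1.0)


def _selection_sf(t: float, df0: int, k: int, thresh: float) -> float:
    if k == 0:
        return float(chi2.sf(t, df0))
    grid, cdf = _conditional_distribution(df0, k, round(thresh, 6))
    return float(1.0 - np.interp(t, grid, cdf))


def _selection_quantile(q: float, df0: int, k: int, thresh: float) -> float:
    if k == 0:
        return float(chi2.ppf(q, df0))
    grid, cdf = _conditional_distribution(df0, k, round(thresh, 6))
    return float(np.interp(q, cdf, grid))


def calibration_belt(probabilities, outcomes,
                     confidence_levels=(0.80, 0.95), *, devel="external",
                     max_degree=4, selection_significance=0.95,
                     n_band_points=100) -> CalibrationBeltResult:
    """Polynomial-recalibration calibration belt and test.

    Parameters
    ----------
    probabilities : predicted death probabilities, strictly inside (0, 1).
    outcomes : observed 0/1 outcomes.
    confidence_levels : belt confidence levels.
    devel : "external" (default) or "internal"; see module docstring.
    max_degree : largest polynomial degree considered (default 4).
    selection_significance : confidence of each forward degree-selection
        likelihood-ratio test (default 0.95).

    Returns a :class:`CalibrationBeltResult`; its ``p_value`` is the
    selection-adjusted test of the identity line (small values mean
    miscalibration).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    if np.allclose(p, p[0]):
        raise ValueError("probabilities are constant; calibration curve undefined")
    if devel not in ("external", "internal"):
        raise ValueError("devel must be 'external' or 'internal'")
    n = len(p)
    if n < 50:
        warnings.warn("calibration belt is asymptotic; n < 50 is unreliable",
                      stacklevel=2)

    g = _logit(p)
    ll_identity = log_likelihood(g, y)

    def poly_fit(m):
        X = np.column_stack([g ** j for j in range(m + 1)])
        return fit_logistic_array(X, y, check_rank=False), X

    m0 = 1 if devel == "external" else 2
    thresh = float(chi2.ppf(selection_significance, 1))
    fit, X = poly_fit(m0)
    m = m0
    while m < max_degree:
        fit_next, X_next = poly_fit(m + 1)
        if 2.0 * (fit_next.llf - fit.llf) > thresh:
            m, fit, X = m + 1, fit_next, X_next
        else:
            break

    stat = max(0.0, 2.0 * (fit.llf - ll_identity))
    df0 = 2 if devel == "external" else 1
    k = m - m0
    p_value = _selection_sf(stat, df0, k, thresh)

    # belt: project the selection-adjusted confidence ellipsoid pointwise
    gg = np.linspace(g.min(), g.max(), n_band_points)
    Xg = np.column_stack([gg ** j for j in range(m + 1)])
    eta = Xg @ fit.coef
    se2 = np.einsum("ij,jk,ik->i", Xg, fit.cov, Xg)
    band = pd.DataFrame({"probability": 1.0 / (1.0 + np.exp(-gg))})
    for cl in confidence_levels:
        r = np.sqrt(np.maximum(_selection_quantile(cl, df0, k, thresh) * se2, 0.0))
        band[f"lower_{cl:g}"] = 1.0 / (1.0 + np.exp(-(eta - r)))
        band[f"upper_{cl:g}"] = 1.0 / (1.0 + np.exp(-(eta + r)))
    return CalibrationBeltResult(degree=m, statistic=stat, p_value=p_value,
                                 band=band, n=n, devel=devel)


# ---------------------------------------------------------------------------
# descriptive comparison


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage recomputed from counts, rounded for table display."""
    if total == 0:
        raise ZeroDivisionError("total is zero")
    return round(100.0 * count / total, decimals)


def describe_cohort(cohort: pd.DataFrame, variables, *,
                    outcome_col: str = "hospital_outcome",
                    continuity_correction: bool = False) -> pd.DataFrame:
    """Compare variable distributions between alive and dead patients.

    ``variables`` maps column name to ``"continuous"`` or ``"categorical"``
    (binary 0/1 columns count as categorical).  Continuous variables are
    summarised as median (Q1, Q3) and tested with the Wilcoxon–Mann–Whitney
    test; categorical variables as count (%) per level with a chi-squared
    test (no continuity correction unless requested).
    """
    if outcome_col not in cohort.columns:
        raise ValueError(f"outcome column {outcome_col!r} missing")
    dead = cohort[outcome_col] == "dead"
    alive = cohort[outcome_col] == "alive"
    rows = []
    for name, kind in variables.items():
        col = cohort[name]
        if kind == "continuous":
            a, d = col[alive].dropna(), col[dead].dropna()
            if a.nunique() <= 1 and d.nunique() <= 1 and set(a) == set(d):
                pval = float("nan")
            else:
                pval = float(mannwhitneyu(a, d, alternative="two-sided").pvalue)

            def q(s):
                return (f"{s.median():g} ({s.quantile(0.25):g}, "
                        f"{s.quantile(0.75):g})")

            rows.append({"variable": name, "level": "median (Q1, Q3)",
                         "total": q(col.dropna()), "alive": q(a), "dead": q(d),
                         "p_value": pval, "test": "Wilcoxon-Mann-Whitney"})
        else:
            tab = pd.crosstab(col, dead[col.index])
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                pval = float("nan")
            else:
                pval = float(chi2_contingency(
                    tab.to_numpy(), correction=continuity_correction)[1])
            n_tot, n_al, n_de = len(col), int(alive.sum()), int(dead.sum())
            for lev in tab.index:
                ct, ca = int((col == lev).sum()), int(((col == lev) & alive).sum())
                cd = int(((col == lev) & dead).sum())
                rows.append({
                    "variable": name, "level": str(lev),
                    "total": f"{ct} ({percent(ct, n_tot)}%)",
                    "alive": f"{ca} ({percent(ca, n_al)}%)",
                    "dead": f"{cd} ({percent(cd, n_de)}%)",
                    "p_value": pval, "test": "chi-squared",
                })
    return pd.DataFrame(rows)
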