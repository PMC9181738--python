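"""Maximum-likelihood logistic regression via Newton/IRLS.

This is the numerical core used by every stage: model development fits
thousands of candidate models during screening and stepwise selection, and
the bootstrap refits the pre- and post-operative models on every resample,
so the solver works directly on dense numpy arrays.  Convergence is declared
when the deviance change falls below ``tol`` (default 1e-8) or after
``max_iter`` Newton steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.special import expit
from scipy.stats import chi2


class GlmError(RuntimeError):
    """Base class for fitting failures."""


class RankDeficiencyError(GlmError):
    """Design matrix is not full column rank."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(map(str, self.columns))
        )


class SeparationError(GlmError):
    """(Quasi-)complete separation: the MLE does not exist."""


class ConvergenceError(GlmError):
    """IRLS failed to converge within the iteration budget."""


def log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli log-likelihood for linear predictor ``eta`` (logit link)."""
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


@dataclass
class LogisticFit:
    """A converged ML logistic fit on a fixed design matrix."""

    coef: np.ndarray
    cov: np.ndarray
    llf: float
    deviance: float
    n_iter: int
    n_obs: int
    columns: list = field(default_factory=list)

    def predict_eta(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.coef)


def _collinear_columns(X: np.ndarray, names) -> list:
    """Name the columns responsible for rank deficiency via pivoted QR."""
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    bad = [piv[i] for i in range(len(d)) if d[i] <= tol]
    return [names[j] for j in sorted(bad)]


def fit_logistic_array(
    X: np.ndarray,
    y: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
    check_rank: bool = True,
    allow_boundary: bool = False,
    column_names=None,
) -> LogisticFit:
    """Fit a logistic regression by IRLS with step halving.

    Parameters
    ----------
    X : (n, p) design matrix, including the intercept column if wanted.
    y : (n,) binary outcome in {0, 1}.

    Raises
    ------
    RankDeficiencyError
        If ``check_rank`` and the design is singular; the error lists the
        collinear columns.
    SeparationError
        If coefficients diverge (complete or quasi-complete separation).
    ConvergenceError
        If the deviance has not stabilised after ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    names = list(column_names) if column_names is not None else list(range(p))
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if check_rank and np.linalg.matrix_rank(X) < p:
        raise RankDeficiencyError(_collinear_columns(X, names))

    beta = np.zeros(p)
    eta = np.zeros(n)
    dev = -2.0 * log_likelihood(eta, y)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        # Newton step: solve (X'WX) delta = X'(y - mu)
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ (y - mu)
        try:
            delta = sla.solve(H, g, assume_a="pos")
        except sla.LinAlgError as exc:  # pragma: no cover - guarded by rank check
            raise RankDeficiencyError(_collinear_columns(X, names)) from exc
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            eta_cand = X @ cand
            dev_cand = -2.0 * log_likelihood(eta_cand, y)
            if dev_cand <= dev + 1e-12:
                break
            step *= 0.5
        beta, eta = cand, eta_cand
        if np.abs(beta).max() > 5e2:
            raise SeparationError(
                "coefficients diverged; data are (quasi-)completely separated"
            )
        if abs(dev - dev_cand) < tol:
            dev = dev_cand
            break
        dev = dev_cand
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")

    # quasi-complete separation shows up as a "converged" fit whose linear
    # predictor has run off to +-inf (fitted probabilities at machine 0/1).
    # ``allow_boundary`` accepts such boundary fits: the fitted-probability
    # limit exists and keeps expected-event sums valid (used by bootstrap
    # refits, where a resample can empty a rare dummy level's event cell).
    if not allow_boundary and np.abs(eta).max() > 20.0:
        raise SeparationError(
            "fitted probabilities reached machine 0/1; data are "
            "(quasi-)completely separated"
        )
    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    H = (X.T * w) @ X
    cov = sla.inv(H)
    llf = log_likelihood(eta, y)
    return LogisticFit(
        coef=beta, cov=cov, llf=llf, deviance=-2.0 * llf,
        n_iter=n_iter, n_obs=n, columns=names,
    )


def lr_test(llf_full: float, llf_null: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio test; returns (statistic, p-value)."""
    stat = max(0.0, 2.0 * (llf_full - llf_null))
    p = float(chi2.sf(stat, df)) if df > 0 else float("nan")
    return stat, p
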