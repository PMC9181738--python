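"""Discrimination, calibration belt behaviour and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest

from dualbench.evaluation import (calibration_belt, describe_cohort, percent,
                                  roc_auc)


def brute_force_auc(p, y):
    """Exhaustive pair concordance with ties counted 1/2."""
    p, y = np.asarray(p, float), np.asarray(y, int)
    ev, non = p[y == 1], p[y == 0]
    wins = (ev[:, None] > non[None, :]).sum()
    ties = (ev[:, None] == non[None, :]).sum()
    return (wins + 0.5 * ties) / (len(ev) * len(non))


def test_auc_perfect_separation():
    res = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
    assert res.auc == 1.0


def test_auc_all_tied_is_half():
    res = roc_auc([0.3] * 6, [1, 0, 1, 0, 0, 0])
    assert res.auc == 0.5


@pytest.mark.parametrize("seed", range(6))
def test_auc_matches_exhaustive_pair_counting(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 200))
    p = np.round(rng.random(n), 2)  # rounding forces ties
    y = (rng.random(n) < 0.3).astype(int)
    if y.sum() == 0 or y.sum() == n:
        y[0], y[-1] = 1, 0
    res = roc_auc(p, y)
    assert res.auc == pytest.approx(brute_force_auc(p, y), abs=1e-12)
    # curve endpoints and monotonicity
    assert res.fpr[0] == 0.0 and res.fpr[-1] == 1.0
    assert np.all(np.diff(res.tpr) >= 0)


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


# -- calibration belt --------------------------------------------------------


def test_calibration_belt_degenerate_inputs():
    y = np.r_[np.ones(30), np.zeros(70)]
    with pytest.raises(ValueError, match="strictly inside"):
        calibration_belt(y.astype(float), y)  # probabilities in {0,1}
    with pytest.raises(ValueError, match="constant"):
        calibration_belt(np.full(100, 0.3), y)


def test_calibration_belt_warns_small_sample():
    rng = np.random.default_rng(0)
    p = rng.uniform(0.05, 0.5, 30)
    y = (rng.random(30) < p).astype(float)
    with pytest.warns(UserWarning, match="n < 50"):
        calibration_belt(p, y)


def test_calibration_belt_band_orders_and_nests():
    rng = np.random.default_rng(1)
    p = rng.uniform(0.02, 0.6, 2000)
    y = (rng.random(2000) < p).astype(float)
    res = calibration_belt(p, y, confidence_levels=(0.80, 0.95))
    band = res.band
    assert (band["lower_0.8"] <= band["upper_0.8"]).all()
    assert (band["lower_0.95"] <= band["lower_0.8"] + 1e-12).all()
    assert (band["upper_0.8"] <= band["upper_0.95"] + 1e-12).all()
    assert res.degree >= 1


def test_calibration_belt_detects_miscalibration():
    """Halving all probabilities is reliably rejected at n = 2000."""
    rng = np.random.default_rng(2)
    rejected = 0
    reps = 20
    for _ in range(reps):
        p = rng.beta(1.2, 20, 2000) * 0.9 + 0.005
        y = (rng.random(2000) < p).astype(float)
        res = calibration_belt(p / 2.0, y)
        rejected += res.p_value < 0.05
    assert rejected >= int(0.95 * reps)


def test_calibration_belt_internal_mode_on_training_fit():
    """On its own training data a ML logistic model passes the internal test."""
    from dualbench._glm import fit_logistic_array
    rng = np.random.default_rng(3)
    X = np.column_stack([np.ones(3000), rng.standard_normal(3000)])
    y = (rng.random(3000) < 1 / (1 + np.exp(-(X @ np.r_[-2.0, 0.8])))).astype(float)
    fit = fit_logistic_array(X, y)
    res = calibration_belt(fit.predict_proba(X), y, devel="internal")
    assert res.p_value > 0.01


# -- descriptive table -------------------------------------------------------


def _table_cohort():
    rng = np.random.default_rng(4)
    n = 400
    df = pd.DataFrame({
        "age": rng.normal(70, 10, n),
        "redo": rng.integers(0, 2, n),
        "hospital_outcome": np.where(rng.random(n) < 0.1, "dead", "alive"),
    })
    return df


def test_describe_cohort_chi_squared_closed_form():
    """Chi-squared statistic agrees with the textbook 2x2 formula."""
    df = pd.DataFrame({
        "flag": np.r_[np.ones(120), np.zeros(280)].astype(int),
        "hospital_outcome": ["dead"] * 60 + ["alive"] * 60
                            + ["dead"] * 40 + ["alive"] * 240,
    })
    out = describe_cohort(df, {"flag": "categorical"})
    # textbook chi2 without continuity correction
    tab = pd.crosstab(df["flag"], df["hospital_outcome"]).to_numpy(float)
    n = tab.sum()
    exp = np.outer(tab.sum(1), tab.sum(0)) / n
    stat = ((tab - exp) ** 2 / exp).sum()
    from scipy.stats import chi2 as chi2_dist
    p_expected = float(chi2_dist.sf(stat, 1))
    assert out["p_value"].iloc[0] == pytest.approx(p_expected, abs=1e-10)


def test_describe_cohort_constant_column_not_applicable():
    df = _table_cohort()
    df["const"] = 1.0
    out = describe_cohort(df, {"const": "continuous"})
    assert np.isnan(out["p_value"].iloc[0])


def test_describe_cohort_layout():
    df = _table_cohort()
    out = describe_cohort(df, {"age": "continuous", "redo": "categorical"})
    assert set(out["variable"]) == {"age", "redo"}
    assert (out.loc[out["variable"] == "age", "test"]
            == "Wilcoxon-Mann-Whitney").all()
    assert (out.loc[out["variable"] == "redo", "test"] == "chi-squared").all()


def test_percent_recomputes_from_counts():
    assert percent(562, 15533) == 3.6
    assert percent(315, 562) == 56.0
    assert percent(37, 562) == 6.6
    with pytest.raises(ZeroDivisionError):
        percent(1, 0)
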