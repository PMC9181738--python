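"""Model-development protocol: ML fits, screening, selection, level merging."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import chi2

from dualbench._glm import (RankDeficiencyError, SeparationError,
                            fit_logistic_array)
from dualbench.development import (SelectionConfig, StepwiseLogisticModel,
                                   VariableDef, bivariate_screen,
                                   fit_logistic, fit_terms, make_term,
                                   merge_levels, screen_rare_variables,
                                   stepwise_select)
from dualbench.terms import (CategoricalTerm, LinearTerm, build_design,
                             categorical_from_levels)
from dualbench.transforms import PiecewiseLogitTransformer


def _two_by_two(a, b, c, d):
    """exposed: a deaths / b alive; unexposed: c deaths / d alive."""
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return np.column_stack([np.ones_like(x), x]), y


def test_two_by_two_log_odds_closed_form():
    X, y = _two_by_two(10, 40, 5, 45)
    fit = fit_logistic_array(X, y)
    assert fit.coef[1] == pytest.approx(np.log((10 * 45) / (40 * 5)), abs=1e-6)
    assert fit.coef[0] == pytest.approx(logit(5 / 50), abs=1e-6)


def test_intercept_only_closed_form():
    X = np.ones((10, 1))
    y = np.r_[np.ones(3), np.zeros(7)]
    fit = fit_logistic_array(X, y)
    assert fit.coef[0] == pytest.approx(logit(0.3), abs=1e-8)


def test_score_equation_fitted_sum_equals_deaths():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(500), rng.standard_normal((500, 3))])
    y = (rng.random(500) < expit(X @ np.r_[-2.0, 0.5, -0.3, 0.8])).astype(float)
    fit = fit_logistic_array(X, y)
    assert fit.predict_proba(X).sum() == pytest.approx(y.sum(), abs=1e-6)


def test_against_statsmodels_oracle():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(42)
    X = np.column_stack([np.ones(800), rng.standard_normal((800, 4))])
    y = (rng.random(800) < expit(X @ np.r_[-1.5, 0.4, 0.0, -0.6, 0.2])).astype(float)
    ours = fit_logistic_array(X, y)
    ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(ours.coef, ref.params, atol=1e-6)
    np.testing.assert_allclose(ours.llf, ref.llf, atol=1e-6)
    np.testing.assert_allclose(ours.cov, ref.cov_params(), rtol=1e-4, atol=1e-7)


def test_rank_deficiency_names_collinear_column():
    X = np.column_stack([np.ones(50), np.arange(50.0), 2 * np.arange(50.0)])
    y = np.r_[np.ones(25), np.zeros(25)]
    with pytest.raises(RankDeficiencyError):
        fit_logistic_array(X, y, column_names=["int", "x", "x2"])


def test_separation_raises():
    x = np.r_[np.ones(30), np.zeros(30)]
    X = np.column_stack([np.ones(60), x])
    with pytest.raises(SeparationError):
        fit_logistic_array(X, x.copy())


# -- rare-variable screening -------------------------------------------------


def _rare_frame(n_exposed, n_events_exposed, n_total=2000):
    df = pd.DataFrame({"flag": np.r_[np.ones(n_exposed),
                                     np.zeros(n_total - n_exposed)].astype(int)})
    y = np.zeros(n_total)
    y[:n_events_exposed] = 1  # events only among exposed; enough for the rule
    y[n_exposed:n_exposed + 200] = 1
    return df, y


@pytest.mark.parametrize("n_exp,ev,kept", [
    (99, 50, False),   # fewer than 100 patients
    (150, 29, False),  # fewer than 30 events
    (100, 30, True),   # both boundaries met (strict 'less than')
])
def test_rare_variable_boundaries(n_exp, ev, kept):
    df, y = _rare_frame(n_exp, ev)
    kept_vars, dropped = screen_rare_variables(
        df, [VariableDef("flag", "binary")], y)
    assert (len(kept_vars) == 1) is kept
    assert ("flag" in dropped) is not kept


def test_rare_categorical_level_merges_into_neighbour():
    rng = np.random.default_rng(1)
    lv = rng.choice(["a", "b", "c"], p=[0.6, 0.38, 0.02], size=3000)
    df = pd.DataFrame({"cat": lv})
    y = (rng.random(3000) < 0.1).astype(float)
    kept, dropped = screen_rare_variables(
        df, [VariableDef("cat", "categorical", ("a", "b", "c"), "a")], y)
    term = make_term(df, kept[0])
    assert isinstance(term, CategoricalTerm)
    assert term.group_map()["c"] == "b"  # folded into its neighbour
    assert "cat" in dropped


# -- bivariate screening -----------------------------------------------------


def _binomial_llf(k, n, p):
    return k * np.log(p) + (n - k) * np.log1p(-p)


def test_bivariate_screen_matches_closed_form_2x2():
    """LRT p from closed-form binomial likelihoods of a 2x2 table."""
    df = pd.DataFrame({"x": np.r_[np.ones(100), np.zeros(900)].astype(int)})
    y = np.r_[np.ones(5), np.zeros(95), np.ones(9), np.zeros(891)]
    res = bivariate_screen(df, [LinearTerm("x")], y)
    ll_null = _binomial_llf(14, 1000, 14 / 1000)
    ll_full = _binomial_llf(5, 100, 5 / 100) + _binomial_llf(9, 900, 9 / 900)
    p_expected = float(chi2.sf(2 * (ll_full - ll_null), 1))
    assert res.loc[0, "p_value"] == pytest.approx(p_expected, abs=1e-8)
    assert bool(res.loc[0, "kept"]) == (p_expected <= 0.25)


def test_bivariate_screen_null_discard_rate():
    """Under independence the 0.25 screen discards ~75% of candidates."""
    rng = np.random.default_rng(7)
    discarded = 0
    n_seeds = 40
    for _ in range(n_seeds):
        df = pd.DataFrame({"x": rng.standard_normal(2000)})
        y = (rng.random(2000) < 0.1).astype(float)
        res = bivariate_screen(df, [LinearTerm("x")], y)
        discarded += not res.loc[0, "kept"]
    assert 0.55 <= discarded / n_seeds <= 0.92


def test_bivariate_screen_flags_separation():
    df = pd.DataFrame({"x": np.r_[np.ones(20), np.zeros(20)].astype(int)})
    y = df["x"].to_numpy(float)
    res = bivariate_screen(df, [LinearTerm("x")], y)
    assert res.loc[0, "flag"] == "separation"
    assert bool(res.loc[0, "kept"])


# -- piecewise ---------------------------------------------------------------


def test_piecewise_type_one_error_linear_truth():
    """With a truly linear logit, knots are added in well under 10% of seeds."""
    rng = np.random.default_rng(3)
    n_knotted = 0
    seeds = 30
    for _ in range(seeds):
        x = rng.uniform(0, 100, 2000)
        y = (rng.random(2000) < expit(-3.0 + 0.02 * x)).astype(float)
        tr = PiecewiseLogitTransformer().fit(x, y)
        n_knotted += len(tr.knots_) > 0
    assert n_knotted / seeds <= 0.10


def test_piecewise_recovers_v_shaped_knot():
    rng = np.random.default_rng(8)
    n = 40000
    x = rng.uniform(0, 100, n)
    eta = -2.2 - 0.08 * np.minimum(x - 50, 0)
    y = (rng.random(n) < expit(eta)).astype(float)
    tr = PiecewiseLogitTransformer().fit(x, y)
    assert len(tr.knots_) >= 1
    assert min(abs(k - 50.0) for k in tr.knots_) <= 8.0
    # slope below the knot markedly negative, above near zero
    assert tr.slopes_[0] < -0.04
    assert abs(tr.slopes_[-1]) < 0.03


def test_piecewise_constant_variable_errors():
    with pytest.raises(ValueError, match="constant"):
        PiecewiseLogitTransformer().fit(np.ones(100), np.r_[np.ones(50),
                                                            np.zeros(50)])


def test_piecewise_transform_shape_matches_knots():
    rng = np.random.default_rng(2)
    x = rng.uniform(0, 1, 500)
    y = (rng.random(500) < 0.2).astype(float)
    tr = PiecewiseLogitTransformer().fit(x, y)
    out = tr.transform(x)
    assert out.shape == (500, 1 + len(tr.knots_))


# -- stepwise ----------------------------------------------------------------


def _noise_frame(rng, n, p_noise):
    cols = {f"n{j:02d}": rng.standard_normal(n) for j in range(p_noise)}
    return pd.DataFrame(cols)


def test_forced_all_equals_full_fit():
    rng = np.random.default_rng(5)
    df = _noise_frame(rng, 1000, 3)
    df["x"] = rng.standard_normal(1000)
    y = (rng.random(1000) < expit(-2 + df["x"])).astype(float)
    terms = [LinearTerm(c) for c in df.columns]
    model = stepwise_select(df, [], y, forced=terms)
    _, full = fit_terms(df, terms, y)
    np.testing.assert_allclose(model.coef_.to_numpy(), full.coef, atol=1e-8)


def test_stepwise_selects_true_and_resists_noise():
    rng = np.random.default_rng(6)
    n = 4000
    df = _noise_frame(rng, n, 6)
    df["x"] = rng.standard_normal(n)
    y = (rng.random(n) < expit(-2.5 + 1.0 * df["x"])).astype(float)
    model = stepwise_select(df, [LinearTerm(c) for c in df.columns], y)
    names = {t.name for t in model.terms_}
    assert "x" in names
    assert len(names - {"x"}) <= 1  # at most one spurious entry


def test_stepwise_estimator_sklearn_contract():
    from sklearn.base import clone
    rng = np.random.default_rng(9)
    df = pd.DataFrame({"x": rng.standard_normal(500)})
    y = (rng.random(500) < expit(-1.5 + df["x"])).astype(int)
    est = StepwiseLogisticModel(candidate_terms=[LinearTerm("x")])
    cloned = clone(est)
    cloned.fit(df, y)
    p = cloned.predict_proba(df)
    assert p.shape == (500, 2)
    np.testing.assert_allclose(p.sum(axis=1), 1.0)
    assert cloned.get_params()["p_enter"] == 0.01


def test_model_json_roundtrip(tmp_path, dev_models):
    pre = dev_models["pre"]
    path = tmp_path / "m.json"
    pre.save(path)
    back = StepwiseLogisticModel.load(path)
    cohort = dev_models["cohort"]
    np.testing.assert_allclose(back.predict_risk(cohort),
                               pre.predict_risk(cohort), atol=1e-12)


def test_postop_model_nests_preop(dev_models):
    pre_names = {t.name for t in dev_models["pre"].terms_}
    post_names = {t.name for t in dev_models["post"].terms_}
    assert pre_names <= post_names


def test_forced_terms_survive_null_effect():
    """A pre-op term with no post-op effect stays in the post-op model."""
    rng = np.random.default_rng(12)
    n = 3000
    df = pd.DataFrame({"a": rng.standard_normal(n), "z": rng.standard_normal(n)})
    y = (rng.random(n) < expit(-2.2 + 0.9 * df["z"])).astype(float)
    forced = [LinearTerm("a")]  # null effect, forced anyway
    model = stepwise_select(df, [LinearTerm("z")], y, forced=forced)
    assert {t.name for t in model.terms_} == {"a", "z"}


# -- level merging -----------------------------------------------------------


def _categorical_cohort(rng, effects, n):
    levels = list(effects)
    lv = rng.choice(levels, size=n)
    df = pd.DataFrame({"g": lv})
    eta = -2.3 + df["g"].map(effects).to_numpy()
    y = (rng.random(n) < expit(eta)).astype(float)
    return df, y


def test_merge_levels_combines_similar_ors():
    rng = np.random.default_rng(30)
    df, y = _categorical_cohort(
        rng, {"I": 0.0, "II": 0.5, "III": 0.55, "IV": 1.8}, 8000)
    term = categorical_from_levels("g", ("I", "II", "III", "IV"), "I")
    model = stepwise_select(df, [], y, forced=[term])
    merged = merge_levels(model, df, y, "g")
    t = next(t for t in merged.terms_ if t.name == "g")
    gm = t.group_map()
    assert gm["II"] == gm["III"]  # indistinguishable neighbours merged
    assert gm["I"] != gm["IV"]


def test_merge_levels_keeps_distinct_ors():
    rng = np.random.default_rng(31)
    df, y = _categorical_cohort(
        rng, {"I": 0.0, "II": 1.2, "III": 2.4}, 20000)
    term = categorical_from_levels("g", ("I", "II", "III"), "I")
    model = stepwise_select(df, [], y, forced=[term])
    merged = merge_levels(model, df, y, "g")
    t = next(t for t in merged.terms_ if t.name == "g")
    assert len(set(t.group_map().values())) == 3


def test_selection_config_invariants():
    with pytest.raises(ValueError):
        SelectionConfig(p_screen=0.01, p_select=0.25)
    with pytest.raises(ValueError):
        SelectionConfig(min_patients=0)
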