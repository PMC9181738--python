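"""Generator contracts: determinism, ground-truth bookkeeping, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from dualbench.synthetic import (ConfigError, PiecewiseSpec, SyntheticConfig,
                                 generate_cohort, preop_linear_predictor,
                                 true_center_d)

from conftest import clean_config


def test_same_seed_same_bytes(tmp_path):
    cfg1 = SyntheticConfig(n_centers=3, patients_per_center=150, seed=9)
    cfg2 = SyntheticConfig(n_centers=3, patients_per_center=150, seed=9)
    df1, tv1 = generate_cohort(cfg1)
    df2, tv2 = generate_cohort(cfg2)
    pd.testing.assert_frame_equal(df1, df2)
    pd.testing.assert_frame_equal(tv1.center, tv2.center)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    df1.to_csv(p1, index=False)
    df2.to_csv(p2, index=False)
    assert p1.read_bytes() == p2.read_bytes()


def test_different_seed_differs():
    df1, _ = generate_cohort(SyntheticConfig(n_centers=2, patients_per_center=100, seed=1))
    df2, _ = generate_cohort(SyntheticConfig(n_centers=2, patients_per_center=100, seed=2))
    assert not df1.equals(df2)


def test_zero_shift_zero_noise_gives_zero_d():
    cfg = clean_config(n_centers=4, patients_per_center=200, seed=5,
                       postop_noise_sd=0.0)
    _, tv = generate_cohort(cfg)
    assert np.allclose(tv.center["d"], 0.0)


def test_true_center_d_matches_direct_summation():
    """Oracle: recompute d from raw covariates and the generating formula."""
    shift = 0.5
    cfg = clean_config(n_centers=3, patients_per_center=400, seed=21,
                       postop_noise_sd=0.0, center_intraop_shift={"C02": shift})
    df, tv = generate_cohort(cfg)
    rows = df[df["center_id"] == "C02"]
    lp = preop_linear_predictor(rows, cfg.preop_coefficients)
    e_pre = expit(lp).sum()
    e_post = expit(lp + shift).sum()
    expected = (e_post - e_pre) / e_pre
    assert true_center_d(tv, "C02") == pytest.approx(expected, abs=1e-10)
    assert true_center_d(tv, "C01") == pytest.approx(0.0, abs=1e-12)


def test_intercept_only_mortality_binomial_oracle():
    coefs = {
        "intercept": float(logit(0.05)),
        "age": PiecewiseSpec((), (0.0,), 0.0),
        "creat_clear": PiecewiseSpec((), (0.0,), 0.0),
        "sex_male": 0.0,
        "nyha": {"I": 0.0, "II-III": 0.0, "IV": 0.0},
        "ef_class": {">50": 0.0, "30-50": 0.0, "<30": 0.0},
        "urgency": {"elective": 0.0, "deferred": 0.0, "emergent": 0.0,
                    "salvage": 0.0},
        "cabg": 0.0, "avs": 0.0, "mvp": 0.0, "mvr": 0.0, "aorta": 0.0,
        "redo": 0.0,
    }
    cfg = clean_config(n_centers=20, patients_per_center=1000, seed=77,
                       preop_coefficients=coefs, postop_noise_sd=0.0)
    df, _ = generate_cohort(cfg)
    n = len(df)
    rate = (df["hospital_outcome"] == "dead").mean()
    se = np.sqrt(0.05 * 0.95 / n)
    assert abs(rate - 0.05) <= 3 * se


def test_shift_monotonicity():
    """Raising one center's shift raises its true d and touches no other."""
    base = clean_config(n_centers=5, patients_per_center=300, seed=13)
    more = clean_config(n_centers=5, patients_per_center=300, seed=13,
                        center_intraop_shift={"C02": 0.4})
    _, tv0 = generate_cohort(base)
    _, tv1 = generate_cohort(more)
    d0 = tv0.center.set_index("center_id")["d"]
    d1 = tv1.center.set_index("center_id")["d"]
    assert d1["C02"] > d0["C02"]
    others = [c for c in d0.index if c != "C02"]
    assert np.allclose(d0[others], d1[others])


def test_observed_deaths_calibrated_to_true_e_post():
    """Deaths per center stay within 3 binomial SE of true e_post."""
    bad = total = 0
    for seed in range(25):
        cfg = clean_config(n_centers=4, patients_per_center=800, seed=seed,
                           center_intraop_shift={"C01": 0.3})
        df, tv = generate_cohort(cfg)
        for _, row in tv.center.iterrows():
            sub = tv.patient[tv.patient["center_id"] == row["center_id"]]
            var = (sub["p_post"] * (1 - sub["p_post"])).sum()
            deaths = ((df["center_id"] == row["center_id"])
                      & (df["hospital_outcome"] == "dead")).sum()
            total += 1
            if abs(deaths - row["e_post"]) > 3 * np.sqrt(var):
                bad += 1
    assert bad / total <= 0.02


@pytest.mark.parametrize("field,value", [
    ("readmission_rate", 1.5),
    ("missing_outcome_rate", -0.1),
    ("n_centers", 0),
    ("postop_noise_sd", -1.0),
])
def test_config_validation_names_field(field, value):
    with pytest.raises(ConfigError, match=field):
        SyntheticConfig(**{field: value})


def test_piecewise_spec_validation():
    with pytest.raises(ConfigError, match="knots"):
        PiecewiseSpec((60.0, 50.0), (0.1, 0.2, 0.3), 50.0)
    spec = PiecewiseSpec((60.0,), (0.0, 0.05), 60.0)
    # continuous at the knot, zero at anchor
    assert spec(60.0) == 0.0
    assert spec(61.0) == pytest.approx(0.05)
    assert spec(59.0) == pytest.approx(0.0)


def test_true_center_d_errors():
    _, tv = generate_cohort(clean_config(n_centers=2, patients_per_center=50,
                                         seed=1))
    with pytest.raises(KeyError):
        true_center_d(tv, "C99")


def test_truth_roundtrip_json(tmp_path):
    from dualbench.synthetic import TrueValues
    _, tv = generate_cohort(clean_config(n_centers=2, patients_per_center=60,
                                         seed=3))
    path = tmp_path / "tv.json"
    tv.to_json(path)
    back = TrueValues.from_json(path)
    assert np.allclose(back.patient["p_post"], tv.patient["p_post"])
    assert np.allclose(back.center["d"], tv.center["d"])
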