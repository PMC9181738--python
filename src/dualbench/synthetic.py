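"""Synthetic multi-center perioperative cohorts with known risk structure.

The generator emulates a registry of cardiac-surgery ICU admissions: a
pre-operative mortality risk driven by demographics, comorbidity class and
procedure flags (with piecewise-linear age and creatinine-clearance effects
on the logit), a per-center intraoperative log-odds shift, patient-level
intraoperative variability recorded as ICU-admission severity covariates,
Bernoulli hospital outcomes, and the data messiness the cohort filters must
handle (re-admissions, month-level record incompleteness, missing outcomes,
a few paediatric / Type-B dissection / ICU-before-surgery records).

The post-operative linear predictor is

    lp_post = lp_pre + shift[center] + s * sum_k beta_k * eps_k

where ``eps_k ~ N(0,1)`` and ``s`` scales the patient-level contribution to
standard deviation ``postop_noise_sd``.  The recorded severity covariates
are ``sev_1 = eps_1 + shift[center] / (s * beta_1)`` and ``sev_k = eps_k``
for the rest, so the identity ``sum_k (s beta_k) sev_k = u + shift`` holds
exactly: the first (dominant) severity covariate carries the whole
center-level intraoperative signal, mirroring the real design where
surgical damage manifests in the patient's state at ICU admission.  A
post-operative model that includes ``sev_1`` therefore recovers center
effects even if it drops the weaker severity covariates (which are
independent of everything else, so omitting them leaves expected-death sums
unbiased).  With ``postop_noise_sd = 0`` the severity covariates are
recorded as pure noise and ``lp_post = lp_pre + shift``.

A patient's *true pre-operative probability* is the risk given pre-operative
information only, i.e. the Bernoulli probability marginalised over the
not-yet-realised patient-level intraoperative variability at a reference
(zero-shift) center: ``p_pre = E_u[expit(lp_pre + u)]`` (Gauss–Hermite
quadrature; reduces to ``expit(lp_pre)`` when ``postop_noise_sd = 0``).  The
*true post-operative probability* conditions on the realised course:
``p_post = expit(lp_post)``.  Defined this way the per-center true d is zero
in expectation for unshifted centers, which is also what a pre-operative
model fitted to outcomes estimates.

Every draw comes from one ``numpy`` Generator seeded from ``config.seed``,
so identical configs produce byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class PiecewiseSpec:
    """True piecewise-linear log-odds effect, continuous and zero at ``anchor``."""

    knots: tuple[float, ...]
    slopes: tuple[float, ...]  # len(knots) + 1 segment slopes
    anchor: float

    def __post_init__(self):
        if list(self.knots) != sorted(set(self.knots)):
            raise ConfigError("knots: must be strictly increasing")
        if len(self.slopes) != len(self.knots) + 1:
            raise ConfigError("slopes: need one slope per segment (knots + 1)")
        if self.knots and self.anchor > self.knots[0]:
            raise ConfigError("anchor: must not exceed the first knot")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = self.slopes[0] * (x - self.anchor)
        for j, k in enumerate(self.knots):
            out = out + (self.slopes[j + 1] - self.slopes[j]) * np.maximum(x - k, 0.0)
        return out

    def to_dict(self):
        return {"knots": list(self.knots), "slopes": list(self.slopes),
                "anchor": self.anchor}

    @classmethod
    def from_dict(cls, d):
        return cls(tuple(d["knots"]), tuple(d["slopes"]), d["anchor"])


def _default_preop_coefficients() -> dict:
    # Log-odds effects loosely matching published cardiac-surgery risk models;
    # the intercept is calibrated so overall hospital mortality is ~3.6%.
    return {
        "intercept": -4.90,
        "age": PiecewiseSpec(knots=(60.0,), slopes=(0.005, 0.055), anchor=60.0),
        "creat_clear": PiecewiseSpec(knots=(60.0,), slopes=(-0.028, -0.004),
                                     anchor=60.0),
        "sex_male": -0.10,
        "nyha": {"I": 0.0, "II-III": 0.45, "IV": 1.50},
        "ef_class": {">50": 0.0, "30-50": 0.40, "<30": 1.10},
        "urgency": {"elective": 0.0, "deferred": 0.45, "emergent": 1.05,
                    "salvage": 2.20},
        "cabg": 0.10,
        "avs": 0.10,
        "mvp": -0.25,
        "mvr": 0.40,
        "aorta": 0.55,
        "redo": 0.50,
    }


def _default_marginals() -> dict:
    # Marginal covariate distributions chosen to resemble a contemporary
    # European adult cardiac-surgery case mix (~68% male, median age 70,
    # ~84% elective, valve/CABG dominated).
    return {
        "age_mean": 68.0, "age_sd": 11.0, "age_min": 18.0, "age_max": 94.0,
        "male_frac": 0.676,
        "nyha_probs": {"I": 0.502, "II-III": 0.463, "IV": 0.035},
        "ef_probs": {">50": 0.678, "30-50": 0.296, "<30": 0.026},
        "clearance_log_median": 74.0, "clearance_log_sd": 0.44,
        "clearance_min": 5.0, "clearance_max": 180.0,
        "urgency_probs": {"elective": 0.838, "deferred": 0.086,
                          "emergent": 0.070, "salvage": 0.006},
        "flag_rates": {"cabg": 0.48, "avs": 0.365, "mvp": 0.112, "mvr": 0.116,
                       "aorta": 0.113, "redo": 0.068},
    }


_PROB_FIELDS = (
    "readmission_rate", "incomplete_month_rate", "incomplete_record_rate_within",
    "background_incomplete_rate", "missing_outcome_rate", "pediatric_rate",
    "typeb_rate", "icu_before_rate",
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic registry.

    ``center_intraop_shift`` maps center id (e.g. ``"C03"``) to the log-odds
    shift applied between the pre- and post-operative stage; centers not
    listed get 0.  Rates default to small values so the study filters have
    work to do without dominating the cohort.
    """

    n_centers: int = 20
    patients_per_center: int = 800
    seed: int = 0
    preop_coefficients: dict = field(default_factory=_default_preop_coefficients)
    center_intraop_shift: dict = field(default_factory=dict)
    postop_effects: tuple[float, ...] = (0.9, 0.35, 0.25)
    postop_noise_sd: float = 0.5
    readmission_rate: float = 0.02
    incomplete_month_rate: float = 0.05
    incomplete_record_rate_within: float = 0.30
    background_incomplete_rate: float = 0.01
    missing_outcome_rate: float = 0.02
    pediatric_rate: float = 0.003
    typeb_rate: float = 0.010
    icu_before_rate: float = 0.010
    n_months: int = 24
    start_year: int = 2016
    marginals: dict = field(default_factory=_default_marginals)

    def __post_init__(self):
        if self.n_centers < 1:
            raise ConfigError("n_centers: must be >= 1")
        if self.patients_per_center < 1:
            raise ConfigError("patients_per_center: must be >= 1")
        if self.n_months < 1:
            raise ConfigError("n_months: must be >= 1")
        if self.postop_noise_sd < 0:
            raise ConfigError("postop_noise_sd: must be >= 0")
        for f in _PROB_FIELDS:
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{f}: probability must be in [0, 1]")
        for key in ("age", "creat_clear"):
            spec = self.preop_coefficients.get(key)
            if spec is not None and not isinstance(spec, PiecewiseSpec):
                self.preop_coefficients[key] = PiecewiseSpec.from_dict(spec)

    def center_ids(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_centers)]

    def shift_for(self, center_id: str) -> float:
        return float(self.center_intraop_shift.get(center_id, 0.0))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("age", "creat_clear"):
            spec = d["preop_coefficients"].get(key)
            if isinstance(spec, PiecewiseSpec):  # pragma: no cover
                d["preop_coefficients"][key] = spec.to_dict()
            elif isinstance(self.preop_coefficients.get(key), PiecewiseSpec):
                d["preop_coefficients"][key] = self.preop_coefficients[key].to_dict()
        d["postop_effects"] = list(self.postop_effects)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "postop_effects" in d:
            d["postop_effects"] = tuple(d["postop_effects"])
        return cls(**d)


SEVERITY_PREFIX = "sev"

#: Column dictionary of the generated cohort CSV.
COLUMN_DICTIONARY = {
    "patient_id": "unique patient identifier (center-scoped)",
    "center_id": "ICU / hospital identifier",
    "admission_ts": "ISO timestamp of ICU admission",
    "admission_year": "calendar year of admission",
    "admission_month": "calendar month of admission (1-12)",
    "readmission_index": "1 for first ICU admission, 2+ for re-admissions",
    "age": "age in years at admission",
    "sex": "M or F",
    "nyha": "NYHA functional class: I, II-III, IV",
    "ef_class": "ejection-fraction class: >50, 30-50, <30 (%)",
    "creat_clear": "creatinine clearance, mL/min",
    "urgency": "elective, deferred, emergent, salvage",
    "cabg": "coronary artery bypass graft performed (0/1)",
    "avs": "aortic valve surgery (0/1)",
    "mvp": "mitral valve repair (0/1)",
    "mvr": "mitral valve replacement (0/1)",
    "aorta": "ascending / thoracic aorta surgery (0/1)",
    "redo": "redo intervention (0/1)",
    "typeB_dissection_repair": "surgery or endovascular repair of Type-B dissection (0/1)",
    "admitted_to_icu_before_surgery": "ICU admission preceded cardiac surgery (0/1)",
    "complete": "record passed completeness checks (0/1)",
    "hospital_outcome": "alive, dead or missing",
    f"{SEVERITY_PREFIX}*": "post-operative severity covariates at ICU admission",
}


@dataclass
class TrueValues:
    """Generating probabilities and the per-center truth derived from them.

    ``patient`` is aligned with the cohort rows and holds the true pre- and
    post-operative death probabilities of every record.  ``center`` holds,
    over eligible records (first adult admissions, no Type-B repair, no ICU
    stay before surgery), the true expected deaths and the true relative
    difference d = (e_post - e_pre) / e_pre.
    """

    patient: pd.DataFrame
    center: pd.DataFrame
    eligible: pd.Series

    def center_table(self, mask=None) -> pd.DataFrame:
        m = self.eligible if mask is None else (self.eligible & mask)
        sub = self.patient.loc[m]
        grp = sub.groupby(self.patient.loc[m, "center_id"], sort=True)
        tab = grp.agg(n=("p_pre", "size"), e_pre=("p_pre", "sum"),
                      e_post=("p_post", "sum"))
        tab["d"] = (tab["e_post"] - tab["e_pre"]) / tab["e_pre"]
        return tab.reset_index().rename(columns={"index": "center_id"})

    def to_json(self, path) -> None:
        payload = {
            "center": self.center.to_dict(orient="list"),
            "patient": {c: self.patient[c].tolist() for c in self.patient.columns},
            "eligible": self.eligible.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TrueValues":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(patient=pd.DataFrame(payload["patient"]),
                   center=pd.DataFrame(payload["center"]),
                   eligible=pd.Series(payload["eligible"], dtype=bool))


def _choice(rng, probs: dict, size: int) -> np.ndarray:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(keys, dtype=object), size=size, p=p)


def marginal_preop_probability(lp_pre, sigma: float, n_nodes: int = 31) -> np.ndarray:
    """Death probability given pre-operative information only.

    Marginalises the Bernoulli probability over the patient-level
    intraoperative log-odds noise ``u ~ N(0, sigma^2)`` by Gauss–Hermite
    quadrature; exact ``expit(lp_pre)`` when ``sigma == 0``.
    """
    lp = np.asarray(lp_pre, dtype=float)
    if sigma == 0.0:
        return expit(lp)
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    vals = expit(lp[:, None] + np.sqrt(2.0) * sigma * x[None, :])
    return vals @ w / np.sqrt(np.pi)


def preop_linear_predictor(df: pd.DataFrame, coefs: dict) -> np.ndarray:
    """True pre-operative log-odds of hospital death for each record."""
    lp = np.full(len(df), float(coefs["intercept"]))
    lp += coefs["age"](df["age"].to_numpy(float))
    lp += coefs["creat_clear"](df["creat_clear"].to_numpy(float))
    lp += float(coefs["sex_male"]) * (df["sex"].to_numpy() == "M")
    for var in ("nyha", "ef_class", "urgency"):
        eff = coefs[var]
        lp += df[var].map(eff).to_numpy(float)
    for flag in ("cabg", "avs", "mvp", "mvr", "aorta", "redo"):
        lp += float(coefs[flag]) * df[flag].to_numpy(float)
    return lp


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, TrueValues]:
    """Generate one synthetic registry and its ground truth.

    Returns the cohort table (one row per ICU admission, re-admissions
    included) and the :class:`TrueValues` computed from the generating
    probabilities.
    """
    rng = np.random.default_rng(config.seed)
    marg = config.marginals
    rows = []
    for ci, center in enumerate(config.center_ids()):
        n = config.patients_per_center
        age = np.clip(rng.normal(marg["age_mean"], marg["age_sd"], n),
                      marg["age_min"], marg["age_max"])
        pediatric = rng.random(n) < config.pediatric_rate
        age[pediatric] = rng.uniform(8.0, 16.0, int(pediatric.sum()))
        sex = np.where(rng.random(n) < marg["male_frac"], "M", "F")
        nyha = _choice(rng, marg["nyha_probs"], n)
        ef = _choice(rng, marg["ef_probs"], n)
        clearance = np.clip(
            np.exp(rng.normal(np.log(marg["clearance_log_median"]),
                              marg["clearance_log_sd"], n)),
            marg["clearance_min"], marg["clearance_max"])
        urgency = _choice(rng, marg["urgency_probs"], n)
        flags = {k: (rng.random(n) < r).astype(int)
                 for k, r in marg["flag_rates"].items()}
        month_idx = rng.integers(0, config.n_months, n)
        day = rng.integers(0, 28, n)
        hour = rng.integers(0, 24, n)
        typeb = (rng.random(n) < config.typeb_rate).astype(int)
        icu_before = (rng.random(n) < config.icu_before_rate).astype(int)
        center_df = pd.DataFrame({
            "patient_id": [f"{center}-{i:05d}" for i in range(n)],
            "center_id": center,
            "month_idx": month_idx, "day": day, "hour": hour,
            "readmission_index": 1,
            "age": np.round(age, 1), "sex": sex, "nyha": nyha, "ef_class": ef,
            "creat_clear": np.round(clearance, 1), "urgency": urgency,
            **flags,
            "typeB_dissection_repair": typeb,
            "admitted_to_icu_before_surgery": icu_before,
        })
        rows.append(center_df)
    df = pd.concat(rows, ignore_index=True)

    # intraoperative stage
    k = len(config.postop_effects)
    beta = np.array(config.postop_effects, dtype=float)
    eps = rng.standard_normal((len(df), k))
    sigma = config.postop_noise_sd
    shift = df["center_id"].map(config.shift_for).to_numpy(float)
    if sigma > 0:
        s = sigma / np.linalg.norm(beta)
        u = s * eps @ beta
        sev = eps.copy()
        sev[:, 0] += shift / (s * beta[0])
    else:
        u = np.zeros(len(df))
        sev = eps
    for j in range(k):
        df[f"{SEVERITY_PREFIX}{j + 1}"] = np.round(sev[:, j], 4)

    lp_pre = preop_linear_predictor(df, config.preop_coefficients)
    lp_post = lp_pre + shift + u
    p_pre = marginal_preop_probability(lp_pre, sigma)
    p_post = expit(lp_post)
    dead = rng.random(len(df)) < p_post
    outcome = np.where(dead, "dead", "alive")
    outcome[rng.random(len(df)) < config.missing_outcome_rate] = "missing"
    df["hospital_outcome"] = outcome

    # month-level completeness degradation
    degraded = {}
    for center in config.center_ids():
        flips = rng.random(config.n_months) < config.incomplete_month_rate
        for m in range(config.n_months):
            degraded[(center, m)] = bool(flips[m])
    stratum_degraded = np.array(
        [degraded[(c, m)] for c, m in zip(df["center_id"], df["month_idx"])]
    )
    draw = rng.random(len(df))
    incomplete = np.where(stratum_degraded,
                          draw < config.incomplete_record_rate_within,
                          draw < config.background_incomplete_rate)
    df["complete"] = (~incomplete).astype(int)

    # re-admissions: duplicated patients with a later timestamp
    re_mask = rng.random(len(df)) < config.readmission_rate
    if re_mask.any():
        dup = df.loc[re_mask].copy()
        dup["readmission_index"] = 2
        dup["day"] = np.minimum(dup["day"] + rng.integers(1, 14, len(dup)), 27)
        df = pd.concat([df, dup], ignore_index=True)
        p_pre = np.concatenate([p_pre, p_pre[re_mask]])
        p_post = np.concatenate([p_post, p_post[re_mask]])

    month0 = df["month_idx"].to_numpy()
    df["admission_year"] = config.start_year + month0 // 12
    df["admission_month"] = month0 % 12 + 1
    ts = pd.to_datetime(dict(year=df["admission_year"], month=df["admission_month"],
                             day=df["day"] + 1, hour=df["hour"]))
    df["admission_ts"] = ts.dt.strftime("%Y-%m-%dT%H:00:00")
    df = df.drop(columns=["month_idx", "day", "hour"])

    df["_p_pre"], df["_p_post"] = p_pre, p_post
    df = df.sort_values(["center_id", "patient_id", "readmission_index"],
                        kind="mergesort").reset_index(drop=True)
    patient = pd.DataFrame({
        "center_id": df["center_id"],
        "p_pre": df.pop("_p_pre"),
        "p_post": df.pop("_p_post"),
    })
    eligible = (
        (df["readmission_index"] == 1)
        & (df["age"] > 16)
        & (df["typeB_dissection_repair"] == 0)
        & (df["admitted_to_icu_before_surgery"] == 0)
    )
    tv = TrueValues(patient=patient, center=pd.DataFrame(), eligible=eligible)
    tv.center = tv.center_table()
    return df, tv


def true_center_d(true_values: TrueValues, center: str) -> float:
    """True relative difference d for one center, from generating probabilities."""
    tab = true_values.center.set_index("center_id")
    if center not in tab.index:
        raise KeyError(f"center {center!r} has no eligible patients")
    row = tab.loc[center]
    if row["e_pre"] <= 0:
        raise ZeroDivisionError(f"center {center!r} has zero expected deaths pre-op")
    return float(row["d"])


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"hospital_outcome": str})
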