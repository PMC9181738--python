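# Methods

## The double-fold model

Let `x_i` be a patient's pre-operative covariates and `z_i` the severity
covariates measured at ICU admission after cardiac surgery. Two logistic
regression models for in-hospital death are developed on a common training
set:

- **pre-operative model** — `logit P(death) = α + f(x_i)`, candidates are
  variables available at operating-theatre admission;
- **post-operative model** — `logit P(death) = α' + f'(x_i) + g(z_i)`,
  where every term selected into the pre-operative model is forced into the
  post-operative model regardless of significance (coefficients are always
  re-estimated, never carried over), keeping the two stages clinically
  comparable.

For a unit (center, or center × subgroup) with patients `U`,
`e_pre = Σ_{i∈U} p̂_pre,i` and `e_post = Σ_{i∈U} p̂_post,i` are expected
death counts and

```
d = (e_post − e_pre) / e_pre
```

is the unit's intraoperative-performance statistic. Because both models are
fitted to the *same realised outcomes*, the pooled pre-operative model
already absorbs the cohort-average intraoperative effect; `d` is therefore
a **relative** measure — a center's deviation from the average
intraoperative course, not from a counterfactual of perfect surgery. Two
consequences worth knowing:

- if one center of `N` carries an intraoperative log-odds shift `δ`, the
  pooled pre-operative model inflates everyone's baseline by roughly
  `exp(δ/N)`, so the remaining centers drift slightly negative and the
  deviant center's `d` is attenuated by the same factor (visible in the
  README example, where the single-center attenuation `exp(0.40/6) ≈ 1.07`
  reproduces the observed gap between the generator truth 0.46 and the
  estimate 0.37 almost exactly);
- the attenuation vanishes as the number of centers grows; with the study's
  ~20 centers it is below 2% for realistic shifts.

### Bootstrap confidence intervals

The 95% CI of each unit's `d` is a percentile bootstrap (2.5th/97.5th
percentiles over `B` replicates, default `B = 1000`). Each replicate
resamples the **whole cohort** with replacement (unstratified, matching the
protocol; per-center stratified resampling is available as an option) and
re-estimates the *coefficients* of both models with the selected term
structure fixed; repeating the entire variable-selection protocol per
replicate is available behind `BootstrapConfig(refit_policy="reselect")`
but is off by default — it is orders of magnitude slower and makes the
replicate statistic jump between model spaces. Replicates in which a unit
draws zero expected pre-operative deaths are dropped for that unit (with a
logged count); a CI is reported only when ≥80% of replicates were usable.
Resamples that make a rare dummy level's event cell empty produce boundary
(quasi-separated) fits; these are accepted in bootstrap refits because the
fitted-probability limit exists and keeps expected-event sums valid.

## Model development protocol

All selection tests are likelihood-ratio tests (well defined in the
presence of forced terms); level-merge contrasts use Wald tests on the
fitted covariance.

1. **Rare-variable screen** — a binary variable whose exposed subgroup has
   fewer than `min_patients = 100` records or fewer than `min_events = 30`
   deaths is excluded (strict `<`, so 100/30 survives); a rare categorical
   level is folded into its neighbour in the declared clinical order.
2. **Bivariate screen** — single-covariate logistic fits; candidates with
   LRT p > 0.25 are discarded. Candidates whose screen fit fails (e.g.
   perfect separation) are flagged and kept for review.
3. **Linearity of the logit** — for each continuous candidate, candidate
   knots are placed at the inner deciles; the best single-knot hinge model
   (by likelihood) is tested against the linear model, and a second knot
   against the first, each at the 0.05 level. Because the knot maximises the
   likelihood over the searched grid, the LRT p-value is Bonferroni-adjusted
   by the number of configurations searched; without the adjustment the
   nominal gate would reject linearity for a truly linear effect far more
   often than 5%. Maximum two knots; with zero knots the term is plain
   linear.
4. **Stepwise selection** — alternating forward entry (smallest LRT p,
   enter if p < 0.01) and backward elimination (largest p among non-forced
   terms, drop if p ≥ 0.01) until stable; ties break on the smaller p then
   the lexically smaller term name, a 20-cycle cap raises an oscillation
   error naming the cycling terms. The procedure is deterministic given the
   data.
5. **Level merging** — after selection, adjacent level groups (ordered by
   estimated odds ratio) of each categorical term are merged while their
   pairwise Wald contrast has p ≥ 0.05 *and* the merged raw levels form a
   clinically admissible group: by default any contiguous block of the
   declared level order (so NYHA II and III may merge, I and IV may not
   skip over II–III); explicit `merge_groups` on the variable definition
   override this. The model is refit after every merge, making "clinical
   reasoning" an auditable configuration input rather than hidden code.

The core fitter is a Newton/IRLS maximum-likelihood solver with step
halving, convergence at |Δdeviance| < 1e-8 (cap 100 iterations), pivoted-QR
detection of collinear columns, and separation detection via the fitted
linear predictor (|η| > 20 ⇒ fitted probabilities at machine 0/1). It is
deliberately lightweight because screening, selection and the bootstrap
perform thousands of fits; the test suite cross-checks coefficients,
covariance and log-likelihood against statsmodels' GLM on the same designs.
On any converged fit with an intercept the canonical-link score equation
guarantees Σ p̂ = observed deaths (tested at 1e-6).

## Evaluation

**Discrimination** is the tie-corrected Mann–Whitney concordance (AUC),
with the exhaustive pair-counting oracle asserted exactly on inputs up to
200 records.

**Calibration** uses a polynomial recalibration belt and test. With
`g = logit(p̂)`, logistic models `logit P = Σ_{j≤m} β_j g^j` of increasing
degree are fitted; the degree grows while the next term's LRT improves fit
at the 0.95 confidence level (max degree 4). The test statistic is the
likelihood ratio of the selected polynomial against the identity line
`logit P = g`. Because the degree is data-selected, the null distribution
is not a plain chi-square: each accepted increment contributes a
chi-square(1) *truncated* above the selection threshold, and the p-value is
computed from the numerical convolution of the base chi-square with those
truncated increments. Evaluation on held-out data (`devel="external"`)
starts at degree 1 with a 2-df base; on the training data
(`devel="internal"`) the degree-1 recalibration is exactly the identity by
the ML score equations, so selection starts at degree 2 with a 1-df base.
Under the null the p-value is uniform: a 500-replicate simulation at
n = 2000 gives a 5.4% rejection rate at the 0.05 level (KS test against
uniformity p = 0.67), and halving all probabilities is rejected essentially
always at that sample size. The belt at confidence level `cl` projects the
selection-adjusted confidence ellipsoid of the polynomial coefficients
pointwise onto the recalibration curve.

Descriptive cohort tables use the Wilcoxon–Mann–Whitney test for continuous
variables and the chi-squared test (no continuity correction by default;
flag available) for categorical ones, with percentages always recomputed
from counts.

## Synthetic registry

The generator emulates a two-year, multi-center adult cardiac-surgery ICU
registry (defaults: 20 centers × 800 admissions). Covariate marginals are
configuration with defaults resembling a contemporary European case mix —
~68% male, median age 70, ~84% elective interventions, valve/CABG-dominated
procedures, creatinine clearance log-normal with median 74 mL/min; no joint
covariate structure is claimed. The true pre-operative logit combines an
intercept (calibrated once so overall hospital mortality is ~3.6%),
piecewise-linear age and creatinine-clearance effects (one knot at 60 in
each), and categorical effects for NYHA class, ejection-fraction class,
urgency and procedure flags.

The intraoperative stage adds a per-center log-odds shift and a patient
contribution `u = s·Σ β_k ε_k` scaled to `postop_noise_sd`. The recorded
ICU severity covariates satisfy `Σ (s β_k) sev_k = u + shift` with the
whole center signal carried by the first, dominant covariate, so a
post-operative model that selects `sev1` recovers center effects even when
the weaker severity covariates are dropped (they are independent of
everything else, so omitting them leaves expected-death sums unbiased).

**Ground truth.** The true post-operative probability conditions on the
realised course, `p_post = expit(lp_pre + shift + u)`. The true
pre-operative probability is the risk *given pre-operative information
only*, i.e. marginalised over the unrealised intraoperative noise at a
reference (zero-shift) center: `p_pre = E_u[expit(lp_pre + u)]`
(Gauss–Hermite quadrature, 31 nodes). This matches what a pre-operative
model fitted to outcomes estimates, makes every unshifted center's true d
zero in expectation even with intraoperative noise present, and reduces to
`expit(lp_pre)` exactly when the noise is zero — in which case zero shifts
give d ≡ 0 identically.

Messiness knobs (all probabilities, all configurable): re-admissions
(duplicate patient IDs with later timestamps, default 2%), degraded
(center, month) strata (5% of strata; 30% of their records incomplete,
versus 1% background) feeding the 10% month filter, missing outcomes (2%),
and small rates of paediatric, Type-B-repair and ICU-before-surgery records
for the eligibility rules to remove. What the generator does **not**
emulate: real joint covariate distributions, secular trends, within-surgeon
clustering, informative missingness — so passing recovery tests demonstrate
the estimator's behaviour under a correctly specified risk structure, not
robustness to real-registry misspecification.

## Cohort filters and split

Filters run in a fixed, documented order (adults > 16 strictly; Type-B
repairs; ICU-before-surgery; first admission only; month completeness;
missing outcomes), each reporting in/excluded/out counts with conservation
enforced, so composed reports chain into a study flowchart. The month rule
removes **every** record of a (center, month) stratum whose incomplete
fraction strictly exceeds 10% — complete records included, since the filter
targets site-level data quality — and strata are per center, so one
center's bad month cannot evict another center's patients. The
train/validation split is simple random sampling without stratification,
`round(0.85·N)` training records under banker's rounding (15,533 records
give 13,203/2,330). Missing covariate values that survive the filters are
handled by complete-case restriction per fitted model with logged counts;
no imputation.

## Problem sizes used by the automated checks

The statistical acceptance checks run at sizes chosen to finish in a
routine CI budget while keeping every acceptance bar at its stated value:
parameter recovery uses 30 replicate experiments of 12 centers × 600
patients with B = 200 (CI must cover the generator's true d in ≥ 90% of
runs); null coverage uses 6 seeds × 12 centers (95% CIs contain zero at the
nominal rate within three binomial standard errors); the calibration
type-I simulation uses the full 500 replicates at n = 2000; the stepwise
operating-characteristics check uses 100 seeds at n = 5000 with eight noise
covariates (true-covariate selection ≥ 95%, per-variable noise inclusion
within Monte-Carlo noise of the nominal 1%). Twelve centers are used in the
recovery experiments because, as discussed above, `d` is relative: with
very few centers a single deviant site contaminates the pooled
pre-operative baseline and the attenuation `exp(δ/N)` becomes comparable to
the CI width.

## Known limitations

- `d` compares a center with the cohort average, not an external standard;
  a registry whose centers are all equally poor shows everyone near zero.
- The percentile bootstrap refits coefficients, not the selection path, so
  model-selection uncertainty is not propagated by default.
- The calibration-belt band uses the pointwise ellipsoid projection; joint
  (whole-curve) coverage is not asserted.
- Level merging explores adjacent pairs greedily (largest p first); with
  many levels the merge path, like any stepwise procedure, is a heuristic.
- The exact printed split sizes of the motivating study (13,211/2,322 of
  15,533) are not an 85/15 rounding under any convention we know; the
  package's split is exactly `round(0.85·N)`.
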