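# Methods

`allrisk` implements a complete prognostic-index (PI) methodology for
relapse risk in pediatric B-cell acute lymphoblastic leukemia (B-ALL):
covariate transformation, Cox proportional-hazards model development
with diagnostics, an external/internal validation battery, data-driven
discretization of the continuous index into ordered risk groups, and
survival-curve comparison of competing risk classifications. This note
records the model, the assumptions, the tunable parameters, and the
design choices made where the design was genuinely open.

## The model

For patient $i$ with covariate vector $x_i$, the hazard of relapse (or
death in remission) from end of induction (EOI) is

$$\lambda(t \mid x_i) = \lambda_0(t)\, e^{\beta^\top x_i},$$

and the prognostic index is the **uncentered linear predictor**
$\mathrm{PI}_i = \beta^\top x_i$. The eight model covariates are:

| covariate | transform | unit/coding |
|---|---|---|
| `tau_d29` | $\tau(\mathrm{MRD}) = -\ln(\mathrm{MRD})$, floored | tau units |
| `tau_d8`  | same, day-8 peripheral blood | tau units |
| `frg` / `urg` | favorable / unfavorable risk genetics | 0/1, mutually exclusive |
| `wbc_log` | $\ln(\mathrm{WBC})$, WBC in $\times 10^9$/L | log units |
| `cns2` / `cns3` | CNS status dummies, CNS1 reference | 0/1 |
| `age` | age at diagnosis | years |

MRD is handled on the fraction scale (0.01% ≡ 1e-4). Values below the
detection threshold `cap_threshold = 1e-5` (including exactly zero) are
assigned the transform of `floor_fraction = 1e-6`, so the transform is
capped at $-\ln(10^{-6}) = 13.8155$ (13.82 at two decimals). Both
constants, and the log base, are configurable; internal computation
keeps full floating-point precision and rounds only for display.

Three coefficient sets ship as config data (`config/coefficients.json`)
rather than code constants, so model updating is a config change: the
externally applied UKALL equation, the same model re-derived on the
external cohort, and the eight-covariate index with its published
risk-group cutpoints (−1.377, −0.589, 0.093). The UKALL good-/high-risk
cytogenetics indicators are mapped onto the cohort schema's `frg`/`urg`
flags in that file, where the mapping can be swapped.

## Cox engine

The partial likelihood is maximized by Newton iteration with
step-halving (relative log-likelihood tolerance 1e-9, 100 iterations
maximum; failure raises, never returns silently). Efron tie handling is
the default; Breslow is available for cross-checking against other
toolchains, and the two coincide exactly when no event times are tied.
The covariance is the inverse observed information. The engine is
written directly against the partial likelihood because the package
needs both tie conventions behind one interface and a Breslow baseline
referenced to covariates = 0 — the uncentered reference is what lets
scores reproduce printed PI equations verbatim. The test suite
cross-checks coefficients, standard errors, and log-likelihoods against
an independent survival library on tied and untied data.

Diagnostics: Schoenfeld residuals at event times with a
Grambsch–Therneau-style trend test per covariate (identity time
transform, exact per-event-time risk-set covariance; simulated type-I
error is close to nominal), and per-subject delta-beta influence from
score residuals rotated through the covariance. Residuals use the
Breslow risk-set form, identical to Efron in the absence of ties.

## Validation battery

* **Calibration slope** — the log-hazard coefficient of the score in a
  univariable Cox refit, with a two-sided Wald test of slope = 1. A
  score equal to the true linear predictor has slope 1; a score
  inflated by $a$ has slope $1/a$.
* **Harrell's C** — pairs are usable when the earlier time is an event;
  concordant pairs score 1, tied scores 0.5. Pairs tied on time with
  both members events are usable and contribute 0.5: no ordering can be
  concordant at tied times, so the half credit is the consistent
  completion of the rule. The implementation is chunked $O(n^2)$ and is
  required by tests to agree exactly with a pure-Python pair-enumeration
  oracle.
* **Coefficient equality** — Wald quadratic form
  $(\hat\beta-\beta_0)^\top \hat V^{-1} (\hat\beta-\beta_0)$ against
  $\chi^2_p$, using the refit covariance only (the published reference
  is treated as fixed constants; an approximation, since published
  covariances are rarely available).
* **Bootstrap optimism** — Harrell's procedure: refit on each resample,
  C on the resample minus C of the resample model on the original data,
  averaged; corrected C = apparent − optimism. A calibration-slope
  shrinkage analog is reported alongside. Seeded, deterministic, refit
  failures counted (more than 10% aborts).
* **Calibration curves** — predicted event-free probability at a
  horizon via $\hat S_0(h)^{\exp(\mathrm{PI})}$ against within-bin
  Kaplan–Meier estimates, default decile bins (the bin count is the
  smoothing parameter; the binned estimate is the primitive and a
  kernel smoother can be layered on the output).

## Risk-group cutpoints

The concordance probability estimate (CPE) of a fitted Cox model is the
average over patient pairs of
$1/(1+e^{-|\eta_i-\eta_j|})$, a function of linear predictors only —
usable under censoring without touching the censored times. Cutpoints
are found by exhaustive search over empirical score quantiles (default
grid step 0.02, configurable; finer grids grow combinatorially and a
step of 0.005 would mean ~1.3M candidate triples); for each candidate
partition the scores are collapsed to ordered group indicators, the Cox
model is refit on those indicators, and the CPE of the refit's fitted
linear predictors is the objective. The refit (rather than computing
CPE on raw categorized scores) reflects that the CPE is defined on a
model's linear predictors; the objective function is isolated so
alternatives can be swapped in.

Tie handling matters here. The search objective credits tied
(within-group) pairs 0.5 over the full pair denominator — the canonical
Gönen–Heller convention. Excluding tied pairs instead makes the search
degenerate: shrinking a group toward the minimum allowed size removes
its within-pairs from the average rather than counting them at 0.5, so
the optimizer rewards carving off minimum-size extreme groups; on
four-cluster synthetic data the degenerate partition then beats the
true gap partition. The standalone `cpe()` statistic defaults to the
exclusion convention with an `include_ties` flag; `find_cutpoints`
defaults to inclusion for the reason above.

Group assignment is left-open/right-closed: label $i$ where
$c_{i-1} < \mathrm{PI} \le c_i$, so a score exactly on a cutpoint falls
in the lower-risk group. Groups from a minimum-fraction-constrained
search are ordered, and assignment is monotone in the score.

The clinical-comparison arm classifies patients with a first-match-wins
rules engine over raw fields (NCI risk, genetics, MRD, CNS), shipped as
config data. The default ruleset is an explicit *approximation* of the
shape of contemporary cooperative-group B-ALL algorithms — the exact
trial algorithm tables are not public — and is labeled as such; it
exists to exercise the cross-tabulation machinery, not to reproduce any
trial's assignments. Cross-tabulations report per-cell Kaplan–Meier
estimates at a horizon with Greenwood standard errors, suppressing
cells under 25 patients (configurable) as too small for reliable
estimation.

## Survival curves

Product-limit estimation with Greenwood variance, right-continuous step
evaluation, events-before-censorings at tied times. Five-year estimates
are read at $t = 5$ exactly; when follow-up ends earlier the last value
carries forward and a truncation flag is available. The k-sample
log-rank test has df = k − 1; for two groups it equals the Cox score
test for the group indicator (exactly so without tied event times).

## Synthetic cohort generator

The generator emulates the covariate structure of a large contemporary
pediatric B-ALL trial population and is the package's substitute for
request-restricted trial data. Defaults (all configurable):

* genetics: favorable 45.4%, unfavorable 5.9%, mutually exclusive;
* CNS 87.9 / 10.4 / 1.3% (renormalized);
* WBC log-normal with median 8.7 ×10⁹/L, log-SD 1.2 (dispersion is not
  published; 1.2 respects the published range of roughly 0.06–6200);
* age: truncated log-normal, median 4.83 y on 1–31 y, log-SD 0.65
  (again chosen to respect the published median and range);
* D8/D29 MRD: four-category multinomials (<0.01%, 0.01–<0.1%, 0.1–<1%,
  ≥1%) with the published frequencies renormalized over measured
  values (D29: 0.782/0.105/0.071/0.042; D8: 0.219/0.262/0.294/0.225),
  log-uniform within category, and a Gaussian-copula rank correlation
  (default 0.5 — the day-8/day-29 correlation is noted but not
  quantified in the literature) between the two time points;
* NCI risk derived from the standard age/WBC criteria (high risk iff
  age ≥ 10 y or WBC ≥ 50);
* event times by inverse-transform sampling from the true
  proportional-hazards model (default true coefficients: the shipped
  eight-covariate set) with Weibull baseline, shape 0.9 (slightly
  decreasing post-induction relapse hazard; shape 1 recovers the
  exponential), scale calibrated numerically so the cohort's marginal
  5-year relapse-free survival equals a target (default 0.90);
* censoring uniform on 4–12 years; event subtypes split 84/16
  relapse/death-in-remission; induction death/failure 0.8%/0.5%
  assigned independently before EOI; post-relapse death 40% for the
  overall-survival fields; MRD missingness defaults to 0 and is
  configurable.

What the generator does *not* emulate: joint dependence between
covariate blocks beyond the configured marginals (genetics are
independent of WBC and age, for example, whereas real favorable-risk
genetics are concentrated in young, low-WBC patients), assay-level MRD
measurement error, trial accrual and treatment-arm structure, and
competing-risks structure in the event subtypes (the subtype label is
bookkeeping drawn independently of the hazard). Passing tests on
synthetic cohorts therefore demonstrate that the estimators recover the
generating model under correct specification — parameter recovery,
calibration, discrimination, optimism behavior — not that any specific
published cohort statistic is reproduced. Headline statistics of the
real cohorts (C-indices near 0.73, calibration slopes 0.79–0.94)
require the restricted data and are treated as plausibility references
only.

## Numerical and edge-case choices

* Newton fitting rejects constant columns by name before iterating;
  singular information raises rather than pseudo-inverting.
* An overflow guard treats any candidate step with linear predictors
  above 300 as a rejected line-search point.
* `cpe` collapses scores to unique values with multiplicity weights, so
  heavily tied inputs cost $O(k^2)$ in the number of distinct values.
* Kaplan–Meier variance at $\hat S = 0$ is set to 0 (the Greenwood sum
  is undefined there).
* All-tied scores return CPE 0.5 by convention; concordance with no
  usable pairs raises an explicit undefined-result error.
* Bootstrap resampling, cohort generation, and every CLI stage take an
  explicit integer seed; fixed seeds give bit-identical outputs.

## Problem sizes in the shipped test suite

The suite exercises parameter recovery at n = 20,000 over 20 seeds,
calibration-slope behavior at n = 10,000, bootstrap optimism at
n = 5,000 (B = 200) and n = 30 (the deliberate overfit regime), oracle
agreement for the concordance statistics at n = 200/500 against
pure-Python enumeration, and cutpoint recovery on 4 × 250 clustered
scores over four replicates — sizes chosen so each property is measured
with comfortable Monte-Carlo margins while the whole suite runs in a
few minutes on one core.

## Known limitations

* Time-varying covariates, stratified baselines, penalized fits, and
  competing-risks cumulative incidence are out of scope.
* The coefficient-equality test ignores uncertainty in the published
  reference coefficients.
* The exhaustive cutpoint search is combinatorial in the grid; for many
  groups or fine grids a dynamic-programming or stepwise search would
  be needed.
* The overall-survival endpoint depends on the optional death
  follow-up columns; without them, deaths after relapse are invisible
  to the record schema and OS falls back to deaths recorded as first
  events.
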