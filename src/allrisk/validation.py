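"""External/internal validation battery for prognostic indices.

Implements the standard checks applied when a published risk score is
carried to a new cohort:

1. calibration slope — the log-hazard coefficient of the score in a
   univariable Cox refit, with a Wald test of slope = 1 (a slope below 1
   signals weaker discrimination in the new data);
2. Harrell's concordance index;
3. a Wald test of equality between refit and published coefficients;
4. Kaplan-Meier curves within score-defined groups (see
   :mod:`allrisk.survival`);

plus bootstrap optimism correction (Harrell's resampling procedure) for
internal validation and binned calibration curves at a fixed horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import cox
from .cohort import SurvivalOutcome
from .errors import SingularityError, UndefinedResultError, UnfitError


def calibration_slope(scores, outcomes):
    """Univariable Cox fit of the outcome on the score.

    Returns ``(slope, se, p_vs_one)`` where the p-value is the two-sided
    Wald test of H0: slope = 1. A score equal to the true linear
    predictor has slope 1 in expectation; a score inflated by a factor a
    has slope 1/a.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.std() == 0:
        raise SingularityError("scores are constant; calibration slope undefined")
    fit = cox.fit_cox(outcomes, scores[:, None], names=("score",))
    slope = float(fit.coef[0])
    se = float(fit.se[0])
    z = (slope - 1.0) / se
    return slope, se, 2 * float(stats.norm.sf(abs(z)))


def harrell_c(scores, outcomes) -> float:
    """Harrell's concordance index.

    A pair is usable when the earlier time is an event (or both are
    events at the same time). A usable pair scores 1 when the higher
    score has the shorter time, 0.5 when the scores are tied, else 0;
    tied-time pairs with both events contribute 0.5. Chunked O(n^2).

    Raises :class:`UndefinedResultError` when no usable pairs exist.
    """
    s = np.asarray(scores, dtype=float)
    t = np.array([o.time for o in outcomes], dtype=float)
    e = np.array([o.event for o in outcomes], dtype=int)
    n = len(s)
    if n < 2 or len(t) != n:
        raise ValueError("need >= 2 scores matching the outcomes")
    numer = 0.0
    denom = 0.0
    chunk = 256
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        ti, si, ei = t[lo:hi, None], s[lo:hi, None], e[lo:hi, None]
        earlier = (ti < t[None, :]) & (ei == 1)
        tied_time = (ti == t[None, :]) & (ei == 1) & (e[None, :] == 1)
        # drop self-pairs and double counting of tied-time pairs
        idx = np.arange(lo, hi)[:, None]
        tied_time &= idx < np.arange(n)[None, :]
        denom += earlier.sum() + tied_time.sum()
        credit = np.where(si > s[None, :], 1.0, np.where(si == s[None, :], 0.5, 0.0))
        numer += float((credit * earlier).sum()) + 0.5 * tied_time.sum()
    if denom == 0:
        raise UndefinedResultError("no usable pairs for the concordance index")
    return float(numer / denom)


def coefficient_equality_test(fit: cox.CoxFit, reference):
    """Wald test that refit coefficients equal a reference set.

    ``(beta_hat - beta_0)' V^{-1} (beta_hat - beta_0)`` against
    chi-square with df = number of coefficients; ``V`` is the refit
    covariance (the reference is treated as fixed constants).
    Names must match in order.
    """
    if tuple(fit.names) != tuple(reference.names):
        raise ValueError(
            f"covariate names/order differ: {fit.names} vs {tuple(reference.names)}"
        )
    delta = fit.coef - np.asarray(reference.coef, dtype=float)
    try:
        stat = float(delta @ np.linalg.solve(fit.cov, delta))
    except np.linalg.LinAlgError as err:
        raise SingularityError(f"singular covariance: {err}") from err
    df = len(delta)
    return stat, df, float(stats.chi2.sf(stat, df))


@dataclass
class OptimismResult:
    """Bootstrap internal validation (Harrell's optimism correction)."""

    apparent_c: float
    optimism: float
    corrected_c: float
    slope_optimism: float
    corrected_slope: float
    n_resamples: int
    n_failures: int


def bootstrap_optimism(outcomes, covariates, B: int = 200, seed: int = 0,
                       tie_method: str = "efron", names=None) -> OptimismResult:
    """Harrell's bootstrap optimism for the concordance index.

    For each resample: refit the model, compute C on the resample
    (boot-apparent) and, with the resample's coefficients, on the
    original data (boot-test). Optimism is the mean gap; the corrected
    C is apparent C minus optimism. The calibration-slope analog uses
    the slope of the resample model's score on the original data
    (boot-apparent slope is 1 by construction).

    Refit failures are counted; more than 10% failed resamples raises
    :class:`UnfitError`. Fully seeded and reproducible.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X, names = cox._as_matrix(covariates, names)
    full_fit = cox.fit_cox(outcomes, X, tie_method=tie_method, names=names)
    lp = X @ full_fit.coef
    apparent = harrell_c(lp, outcomes)
    rng = np.random.default_rng(seed)
    n = len(outcomes)
    gaps, slope_gaps = [], []
    failures = 0
    outcomes = list(outcomes)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot_out = [outcomes[i] for i in idx]
        try:
            boot_fit = cox.fit_cox(boot_out, X[idx], tie_method=tie_method, names=names)
            boot_lp = X[idx] @ boot_fit.coef
            c_boot = harrell_c(boot_lp, boot_out)
            c_test = harrell_c(X @ boot_fit.coef, outcomes)
            slope_test, _, _ = calibration_slope(X @ boot_fit.coef, outcomes)
        except (UnfitError, SingularityError, UndefinedResultError):
            failures += 1
            continue
        gaps.append(c_boot - c_test)
        slope_gaps.append(1.0 - slope_test)
    if failures > 0.1 * B:
        raise UnfitError(f"{failures}/{B} bootstrap refits failed")
    optimism = float(np.mean(gaps))
    slope_optimism = float(np.mean(slope_gaps))
    return OptimismResult(
        apparent_c=apparent,
        optimism=optimism,
        corrected_c=apparent - optimism,
        slope_optimism=slope_optimism,
        corrected_slope=1.0 - slope_optimism,
        n_resamples=B - failures,
        n_failures=failures,
    )


def calibration_curve(scores, outcomes, baseline: cox.BaselineSurvival,
                      horizon: float, bins: int = 10) -> pd.DataFrame:
    """Binned calibration at a fixed horizon.

    Predicted event-free probability is ``s0(horizon) ** exp(score)``
    (baseline referenced to covariates = 0, matching the uncentered
    score); observed is the within-bin Kaplan-Meier estimate at the
    horizon. Bins are score quantiles. Returns one row per bin with
    ``n``, ``mean_predicted``, ``observed_km``, ``observed_se``.
    """
    from .survival import km_estimate

    if bins < 1:
        raise ValueError("bins must be >= 1")
    scores = np.asarray(scores, dtype=float)
    tmax = max(o.time for o in outcomes)
    if horizon > tmax:
        raise ValueError(f"horizon {horizon} beyond last observed time {tmax}")
    s0_h = baseline.at(horizon)
    predicted = s0_h ** np.exp(scores)
    if bins == 1:
        bin_id = np.zeros(len(scores), dtype=int)
    else:
        edges = np.quantile(scores, np.linspace(0, 1, bins + 1)[1:-1])
        bin_id = np.searchsorted(edges, scores, side="left")
    rows = []
    outcomes = list(outcomes)
    for b in sorted(set(bin_id)):
        mask = bin_id == b
        members = [outcomes[i] for i in np.flatnonzero(mask)]
        curve = km_estimate(members)
        rows.append(
            {
                "bin": b,
                "n": int(mask.sum()),
                "mean_predicted": float(predicted[mask].mean()),
                "observed_km": float(curve.at(horizon)),
                "observed_se": float(curve.se_at(horizon)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Summary of the external-validation battery for one score."""

    calibration_slope: float
    slope_se: float
    slope_p_vs_one: float
    c_index: float
    coefficient_test: tuple[float, int, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "calibration_slope": self.calibration_slope,
            "slope_se": self.slope_se,
            "slope_p_vs_one": self.slope_p_vs_one,
            "c_index": self.c_index,
        }
        if self.coefficient_test is not None:
            stat, df, p = self.coefficient_test
            d["coefficient_test"] = {"statistic": stat, "df": df, "p": p}
        return d


def validation_battery(coeffs, covariates, outcomes, refit: bool = True,
                       tie_method: str = "efron") -> ValidationReport:
    """Steps 1-3 of the external-validation sequence for a published
    coefficient set: calibration slope (with slope=1 test), Harrell's C
    of the published score, and — when ``refit`` — the Wald equality
    test of refit vs published coefficients.
    """
    X, _ = cox._as_matrix(covariates, tuple(coeffs.names))
    scores = X @ np.asarray(coeffs.coef, dtype=float)
    slope, se, p = calibration_slope(scores, outcomes)
    c = harrell_c(scores, outcomes)
    coef_test = None
    if refit:
        fit = cox.fit_cox(outcomes, X, tie_method=tie_method, names=tuple(coeffs.names))
        coef_test = coefficient_equality_test(fit, coeffs)
    return ValidationReport(
        calibration_slope=slope,
        slope_se=se,
        slope_p_vs_one=p,
        c_index=c,
        coefficient_test=coef_test,
    )
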