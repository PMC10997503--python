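import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allrisk.cox import (
    baseline_survival,
    cox_score_test,
    fit_cox,
    linear_predictor,
    lrt_nested,
    ph_diagnostics,
)
from allrisk.errors import SingularityError, UnfitError
from allrisk.index import CoefficientSet, score_pi
from allrisk.survival import logrank
from allrisk.transforms import CovariateVector

from conftest import make_outcomes, survival_data


@pytest.fixture(scope="module")
def ph_data():
    rng = np.random.default_rng(7)
    return survival_data(rng, 400, [0.5, -0.3, 0.2])


@pytest.fixture(scope="module")
def ph_data_tied(ph_data):
    X, outcomes = ph_data
    tied = make_outcomes([np.ceil(o.time * 4) / 4 for o in outcomes],
                         [o.event for o in outcomes])
    return X, tied


class TestFit:
    @pytest.mark.parametrize("tied", [False, True])
    def test_matches_lifelines(self, ph_data, ph_data_tied, tied):
        """Independent cross-check of the partial-likelihood optimizer."""
        from lifelines import CoxPHFitter

        X, outcomes = ph_data_tied if tied else ph_data
        fit = fit_cox(outcomes, X, names=("a", "b", "c"))
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"] = [o.time for o in outcomes]
        df["E"] = [o.event for o in outcomes]
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=1e-5)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-5)

    def test_efron_equals_breslow_without_ties(self, ph_data):
        X, outcomes = ph_data
        fe = fit_cox(outcomes, X, tie_method="efron")
        fb = fit_cox(outcomes, X, tie_method="breslow")
        np.testing.assert_array_equal(fe.coef, fb.coef)
        assert fe.loglik == fb.loglik

    def test_fitted_loglik_beats_null(self, ph_data):
        X, outcomes = ph_data
        fit = fit_cox(outcomes, X)
        assert fit.loglik >= fit.loglik_null

    def test_scaling_reparameterization(self, ph_data):
        X, outcomes = ph_data
        fit = fit_cox(outcomes, X)
        X2 = X.copy()
        X2[:, 0] *= 10.0
        fit2 = fit_cox(outcomes, X2)
        assert fit2.coef[0] == pytest.approx(fit.coef[0] / 10.0, rel=1e-6)
        np.testing.assert_allclose(fit2.coef[1:], fit.coef[1:], rtol=1e-6)

    def test_all_censored_unfit(self):
        outcomes = make_outcomes([1.0, 2.0, 3.0], [0, 0, 0])
        with pytest.raises(UnfitError):
            fit_cox(outcomes, np.arange(3.0)[:, None])

    def test_constant_column_named(self, ph_data):
        X, outcomes = ph_data
        X2 = np.column_stack([X, np.ones(len(X))])
        with pytest.raises(SingularityError, match="const"):
            fit_cox(outcomes, X2, names=("a", "b", "c", "const"))

    def test_json_round_trip(self, ph_data, tmp_path):
        X, outcomes = ph_data
        fit = fit_cox(outcomes, X, names=("a", "b", "c"))
        fit.to_json(tmp_path / "fit.json")
        back = type(fit).from_json(tmp_path / "fit.json")
        np.testing.assert_array_equal(back.coef, fit.coef)
        assert back.names == fit.names and back.n_events == fit.n_events


class TestLinearPredictor:
    def test_zero_coefficients(self):
        cs = CoefficientSet("z", [("frg", 0.0), ("age", 0.0)])
        vec = CovariateVector(frg=1, age=12.0)
        assert linear_predictor(cs, vec) == 0.0

    def test_arithmetic(self):
        cs = CoefficientSet("t", [("frg", 1.0), ("age", -1.0)])
        assert linear_predictor(cs, CovariateVector(frg=2, age=3)) == -1.0

    def test_consistency_with_score_pi(self, ph_data):
        X, outcomes = ph_data
        fit = fit_cox(outcomes, X, names=("frg", "urg", "age"))
        cs = CoefficientSet.from_fit(fit)
        vec = CovariateVector(frg=0.3, urg=-1.2, age=2.0)
        assert linear_predictor(fit, vec) == score_pi(cs, vec)


class TestBaseline:
    def test_exponential_closed_form(self):
        # true baseline hazard 0.05/y with a null covariate: S0(5)=e^-0.25
        rng = np.random.default_rng(21)
        n = 5000
        X = rng.normal(size=(n, 1))
        t = rng.exponential(1 / 0.05, size=n)
        c = np.full(n, 30.0)
        outcomes = make_outcomes(np.minimum(t, c), (t <= c).astype(int))
        fit = fit_cox(outcomes, X)
        base = baseline_survival(fit, outcomes, X)
        assert base.at(5.0) == pytest.approx(np.exp(-0.25), abs=0.02)
        assert base.at(0.0) == 1.0
        assert np.all(np.diff(base.s0) <= 1e-12)

    def test_dimension_mismatch(self, ph_data):
        X, outcomes = ph_data
        fit = fit_cox(outcomes, X)
        with pytest.raises(ValueError):
            baseline_survival(fit, outcomes, X[:, :2])


class TestScoreTestAndLRT:
    def test_score_test_equals_logrank_two_groups(self):
        rng = np.random.default_rng(3)
        g = (rng.random(50) < 0.5).astype(float)
        t = rng.exponential(np.exp(-0.8 * g))
        c = rng.exponential(2.0, 50)
        outcomes = make_outcomes(np.minimum(t, c), (t <= c).astype(int))
        stat, df, p = cox_score_test(outcomes, g[:, None])
        groups = [[o for o, gi in zip(outcomes, g) if gi == v] for v in (0.0, 1.0)]
        lr_stat, lr_df, lr_p = logrank(groups)
        assert stat == pytest.approx(lr_stat, rel=1e-9)
        assert (df, p) == (1, pytest.approx(lr_p, rel=1e-9))

    def test_identical_models(self, ph_data):
        X, outcomes = ph_data
        fit = fit_cox(outcomes, X)
        stat, df, p = lrt_nested(fit, fit)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_df_bookkeeping(self, ph_data):
        X, outcomes = ph_data
        full = fit_cox(outcomes, X, names=("a", "b", "c"))
        reduced = fit_cox(outcomes, X[:, :1], names=("a",))
        stat, df, p = lrt_nested(full, reduced)
        assert df == 2 and stat > 0

    def test_non_nested_rejected(self, ph_data):
        X, outcomes = ph_data
        fa = fit_cox(outcomes, X[:, :2], names=("a", "b"))
        fb = fit_cox(outcomes, X[:, 1:], names=("b", "c"))
        with pytest.raises(ValueError):
            lrt_nested(fa, fb)

    def test_null_distribution_is_chisquare(self):
        """Adding truly-null covariates: the LRT statistic follows chi2(df)."""
        rng = np.random.default_rng(17)
        stats_null = []
        for _ in range(200):
            X, outcomes = survival_data(rng, 120, [0.5, 0.0, 0.0])
            full = fit_cox(outcomes, X, names=("a", "b", "c"))
            reduced = fit_cox(outcomes, X[:, :1], names=("a",))
            stats_null.append(lrt_nested(full, reduced)[0])
        ks = stats.kstest(stats_null, stats.chi2(df=2).cdf)
        assert ks.pvalue > 0.01


class TestDiagnostics:
    def test_schoenfeld_residuals_sum_to_zero(self, ph_data):
        X, outcomes = ph_data
        fit = fit_cox(outcomes, X, names=("a", "b", "c"))
        diag = ph_diagnostics(fit, outcomes, X)
        sums = diag.schoenfeld[["a", "b", "c"]].sum().to_numpy()
        np.testing.assert_allclose(sums, 0.0, atol=1e-6)

    def test_dfbeta_approximates_duplication_effect(self):
        rng = np.random.default_rng(9)
        X, outcomes = survival_data(rng, 40, [0.6, -0.4], censor_scale=100.0)
        fit = fit_cox(outcomes, X, names=("a", "b"))
        diag = ph_diagnostics(fit, outcomes, X)
        for i in (3, 17, 30):
            X2 = np.vstack([X, X[i]])
            fit2 = fit_cox(outcomes + [outcomes[i]], X2, names=("a", "b"))
            actual = fit2.coef - fit.coef
            approx = diag.dfbeta.iloc[i].to_numpy()
            np.testing.assert_allclose(approx, actual, rtol=0.35, atol=0.01)

    def test_too_few_events(self):
        outcomes = make_outcomes([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0])
        X = np.arange(4.0)[:, None]
        fit = fit_cox(outcomes, X)
        with pytest.raises(UnfitError):
            ph_diagnostics(fit, outcomes, X)
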