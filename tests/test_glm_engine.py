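import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from hetfit.glm_engine import (FittedModel, ModelSet, SeparationError, aicc,
                               akaike_weights, build_design, fit_logistic,
                               mlh_vs_slh_ftest, model_average, model_selection)


def _two_by_two():
    y = np.r_[np.ones(30), np.zeros(20), np.ones(10), np.zeros(40)]
    x = np.r_[np.ones(50), np.zeros(50)]
    return y, np.column_stack([np.ones(100), x])


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        y, X = _two_by_two()
        fm = fit_logistic(y, X, names=["(Intercept)", "x"])
        assert fm.coefficients[1] == pytest.approx(np.log(6.0), abs=1e-8)
        assert fm.coefficients[0] == pytest.approx(np.log(10 / 40), abs=1e-8)

    def test_balanced_intercept_only_is_exactly_zero(self):
        y = np.r_[np.ones(3), np.zeros(3)]
        fm = fit_logistic(y, np.ones((6, 1)), names=["(Intercept)"])
        assert fm.coefficients[0] == 0.0

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(10)
        X = np.column_stack([np.ones(200), rng.normal(size=(200, 2))])
        eta = X @ np.array([-0.3, 0.8, -0.5])
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        fm = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fm.coefficients, ref.params, atol=1e-7)
        assert np.allclose(fm.standard_errors, ref.bse, atol=1e-6)
        assert fm.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_complete_separation_raises(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        X = np.column_stack([np.ones(20), x])
        with pytest.raises(SeparationError):
            fit_logistic(y, X, names=["(Intercept)", "x"])

    def test_aliased_column_dropped(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.warns(UserWarning, match="aliased"):
            fm = fit_logistic(y, X, names=["(Intercept)", "x", "x2"])
        assert fm.terms == ["(Intercept)", "x"]


class TestRandomIntercept:
    def test_matches_lme4_frozen_fit(self):
        """Frozen oracle: lme4::glmer(y ~ x + (1|g), binomial, nAGQ=25) on the
        same generated data returned beta=(0.3333211, 1.0718639),
        SE=(0.1219376, 0.1573453), sd(g)=0.4125943, logLik=-233.9223."""
        rng = np.random.default_rng(42)
        m = 200
        b = rng.normal(0, 1.0, m)
        g = np.repeat(np.arange(m), 2)
        x = rng.normal(size=400)
        eta = 0.3 + 1.0 * x + b[g]
        y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
        fm = fit_logistic(y, np.column_stack([np.ones(400), x]),
                          names=["(Intercept)", "x"], groups=g)
        assert fm.coefficients == pytest.approx([0.3333211, 1.0718639], abs=2e-4)
        assert fm.standard_errors == pytest.approx([0.1219376, 0.1573453], abs=2e-4)
        assert fm.random_intercept_sd == pytest.approx(0.4125943, abs=5e-4)
        assert fm.loglik == pytest.approx(-233.9223, abs=1e-3)
        assert fm.k_params == 3

    def test_zero_sd_boundary_matches_fixed_loglik(self):
        """At a vanishing random-intercept SD, the quadrature marginal
        likelihood must coincide with the fixed-effects likelihood, and the ML
        mixed fit on independent data must find only a negligible SD."""
        from hetfit.glm_engine import _aghq_loglik
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        g = np.repeat(np.arange(150), 2)
        eta = 0.2 + 0.7 * x
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(300), x])
        fixed = fit_logistic(y, X)
        z, w = np.polynomial.hermite.hermgauss(25)
        theta = np.concatenate([fixed.coefficients, [-10.0]])  # sd = e^-10
        ll_boundary, _, _ = _aghq_loglik(theta, y, X, g, 150, z, np.log(w))
        assert ll_boundary == pytest.approx(fixed.loglik, abs=1e-6)
        mixed = fit_logistic(y, X, groups=g)
        assert mixed.loglik >= fixed.loglik - 1e-8
        assert mixed.random_intercept_sd < 0.2


class TestAicc:
    def test_plug_in_arithmetic(self):
        m = FittedModel(terms=["a", "b"], coefficients=np.zeros(2),
                        standard_errors=np.zeros(2), loglik=-10.0, k_params=2,
                        n_obs=23, deviance=20.0)
        assert aicc(m) == pytest.approx(24.6)

    def test_zero_params(self):
        m = FittedModel(terms=[], coefficients=np.zeros(0),
                        standard_errors=np.zeros(0), loglik=-7.0, k_params=0,
                        n_obs=10, deviance=14.0)
        assert aicc(m) == pytest.approx(14.0)

    def test_degenerate_denominator(self):
        m = FittedModel(terms=["a"], coefficients=np.zeros(1),
                        standard_errors=np.zeros(1), loglik=-1.0, k_params=4,
                        n_obs=5, deviance=2.0)
        with pytest.raises(ValueError, match="AICc undefined"):
            aicc(m)

    def test_monotone_in_loglik(self):
        def make(ll):
            return FittedModel(terms=["a"], coefficients=np.zeros(1),
                               standard_errors=np.zeros(1), loglik=ll,
                               k_params=2, n_obs=30, deviance=-2 * ll)
        assert aicc(make(-5.0)) < aicc(make(-6.0)) < aicc(make(-7.0))


class TestModelSelection:
    def _data(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "x1": rng.normal(size=n), "x2": rng.normal(size=n),
            "x3": rng.normal(size=n),
            "plot": rng.choice(["A", "B"], n),
        })
        eta = -0.2 + 1.2 * df["x1"]
        df["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return df

    def test_weights_for_delta_zero_two(self):
        delta, w = akaike_weights([100.0, 102.0])
        assert np.allclose(delta, [0.0, 2.0])
        assert w == pytest.approx([0.7311, 0.2689], abs=1e-4)
        assert w.sum() == pytest.approx(1.0)

    def test_enumerates_all_subsets(self):
        df = self._data()
        ms1 = model_selection(df, "y", ["x1"], [])
        ms3 = model_selection(df, "y", ["x1", "x2", "x3"], [])
        assert len(ms1.models) == 2
        assert len(ms3.models) == 8
        assert ms3.delta_aicc.min() == 0.0
        assert ms3.weights.sum() == pytest.approx(1.0)
        assert all(ms3.delta_aicc[i] <= 2 for i in ms3.top_set)

    def test_cap_enforced(self):
        df = self._data()
        with pytest.raises(ValueError, match="cap"):
            model_selection(df, "y", ["x1", "x2", "x3"], [], max_models=4)

    def test_factor_terms_enter_design(self):
        df = self._data()
        X, names = build_design(df, ["plot", "x1"])
        assert names[0] == "(Intercept)" and "plot_B" in names
        assert X.shape[1] == 3


class TestModelAverage:
    def _model(self, terms, coefs, ses, ll, n=100):
        return FittedModel(terms=terms, coefficients=np.asarray(coefs, float),
                           standard_errors=np.asarray(ses, float), loglik=ll,
                           k_params=len(terms), n_obs=n, deviance=-2 * ll)

    def test_single_model_identity(self):
        m = self._model(["(Intercept)", "h"], [0.1, 1.5], [0.2, 0.4], -40)
        ms = ModelSet(models=[m], term_sets=[("h",)], delta_aicc=np.array([0.0]),
                      weights=np.array([1.0]), top_set=[0])
        out = model_average(ms).set_index("term")
        assert out.loc["h", "estimate"] == pytest.approx(1.5)
        assert out.loc["h", "use"] == pytest.approx(0.4)
        assert out.loc["h", "sum_weights"] == pytest.approx(1.0)

    def test_hand_computed_use(self):
        # (theta, SE, w~) = (1.0, 0.5, 0.6) and (2.0, 0.5, 0.4)
        m1 = self._model(["(Intercept)", "h"], [0.0, 1.0], [0.1, 0.5], -10)
        m2 = self._model(["(Intercept)", "h"], [0.0, 2.0], [0.1, 0.5], -10)
        w = np.array([0.6, 0.4])
        ms = ModelSet(models=[m1, m2], term_sets=[("h",), ("h",)],
                      delta_aicc=np.array([0.0, 0.5]), weights=w, top_set=[0, 1])
        out = model_average(ms).set_index("term")
        assert out.loc["h", "estimate"] == pytest.approx(1.4)
        expected_use = 0.6 * np.sqrt(0.25 + 0.16) + 0.4 * np.sqrt(0.25 + 0.36)
        assert out.loc["h", "use"] == pytest.approx(expected_use, abs=1e-6)
        assert out.loc["h", "use"] == pytest.approx(0.6966, abs=1e-4)
        assert out.loc["h", "ci_low"] == pytest.approx(1.4 - 1.96 * expected_use)
        assert bool(out.loc["h", "significant"]) == (out.loc["h", "ci_low"] > 0)

    def test_term_absent_from_top_set_omitted(self):
        m1 = self._model(["(Intercept)", "a"], [0.0, 1.0], [0.1, 0.2], -10)
        m2 = self._model(["(Intercept)"], [0.0], [0.1], -30)
        ms = ModelSet(models=[m1, m2], term_sets=[("a",), ()],
                      delta_aicc=np.array([0.0, 40.0]),
                      weights=np.array([0.99, 0.01]), top_set=[0])
        out = model_average(ms)
        assert set(out["term"]) == {"a"}


class TestMlhVsSlh:
    def test_single_locus_errors(self):
        y = np.zeros(30)
        with pytest.raises(ValueError):
            mlh_vs_slh_ftest(y, np.random.default_rng(0).normal(size=(30, 1)),
                             np.zeros(30), np.zeros((30, 1)))

    def test_matches_statsmodels_anova(self):
        rng = np.random.default_rng(4)
        n, L = 120, 5
        S = rng.normal(size=(n, L))
        mlh = S.mean(axis=1)
        base = rng.normal(size=(n, 2))
        y = (rng.random(n) < 0.4).astype(float)
        F, df1, df2, p = mlh_vs_slh_ftest(y, base, mlh, S)
        X1 = sm.add_constant(np.column_stack([base, mlh]))
        X2 = sm.add_constant(np.column_stack([base, S]))
        rss1 = sm.OLS(y, X1).fit().ssr
        rss2 = sm.OLS(y, X2).fit().ssr
        F_ref = ((rss1 - rss2) / (L - 1)) / (rss2 / (n - 2 - L - 1))
        assert F == pytest.approx(F_ref, rel=1e-10)
        assert (df1, df2) == (L - 1, n - 2 - L - 1)
        assert 0 <= p <= 1

    def test_private_locus_effect_detected(self):
        rng = np.random.default_rng(8)
        n, L = 400, 8
        S = rng.normal(size=(n, L))
        mlh = S.mean(axis=1)
        y = 0.5 + 0.8 * S[:, 0] + rng.normal(scale=0.5, size=n)
        F, _, _, p = mlh_vs_slh_ftest(y, rng.normal(size=(n, 1)), mlh, S)
        assert p < 0.01
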