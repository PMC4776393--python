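import math

import numpy as np
import pandas as pd
import pytest

from embryosel import lr_model as lr
from conftest import make_cass_features


def _two_by_two(n11, n10, n01, n00):
    """Design / outcome arrays for a 2x2 exposure table.

    Exposed: n11 events, n10 non-events; unexposed: n01 events, n00.
    """
    x = np.r_[np.ones(n11 + n10), np.zeros(n01 + n00)]
    y = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    return x[:, None], y


class TestFitLogistic:
    def test_2x2_slope_matches_log_odds_ratio(self):
        X, y = _two_by_two(10, 10, 10, 20)
        fit = lr.fit_logistic(X, y)
        assert fit.coefficients[1] == pytest.approx(math.log(2.0), abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            lr.fit_logistic(np.random.default_rng(0).normal(size=(20, 1)),
                            np.ones(20))

    def test_duplicated_column_rejected(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        X = np.c_[x, x]
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(lr.RankDeficiencyError, match="x1"):
            lr.fit_logistic(X, y)

    def test_separation_detected(self):
        x = np.r_[np.linspace(-2, -1, 20), np.linspace(1, 2, 20)]
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.raises(lr.SeparationError):
            lr.fit_logistic(x[:, None], y)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 400
        X = rng.standard_normal((n, 3))
        eta = 0.3 + X @ [0.8, -0.5, 0.0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = lr.fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-5)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-5)

    def test_wald_outputs_shape(self, rng):
        X = rng.standard_normal((100, 2))
        y = (rng.random(100) < 0.5).astype(float)
        fit = lr.fit_logistic(X, y, term_names=["a", "b"])
        assert fit.term_names == ["(intercept)", "a", "b"]
        assert np.all((fit.p_values >= 0) & (fit.p_values <= 1))
        assert len(fit.coefficients) == 3

    def test_parameter_recovery_coverage(self, rng):
        true = np.array([-0.5, 0.8, -0.6])
        covered = np.zeros(3)
        reps = 40
        for _ in range(reps):
            X = rng.standard_normal((1500, 2))
            eta = true[0] + X @ true[1:]
            y = (rng.random(1500) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = lr.fit_logistic(X, y)
            covered += np.abs(fit.coefficients - true) <= 2 * fit.standard_errors
        assert np.all(covered / reps >= 0.85)


class TestBackwardEliminate:
    def _fit(self, frame, y, terms):
        return lr.fit_logistic_terms(frame, y, terms)

    def test_noise_terms_removed(self, rng):
        n = 1500
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + 1.2 * x1)))).astype(float)
        frame = pd.DataFrame({"x1": x1, "x2": x2})
        fit = self._fit(frame, y, lr.full_interaction_terms(["x1", "x2"]))
        final = lr.backward_eliminate(fit, removal_p=0.1)
        assert ("x1",) in final.terms

    def test_noise_removal_rate(self, rng):
        removed = 0
        reps = 30
        for _ in range(reps):
            n = 800
            x1 = rng.standard_normal(n)
            x2 = rng.standard_normal(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-(1.5 * x1)))).astype(float)
            frame = pd.DataFrame({"x1": x1, "x2": x2})
            fit = self._fit(frame, y, lr.full_interaction_terms(["x1", "x2"]))
            final = lr.backward_eliminate(fit, removal_p=0.1)
            if ("x2",) not in final.terms and ("x1", "x2") not in final.terms:
                removed += 1
        assert removed / reps >= 0.6  # pure-noise terms usually eliminated

    def test_removal_p_one_gives_intercept_only(self, rng):
        n = 300
        frame = pd.DataFrame({"x": rng.standard_normal(n)})
        y = (rng.random(n) < 0.5).astype(float)
        fit = self._fit(frame, y, [("x",)])
        final = lr.backward_eliminate(fit, removal_p=1.0)
        assert final.terms == ((),)

    def test_fixed_point(self, rng):
        n = 3000
        x = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(float)
        frame = pd.DataFrame({"x": x})
        fit = self._fit(frame, y, [("x",)])
        final = lr.backward_eliminate(fit, removal_p=0.1)
        assert final.terms == fit.terms
        np.testing.assert_allclose(final.coefficients, fit.coefficients)

    def test_hierarchy_preserved(self, rng):
        # strong interaction: main effects are not removable while the
        # product term stays
        n = 2000
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        eta = 1.5 * x1 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        frame = pd.DataFrame({"x1": x1, "x2": x2})
        fit = self._fit(frame, y, lr.full_interaction_terms(["x1", "x2"]))
        final = lr.backward_eliminate(fit, removal_p=0.1)
        if ("x1", "x2") in final.terms:
            assert ("x1",) in final.terms and ("x2",) in final.terms

    def test_order_invariance(self, rng):
        n = 600
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * x1 - 0.4 * x2)))).astype(float)
        frame = pd.DataFrame({"x1": x1, "x2": x2})
        terms = lr.full_interaction_terms(["x1", "x2"])
        a = lr.backward_eliminate(self._fit(frame, y, terms), 0.1)
        b = lr.backward_eliminate(self._fit(frame, y, terms[::-1]), 0.1)
        assert sorted(a.term_names) == sorted(b.term_names)


class TestIrlsMonotonicity:
    def test_log_likelihood_non_decreasing(self, rng):
        # step-halving guarantees monotone log-likelihood; verify final
        # likelihood beats the intercept-only fit
        n = 200
        X = rng.standard_normal((n, 2))
        y = (rng.random(n) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
        fit = lr.fit_logistic(X, y)
        p0 = y.mean()
        ll0 = n * (p0 * math.log(p0) + (1 - p0) * math.log(1 - p0))
        assert fit.log_likelihood >= ll0


class TestPublishedScore:
    def test_all_zero_terms_gives_intercept(self):
        f = make_cass_features(
            n_d2=0.0, n_d3=8, tcv_d2=0.0, cod_d2=0.0, cod_d3=0.0,
            frag_d2=0.0, frag_d3=0.0,
        )
        # force every feature entering the score to zero
        object.__setattr__(f, "n_d3_dev", 0.0)
        object.__setattr__(f, "parity_d2", 0)
        object.__setattr__(f, "tcv_d2", 0.0)
        assert lr.published_score(f, male_age=0.0) == pytest.approx(12.070)

    def test_single_unit_number_day2(self):
        f = make_cass_features(
            n_d2=1, tcv_d2=0.0, cod_d2=0.0, cod_d3=0.0, frag_d2=0.0
        )
        object.__setattr__(f, "n_d3_dev", 0.0)
        object.__setattr__(f, "parity_d2", 0)
        assert lr.published_score(f, male_age=0.0) == pytest.approx(12.887)

    def test_fragmentation_strictly_decreases_score(self):
        lo = make_cass_features(frag_d2=0.1)
        hi = make_cass_features(frag_d2=0.4)
        s_lo = lr.published_score(lo, male_age=0.0)
        s_hi = lr.published_score(hi, male_age=0.0)
        assert s_hi < s_lo

    def test_missing_feature_named(self):
        f = make_cass_features(frag_d2=float("nan"))
        with pytest.raises(ValueError, match="frag"):
            lr.published_score(f, male_age=33.0)

    def test_tcv_scale_config(self):
        pub = lr.load_published_score()
        assert pub.tcv_scale == pytest.approx(1e-5)
        custom = lr.PublishedScore(coefficients=pub.coefficients, tcv_scale=1.0)
        f = make_cass_features()
        assert lr.published_score(f, 33.0, custom) != lr.published_score(f, 33.0, pub)

    def test_coefficients_complete(self):
        pub = lr.load_published_score()
        assert len(pub.coefficients) == 12
        assert pub.coefficients["parity_day2:number_day3"] == pytest.approx(0.730)

    def test_missing_coefficient_rejected(self):
        with pytest.raises(ValueError, match="missing terms"):
            lr.PublishedScore(coefficients={"intercept": 12.07}, tcv_scale=1e-5)
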