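import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rndvi.curves import CurveSpec, eval_curve
from rndvi.fitting import (
    FitError,
    ModelFit,
    compare_parameters,
    fit_curve,
    goodness,
    rank_models,
    relationship_fit,
)
from rndvi.reference import CANDIDATE_RESULTS, HIGH_YIELD_POOLED


class TestGoodness:
    def test_hand_computed_example(self):
        r2, rmse = goodness((0.2, 0.4, 0.6), (0.3, 0.4, 0.5))
        assert rmse == pytest.approx(0.08164965809277258, abs=1e-12)
        assert r2 == pytest.approx(0.75, abs=1e-12)

    def test_perfect_fit(self):
        y = np.array([0.1, 0.5, 0.9])
        assert goodness(y, y) == (1.0, 0.0)

    def test_mean_prediction_scores_zero(self):
        y = np.array([0.2, 0.4, 0.6])
        r2, _ = goodness(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_observations_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            r2, _ = goodness((0.5, 0.5, 0.5), (0.4, 0.5, 0.6))
        assert np.isnan(r2)

    def test_constant_observations_fit_exactly_scores_zero(self):
        r2, rmse = goodness((0.5, 0.5, 0.5), (0.5, 0.5, 0.5))
        assert (r2, rmse) == (0.0, 0.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        shift=st.floats(-5, 5),
        seed=st.integers(0, 2**16),
    )
    def test_rmse_translation_equivariant(self, shift, seed):
        rng = np.random.default_rng(seed)
        obs = rng.uniform(0, 1, 12)
        sim = obs + rng.normal(0, 0.05, 12)
        _, rmse0 = goodness(obs, sim)
        _, rmse1 = goodness(obs + shift, sim + shift)
        assert rmse1 == pytest.approx(rmse0, rel=1e-9, abs=1e-12)


class TestFitCurve:
    @pytest.mark.parametrize(
        "family",
        ["double_logistic", "cubic", "rational_quad", "rational_power", "logistic3"],
    )
    def test_noiseless_recovery_of_published_coefficients(self, family):
        """Each candidate family refitted to 50 noiseless points of its
        own published curve recovers the coefficients."""
        spec, _, _ = CANDIDATE_RESULTS[family]
        x = np.linspace(0, 1.1, 50)
        y = eval_curve(spec, x)
        fit = fit_curve(family, (x, y))
        assert fit.converged
        tol = 1e-6 if family == "cubic" else 1e-3
        np.testing.assert_allclose(fit.spec.params, spec.params, rtol=tol)
        assert fit.rmse < 1e-6

    def test_underdetermined_fit_rejected(self):
        x = np.array([0.1, 0.5, 0.9])
        with pytest.raises(FitError, match="cannot determine"):
            fit_curve("double_logistic", (x, x))

    def test_deterministic_given_identical_inputs(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1.1, 30)
        y = eval_curve(HIGH_YIELD_POOLED, x) + rng.normal(0, 0.03, 30)
        f1 = fit_curve("double_logistic", (x, y))
        f2 = fit_curve("double_logistic", (x, y))
        assert f1.spec.params == f2.spec.params

    def test_standard_errors_shrink_with_sample_size(self):
        rng = np.random.default_rng(4)
        ses = []
        for n in (25, 400):
            x = np.linspace(0, 1.1, n)
            y = eval_curve(HIGH_YIELD_POOLED, x) + rng.normal(0, 0.03, n)
            ses.append(fit_curve("double_logistic", (x, y)).param_se)
        assert all(b < a for a, b in zip(*ses))


def _dummy_fit(family, r2, rmse, params=None):
    arity = {"double_logistic": 4, "cubic": 4, "rational_quad": 4,
             "logistic3": 3}[family]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = CurveSpec(family, params or tuple([1.0] * arity))
    return ModelFit(spec, r2, rmse, 100, (0.1,) * arity, True)


class TestRankModels:
    def test_published_r2_ordering(self):
        """With the published goodness values the double logistic ranks
        first, then cubic, then the rational form."""
        fits = [
            _dummy_fit("rational_quad", 0.8319, 0.1373),
            _dummy_fit("double_logistic", 0.8577, 0.1161),
            _dummy_fit("cubic", 0.8357, 0.1357),
        ]
        ranked = rank_models(fits)
        assert [f.spec.family for f in ranked] == [
            "double_logistic", "cubic", "rational_quad",
        ]

    def test_ties_break_on_rmse_then_arity(self):
        a = _dummy_fit("cubic", 0.85, 0.13)
        b = _dummy_fit("double_logistic", 0.85, 0.11)
        c = _dummy_fit("logistic3", 0.85, 0.11)
        ranked = rank_models([a, b, c])
        assert ranked[0].spec.family == "logistic3"  # same rmse, fewer params
        assert ranked[-1].spec.family == "cubic"

    def test_single_fit_ranks_as_itself(self):
        fit = _dummy_fit("cubic", 0.9, 0.1)
        assert rank_models([fit]) == [fit]

    def test_all_unconverged_is_error(self):
        fit = _dummy_fit("cubic", 0.9, 0.1)
        fit.converged = False
        with pytest.raises(FitError, match="no converged"):
            rank_models([fit])


class TestCompareParameters:
    def _fit(self, params, se):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = CurveSpec("double_logistic", params)
        return ModelFit(spec, 0.9, 0.1, 50, se, True)

    def test_identical_fits_give_z0_p1(self):
        fit = self._fit((15.0, 0.2, 11.0, 1.0), (0.5, 0.01, 0.5, 0.01))
        for z, p in compare_parameters(fit, fit).values():
            assert z == 0.0 and p == 1.0

    def test_vanishing_errors_drive_p_to_zero(self):
        a = self._fit((15.0, 0.2, 11.0, 1.0), (0.0, 0.0, 0.0, 0.0))
        b = self._fit((16.0, 0.3, 12.0, 1.1), (0.0, 0.0, 0.0, 0.0))
        for z, p in compare_parameters(a, b).values():
            assert np.isinf(z) and p == 0.0

    def test_antisymmetry(self):
        a = self._fit((15.0, 0.2, 11.0, 1.0), (0.5, 0.02, 0.5, 0.02))
        b = self._fit((16.0, 0.25, 12.0, 1.05), (0.4, 0.03, 0.6, 0.01))
        ab = compare_parameters(a, b)
        ba = compare_parameters(b, a)
        for name in ab:
            assert ab[name][0] == pytest.approx(-ba[name][0])
            assert ab[name][1] == pytest.approx(ba[name][1])

    def test_requires_same_family_and_errors(self):
        a = self._fit((15.0, 0.2, 11.0, 1.0), (0.5, 0.02, 0.5, 0.02))
        b = ModelFit(CurveSpec("cubic", (0, 1, 0, 0)), 0.9, 0.1, 50, (1, 1, 1, 1))
        with pytest.raises(ValueError, match="family"):
            compare_parameters(a, b)
        no_se = ModelFit(a.spec, 0.9, 0.1, 50, ())
        with pytest.raises(ValueError, match="standard errors"):
            compare_parameters(a, no_se)


class TestRelationshipFit:
    def test_linear_data_fits_exactly(self):
        x = np.linspace(1, 8, 12)  # e.g. LAI
        y = 0.2 + 0.05 * x
        fit = relationship_fit(x, y, "linear")
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(fit.spec.params, (0.2, 0.05), rtol=1e-9)

    def test_constant_response_scores_zero(self):
        x = np.linspace(1, 8, 12)
        fit = relationship_fit(x, np.full(12, 0.7), "linear")
        assert fit.r2 == 0.0

    def test_saturating_data_prefers_saturating_family(self):
        """NDVI saturates against dense canopies; on saturating data the
        asymptotic family must beat the straight line."""
        x = np.linspace(0.5, 10, 25)
        y = 0.9 - 0.7 * np.exp(-0.6 * x)
        lin = relationship_fit(x, y, "linear")
        sat = relationship_fit(x, y, "exponential_saturating")
        assert sat.r2 > lin.r2
        assert sat.r2 == pytest.approx(1.0, abs=1e-8)

    def test_power_family_and_input_guards(self):
        x = np.linspace(0.5, 6, 20)
        y = 0.3 * x**0.6
        fit = relationship_fit(x, y, "power")
        np.testing.assert_allclose(fit.spec.params, (0.3, 0.6), rtol=1e-6)
        with pytest.raises(FitError, match="at least 3"):
            relationship_fit([1, 2], [0.1, 0.2], "linear")
        with pytest.raises(ValueError, match="not in"):
            relationship_fit(x, y, "cubic")
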