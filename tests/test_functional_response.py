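"""Rogers model solution, MLE fitting, flexible exponent, type determination."""

import numpy as np
import pandas as pd
import pytest

import predfr as pf
from predfr.functional_response import (
    FlexibleTypeII,
    FunctionalResponseResults,
    RogersTypeII,
    predict_curve,
    rogers_expected,
)

from conftest import TRUE_A, TRUE_H, newton_rogers

# frozen from the Newton-iteration oracle on the implicit equation
NE_10_ORACLE = 4.007215980360806


class TestRogersExpected:
    def test_boundary_zeros(self):
        assert rogers_expected(0, 2.0, 0.1) == 0.0
        assert rogers_expected(5, 0.0, 0.1) == 0.0

    def test_closed_form_h_zero(self):
        assert rogers_expected(5, 1.0, 0.0, 1.0) == pytest.approx(
            5 * (1 - np.exp(-1)), rel=1e-12
        )

    def test_reference_parameter_point(self):
        """Ne(10; a=4.05, h=0.218, T=1) from the independent Newton oracle."""
        assert rogers_expected(10, TRUE_A, TRUE_H, 1.0) == pytest.approx(
            NE_10_ORACLE, abs=1e-9
        )

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError):
            rogers_expected(5, np.nan, 0.1)
        with pytest.raises(ValueError):
            rogers_expected(5, 1.0, -0.1)

    def test_lambert_matches_newton_oracle_on_grid(self):
        for a in (0.01, 0.5, 4.05, 20.0):
            for h in (0.01, 0.218, 0.5):
                for n0 in (1, 5, 20, 50):
                    assert rogers_expected(n0, a, h, 1.0) == pytest.approx(
                        newton_rogers(n0, a, h, 1.0), abs=1e-10
                    )

    def test_monotonicity_and_bounds(self):
        n0 = np.arange(1, 51, dtype=float)
        prev = None
        for a in (0.5, 1.0, 4.0):
            ne = rogers_expected(n0, a, 0.2, 1.0)
            assert np.all(np.diff(ne) > 0)  # increasing in N0
            assert np.all(ne <= n0 + 1e-12)
            assert np.all(ne <= 1.0 / 0.2 + 1e-12)  # T/h cap
            if prev is not None:
                assert np.all(ne >= prev)  # increasing in a
            prev = ne
        # decreasing in h
        ne_lo = rogers_expected(n0, 2.0, 0.05, 1.0)
        ne_hi = rogers_expected(n0, 2.0, 0.4, 1.0)
        assert np.all(ne_hi <= ne_lo)

    def test_proportion_consumed_declines_in_density(self):
        n0 = np.arange(1, 51, dtype=float)
        for a, h in ((0.5, 0.05), (TRUE_A, TRUE_H), (10.0, 0.4)):
            prop = rogers_expected(n0, a, h, 1.0) / n0
            assert np.all(np.diff(prop) < 0)


class TestRogersFit:
    def test_recovery_in_closed_form_limit(self):
        """Data generated with h = 0: a recovered near 1, h near the boundary."""
        ds = pf.simulate_fr_dataset(
            pf.FrGeneratorConfig(a=1.0, h=0.0, reps=500, seed=31)
        )
        fit = pf.fit_rogers(ds)
        assert fit.converged
        assert fit.params["a"] == pytest.approx(1.0, rel=0.10)
        assert fit.params["h"] < 0.02

    def test_loglik_at_estimate_beats_truth(self, fr_dataset):
        fit = pf.fit_rogers(fr_dataset)
        model = fit.model
        assert -model.nloglik(np.log(fit.params.values)) >= -model.nloglik(
            np.log([TRUE_A, TRUE_H])
        ) - 1e-9

    def test_all_zero_consumption_reported_not_estimated(self):
        model = RogersTypeII([1, 2, 4, 6], [0, 0, 0, 0])
        fit = model.fit()
        assert not fit.converged
        assert fit.params["a"] == 0.0

    def test_standard_errors_finite_and_positive(self, fr_dataset):
        fit = pf.fit_rogers(fr_dataset)
        assert np.all(np.isfinite(fit.bse.values))
        assert np.all(fit.bse.values > 0)
        ci = fit.conf_int()
        assert (ci["lower"] < fit.params).all()
        assert (ci["upper"] > fit.params).all()

    def test_aic_identity(self, fr_dataset):
        fit = pf.fit_rogers(fr_dataset)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.llf)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            RogersTypeII([5, 5, 5], [1, 2, 3])  # one distinct density
        with pytest.raises(ValueError):
            RogersTypeII([1, 2], [2, 1])  # consumed > N0


class TestFlexibleFit:
    def test_fixed_q_zero_matches_rogers(self, fr_dataset):
        rogers = pf.fit_rogers(fr_dataset)
        fixed = pf.fit_flex(fr_dataset, fix_q=0.0)
        assert fixed.llf == pytest.approx(rogers.llf, abs=1e-6)
        assert fixed.params["b"] == pytest.approx(rogers.params["a"], rel=1e-3)
        assert fixed.k_params == 2

    def test_free_q_at_least_fixed_q(self, fr_dataset):
        free = pf.fit_flex(fr_dataset)
        fixed = pf.fit_flex(fr_dataset, fix_q=0.0)
        assert free.llf >= fixed.llf - 1e-6

    def test_q_recovered_near_zero_on_type_II_data(self):
        ds = pf.simulate_fr_dataset(
            pf.FrGeneratorConfig(a=TRUE_A, h=TRUE_H, reps=1000, seed=41)
        )
        free = pf.fit_flex(ds)
        assert abs(free.params["q"]) < 0.3


def test_bootstrap_ci_well_formed(fr_dataset):
    """Stratified percentile bootstrap yields ordered intervals that contain
    the point estimate (coverage of the truth is a repeated-sampling
    property, not a per-realisation one)."""
    from predfr.functional_response import bootstrap_ci

    fit = pf.fit_rogers(fr_dataset)
    ci = bootstrap_ci(fit, n_boot=60, seed=2)
    assert (ci["lower"] < ci["upper"]).all()
    for name in ("a", "h"):
        assert ci.loc[name, "lower"] < fit.params[name] < ci.loc[name, "upper"]
    assert (ci["n_converged"] > 0).all()


class TestCompareModels:
    def test_identical_loglik_gives_plus_two(self, fr_dataset):
        free = pf.fit_flex(fr_dataset)
        fixed = pf.fit_flex(fr_dataset, fix_q=0.0)
        if abs(free.llf - fixed.llf) < 1e-9:
            cmp_ = pf.compare_models(free, fixed)
            assert cmp_.delta_aic == pytest.approx(2.0, abs=1e-6)
        # arithmetic check with synthetic results on the same data
        clone = FunctionalResponseResults(
            model=fixed.model, params=fixed.params, bse=fixed.bse,
            llf=fixed.llf + 5.0, converged=True, n_restarts=1, k_params=3,
        )
        cmp_ = pf.compare_models(clone, fixed)
        assert cmp_.delta_aic == pytest.approx(2.0 - 10.0)
        assert cmp_.conclusion == "deviation from Type II"

    def test_nesting_bound_holds(self, fr_dataset):
        free = pf.fit_flex(fr_dataset)
        fixed = pf.fit_flex(fr_dataset, fix_q=0.0)
        cmp_ = pf.compare_models(free, fixed)
        assert cmp_.delta_aic <= 2.0 + 1e-6
        assert cmp_.conclusion == "retain Type II"

    def test_mismatched_datasets_rejected(self, fr_dataset):
        free = pf.fit_flex(fr_dataset)
        other = pf.simulate_fr_dataset(
            pf.FrGeneratorConfig(a=1.0, h=0.1, seed=99)
        )
        fixed_other = pf.fit_flex(other, fix_q=0.0)
        with pytest.raises(ValueError, match="same dataset"):
            pf.compare_models(free, fixed_other)


class TestDetermineType:
    def test_constant_proportion_indeterminate(self):
        rng = np.random.default_rng(5)
        n0 = np.repeat([2, 4, 6, 8, 10], 30)
        consumed = rng.binomial(n0, 0.5)
        frame = pd.DataFrame({"N0": n0, "consumed": consumed})
        det = pf.determine_type(frame)
        assert det.response_type == "indeterminate"

    def test_type_II_on_rogers_generated_data(self):
        ds = pf.simulate_fr_dataset(
            pf.FrGeneratorConfig(a=TRUE_A, h=TRUE_H, reps=200, seed=51)
        )
        det = pf.determine_type(ds)
        assert det.response_type == "II"
        assert det.b1 < 0
        assert det.b1_p < 0.05

    def test_type_III_signature_on_rising_then_falling_proportions(self):
        """Hand-built counts with proportion rising then falling in N0."""
        n0 = np.repeat([1, 2, 4, 6, 8, 10], 50)
        props = {1: 0.10, 2: 0.35, 4: 0.65, 6: 0.70, 8: 0.55, 10: 0.35}
        rng = np.random.default_rng(6)
        consumed = rng.binomial(n0, [props[v] for v in n0])
        det = pf.determine_type(pd.DataFrame({"N0": n0, "consumed": consumed}))
        assert det.b1 > 0
        assert det.b2 < 0
        assert det.response_type == "III"

    def test_reduced_linear_model_reported(self, fr_dataset):
        det = pf.determine_type(fr_dataset)
        if det.b2_p >= 0.05:
            assert det.linear_only is not None
            assert det.linear_only["b1"] < 0

    def test_requires_three_densities(self):
        frame = pd.DataFrame({"N0": [2, 2, 4, 4], "consumed": [1, 1, 2, 2]})
        with pytest.raises(ValueError, match="densities"):
            pf.determine_type(frame)


class TestPredictCurve:
    def test_curve_shape_and_bounds(self, fr_dataset):
        fit = pf.fit_rogers(fr_dataset)
        densities = np.arange(1, 11, dtype=float)
        curve = predict_curve(fit, densities)
        ne = curve["expected_consumed"].to_numpy()
        assert np.all(np.diff(ne) > 0)
        assert np.all(ne <= np.minimum(densities, 1.0 / fit.params["h"]) + 1e-9)
        # increasing and flattening: increments shrink
        assert np.all(np.diff(np.diff(ne)) < 0)

    def test_h_zero_closed_form(self):
        model = RogersTypeII([1, 2, 4], [1, 1, 2])
        fit = FunctionalResponseResults(
            model=model,
            params=pd.Series({"a": 1.0, "h": 0.0}),
            bse=pd.Series({"a": np.nan, "h": np.nan}),
            llf=0.0, converged=True, n_restarts=1, k_params=2,
        )
        ne = fit.predict([1.0, 2.0])
        assert ne == pytest.approx((1 - np.exp(-1)) * np.array([1.0, 2.0]))

    def test_nonconverged_fit_rejected(self):
        model = RogersTypeII([1, 2, 4, 6], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="non-converged"):
            predict_curve(model.fit(), [1, 2])
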