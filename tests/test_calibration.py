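"""Fitness metrics and parameter fitting."""

import numpy as np
import pytest

from ehcvsim import (
    CalibrationSpec,
    ExpenditureSeries,
    ValidationError,
    apply_parameters,
    fit_parameters,
    mape,
    r_squared,
    synthetic_expenditure,
)


def series(years, amounts):
    return ExpenditureSeries(years=np.asarray(years), amounts=np.asarray(amounts, dtype=float))


class TestMape:
    def test_identical_series_zero(self):
        s = series([2009, 2010, 2011], [100, 200, 400])
        assert mape(s, s) == 0.0

    def test_hand_computed_example(self):
        obs = series([2009, 2010, 2011], [100, 200, 400])
        sim = series([2009, 2010, 2011], [90, 220, 400])
        assert mape(sim, obs) == pytest.approx(20.0 / 3.0)

    def test_zero_observed_value_undefined(self):
        with pytest.raises(ValidationError):
            mape(series([2009], [1.0]), series([2009], [0.0]))

    def test_year_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mape(series([2009, 2010], [1, 2]), series([2011], [1.0]))

    def test_scale_invariance_under_common_rescaling(self):
        obs = series([2009, 2010, 2011], [100, 200, 400])
        sim = series([2009, 2010, 2011], [90, 220, 400])
        obs10 = series(obs.years, obs.amounts * 10)
        sim10 = series(sim.years, sim.amounts * 10)
        assert mape(sim10, obs10) == pytest.approx(mape(sim, obs))


class TestRSquared:
    def test_identical_series_one(self):
        s = series([2009, 2010, 2011], [1, 2, 3])
        assert r_squared(s, s) == 1.0

    def test_mean_predictor_zero(self):
        obs = series([2009, 2010, 2011], [1, 2, 3])
        sim = series([2009, 2010, 2011], [2, 2, 2])
        assert r_squared(sim, obs) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        obs = series([2009, 2010, 2011], [1, 2, 3])
        sim = series([2009, 2010, 2011], [1.1, 1.9, 3.0])
        assert r_squared(sim, obs) == pytest.approx(1 - 0.02 / 2)

    def test_zero_variance_rejected(self):
        flat = series([2009, 2010], [5, 5])
        with pytest.raises(ValidationError):
            r_squared(series([2009, 2010], [4, 6]), flat)


class TestApplyParameters:
    def test_unknown_name_rejected(self, synthetic_bundle):
        with pytest.raises(ValidationError):
            apply_parameters(synthetic_bundle, {"uptake.banana": 1.0})

    def test_original_bundle_untouched(self, synthetic_bundle):
        w0 = synthetic_bundle.uptake.w_max
        out = apply_parameters(synthetic_bundle, {"uptake.w_max": 0.123})
        assert synthetic_bundle.uptake.w_max == w0
        assert out.uptake.w_max == 0.123

    def test_substitution_remainder_goes_private(self, synthetic_bundle):
        out = apply_parameters(
            synthetic_bundle, {"substitution.from_public": 0.4, "substitution.induced": 0.3}
        )
        assert out.substitution.from_private == pytest.approx(0.3)

    def test_price_scale_multiplies_all_prices(self, synthetic_bundle):
        out = apply_parameters(synthetic_bundle, {"mix.price_scale": 2.0})
        np.testing.assert_allclose(out.service_mix.base_price, 2 * synthetic_bundle.service_mix.base_price)


class TestFitParameters:
    def test_noiseless_self_fit_recovers_w_max(self, synthetic_bundle):
        true_w = 0.6
        observed = synthetic_expenditure(
            synthetic_bundle, {"uptake.w_max": true_w}, noise_cv=0.0, seed=0
        )
        spec = CalibrationSpec(
            free_parameters=[("uptake.w_max", 0.2, 0.95)], max_evaluations=120, n_starts=2, seed=3
        )
        result = fit_parameters(spec, observed, synthetic_bundle)
        assert result.mape < 1.0
        assert result.parameters["uptake.w_max"] == pytest.approx(true_w, rel=0.01)
        assert result.accepted

    def test_result_within_bounds_and_no_worse_than_starts(self, synthetic_bundle):
        observed = synthetic_expenditure(
            synthetic_bundle, {"uptake.w_max": 0.55}, noise_cv=0.05, seed=11
        )
        spec = CalibrationSpec(
            free_parameters=[("uptake.w_max", 0.3, 0.9), ("uptake.growth_rate", 0.1, 1.0)],
            max_evaluations=150,
            n_starts=3,
            seed=5,
        )
        result = fit_parameters(spec, observed, synthetic_bundle)
        assert 0.3 <= result.parameters["uptake.w_max"] <= 0.9
        assert 0.1 <= result.parameters["uptake.growth_rate"] <= 1.0
        finite_starts = [f for f in result.start_objectives if np.isfinite(f)]
        assert result.objective <= min(finite_starts) + 1e-9

    def test_reproducible_for_fixed_seed(self, synthetic_bundle):
        observed = synthetic_expenditure(
            synthetic_bundle, {"uptake.w_max": 0.5}, noise_cv=0.05, seed=2
        )
        spec = CalibrationSpec(
            free_parameters=[("uptake.w_max", 0.2, 0.9)], max_evaluations=60, n_starts=2, seed=9
        )
        a = fit_parameters(spec, observed, synthetic_bundle)
        b = fit_parameters(spec, observed, synthetic_bundle)
        assert a.parameters == b.parameters

    def test_anchor_pulls_fit_toward_target(self, hk_bundle):
        # calibrating with the published 2018 ratio as an anchor keeps the
        # baseline run on that trajectory value
        observed = hk_bundle.observed_expenditure
        spec = CalibrationSpec(
            free_parameters=[("uptake.w_max", 0.5, 0.95)],
            max_evaluations=80,
            n_starts=2,
            seed=1,
            anchor_weight=2e4,
        )
        anchors = {"ratio18": (2018, "ratio_public_private", 0.70)}
        result = fit_parameters(spec, observed, hk_bundle, anchors=anchors, end_year=2018)
        from ehcvsim import SimulationConfig, get_scenario, run_scenario

        bundle = apply_parameters(hk_bundle, result.parameters)
        rec = run_scenario(
            SimulationConfig(fixture=bundle, scenario=get_scenario("baseline"))
        ).records.set_index("year")
        assert rec.loc[2018, "ratio_public_private"] == pytest.approx(0.70, abs=0.02)
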