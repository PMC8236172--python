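"""Synthetic fixture generation and the packaged anchored bundle."""

import json

import numpy as np
import pytest

from ehcvsim import (
    FixtureBundle,
    ValidationError,
    generate_synthetic_fixture,
    hk_anchor_fixture,
    mape,
    synthetic_expenditure,
)
from ehcvsim.bands import BAND_LABELS
from ehcvsim.fixtures import HK_ANCHOR_RTOL, HK_ANCHORS, check_hk_anchors


class TestSyntheticGenerator:
    def test_same_seed_bit_identical_serialization(self):
        a = generate_synthetic_fixture(seed=42)
        b = generate_synthetic_fixture(seed=42)
        assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(b.to_dict(), sort_keys=True)

    def test_different_seeds_differ(self):
        a = generate_synthetic_fixture(seed=1)
        b = generate_synthetic_fixture(seed=2)
        assert json.dumps(a.to_dict()) != json.dumps(b.to_dict())

    def test_zero_scale_rejected(self):
        with pytest.raises(ValidationError):
            generate_synthetic_fixture(seed=0, scale=0.0)

    @pytest.mark.parametrize("seed", range(100))
    def test_public_share_rises_with_age(self, seed):
        bundle = generate_synthetic_fixture(seed=seed)
        share = bundle.demography.public_share
        assert np.all(share[:, 3] >= share[:, 0])

    def test_death_rates_decline_over_calendar_time(self):
        for seed in range(10):
            bundle = generate_synthetic_fixture(seed=seed)
            death = bundle.demography.death_rate
            assert np.all(death[-1] <= death[0])

    def test_generated_bundle_serialization_round_trip(self):
        bundle = generate_synthetic_fixture(seed=5)
        back = FixtureBundle.from_dict(bundle.to_dict())
        assert json.dumps(back.to_dict(), sort_keys=True) == json.dumps(
            bundle.to_dict(), sort_keys=True
        )


class TestSyntheticExpenditure:
    def test_zero_noise_matches_model_exactly(self, synthetic_bundle):
        series = synthetic_expenditure(synthetic_bundle, {"uptake.w_max": 0.6}, noise_cv=0.0, seed=0)
        again = synthetic_expenditure(synthetic_bundle, {"uptake.w_max": 0.6}, noise_cv=0.0, seed=99)
        np.testing.assert_array_equal(series.amounts, again.amounts)

    def test_noisy_series_reproducible_for_fixed_seed(self, synthetic_bundle):
        a = synthetic_expenditure(synthetic_bundle, {}, noise_cv=0.05, seed=4)
        b = synthetic_expenditure(synthetic_bundle, {}, noise_cv=0.05, seed=4)
        np.testing.assert_array_equal(a.amounts, b.amounts)

    def test_noise_is_mean_one_across_seeds(self, synthetic_bundle):
        # lognormal parameterization: E[multiplier] = 1, so the
        # seed-average of noisy/true converges to 1
        truth = synthetic_expenditure(synthetic_bundle, {}, noise_cv=0.0, seed=0)
        ratios = []
        for seed in range(200):
            noisy = synthetic_expenditure(synthetic_bundle, {}, noise_cv=0.05, seed=seed)
            ratios.append(noisy.amounts / truth.amounts)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.01)

    def test_noisy_mape_scales_with_cv(self, synthetic_bundle):
        truth = synthetic_expenditure(synthetic_bundle, {}, noise_cv=0.0, seed=0)
        noisy = synthetic_expenditure(synthetic_bundle, {}, noise_cv=0.05, seed=1)
        assert 0.0 < mape(noisy, truth) < 20.0


class TestAnchoredFixture:
    def test_loads_and_passes_self_check(self, hk_bundle):
        achieved = check_hk_anchors(hk_bundle)
        assert set(achieved) == set(HK_ANCHORS)

    def test_every_anchor_within_tolerance(self, hk_bundle):
        achieved = check_hk_anchors(hk_bundle)
        for key, target in HK_ANCHORS.items():
            assert abs(achieved[key] - target) <= HK_ANCHOR_RTOL * abs(target), key

    def test_provenance_present_for_every_top_level_field(self, hk_bundle):
        expected = {
            "initial_counts",
            "demography",
            "service_mix",
            "chronic",
            "uptake",
            "substitution",
            "substitution_chronic",
            "carry_release_fraction",
            "observed_expenditure",
        }
        assert expected.issubset(hk_bundle.provenance.keys())
        assert hk_bundle.provenance["observed_expenditure"] == "synthetic"

    def test_observed_expenditure_fits_below_mape_threshold(self, hk_bundle):
        from ehcvsim import ExpenditureSeries, SimulationConfig, get_scenario, run_scenario

        obs = hk_bundle.observed_expenditure
        out = run_scenario(
            SimulationConfig(
                fixture=hk_bundle, scenario=get_scenario("baseline"), start_year=2009, end_year=2016
            )
        )
        sim = ExpenditureSeries(
            years=out.records["year"].to_numpy(), amounts=out.records["expenditure_hkd"].to_numpy()
        )
        assert mape(sim, obs) < 40.0

    def test_mutating_returned_copy_does_not_affect_cache(self):
        a = hk_anchor_fixture()
        a.initial_counts[:] = 0
        b = hk_anchor_fixture()
        assert b.initial_counts.sum() > 0

    def test_band_labels_round_trip_in_serialization(self, hk_bundle):
        data = hk_bundle.to_dict()
        assert data["band_labels"] == list(BAND_LABELS)
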