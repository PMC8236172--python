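"""Population stepping, visit generation and the sector split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehcvsim import (
    IntegrationInstabilityError,
    PopulationState,
    SimulationConfig,
    ValidationError,
    generate_visits,
    get_scenario,
    run_scenario,
    split_public_private,
    step_population,
)
from ehcvsim import DemographyRates
from ehcvsim.bands import BAND_LABELS, N_BANDS


def _rates(birth=0.0, death=(0, 0, 0, 0), aging=(0, 0, 0, 0), visit=(0, 0, 0, 0), public=(0, 0, 0, 0)):
    return DemographyRates(
        birth_inflow=birth,
        death_rate=np.asarray(death, dtype=float),
        aging_rate=np.asarray(aging, dtype=float),
        visit_rate=np.asarray(visit, dtype=float),
        public_share=np.asarray(public, dtype=float),
    )


class TestStepPopulation:
    def test_zero_rates_identity(self, simple_state, zero_rates):
        out = step_population(simple_state, zero_rates, dt=1.0)
        np.testing.assert_array_equal(out.counts, simple_state.counts)
        assert out.week_index == simple_state.week_index + 1

    def test_single_band_decay_matches_geometric_closed_form(self, rates_factory):
        # one band with only deaths follows N0*(1-mu*dt)^n exactly
        mu = 0.001
        state = PopulationState(0.0, np.array([10_000.0, 0, 0, 0]))
        rates = rates_factory(death=(mu, 0, 0, 0))
        for _ in range(52):
            state = step_population(state, rates, dt=1.0)
        expected = 10_000.0 * (1 - mu) ** 52  # ~9493 persons
        assert state.counts[0] == pytest.approx(expected, rel=1e-12)
        assert state.counts[0] == pytest.approx(9493, abs=1.0)

    @given(
        aging=st.tuples(*[st.floats(0, 0.02) for _ in range(3)]),
        counts=st.tuples(*[st.floats(0, 1e6) for _ in range(4)]),
    )
    @settings(max_examples=50, deadline=None)
    def test_aging_only_conserves_total_population(self, aging, counts):
        state = PopulationState(0.0, np.array(counts))
        rates = _rates(aging=(*aging, 0.0))
        total0 = state.total
        for _ in range(20):
            state = step_population(state, rates, dt=1.0)
        assert state.total == pytest.approx(total0, rel=1e-9)

    def test_negative_stock_raises_naming_band(self, rates_factory):
        state = PopulationState(0.0, np.array([0.0, 100.0, 0, 0]))
        rates = rates_factory(death=(0, 2.0, 0, 0))  # 200%/week: unstable at dt=1
        with pytest.raises(IntegrationInstabilityError, match="b60_64"):
            step_population(state, rates, dt=1.0)

    def test_nonfinite_rate_rejected(self):
        with pytest.raises(ValidationError):
            PopulationState(0.0, np.array([1.0, np.nan, 0, 0]))
        from ehcvsim import DemographyRates

        with pytest.raises(ValidationError):
            DemographyRates(
                birth_inflow=0.0,
                death_rate=np.array([np.inf, 0, 0, 0]),
                aging_rate=np.zeros(4),
                visit_rate=np.zeros(4),
                public_share=np.zeros(4),
            )

    def test_terminal_band_aging_rejected(self, rates_factory):
        with pytest.raises(ValidationError):
            rates_factory(aging=(0, 0, 0, 0.1))

    def test_richardson_halving_dt_halves_decay_error(self, rates_factory):
        # explicit Euler is first order: against the exact exponential
        # solution, halving dt halves the error
        mu = 0.01
        exact = 1e4 * np.exp(-mu * 52)
        errors = []
        for dt in (1.0, 0.5):
            state = PopulationState(0.0, np.array([1e4, 0, 0, 0]))
            rates = rates_factory(death=(mu, 0, 0, 0))
            for _ in range(int(52 / dt)):
                state = step_population(state, rates, dt=dt)
            errors.append(abs(state.counts[0] - exact))
        assert errors[0] / errors[1] == pytest.approx(2.0, rel=0.05)


class TestVisits:
    def test_zero_population_zero_visits(self, zero_rates):
        state = PopulationState(0.0, np.zeros(4))
        assert generate_visits(state, zero_rates).total.sum() == 0

    def test_single_band_product(self, rates_factory):
        state = PopulationState(0.0, np.array([1000.0, 0, 0, 0]))
        flows = generate_visits(state, rates_factory(visit=(0.1, 0, 0, 0)))
        np.testing.assert_allclose(flows.total, [100.0, 0, 0, 0])

    @pytest.mark.parametrize(
        "share, pub, priv",
        [(0.5, 100.0, 100.0), (0.0, 0.0, 200.0), (0.42, 84.0, 116.0)],
    )
    def test_split_arithmetic(self, rates_factory, share, pub, priv):
        state = PopulationState(0.0, np.array([2000.0, 0, 0, 0]))
        rates = rates_factory(visit=(0.1, 0, 0, 0), public=(share, share, share, share))
        flows = split_public_private(generate_visits(state, rates), rates)
        assert flows.public_base[0] == pytest.approx(pub)
        assert flows.private_base[0] == pytest.approx(priv)

    @given(
        counts=st.tuples(*[st.floats(0, 1e6) for _ in range(4)]),
        shares=st.tuples(*[st.floats(0, 1) for _ in range(4)]),
    )
    @settings(max_examples=50, deadline=None)
    def test_split_components_sum_to_total(self, counts, shares):
        state = PopulationState(0.0, np.array(counts))
        rates = _rates(visit=(0.05, 0.1, 0.12, 0.3), public=shares)
        flows = split_public_private(generate_visits(state, rates), rates)
        np.testing.assert_allclose(flows.public_base + flows.private_base, flows.total, rtol=1e-12)

    def test_share_above_one_rejected(self, rates_factory):
        with pytest.raises(ValidationError):
            rates_factory(public=(1.2, 0, 0, 0))


class TestAnchoredDemography:
    def test_2009_band_shares_match_survey_pattern(self, hk_bundle):
        # 70+ generates ~35% and under-60 ~54% of all 2009 visits
        out = run_scenario(SimulationConfig(fixture=hk_bundle, scenario=get_scenario("baseline")))
        row = out.records.set_index("year").loc[2009]
        total = sum(row[f"visits_{b}"] for b in BAND_LABELS)
        assert row["visits_b70plus"] / total == pytest.approx(0.35, rel=0.10)
        assert row["visits_under60"] / total == pytest.approx(0.54, rel=0.10)

    def test_halving_dt_changes_2032_population_under_one_percent(self, hk_bundle):
        pops = []
        for dt in (1.0, 0.5):
            cfg = SimulationConfig(fixture=hk_bundle, scenario=get_scenario("baseline"), dt=dt)
            rec = run_scenario(cfg).records.set_index("year").loc[2032]
            pops.append(np.array([rec[f"pop_{b}"] for b in BAND_LABELS]))
        assert np.all(np.abs(pops[0] - pops[1]) / pops[1] < 0.01)
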