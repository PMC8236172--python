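import numpy as np
import pytest

from ehcvsim import (
    DemographyRates,
    PopulationState,
    generate_synthetic_fixture,
    hk_anchor_fixture,
)
from ehcvsim.bands import N_BANDS, WEEKS_PER_YEAR


@pytest.fixture(scope="session")
def hk_bundle():
    """Packaged Hong-Kong-anchored bundle (self-check runs on first load)."""
    return hk_anchor_fixture()


@pytest.fixture()
def synthetic_bundle():
    return generate_synthetic_fixture(seed=7, scale=7e6)


@pytest.fixture()
def zero_rates():
    z = np.zeros(N_BANDS)
    return DemographyRates(
        birth_inflow=0.0, death_rate=z, aging_rate=z, visit_rate=z, public_share=z
    )


@pytest.fixture()
def simple_state():
    return PopulationState(week_index=0.0, counts=np.array([6e6, 3e5, 3e5, 6e5]))


def make_rates(
    birth=0.0, death=(0, 0, 0, 0), aging=(0, 0, 0, 0), visit=(0, 0, 0, 0), public=(0, 0, 0, 0)
):
    return DemographyRates(
        birth_inflow=birth,
        death_rate=np.asarray(death, dtype=float),
        aging_rate=np.asarray(aging, dtype=float),
        visit_rate=np.asarray(visit, dtype=float),
        public_share=np.asarray(public, dtype=float),
    )


@pytest.fixture()
def rates_factory():
    return make_rates


@pytest.fixture(scope="session")
def weeks_per_year():
    return WEEKS_PER_YEAR
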