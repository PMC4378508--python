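import datetime as dt

import pytest

from seedlife import DEFAULT_GERMINATION_PARAMS, DEFAULT_SEED_SET_PARAMS
from seedlife.phenology import BoltingModelConfig, ThermalModelParams
from seedlife.simulator import GenotypeConfig
from seedlife.synthetic import (
    SyntheticAssaySpec,
    SyntheticClimateSpec,
    synth_climate,
    synth_germination_assays,
)


@pytest.fixture(scope="session")
def params():
    """The published four-parameter germination model."""
    return DEFAULT_GERMINATION_PARAMS


@pytest.fixture(scope="session")
def seed_set_params():
    """The published Col-0 seed-set thermal-time model."""
    return DEFAULT_SEED_SET_PARAMS


@pytest.fixture(scope="session")
def noise_free_assays(params):
    """Exact model fractions over the full training design."""
    return synth_germination_assays(SyntheticAssaySpec(params=params, noise=False))


@pytest.fixture(scope="session")
def sinusoidal_climate():
    """One-year temperate climate: mean 9 degC, amplitude 8 degC."""
    return synth_climate(
        SyntheticClimateSpec(mean=9.0, amplitude=8.0, diurnal_range=6.0, n_years=1)
    )


def constant_climate(temp: float, n_years: int = 3):
    return synth_climate(
        SyntheticClimateSpec(
            mean=temp, amplitude=0.0, diurnal_range=0.0, n_years=n_years
        )
    )


@pytest.fixture(scope="session")
def surrogate_genotype(seed_set_params, params):
    """Winter-annual genotype: surrogate photothermal bolting + published models."""
    return GenotypeConfig(
        bolting=BoltingModelConfig(
            model="generic",
            params=ThermalModelParams(t_b=3.0, threshold=6500.0, mode="photothermal"),
        ),
        seed_set=seed_set_params,
        germination=params,
    )


@pytest.fixture(scope="session")
def stub_genotype(seed_set_params, params):
    """Fixed 30-day bolting stub over the published seed-set/dormancy models."""
    return GenotypeConfig(
        bolting=BoltingModelConfig(model="fixed", duration_days=30),
        seed_set=seed_set_params,
        germination=params,
    )


@pytest.fixture
def autumn_sowing():
    return dt.date(2001, 10, 1)
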