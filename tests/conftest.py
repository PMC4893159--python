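import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import uvddr
from uvddr.synthetic_data import RNAiSimConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(seed: int = 0, **overrides) -> uvddr.SimulationConfig:
    """A reduced bundle (600 proteins, 40 true factors, 100 cells/well) used
    by the unit suite; statistical structure identical to the defaults."""
    base = dict(
        n_proteins=600,
        n_true_factors=40,
        rnai=RNAiSimConfig(
            cells_per_well=100,
            test_wells_per_plate=80,
            non_targeting_per_plate=8,
            risc_free_per_plate=8,
            positive_controls_per_plate=4,
        ),
    )
    base.update(overrides)
    return uvddr.default_config(seed=seed, **base)


@pytest.fixture(scope="session")
def small_bundle() -> uvddr.Bundle:
    return uvddr.generate_bundle(small_config(seed=11))


@pytest.fixture(scope="session")
def small_result(small_bundle) -> uvddr.PipelineResult:
    return uvddr.run_bundle(small_bundle)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160512)
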