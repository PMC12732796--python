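import numpy as np
import pytest

from gik import synthetic_data as sd


@pytest.fixture(scope="session")
def planted_record():
    """Static complex with two well-separated planted contacts."""
    spec = sd.ScenarioSpec(
        seed=101,
        planted_contacts=[sd.PlantedContact("3.50", "H5.23", 1.0),
                          sd.PlantedContact("5.65", "H5.20", 1.0)])
    return sd.make_complex(spec)


@pytest.fixture(scope="session")
def small_scenario():
    return sd.ScenarioSpec(
        seed=42, n_replicates=2, frames_per_replicate=80,
        planted_contacts=[sd.PlantedContact("3.54", "H5.20", 1.0),
                          sd.PlantedContact("6.33", "H5.25", 0.5)])


@pytest.fixture(scope="session")
def small_ensemble(small_scenario):
    return sd.make_ensemble(small_scenario)


@pytest.fixture(scope="session")
def small_ensemble_record(small_scenario):
    return sd.make_complex(small_scenario, verify=False)


@pytest.fixture(scope="session")
def funnel():
    return sd.funnel_fixture(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
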