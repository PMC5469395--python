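import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nirstherm as nt

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def animal_grid():
    return nt.WavelengthGrid.linspace(662.0, 984.0, 322)


@pytest.fixture(scope="session")
def human_grid():
    return nt.WavelengthGrid.linspace(770.0, 906.0, 136)


@pytest.fixture(scope="session")
def animal_table(animal_grid):
    return nt.make_extinction_table(animal_grid)


@pytest.fixture(scope="session")
def human_table(human_grid):
    return nt.make_extinction_table(human_grid)


@pytest.fixture(scope="session")
def band_selection(animal_grid):
    return nt.select_wavelengths(animal_grid, "band_720_880")


@pytest.fixture(scope="session")
def cooling_recording(animal_table):
    """Noiseless continuous-cooling recording, constant concentrations."""
    return nt.simulate_recording(
        animal_table, nt.Protocol.continuous_cooling(), noise_sd=0.0, seed=7
    )


@pytest.fixture(scope="session")
def rewarming_recording(human_table):
    """Noiseless stepwise-rewarming recording with systemic channels."""
    protocol = nt.Protocol.stepwise_rewarming(
        duration_s=4500.0, sampling_hz=0.2, step_interval_s=600.0
    )
    return nt.simulate_recording(
        human_table, protocol, noise_sd=0.0,
        systemic_spec=nt.SystemicSpec(), seed=3, relaxation_tau_s=10.0,
    )


@pytest.fixture(scope="session")
def matched_gain(cooling_recording):
    """Extinction->attenuation unit conversion matching the simulator."""
    meta = cooling_recording.meta
    return meta["pathlength_cm"] * meta["concentrations"]["h2o_fraction"]
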