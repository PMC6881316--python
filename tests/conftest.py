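import numpy as np
import pytest

from spectratype import SimulationConfig, pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A light 3-species study configuration for fast end-to-end tests."""
    return SimulationConfig(
        n_species=3,
        specimens_per_species=(2, 2, 2),
        peaks_per_species=15,
        grid_step=2.0,
        seed=99,
    )


@pytest.fixture(scope="session")
def fixture_study():
    """One study-scale simulation (34 specimens, 204 spectra), shared."""
    return pipeline.simulate_fixture_study(seed=0)


@pytest.fixture(scope="session")
def fixture_peaklists(fixture_study):
    return pipeline.peaklists_by_specimen(fixture_study)
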