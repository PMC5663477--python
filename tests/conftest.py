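import numpy as np
import pytest

from popcircuit.params import default_params
from popcircuit.population import PopulationLogisticParams
from popcircuit.synth import GroundTruthSpec, sample_raster


@pytest.fixture(scope="session")
def tiny_circuit():
    """Small uncompensated circuit for structural checks."""
    return default_params(scale=0.1, scale_compensate=False)


@pytest.fixture(scope="session")
def small_circuit():
    """Reduced circuit with amplitude compensation (functional checks)."""
    return default_params(scale=0.1)


@pytest.fixture(scope="session")
def het_pop_params():
    """A heterogeneous population in the physiological statistic range."""
    return PopulationLogisticParams(mu_thresh=1.0, mu_slope=3.0,
                                    sd_thresh=0.4, sd_slope=0.8,
                                    rho_slope_thresh=0.3)


@pytest.fixture(scope="session")
def correlated_raster():
    """Binary raster with substantial pairwise correlation (60 neurons)."""
    params = PopulationLogisticParams(mu_thresh=1.0, mu_slope=6.0,
                                      sd_thresh=0.2, sd_slope=0.5)
    spec = GroundTruthSpec(pop_params=params, n_neurons=60, n_bins=1500,
                           seed=11)
    _, binary = sample_raster(spec)
    return binary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
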