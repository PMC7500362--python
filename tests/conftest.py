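import numpy as np
import pytest

from mimsflux import load_gas_registry, preset, simulate
from mimsflux.simulator import truth_calibration


@pytest.fixture(scope="session")
def registry():
    return load_gas_registry()


@pytest.fixture(scope="session")
def s1_run(registry):
    """Noise-free ¹⁸O₂-labeling scenario with its exact calibration."""
    spec = preset("s1_o2_isotope", seed=1)
    trace, truth = simulate(spec, registry)
    return spec, trace, truth, truth_calibration(spec)


@pytest.fixture(scope="session")
def s2_run(registry):
    spec = preset("s2_hd_exchange", seed=1)
    trace, truth = simulate(spec, registry)
    return spec, trace, truth, truth_calibration(spec)


@pytest.fixture(scope="session")
def s3_run(registry):
    spec = preset("s3_ca_unlabeling", seed=1)
    trace, truth = simulate(spec, registry)
    return spec, trace, truth, truth_calibration(spec)


@pytest.fixture(scope="session")
def s4_run(registry):
    spec = preset("s4_ci_depletion", seed=1)
    trace, truth = simulate(spec, registry)
    return spec, trace, truth, truth_calibration(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
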