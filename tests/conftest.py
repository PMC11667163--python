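import numpy as np
import pytest

from adipoflux.network import (
    FluxVector,
    load_network,
    reference_adipocyte_network,
)


@pytest.fixture(scope="session")
def reference_network():
    return reference_adipocyte_network()


@pytest.fixture(scope="session")
def toy_cycle():
    return load_network("toy_cycle")


@pytest.fixture(scope="session")
def toy_cycle_fluxes():
    # balanced by construction: cycle throughput 10, anaplerosis 2, efflux 2
    return FluxVector(
        {"u": 10.0, "cs": 10.0, "cl": 10.0, "od": 10.0, "sd": 10.0,
         "md": 8.0, "an": 2.0, "ex": 2.0},
        {"sd": 5.0},
    )


@pytest.fixture(scope="session")
def control_truth(reference_network):
    from adipoflux.synthetic import sample_feasible_fluxes

    return sample_feasible_fluxes(reference_network, scenario="control")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
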