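import numpy as np
import pytest

from calspine import (SolverConfig, default_parameters, two_spine_arrangement)


@pytest.fixture(scope="session")
def params():
    """Physiological defaults with the fig2 plasticity preset."""
    return default_parameters("fig2")


@pytest.fixture(scope="session")
def two_spines():
    """Two plain spines 1 um apart on a 20 um cable, weights 0.5/0.5."""
    return two_spine_arrangement()


@pytest.fixture()
def fast_cfg():
    """Coarser solver settings used to keep simulation tests quick."""
    return SolverConfig(dt=1e-4, store_every=10)
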