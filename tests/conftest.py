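"""Shared fixtures: circuit models, frequency grids, small synthetic inputs."""

import numpy as np
import pytest

from protoelec import circuits


@pytest.fixture(scope="session")
def sweep_frequencies():
    """Instrument sweep: 1e-4 Hz to 100 kHz, 10 points per decade."""
    return np.logspace(-4, 5, 91)


@pytest.fixture(scope="session")
def actin_model():
    return circuits.build_named_circuit("actin")


@pytest.fixture(scope="session")
def proteinoid_model():
    return circuits.build_named_circuit("proteinoid")


@pytest.fixture(scope="session")
def mixture_model():
    return circuits.build_named_circuit("mixture")
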