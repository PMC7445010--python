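"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from ctamem.synthetic import (NeuronSimParams, StepProtocol,
                              simulate_neuron_sweeps)


@pytest.fixture(scope="session")
def quiet_cell():
    """Noiseless, sag-free LIF cell with the default step family + truth."""
    params = NeuronSimParams(noise_sd_mv=0.0, sag_g_ratio=0.0, seed=0)
    sweeps, truth = simulate_neuron_sweeps(params)
    return params, sweeps, truth


@pytest.fixture(scope="session")
def sag_cell():
    """Noiseless cell with the sag conductance enabled + oracle truth."""
    params = NeuronSimParams(noise_sd_mv=0.0, sag_g_ratio=0.2, seed=0)
    sweeps, truth = simulate_neuron_sweeps(params)
    return params, sweeps, truth


@pytest.fixture(scope="session")
def default_protocol():
    return StepProtocol()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
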