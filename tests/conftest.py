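import dataclasses

import numpy as np
import pytest

from phasekeeper import (
    DEFAULT_NEURON,
    ClampProtocol,
    PhaseModelParams,
    run_clamp_grid,
)

# the lumped parameters fitted to the biological realistic-waveform data
FIT_TAU_S = 26.0
FIT_G_STAR = 0.021
FIT_C = 0.43


@pytest.fixture(scope="session")
def params():
    return PhaseModelParams(tau_r=0.1, tau_s=FIT_TAU_S, g_star=FIT_G_STAR)


@pytest.fixture(scope="session")
def fast_neuron():
    """Fast-membrane clamp neuron (tau_m = 2 ms) for model-bridge checks."""
    return dataclasses.replace(DEFAULT_NEURON, C_m=0.2)


@pytest.fixture(scope="session")
def triangular_surface():
    """Single-replicate triangular-grid surface with the default neuron."""
    return run_clamp_grid(
        DEFAULT_NEURON, ClampProtocol(n_replicates=1, jitter=0.0, seed=0)
    )


@pytest.fixture(scope="session")
def fast_surface(fast_neuron):
    """Triangular-grid surface with the fast-membrane neuron."""
    return run_clamp_grid(
        fast_neuron, ClampProtocol(n_replicates=1, jitter=0.0, seed=0)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
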