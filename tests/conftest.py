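"""Shared fixtures: small, seeded synthetic inputs for every stage."""

import numpy as np
import pytest

import ecap_ipg as eig
from ecap_ipg.scales import cl_to_current, current_to_charge

DEFAULT_PHASE_US = 50.0


@pytest.fixture
def level_grid():
    return np.arange(150.0, 211.0, 4.0)


@pytest.fixture
def charge_grid(level_grid):
    current = np.array([cl_to_current(l) for l in level_grid])
    return current_to_charge(current, DEFAULT_PHASE_US)


@pytest.fixture
def noise_free_sweeps():
    cfg = eig.SweepSimConfig(
        latency_jitter_sd=0.0, amplitude_jitter_cv=0.0, noise_sd=0.0, seed=0
    )
    return eig.simulate_sweeps(cfg)


@pytest.fixture
def sigmoid_truth():
    return eig.SigmoidParams(y0=0.0, a=300.0, b=24.0, c=3.0)


def make_io(level_grid, amplitudes, ipg=7.0, c_level=210.0, phase=DEFAULT_PHASE_US):
    return eig.IOFunction(
        levels=np.asarray(level_grid, dtype=float),
        amplitudes=np.asarray(amplitudes, dtype=float),
        c_level=c_level,
        phase_duration=phase,
        ipg=ipg,
    )


@pytest.fixture
def noise_free_pair(sigmoid_truth):
    """IPG-42 curve = IPG-7 curve with midpoint shifted left by 2.5 nC."""
    truth42 = eig.SigmoidParams(
        sigmoid_truth.y0, sigmoid_truth.a, sigmoid_truth.b - 2.5, sigmoid_truth.c
    )
    cfg = eig.IOSimConfig(
        sigmoid_truth_per_ipg={7.0: sigmoid_truth, 42.0: truth42}, noise_sd=0.0
    )
    return eig.simulate_io_pair(cfg)
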