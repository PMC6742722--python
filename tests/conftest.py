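"""Shared fixtures: small synthetic recordings and their detected bursts."""

from __future__ import annotations

import numpy as np
import pytest

from meaburst import (
    condition_preset,
    detect_network_bursts,
    generate_recording,
    pool_spikes,
)


@pytest.fixture(scope="session")
def ctrl_recording():
    """A short control-regime recording with ground truth (seed 11)."""
    params = condition_preset("CTRL", seed=11, duration=600.0)
    sts, truth = generate_recording(params)
    return params, sts, truth


@pytest.fixture(scope="session")
def ctrl_bursts(ctrl_recording):
    _, sts, _ = ctrl_recording
    pooled = pool_spikes(sts)
    return pooled, detect_network_bursts(pooled)


def make_pooled(times, electrodes):
    """Build a pooled spike list from parallel time/electrode sequences."""
    from meaburst.burst_detection import PooledSpike

    return [PooledSpike(float(t), str(e)) for t, e in zip(times, electrodes)]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
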