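"""Shared fixtures: synthetic sessions and phantoms reused across test modules.

The heavier fixtures (full stimulus sessions) are session-scoped so the
generation and pipeline cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from widefield import hemodynamics as hd
from widefield import synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def epoch_spec():
    return hd.EpochSpec()


@pytest.fixture(scope="session")
def two_tone_session():
    """Strong-global two-tone session: 60 epochs (30 per stimulus), 64x64,
    response amplitude 2% HbT / 5% Ca, global fluctuation 3x the response."""
    cfg = synthetic.SessionConfig(
        territories=[
            synthetic.Territory((32, 18), 8, {"Ca": 0.05, "HbT": 0.02}, "4kHz"),
            synthetic.Territory((32, 46), 8, {"Ca": 0.05, "HbT": 0.02}, "24kHz"),
        ],
        noise_sd={"Ca": 0.02, "HbT": 0.02},
        global_amp=0.06,
        n_epochs=60,
        seed=11,
    )
    stacks, events, truth = synthetic.simulate_neurovascular_session(cfg)
    return stacks, events, truth


@pytest.fixture(scope="session")
def two_tone_responses(two_tone_session, epoch_spec):
    """Per-stimulus Ca and HbT response stacks from the two-tone session."""
    stacks, events, truth = two_tone_session
    out = {}
    for label in ("4kHz", "24kHz"):
        out[label] = {
            "Ca": hd.standard_response_pipeline(stacks["Ca"], events, epoch_spec, "Ca", label=label),
            "HbT": hd.standard_response_pipeline(stacks["HbT"], events, epoch_spec, "HbT", label=label),
        }
    return out, truth


@pytest.fixture(scope="session")
def quiet_session():
    """Noise-free, global-free single-territory session for exact-fidelity checks."""
    cfg = synthetic.SessionConfig(
        territories=[synthetic.Territory((32, 32), 8, {"Ca": 0.05, "HbT": 0.02}, "stim")],
        noise_sd={},
        global_amp=0.0,
        n_epochs=10,
        seed=3,
    )
    return synthetic.simulate_neurovascular_session(cfg)


@pytest.fixture(scope="session")
def bolus_phantom():
    arrival, mask = synthetic.make_bolus_arrival_phantom()
    stack, truth = synthetic.simulate_tracer_bolus(arrival, 200.0, mask, noise_sd=0.1, seed=5)
    return stack, arrival, mask
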