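"""Shared fixtures: small synthetic datasets, reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from somnostage import synthetic_psg as sp


@pytest.fixture(scope="session")
def signal_profile():
    return sp.default_signal_profile()


@pytest.fixture(scope="session")
def night_dynamics():
    return sp.default_dynamics(20)


@pytest.fixture(scope="session")
def short_recording(night_dynamics, signal_profile):
    """10-minute healthy night at 128 Hz, 20-s epochs."""
    protocol = sp.Protocol(kind="night", total_duration_min=10)
    return sp.generate_recording(night_dynamics, signal_profile, protocol, 128.0, 20, seed=42)


@pytest.fixture(scope="session")
def small_roster():
    """Six one-hour healthy nights (one per subject)."""
    return sp.generate_dataset(6, 1, "healthy", seed=7, duration_min=60)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
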