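"""Shared fixtures: small-but-valid configurations and profiles."""

import numpy as np
import pytest

from vmmn import (GroupProfile, ComponentSpec, SessionConfig, older_profile,
                  young_profile)
from vmmn.channels import ROI_CHANNELS


@pytest.fixture(scope="session")
def default_config() -> SessionConfig:
    return SessionConfig()


@pytest.fixture(scope="session")
def small_config() -> SessionConfig:
    """A short session for fast end-to-end runs (same structure, fewer
    trials)."""
    return SessionConfig(n_trials_per_sequence=50, iti_mean=400.0,
                         iti_jitter=30.0,
                         task_event_interval_range=(2_000.0, 6_000.0),
                         task_event_mean_interval=4_000.0)


@pytest.fixture(scope="session")
def roi_channels() -> tuple[str, ...]:
    return ROI_CHANNELS


@pytest.fixture
def single_component_profile() -> GroupProfile:
    """Noiseless profile with one unit-topography component on PO8."""
    spec = ComponentSpec("probe", peak_latency=100.0, amplitude=2.0,
                         width=15.0, topography={"PO8": 1.0})
    return GroupProfile(group="young", persistence_limit_letter=-1.0,
                        persistence_limit_pseudo=0.0, component_specs=(spec,),
                        noise_amplitude=0.0)


@pytest.fixture
def noiseless_older() -> GroupProfile:
    return older_profile(noise_amplitude=0.0)


@pytest.fixture
def noiseless_young() -> GroupProfile:
    return young_profile(noise_amplitude=0.0)
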