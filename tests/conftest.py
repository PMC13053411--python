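"""Shared fixtures for the test suite."""

from __future__ import annotations

import pytest

from attentraits.behavior_sim import PopulationParams


@pytest.fixture
def quiet_population() -> PopulationParams:
    """A small deterministic population with moderate heterogeneous effects."""
    return PopulationParams(
        n_participants=8,
        mean_effects={"tl_frequency": 40.0, "presence_tll": 50.0},
        between_sd={"tl_frequency": 25.0, "presence_tll": 30.0},
        within_rt_sd=120.0,
        lapse_rate=0.0,
        master_seed=11,
    )
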