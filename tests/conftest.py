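from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clonotrace.core import DEFAULT_TAGS, random_dna
from clonotrace.simulate import Founder, Integration, PopulationState

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def tags():
    return DEFAULT_TAGS


def make_founders(n: int, rng, integrations_per_founder: int = 1,
                  fitness: float = 1.0) -> list[Founder]:
    """Founders with fixed integration counts, colors cycling over the tags."""
    out = []
    for i in range(n):
        ints = tuple(
            Integration(DEFAULT_TAGS[(i + j) % 3].name, random_dna(rng, 16))
            for j in range(integrations_per_founder)
        )
        out.append(Founder(f"F{i:04d}", ints, fitness))
    return out


def uniform_state(n_clones: int, rng, cells_per_clone: int = 100,
                  passage: int = 0) -> PopulationState:
    founders = make_founders(n_clones, rng)
    return PopulationState(passage, {f: cells_per_clone for f in founders})
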