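"""Shared fixtures: synthetic sessions, segmented behaviour, helper builders.

Session-scoped fixtures are deliberately reused across test modules — the
generator is seeded, so every run sees identical data.
"""

from __future__ import annotations

import numpy as np
import pytest

from crossmap.behavior import (
    extract_flights,
    preprocess_trajectory,
    segment_modes,
    solo_flight_records,
)
from crossmap.synth import SessionConfig, simulate_session
from crossmap.synth.model import (
    DistanceProfile,
    ModelMap2D,
    NeuronModelConfig,
    build_neuron_map,
)
from crossmap.utils import bin_centers


def make_profiled_cell(seed: int, profile: DistanceProfile | None,
                       x_sep: float = 0.2) -> ModelMap2D:
    """A model neuron whose every field shares one distance profile
    (profile=None gives a pure place cell)."""
    m = build_neuron_map(NeuronModelConfig(x_sep=x_sep),
                         np.random.default_rng(seed))
    pc = bin_centers(m.pos_edges)
    dc = bin_centers(m.dist_edges)
    grid = np.zeros_like(m.rate_grid)
    gain = profile.evaluate(dc) if profile is not None else np.ones(dc.size)
    for lo, hi, _ in m.fields:
        grid[(pc >= lo) & (pc < hi), :] = gain[None, :]
    m.rate_grid = grid
    m.hotspot = None
    m.profiles = [profile] if profile is not None else [DistanceProfile("none")]
    m.fields = [(lo, hi, 0) for lo, hi, _ in m.fields]
    return m


def segmented_session(seed: int, n_flights: int, rest_law: str = "uniform:1:15"):
    """Simulate, preprocess and segment one session; returns a dict."""
    rng = np.random.default_rng(seed)
    scfg = SessionConfig(n_flights_per_direction=n_flights,
                         rest_duration_law=rest_law)
    session = simulate_session(scfg, rng)
    trajs = [preprocess_trajectory(df.t.to_numpy(), df.x.to_numpy(),
                                   df.y.to_numpy()) for df in session.raw]
    flights = [extract_flights(t) for t in trajs]
    table = segment_modes(trajs[0], trajs[1], flights[0], flights[1])
    return {
        "session": session,
        "trajs": trajs,
        "flights": flights,
        "table": table,
        "cross_pos": [c for c in table.valid_crossovers() if c.direction == 1],
        "solo_pos": [r for r in solo_flight_records(trajs[0], table)
                     if r["direction"] == 1],
    }


@pytest.fixture(scope="session")
def small_session():
    """~20 valid cross-overs per direction; cheap enough for unit tests."""
    return segmented_session(seed=42, n_flights=40)


@pytest.fixture(scope="session")
def big_session():
    """~80 cross-overs per direction; used by power/calibration tests."""
    return segmented_session(seed=43, n_flights=130, rest_law="uniform:1:12")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
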