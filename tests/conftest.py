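"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from ripplenf.signals import RippleSeries
from ripplenf.synth import (
    SessionConfig,
    estimate_background_stats,
    gen_background_lfp,
    gen_movement_spikes,
    gen_place_model,
)
from ripplenf.track import bin_path, make_eight_arm_maze


@pytest.fixture(scope="session")
def track():
    return make_eight_arm_maze()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def background_600():
    """600 s clean background with cached consensus statistics (4 tetrodes)."""
    cfg = SessionConfig(duration=600.0, rng_seed=1)
    lfp = gen_background_lfp(cfg)
    stats = estimate_background_stats(lfp)
    return lfp, stats, cfg


@pytest.fixture(scope="session")
def place_model(track):
    return gen_place_model(30, track, np.random.default_rng(7))


def make_trajectory(track, arm_sequence, speed=30.0, fs=30.0):
    """Bin-resolution trajectory visiting home then each arm end in turn."""
    home = track.bin_of("home", 1.0)
    stops = [home]
    for arm in arm_sequence:
        stops.append(track.bin_of(f"arm{arm}", track.segment_lengths[1 + arm] - 5.0))
        stops.append(home)
    xs = []
    for a, b in zip(stops, stops[1:]):
        p = bin_path(track, a, b)
        arc = np.arange(p.size) * track.bin_size
        n = max(int(arc[-1] / speed * fs), 2)
        s = np.linspace(0, arc[-1], n)
        xs.append(track.bin_centers_linear[p[np.searchsorted(arc, s, side="right") - 1]])
    x = np.concatenate(xs)
    t = np.arange(x.size) / fs
    speeds = np.full(x.size, speed)
    return t, x, speeds


@pytest.fixture(scope="session")
def movement_session(track, place_model):
    """Trajectory covering all eight arms, with place-cell marked spikes."""
    t, x, speeds = make_trajectory(track, [1, 3, 5, 7, 2, 4, 6, 8])
    spikes = gen_movement_spikes(t, x, place_model, np.random.default_rng(11))
    return {"times": t, "linear": x, "speeds": speeds, "spikes": spikes}


@pytest.fixture(scope="session")
def fitted_decoder(track, place_model, movement_session):
    from ripplenf.decoding import ClusterlessDecoder

    dec = ClusterlessDecoder(graph=track)
    dec.fit(
        movement_session["spikes"],
        movement_session["times"],
        movement_session["linear"],
        speeds=movement_session["speeds"],
    )
    return dec
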