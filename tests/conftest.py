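import numpy as np
import pytest

from popdecode.core import Environment, Trajectory
from popdecode import synthetic as syn
from popdecode.placefields import estimate_place_fields


@pytest.fixture(scope="session")
def open_field():
    return Environment("open_field", (100.0, 100.0), 15.0)


@pytest.fixture(scope="session")
def linear_track():
    return Environment("linear_track", 200.0, 10.0)


@pytest.fixture(scope="session")
def circular_track():
    return Environment("circular_track", 200.0, 10.0)


@pytest.fixture(scope="session")
def track_session(linear_track):
    """A linear-track run session: truth, trajectory, filtered counts, fields."""
    truth = syn.make_population(linear_track, n_cells=40, seed=1)
    traj = syn.simulate_trajectory(linear_track, 300.0, 25.0, seed=2)
    counts = syn.sample_spike_counts(truth, traj, 0.25, seed=3)
    counts = syn.apply_speed_filter(counts, traj)
    fields = estimate_place_fields(counts, traj, linear_track)
    return {"env": linear_track, "truth": truth, "traj": traj,
            "counts": counts, "fields": fields}


@pytest.fixture(scope="session")
def field_session(open_field):
    """A small open-field session for 2-D decoding tests."""
    truth = syn.make_population(open_field, n_cells=36, seed=11)
    traj = syn.simulate_trajectory(open_field, 240.0, 25.0, seed=12)
    counts = syn.sample_spike_counts(truth, traj, 0.25, seed=13)
    counts = syn.apply_speed_filter(counts, traj)
    fields = estimate_place_fields(counts, traj, open_field)
    return {"env": open_field, "truth": truth, "traj": traj,
            "counts": counts, "fields": fields}


def constant_speed_trajectory(env, speed, duration, sample_hz=60.0):
    """Straight constant-speed motion (wrapped on circular tracks)."""
    n = int(duration * sample_hz) + 1
    t = np.arange(n) / sample_hz
    x = speed * t
    if env.kind == "circular_track":
        x = np.mod(x, env.extent)
    elif env.kind == "linear_track":
        m = np.mod(x, 2 * env.extent)
        x = np.where(m <= env.extent, m, 2 * env.extent - m)
    return Trajectory(t, x, env=env)
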