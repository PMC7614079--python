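import numpy as np
import pytest

from foldscape.io import Trajectory
from foldscape.simulate import ObservationSpec, simulate_trajectory, two_state_network


def square_wave_trajectory(
    levels=(0.0, 18.2),
    dwell_s=1.0,
    n_cycles=10,
    sampling_rate=1000.0,
    noise_sd=0.0,
    force=8.5,
    seed=0,
) -> Trajectory:
    """Deterministic two-level square wave with optional white noise."""
    rng = np.random.default_rng(seed)
    per_dwell = int(round(dwell_s * sampling_rate))
    z = np.tile(
        np.concatenate([np.full(per_dwell, levels[0]), np.full(per_dwell, levels[1])]),
        n_cycles,
    ).astype(float)
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, z.size)
    time = np.arange(z.size) / sampling_rate
    return Trajectory(time, z, force, sampling_rate, "square")


@pytest.fixture
def square_wave():
    return square_wave_trajectory


@pytest.fixture(scope="session")
def short_two_state():
    """A 200 s native two-state recording with catalogue noise (session-cached)."""
    conf, net = two_state_network()
    traj, path = simulate_trajectory(
        net,
        conf,
        duration=200.0,
        force=8.5,
        observation=ObservationSpec(sampling_rate=1000.0),
        seed=42,
        initial_label="F",
    )
    return traj, path
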