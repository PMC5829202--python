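import numpy as np
import pytest

from shoalkit.trajectory import Circle, Trajectory, TrialMetadata


def make_trajectory(positions, trial_id="t1", fps=24.0, ids=None, smoothed=True):
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[1]
    return Trajectory(
        trial_id=trial_id,
        fps=fps,
        positions=positions,
        individual_ids=ids or [f"f{i + 1}" for i in range(n)],
        smoothed=smoothed,
    )


def translating_group(offsets, velocity=(10.0, 0.0), n_frames=20, fps=24.0):
    """A rigidly translating group: member i at offset[i] + t * velocity."""
    offsets = np.asarray(offsets, dtype=float)
    v = np.asarray(velocity, dtype=float)
    t = np.arange(n_frames)[:, None, None]
    pos = offsets[None, :, :] + t * v[None, None, :]
    return make_trajectory(pos)


@pytest.fixture
def open_meta():
    return TrialMetadata(
        trial_id="t1",
        group_id="g1",
        context="open",
        trial_number=1,
        arena=Circle((0.0, 0.0), 400.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
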