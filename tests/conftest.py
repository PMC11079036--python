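import numpy as np
import pytest

import arbbt as a


@pytest.fixture
def stream_cfg():
    return a.StreamConfig()


@pytest.fixture
def pinch_cfg():
    return a.PinchConfig()  # 64 px grab, 80 px release


@pytest.fixture
def session_cfg():
    return a.SessionConfig()


@pytest.fixture
def center_spawn_cfg():
    """Session config with deterministic spawns at the source-compartment
    centre, for hand-computable scripted scenarios."""
    return a.SessionConfig(arena=a.ArenaConfig(spawn_mode="center"))


def tips_frame(t, thumb, index, stream=None, handedness="right"):
    """Frame with exact pixel fingertip positions."""
    stream = stream if stream is not None else a.StreamConfig()
    return a.frame_from_tips(t, thumb, index, stream, handedness=handedness)


def uniform_frame(t, x, y, handedness="right"):
    """Frame with all 21 landmarks at one normalized point."""
    pts = np.zeros((21, 3))
    pts[:, 0] = x
    pts[:, 1] = y
    return a.LandmarkFrame(t=t, handedness=handedness, landmarks=pts)
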