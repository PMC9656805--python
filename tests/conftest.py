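import numpy as np
import pytest

from graspadl.hand_model import JOINT_CHANNELS, POSITION_SLOTS, identity_basis_row
from graspadl.preprocess import RigidTransform
from graspadl.trial import TrialRecording, CoordinateFrame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_frame_row(rng: np.random.Generator, scale: float = 60.0) -> np.ndarray:
    """A valid random 84-vector: random positions, random orthonormal basis."""
    row = np.empty(84)
    T = RigidTransform.random(rng, translation_scale=0.0)
    R = T.rotation
    row[3:6] = R[:, 0]
    row[6:9] = R[:, 1]
    row[9:12] = R[:, 2]
    for s in POSITION_SLOTS:
        row[s : s + 3] = rng.standard_normal(3) * scale
    return row


def random_trial(rng: np.random.Generator, n_frames: int = 10, **kw) -> TrialRecording:
    frames = np.stack([random_frame_row(rng) for _ in range(n_frames)])
    kw.setdefault("task_label", "cup")
    kw.setdefault("subject_id", "S0")
    return TrialRecording(frames=frames, **kw)


def make_hcs_trial(channels: np.ndarray, fps: float = 30.0) -> TrialRecording:
    """HCS trial whose 72 joint-coordinate channels are the given matrix."""
    channels = np.atleast_2d(channels)
    frames = np.tile(identity_basis_row(), (channels.shape[0], 1))
    frames[:, list(JOINT_CHANNELS)] = channels
    return TrialRecording(
        frames=frames,
        task_label="cup",
        subject_id="S0",
        fps=fps,
        coordinate_frame=CoordinateFrame.HCS,
    )


def scale_positions(trial: TrialRecording, s: float) -> TrialRecording:
    """Uniformly scale all position coordinates (hand-size change); the unit
    basis vectors are directions and stay unscaled."""
    frames = trial.frames.copy()
    for slot in POSITION_SLOTS:
        frames[:, slot : slot + 3] *= s
    return trial.with_frames(frames)
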