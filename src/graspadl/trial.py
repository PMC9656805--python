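"""Trial recording container and validation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from graspadl.hand_model import N_VALUES, DEFAULT_TASKS

__all__ = ["CoordinateFrame", "TrialRecording"]


class CoordinateFrame(str, Enum):
    GCS = "GCS"
    HCS = "HCS"


@dataclass
class TrialRecording:
    """One recorded trial: an ``n_frames x 84`` coordinate matrix plus metadata.

    Coordinates are in millimeters.  ``coordinate_frame`` records whether the
    rows are expressed in the global coordinate system (GCS) or the
    palm-anchored hand coordinate system (HCS); only the preprocessing step
    changes it.
    """

    frames: np.ndarray
    task_label: str
    subject_id: str
    trial_index: int = 0
    fps: float = 30.0
    coordinate_frame: CoordinateFrame = CoordinateFrame.GCS
    task_vocabulary: tuple[str, ...] = field(default=DEFAULT_TASKS, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[1] != N_VALUES:
            raise ValueError(
                f"frames must be n_frames x {N_VALUES}, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trial must contain at least one frame")
        if not np.all(np.isfinite(self.frames)):
            r, c = np.argwhere(~np.isfinite(self.frames))[0]
            raise ValueError(f"non-finite value at frame {r}, column {c}")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.task_label not in self.task_vocabulary:
            raise ValueError(
                f"task_label {self.task_label!r} not in vocabulary {self.task_vocabulary}"
            )
        self.coordinate_frame = CoordinateFrame(self.coordinate_frame)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def trial_id(self) -> str:
        """Stable identifier used for group-aware cross-validation."""
        return f"{self.subject_id}/{self.task_label}/{self.trial_index}"

    def with_frames(self, frames: np.ndarray, coordinate_frame=None) -> "TrialRecording":
        """Copy with replaced frame matrix (and optionally coordinate frame)."""
        cf = self.coordinate_frame if coordinate_frame is None else coordinate_frame
        return replace(self, frames=frames, coordinate_frame=cf)
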