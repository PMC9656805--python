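"""Coordinate normalization into the hand frame, and median filtering.

Expressing every joint in the palm-anchored hand coordinate system (HCS)
removes gross rigid-body hand motion and leaves only the grasp shape: per
frame, each position point ``p`` becomes ``A^-1 (p - C)`` where the columns
of ``A`` are the palm basis vectors in global coordinates and ``C`` is the
palm center.  Since ``A`` is orthonormal, the inverse is the transpose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from graspadl.hand_model import POSITION_SLOTS, _orthonormalize
from graspadl.trial import TrialRecording, CoordinateFrame

__all__ = ["RigidTransform", "apply_rigid_transform", "to_hcs", "median_filter_trial"]

_BASIS_SLOTS = (3, 6, 9)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-6:
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation matrix must have determinant +1 (no reflections)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def random(cls, rng: np.random.Generator, translation_scale: float = 100.0) -> "RigidTransform":
        """Haar-random rotation (QR of a Gaussian matrix) + Gaussian translation."""
        A = rng.standard_normal((3, 3))
        Q, R = np.linalg.qr(A)
        Q = Q * np.sign(np.diag(R))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        return cls(Q, rng.standard_normal(3) * translation_scale)


def _transform_row(row: np.ndarray, T: RigidTransform) -> np.ndarray:
    out = row.copy()
    R, t = T.rotation, T.translation
    for s in POSITION_SLOTS:
        out[s : s + 3] = R @ row[s : s + 3] + t
    for s in _BASIS_SLOTS:  # direction vectors rotate but do not translate
        out[s : s + 3] = R @ row[s : s + 3]
    return out


def apply_rigid_transform(
    trial: TrialRecording,
    T: RigidTransform | Sequence[RigidTransform],
) -> TrialRecording:
    """Apply a rigid transform (or one transform per frame) to a GCS trial.

    Position points map as ``x -> R x + t``; the palm basis vectors are
    directions and only rotate.
    """
    if trial.coordinate_frame is not CoordinateFrame.GCS:
        raise ValueError("rigid transforms apply to trials in GCS")
    if isinstance(T, RigidTransform):
        transforms: Sequence[RigidTransform] = [T] * trial.n_frames
    else:
        transforms = list(T)
        if len(transforms) != trial.n_frames:
            raise ValueError(
                f"got {len(transforms)} transforms for {trial.n_frames} frames"
            )
    frames = np.stack(
        [_transform_row(row, Ti) for row, Ti in zip(trial.frames, transforms)]
    )
    return trial.with_frames(frames)


def to_hcs(trial: TrialRecording) -> TrialRecording:
    """Change basis from GCS to the per-frame hand coordinate system.

    Per frame every position point ``p`` becomes ``A^T (p - C)`` (``A``
    re-orthonormalized; an exact linear solve is used as fallback if the
    stored basis needed a correction beyond 1e-6).  In the output the palm
    center is exactly zero and the basis block is exactly canonical.
    """
    if trial.coordinate_frame is not CoordinateFrame.HCS and trial.coordinate_frame is not CoordinateFrame.GCS:
        raise ValueError(f"unknown coordinate frame {trial.coordinate_frame}")
    if trial.coordinate_frame is CoordinateFrame.HCS:
        raise ValueError("trial is already in HCS")

    out = np.empty_like(trial.frames)
    for i, row in enumerate(trial.frames):
        C = row[0:3]
        h, n_vec, b = row[3:6], row[6:9], row[9:12]
        A = np.column_stack([h, n_vec, b])
        defect = np.max(np.abs(A.T @ A - np.eye(3)))
        if defect > 1e-6:
            try:
                h2, n2, b2 = _orthonormalize(h, n_vec)
            except ValueError as exc:
                raise ValueError(f"degenerate basis at frame {i}: {exc}") from exc
            A2 = np.column_stack([h2, n2, b2])
            if np.max(np.abs(A2 - A)) > 1e-3:
                # heavy correction: honor the stored (possibly skewed) basis
                # with an exact solve rather than the transpose shortcut
                inv = np.linalg.inv(A)
            else:
                inv = A2.T
        else:
            inv = A.T
        row_out = row.copy()
        for s in POSITION_SLOTS:
            row_out[s : s + 3] = inv @ (row[s : s + 3] - C)
        row_out[0:3] = 0.0
        row_out[3:6] = (1.0, 0.0, 0.0)
        row_out[6:9] = (0.0, 1.0, 0.0)
        row_out[9:12] = (0.0, 0.0, 1.0)
        out[i] = row_out
    return trial.with_frames(out, coordinate_frame=CoordinateFrame.HCS)


def median_filter_trial(trial: TrialRecording, window: int = 5) -> TrialRecording:
    """Centered running median over each of the 84 channels independently.

    At the boundaries the window shrinks symmetrically so only recorded
    samples enter the median (no fabricated padding).  Metadata is preserved.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    n = trial.n_frames
    if window > n:
        raise ValueError(f"window {window} exceeds trial length {n}")
    half = window // 2
    out = np.empty_like(trial.frames)
    for i in range(n):
        k = min(i, n - 1 - i, half)
        out[i] = np.median(trial.frames[i - k : i + k + 1], axis=0)
    return trial.with_frames(out)
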