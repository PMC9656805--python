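"""Synthetic hand-kinematics generator.

Produces tracking-style trials with the statistical structure the analysis
pipeline assumes: eight distinguishable grasp archetypes held quasi-statically,
a dynamic phase in which the whole hand follows a rigid trajectory, per-subject
hand-size scaling, small articulation jitter on the joint angles, and additive
sensor noise on the emitted coordinates.  The archetypes are hand-authored
conventions covering power and precision grasps; they are stand-ins, not
reconstructions of any participant's grasp.

The kinematic model is a serial chain per finger: a structural root offset
from the palm center in the palm plane, then successive unit-length directions
rotated by the abduction angle (about the palm normal) and curled by
cumulative flexion in a fixed curl plane; the thumb's curl plane is
additionally rotated about its chain axis by an opposition angle.  Every
emitted segment has exactly its configured length, and with all angles zero a
finger lies straight in the palm plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.spatial.transform import Rotation

from graspadl.hand_model import FINGERS, JOINTS_PER_FINGER, HandFrame, flatten_frame
from graspadl.trial import TrialRecording, CoordinateFrame
from graspadl.preprocess import RigidTransform

__all__ = [
    "GraspArchetype",
    "HandGeometry",
    "MotionProfile",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_GEOMETRY",
    "forward_kinematics",
    "generate_trial",
    "generate_dataset",
]

FLEXION_MAX = 0.7 * math.pi
ABDUCTION_MAX = math.pi / 6


@dataclass(frozen=True)
class GraspArchetype:
    """Joint-angle configuration of one synthetic grasp class (radians)."""

    task_name: str
    flexion: dict[str, tuple[float, float, float]]  # per finger: MCP, PIP, DIP roles
    abduction: dict[str, float]
    thumb_opposition: float = 0.0

    def __post_init__(self) -> None:
        for f in FINGERS:
            if f not in self.flexion or f not in self.abduction:
                raise ValueError(f"archetype {self.task_name!r} missing angles for {f}")
            for a in self.flexion[f]:
                if not 0.0 <= a <= FLEXION_MAX:
                    raise ValueError(
                        f"{self.task_name}/{f}: flexion {a:.3f} outside [0, {FLEXION_MAX:.3f}]"
                    )
            if not -ABDUCTION_MAX <= self.abduction[f] <= ABDUCTION_MAX:
                raise ValueError(f"{self.task_name}/{f}: abduction out of bounds")

    def jittered(self, rng: np.random.Generator, sd: float) -> "GraspArchetype":
        """Independent Gaussian jitter on every angle, clipped to bounds."""
        if sd == 0:
            return self
        flex = {
            f: tuple(
                float(np.clip(a + rng.normal(0, sd), 0.0, FLEXION_MAX))
                for a in self.flexion[f]
            )
            for f in FINGERS
        }
        abd = {
            f: float(np.clip(self.abduction[f] + rng.normal(0, sd), -ABDUCTION_MAX, ABDUCTION_MAX))
            for f in FINGERS
        }
        opp = float(self.thumb_opposition + rng.normal(0, sd))
        return GraspArchetype(self.task_name, flex, abd, opp)


#: default segment lengths (mm): palm-center-to-root, then successive bones,
#: matching the stored joint chain of each finger
_DEFAULT_SEGMENTS = {
    "thumb": (35.0, 45.0, 35.0, 30.0),
    "index": (25.0, 60.0, 40.0, 25.0, 20.0),
    "middle": (25.0, 62.0, 45.0, 28.0, 22.0),
    "ring": (25.0, 58.0, 42.0, 26.0, 20.0),
    "pinky": (28.0, 50.0, 32.0, 20.0, 18.0),
}

#: structural splay of each finger root in the palm plane (radians about n)
_DEFAULT_SPREAD = {"thumb": -0.9, "index": -0.22, "middle": 0.0, "ring": 0.2, "pinky": 0.42}


@dataclass(frozen=True)
class HandGeometry:
    """Per-finger segment lengths (mm) and root splay; ``scale`` multiplies
    every length (subject hand size)."""

    scale: float = 1.0
    segment_lengths: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_SEGMENTS)
    )
    spread_angles: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SPREAD))

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        for f in FINGERS:
            lengths = self.segment_lengths[f]
            if len(lengths) != len(JOINTS_PER_FINGER[f]):
                raise ValueError(f"{f}: expected {len(JOINTS_PER_FINGER[f])} segment lengths")
            if any(L <= 0 for L in lengths):
                raise ValueError(f"{f}: segment lengths must be positive")

    def lengths(self, finger: str) -> tuple[float, ...]:
        return tuple(L * self.scale for L in self.segment_lengths[finger])


DEFAULT_GEOMETRY = HandGeometry()


def _rot_about(axis: np.ndarray, angle: float) -> np.ndarray:
    return Rotation.from_rotvec(axis * angle).as_matrix()


def forward_kinematics(
    archetype: GraspArchetype,
    geom: HandGeometry = DEFAULT_GEOMETRY,
    pose: RigidTransform | None = None,
) -> HandFrame:
    """Place every joint of the configured grasp and move the hand by ``pose``.

    In the local frame the palm center is at the origin with basis
    h = e1 (finger direction), n = e3 (palm normal), b = h x n.
    """
    pose = pose or RigidTransform.identity()
    C = np.zeros(3)
    h = np.array([1.0, 0.0, 0.0])
    n = np.array([0.0, 0.0, 1.0])
    b = np.cross(h, n)

    joints: dict[str, dict[str, np.ndarray]] = {}
    for f in FINGERS:
        lengths = geom.lengths(f)
        spread = geom.spread_angles[f]
        abd = archetype.abduction[f]
        u_root = _rot_about(n, spread) @ h
        dir0 = _rot_about(n, spread + abd) @ h
        curl = n
        if f == "thumb" and archetype.thumb_opposition != 0.0:
            curl = _rot_about(dir0, archetype.thumb_opposition) @ n

        names = JOINTS_PER_FINGER[f]
        pts = [C + lengths[0] * u_root]  # structural root (CMC)
        if f == "thumb":
            flex_per_segment = archetype.flexion[f]  # three segments after CMC
        else:
            pts.append(pts[-1] + lengths[1] * dir0)  # metacarpal, unflexed
            flex_per_segment = archetype.flexion[f]
        phi = 0.0
        seg_lengths = lengths[1:] if f == "thumb" else lengths[2:]
        for L, theta in zip(seg_lengths, flex_per_segment):
            phi += theta
            d = math.cos(phi) * dir0 - math.sin(phi) * curl
            pts.append(pts[-1] + L * d)
        joints[f] = {name: p for name, p in zip(names, pts)}

    R, t = pose.rotation, pose.translation
    frame = HandFrame(
        palm_center=R @ C + t,
        h=R @ h,
        n_vec=R @ n,
        b=R @ b,
        joints={f: {j: R @ p + t for j, p in joints[f].items()} for f in joints},
    )
    return frame


@dataclass(frozen=True)
class MotionProfile:
    """Static/dynamic phase layout, noise levels, and the gross trajectory.

    ``trajectory`` maps a phase fraction u in [0, 1] to a rigid transform; if
    None, a smooth default (sinusoidal rotation + looping translation) is
    drawn per trial.  ``dynamic_duration`` is the length of one repetition.
    """

    articulation_jitter_sd: float = 0.02  # radians
    sensor_noise_sd: float = 0.5  # mm
    fps: float = 30.0
    static_duration: float = 10.0  # s
    dynamic_duration: float = 1.0  # s per repetition
    repetitions: int = 5
    rotation_amplitude: float = 0.6  # rad, default trajectory
    translation_amplitude: float = 120.0  # mm, default trajectory
    trajectory: Callable[[float], RigidTransform] | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.static_duration < 0 or self.dynamic_duration < 0 or self.repetitions < 0:
            raise ValueError("durations and repetitions must be non-negative")
        if self.articulation_jitter_sd < 0 or self.sensor_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")


def _default_trajectory(profile: MotionProfile, rng: np.random.Generator):
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    phase = rng.uniform(0, 2 * math.pi)

    def traj(u: float) -> RigidTransform:
        angle = profile.rotation_amplitude * math.sin(2 * math.pi * u + phase)
        t = profile.translation_amplitude * math.sin(math.pi * u) * direction
        return RigidTransform(Rotation.from_rotvec(axis * angle).as_matrix(), t)

    return traj


def generate_trial(
    archetype: GraspArchetype,
    geom: HandGeometry,
    profile: MotionProfile,
    seed: int,
    task_label: str | None = None,
    subject_id: str = "S0",
    trial_index: int = 0,
) -> TrialRecording:
    """Simulate one trial in GCS: a static hold followed by repeated gross
    motion, with articulation jitter on the angles and sensor noise on the
    emitted position coordinates (the palm basis stays exactly orthonormal).

    Fully deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_static = round(profile.static_duration * profile.fps)
    n_dyn = round(profile.dynamic_duration * profile.fps)
    total = n_static + n_dyn * profile.repetitions
    if total < 1:
        raise ValueError("profile produces zero frames (no static phase, no repetitions)")

    traj = profile.trajectory or _default_trajectory(profile, rng)
    poses = [traj(0.0)] * n_static
    for _ in range(profile.repetitions):
        poses.extend(traj(i / n_dyn) for i in range(n_dyn))

    from graspadl.hand_model import POSITION_SLOTS  # local to avoid cycle at import

    rows = np.empty((total, 84))
    for i, pose in enumerate(poses):
        jit = archetype.jittered(rng, profile.articulation_jitter_sd)
        row = flatten_frame(forward_kinematics(jit, geom, pose))
        if profile.sensor_noise_sd > 0:
            for s in POSITION_SLOTS:
                row[s : s + 3] += rng.normal(0, profile.sensor_noise_sd, size=3)
        rows[i] = row
    return TrialRecording(
        frames=rows,
        task_label=task_label or archetype.task_name,
        subject_id=subject_id,
        trial_index=trial_index,
        fps=profile.fps,
        coordinate_frame=CoordinateFrame.GCS,
    )


def _archetype(task, flex, abd_spread, opp):
    flexion = {f: flex[f] for f in FINGERS}
    abduction = {f: abd_spread[f] for f in FINGERS}
    return GraspArchetype(task, flexion, abduction, opp)


def _flex(thumb, index, middle, ring, pinky):
    return dict(zip(FINGERS, (thumb, index, middle, ring, pinky)))


def _abd(thumb=0.0, index=0.0, middle=0.0, ring=0.0, pinky=0.0):
    return dict(zip(FINGERS, (thumb, index, middle, ring, pinky)))


#: hand-authored grasp archetypes for the eight ADL tasks (power and
#: precision grasps with distinct flexion/abduction signatures)
DEFAULT_ARCHETYPES: dict[str, GraspArchetype] = {
    "cup": _archetype(
        "cup",
        _flex((0.35, 0.40, 0.25), (0.55, 0.65, 0.35), (0.55, 0.65, 0.35), (0.60, 0.70, 0.40), (0.65, 0.75, 0.45)),
        _abd(thumb=-0.15, index=-0.08, ring=0.08, pinky=0.15),
        0.55,
    ),
    "fork": _archetype(
        "fork",
        _flex((0.50, 0.45, 0.30), (0.85, 0.95, 0.55), (0.90, 1.00, 0.60), (1.20, 1.30, 0.85), (1.30, 1.40, 0.90)),
        _abd(thumb=-0.10, index=-0.05),
        0.85,
    ),
    "key": _archetype(
        "key",
        _flex((0.20, 0.25, 0.15), (1.45, 1.55, 1.00), (1.50, 1.60, 1.05), (1.55, 1.65, 1.05), (1.55, 1.65, 1.10)),
        _abd(thumb=-0.05),
        0.20,
    ),
    "knife": _archetype(
        "knife",
        _flex((0.70, 0.60, 0.40), (1.05, 1.20, 0.75), (1.10, 1.25, 0.80), (1.10, 1.25, 0.80), (1.15, 1.30, 0.85)),
        _abd(),
        0.80,
    ),
    "nail clipper": _archetype(
        "nail clipper",
        _flex((0.55, 0.50, 0.30), (0.90, 1.00, 0.60), (1.35, 1.45, 0.95), (1.45, 1.55, 1.00), (1.50, 1.60, 1.05)),
        _abd(index=-0.12),
        1.05,
    ),
    "pen": _archetype(
        "pen",
        _flex((0.65, 0.50, 0.30), (0.75, 0.60, 0.35), (0.80, 0.65, 0.40), (1.55, 1.60, 1.05), (1.60, 1.65, 1.10)),
        _abd(thumb=-0.20, index=-0.10),
        0.95,
    ),
    "spherical doorknob": _archetype(
        "spherical doorknob",
        _flex((0.45, 0.45, 0.30), (0.60, 0.55, 0.35), (0.60, 0.55, 0.35), (0.60, 0.55, 0.35), (0.65, 0.60, 0.40)),
        _abd(thumb=-0.30, index=-0.25, middle=-0.05, ring=0.20, pinky=0.40),
        0.70,
    ),
    "spoon": _archetype(
        "spoon",
        _flex((0.45, 0.40, 0.25), (0.95, 0.75, 0.45), (1.00, 0.80, 0.50), (1.05, 0.85, 0.50), (1.40, 1.50, 0.95)),
        _abd(index=0.05, middle=0.10),
        0.60,
    ),
}


def generate_dataset(
    archetypes: dict[str, GraspArchetype] | None = None,
    n_subjects: int = 6,
    trials_per_task: int = 2,
    profile: MotionProfile = MotionProfile(),
    seed: int = 0,
    scale_range: tuple[float, float] = (0.85, 1.15),
) -> tuple[list[TrialRecording], set[str], dict]:
    """Generate a full multi-subject dataset.

    Per subject: one sampled hand scale, ``trials_per_task`` trials per task,
    and the subject's first "cup" trial flagged as the calibration trial for
    hand-length computation.  Per-trial seeds are derived from the master
    seed via ``numpy.random.SeedSequence`` so generation is reproducible and
    order-independent.

    Returns ``(trials, calibration_trial_ids, metadata)``.
    """
    archetypes = archetypes or DEFAULT_ARCHETYPES
    if len(archetypes) < 8:
        raise ValueError(f"need at least 8 archetypes, got {len(archetypes)}")
    tasks = list(archetypes)
    master = np.random.SeedSequence(seed)
    scale_rng = np.random.default_rng(master.spawn(1)[0])

    trials: list[TrialRecording] = []
    calibration: set[str] = set()
    scales: dict[str, float] = {}
    for si in range(n_subjects):
        subject = f"S{si:02d}"
        scale = float(scale_rng.uniform(*scale_range))
        scales[subject] = scale
        geom = replace(DEFAULT_GEOMETRY, scale=scale)
        for ti, task in enumerate(tasks):
            for k in range(trials_per_task):
                trial_seed = int(
                    np.random.SeedSequence([seed, si, ti, k]).generate_state(1)[0]
                )
                t = generate_trial(
                    archetypes[task],
                    geom,
                    profile,
                    seed=trial_seed,
                    subject_id=subject,
                    trial_index=k,
                )
                trials.append(t)
                if task == "cup" and k == 0:
                    calibration.add(t.trial_id)
    metadata = {
        "seed": seed,
        "n_subjects": n_subjects,
        "trials_per_task": trials_per_task,
        "tasks": tasks,
        "subject_scales": scales,
        "profile": {
            "articulation_jitter_sd": profile.articulation_jitter_sd,
            "sensor_noise_sd": profile.sensor_noise_sd,
            "fps": profile.fps,
            "static_duration": profile.static_duration,
            "dynamic_duration": profile.dynamic_duration,
            "repetitions": profile.repetitions,
        },
    }
    return trials, calibration, metadata
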