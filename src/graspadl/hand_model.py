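"""Structured hand data model and the flat 84-value frame layout.

A single tracking frame carries 28 three-dimensional quantities (84 scalar
values, millimeters): the palm center, three orthonormal palm basis vectors,
and the finger joint positions.  The flat layout, version ``1``, is::

    slot  0:3    palm center C
    slot  3:6    h      (finger direction, unit)
    slot  6:9    n_vec  (palm normal, unit)
    slot  9:12   b      (h x n_vec, unit)
    slot 12:24   thumb:  CMC, MCP, DIP, tip            (4 points)
    slot 24:39   index:  CMC, MCP, PIP, DIP, tip       (5 points)
    slot 39:54   middle: CMC, MCP, PIP, DIP, tip
    slot 54:69   ring:   CMC, MCP, PIP, DIP, tip
    slot 69:84   pinky:  CMC, MCP, PIP, DIP, tip

The thumb has no intermediate phalanx, so it carries four points; its
CMC/MCP/DIP/tip are mapped onto the MCP/PIP/DIP/tip *roles* so that every
joint-angle and fingertip formula applies uniformly across the five fingers.
The non-thumb fingers additionally carry the metacarpal root (CMC), which is
part of the tracked skeleton but is not used by any feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FINGERS",
    "JOINTS_PER_FINGER",
    "LAYOUT_VERSION",
    "DEFAULT_TASKS",
    "TaskVocabulary",
    "HandFrame",
    "structure_frame",
    "flatten_frame",
    "identity_basis_row",
]

LAYOUT_VERSION = "1"

FINGERS = ("thumb", "index", "middle", "ring", "pinky")

#: stored joint names per finger, in layout order
JOINTS_PER_FINGER = {
    "thumb": ("cmc", "mcp", "dip", "tip"),
    "index": ("cmc", "mcp", "pip", "dip", "tip"),
    "middle": ("cmc", "mcp", "pip", "dip", "tip"),
    "ring": ("cmc", "mcp", "pip", "dip", "tip"),
    "pinky": ("cmc", "mcp", "pip", "dip", "tip"),
}

#: mapping of stored joints onto the four feature roles (mcp, pip, dip, tip)
ROLE_JOINTS = {
    "thumb": ("cmc", "mcp", "dip", "tip"),
    "index": ("mcp", "pip", "dip", "tip"),
    "middle": ("mcp", "pip", "dip", "tip"),
    "ring": ("mcp", "pip", "dip", "tip"),
    "pinky": ("mcp", "pip", "dip", "tip"),
}

N_VALUES = 84

# slot offsets (start index of each 3-vector), derived once from the layout
_SLOTS: dict[str, int] = {"C": 0, "h": 3, "n_vec": 6, "b": 9}
_off = 12
for _f in FINGERS:
    for _j in JOINTS_PER_FINGER[_f]:
        _SLOTS[f"{_f}.{_j}"] = _off
        _off += 3
assert _off == N_VALUES

DEFAULT_TASKS = (
    "cup",
    "fork",
    "key",
    "knife",
    "nail clipper",
    "pen",
    "spherical doorknob",
    "spoon",
)


@dataclass(frozen=True)
class TaskVocabulary:
    """Ordered vocabulary of the eight ADL task names, indices 0-7."""

    tasks: tuple[str, ...] = DEFAULT_TASKS

    def __post_init__(self) -> None:
        if len(self.tasks) != 8:
            raise ValueError(f"task vocabulary must have exactly 8 entries, got {len(self.tasks)}")
        if len(set(self.tasks)) != 8:
            raise ValueError("task names must be unique")

    def index(self, task: str) -> int:
        try:
            return self.tasks.index(task)
        except ValueError:
            raise KeyError(f"unknown task {task!r}; vocabulary: {self.tasks}") from None

    def __contains__(self, task: str) -> bool:
        return task in self.tasks

    def __iter__(self):
        return iter(self.tasks)

    def __len__(self) -> int:
        return 8


@dataclass
class HandFrame:
    """One structured tracking frame.

    ``joints[finger][joint]`` holds the stored joint positions; use
    :meth:`role_joints` to obtain the (mcp, pip, dip, tip) role tuple that
    the feature formulas index, with the thumb's stored joints shifted one
    role proximally.
    """

    palm_center: np.ndarray
    h: np.ndarray
    n_vec: np.ndarray
    b: np.ndarray
    joints: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def role_joints(self, finger: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Positions filling the (mcp, pip, dip, tip) roles for ``finger``."""
        names = ROLE_JOINTS[finger]
        jf = self.joints[finger]
        return tuple(jf[n] for n in names)  # type: ignore[return-value]

    def fingertip(self, finger: str) -> np.ndarray:
        return self.joints[finger]["tip"]

    def basis_matrix(self) -> np.ndarray:
        """3x3 change-of-basis matrix with columns (h, n_vec, b)."""
        return np.column_stack([self.h, self.n_vec, self.b])


def _orthonormalize(h: np.ndarray, n_vec: np.ndarray, warn_tol: float = 1e-3):
    """Gram-Schmidt repair of the stored basis (h kept, n_vec projected,
    b recomputed as h x n_vec).  Warns if the correction is large."""
    nh = np.linalg.norm(h)
    if nh < 1e-12:
        raise ValueError("degenerate basis: h has zero norm")
    h2 = h / nh
    n2 = n_vec - (n_vec @ h2) * h2
    nn = np.linalg.norm(n2)
    if nn < 1e-12:
        raise ValueError("degenerate basis: n_vec parallel to h")
    n2 = n2 / nn
    b2 = np.cross(h2, n2)
    return h2, n2, b2


def structure_frame(row: np.ndarray) -> HandFrame:
    """Structure an 84-vector into a :class:`HandFrame`.

    The stored basis is checked for orthonormality; deviations beyond 1e-6
    are repaired by projection with a warning (loud failure above 1e-3 is
    left to the caller via the warning filter).
    """
    row = np.asarray(row, dtype=float)
    if row.shape != (N_VALUES,):
        raise ValueError(f"frame row must have {N_VALUES} values, got shape {row.shape}")
    if not np.all(np.isfinite(row)):
        bad = int(np.flatnonzero(~np.isfinite(row))[0])
        raise ValueError(f"non-finite value at position {bad}")

    h = row[3:6].copy()
    n_vec = row[6:9].copy()
    b = row[9:12].copy()
    err = max(
        abs(np.linalg.norm(h) - 1.0),
        abs(np.linalg.norm(n_vec) - 1.0),
        abs(float(h @ n_vec)),
        float(np.max(np.abs(np.cross(h, n_vec) - b))) if np.linalg.norm(b) > 0 else np.inf,
    )
    if err > 1e-6:
        h2, n2, b2 = _orthonormalize(h, n_vec)
        correction = max(
            float(np.max(np.abs(h2 - h))),
            float(np.max(np.abs(n2 - n_vec))),
            float(np.max(np.abs(b2 - b))),
        )
        if correction > 1e-3:
            warnings.warn(
                f"stored basis deviates from orthonormality by {correction:.2e}; re-orthonormalized",
                stacklevel=2,
            )
        h, n_vec, b = h2, n2, b2

    joints: dict[str, dict[str, np.ndarray]] = {}
    for f in FINGERS:
        joints[f] = {}
        for j in JOINTS_PER_FINGER[f]:
            s = _SLOTS[f"{f}.{j}"]
            joints[f][j] = row[s : s + 3].copy()
    return HandFrame(palm_center=row[0:3].copy(), h=h, n_vec=n_vec, b=b, joints=joints)


def flatten_frame(frame: HandFrame) -> np.ndarray:
    """Flatten a :class:`HandFrame` back to the 84-value layout."""
    row = np.empty(N_VALUES, dtype=float)
    row[0:3] = frame.palm_center
    row[3:6] = frame.h
    row[6:9] = frame.n_vec
    row[9:12] = frame.b
    for f in FINGERS:
        for j in JOINTS_PER_FINGER[f]:
            s = _SLOTS[f"{f}.{j}"]
            row[s : s + 3] = frame.joints[f][j]
    return row


def identity_basis_row() -> np.ndarray:
    """An all-zero frame row with the canonical basis (e1, e2, e3) filled in."""
    row = np.zeros(N_VALUES)
    row[3:6] = (1.0, 0.0, 0.0)
    row[6:9] = (0.0, 1.0, 0.0)
    row[9:12] = (0.0, 0.0, 1.0)
    return row


#: column indices of the position-valued channels (everything but the basis)
POSITION_SLOTS = tuple(
    s for name, s in _SLOTS.items() if name not in ("h", "n_vec", "b")
)

#: column indices of the 72 joint-coordinate channels (positions minus palm
#: center and basis) — the channels carried forward by windowed features in HCS
JOINT_CHANNELS = tuple(
    i for name, s in _SLOTS.items() if name not in ("C", "h", "n_vec", "b") for i in range(s, s + 3)
)
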