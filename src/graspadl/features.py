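"""Grasp feature bank: hand-length normalizer, geometric per-frame features,
windowed time-domain features, windowed DFT magnitudes, and feature-matrix
assembly / standardization.

Conventions shared by all feature formulas:

* angles are normalized to [0, 1] by dividing by pi;
* distances are normalized by the subject's hand length ``M`` (the summed
  palm-center-to-middle-fingertip segment lengths, averaged over the first
  second of the subject's calibration trial);
* per-frame geometric features produce one sample per frame, windowed
  features one sample per complete non-overlapping window (default 15
  frames = 0.5 s at 30 fps), trailing partial windows dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from graspadl.hand_model import (
    FINGERS,
    JOINTS_PER_FINGER,
    JOINT_CHANNELS,
    HandFrame,
    structure_frame,
    TaskVocabulary,
)
from graspadl.trial import TrialRecording, CoordinateFrame

__all__ = [
    "FeatureError",
    "HandLengthM",
    "FeatureBlock",
    "FeatureMatrix",
    "hand_length",
    "afa",
    "atd",
    "dpuv",
    "nptd",
    "ja",
    "fha",
    "fte",
    "geometric_features",
    "windowed_td_features",
    "dft_features",
    "assemble",
    "standardize",
    "build_feature_matrix",
    "GEOMETRIC_FEATURES",
    "WINDOWED_FEATURES",
]

ADJACENT_PAIRS = (("thumb", "index"), ("index", "middle"), ("middle", "ring"), ("ring", "pinky"))

GEOMETRIC_FEATURES = ("AFA", "ATD", "DPUV", "NPTD", "JA", "FHA", "FTE")
WINDOWED_FEATURES = ("MAV", "RMS", "VAR", "WL", "DFT")

#: human-readable names of the 72 joint coordinate channels, layout order
JOINT_CHANNEL_NAMES = tuple(
    f"{f}.{j}.{ax}"
    for f in FINGERS
    for j in JOINTS_PER_FINGER[f]
    for ax in "xyz"
)


class FeatureError(ValueError):
    """Degenerate geometry made a feature undefined (zero-length vector)."""


@dataclass(frozen=True)
class HandLengthM:
    """Hand-length normalizer (mm), from a designated calibration trial."""

    M: float
    subject_id: str = ""
    source: str = ""
    n_frames_averaged: int = 30

    def __post_init__(self) -> None:
        if not self.M > 0:
            raise ValueError(f"hand length M must be positive, got {self.M}")

    def __float__(self) -> float:
        return self.M


@dataclass
class FeatureBlock:
    """Named block of feature columns for one trial."""

    name: str
    values: np.ndarray  # n_samples x m
    column_names: tuple[str, ...]
    sample_rate_kind: str  # "per_frame" | "per_window"
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column_names length must match value columns")
        if np.isnan(self.values).any():
            raise ValueError(f"feature block {self.name} contains NaN")
        if self.sample_rate_kind not in ("per_frame", "per_window"):
            raise ValueError(f"bad sample_rate_kind {self.sample_rate_kind!r}")


@dataclass
class FeatureMatrix:
    """Sample-aligned classification matrix with labels and trial groups."""

    values: np.ndarray  # n_samples x m_total
    labels: np.ndarray  # n_samples int class indices
    groups: np.ndarray  # n_samples trial-id strings
    column_names: tuple[str, ...]
    standardization: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.groups = np.asarray(self.groups)
        n = self.values.shape[0]
        if not (len(self.labels) == len(self.groups) == n):
            raise ValueError("values, labels and groups must have equal row counts")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column_names length must match value columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# hand length


def hand_length(calibration_trial: TrialRecording, n_frames: int = 30) -> HandLengthM:
    """Hand length ``M``: summed middle-finger chain lengths, averaged over
    the first ``n_frames`` frames of the calibration trial.

    Per frame the chain is palm center -> MCP -> PIP -> DIP -> fingertip of
    the middle finger; ``M`` is the mean of the four-segment sum.
    """
    if calibration_trial.n_frames < n_frames:
        raise ValueError(
            f"calibration trial has {calibration_trial.n_frames} frames, "
            f"need at least {n_frames}"
        )
    per_frame = np.empty(n_frames)
    for i in range(n_frames):
        frame = structure_frame(calibration_trial.frames[i])
        mcp, pip_, dip, tip = frame.role_joints("middle")
        chain = (frame.palm_center, mcp, pip_, dip, tip)
        per_frame[i] = sum(
            float(np.linalg.norm(b - a)) for a, b in zip(chain[:-1], chain[1:])
        )
    return HandLengthM(
        M=float(per_frame.mean()),
        subject_id=calibration_trial.subject_id,
        source=calibration_trial.trial_id,
        n_frames_averaged=n_frames,
    )


# ---------------------------------------------------------------------------
# per-frame geometric features


def _angle(u: np.ndarray, v: np.ndarray, what: str) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise FeatureError(f"zero-length vector in {what}")
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def afa(frame: HandFrame) -> np.ndarray:
    """Adjacent fingertip angles: angle between palm-center-to-fingertip
    vectors of the four adjacent finger pairs, divided by pi."""
    C = frame.palm_center
    out = np.empty(4)
    for k, (fa, fb) in enumerate(ADJACENT_PAIRS):
        out[k] = _angle(frame.fingertip(fa) - C, frame.fingertip(fb) - C, f"AFA[{fa}-{fb}]") / np.pi
    return out


def atd(frame: HandFrame, M: HandLengthM) -> np.ndarray:
    """Adjacent fingertip distances, normalized by M."""
    out = np.empty(4)
    for k, (fa, fb) in enumerate(ADJACENT_PAIRS):
        out[k] = np.linalg.norm(frame.fingertip(fa) - frame.fingertip(fb)) / M.M
    return out


def dpuv(frame: HandFrame) -> np.ndarray:
    """Distal phalanx unit vectors: (tip - DIP) / ||tip - DIP|| per finger."""
    out = np.empty(15)
    for k, f in enumerate(FINGERS):
        _, _, dip, tip = frame.role_joints(f)
        v = tip - dip
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise FeatureError(f"fingertip coincides with DIP joint on {f}")
        out[3 * k : 3 * k + 3] = v / n
    return out


def nptd(frame: HandFrame, M: HandLengthM) -> np.ndarray:
    """Palm-center-to-fingertip distances, normalized by M."""
    return np.array(
        [np.linalg.norm(frame.fingertip(f) - frame.palm_center) / M.M for f in FINGERS]
    )


def ja(frame: HandFrame) -> np.ndarray:
    """Joint angles at the MCP/PIP/DIP roles of each finger, divided by pi.

    The bone proximal to the MCP role is taken as (MCP - palm center); the
    thumb's stored CMC/MCP/DIP/tip fill the four roles.
    """
    out = np.empty(15)
    for k, f in enumerate(FINGERS):
        mcp, pip_, dip, tip = frame.role_joints(f)
        bones = (mcp - frame.palm_center, pip_ - mcp, dip - pip_, tip - dip)
        names = ("MCP", "PIP", "DIP")
        for j in range(3):
            out[3 * k + j] = _angle(bones[j], bones[j + 1], f"JA[{f}.{names[j]}]") / np.pi
    return out


def _project_to_palm_plane(p: np.ndarray, frame: HandFrame) -> np.ndarray:
    d = float(np.dot(p - frame.palm_center, frame.n_vec))
    return p - d * frame.n_vec


def fha(frame: HandFrame) -> np.ndarray:
    """Angle between h and the palm-plane projection of each fingertip
    (taken from the palm center), divided by pi."""
    out = np.empty(5)
    for k, f in enumerate(FINGERS):
        fp = _project_to_palm_plane(frame.fingertip(f), frame)
        out[k] = _angle(fp - frame.palm_center, frame.h, f"FHA[{f}]") / np.pi
    return out


def fte(frame: HandFrame, M: HandLengthM) -> np.ndarray:
    """Signed fingertip elevation above the palm plane, normalized by M."""
    out = np.empty(5)
    for k, f in enumerate(FINGERS):
        tip = frame.fingertip(f)
        fp = _project_to_palm_plane(tip, frame)
        d = tip - fp
        sign = np.sign(float(np.dot(d, frame.n_vec)))
        out[k] = sign * float(np.linalg.norm(d)) / M.M
    return out


_PAIR_NAMES = tuple(f"{a}-{b}" for a, b in ADJACENT_PAIRS)

_GEOM_COLUMNS = {
    "AFA": _PAIR_NAMES,
    "ATD": _PAIR_NAMES,
    "DPUV": tuple(f"{f}.{ax}" for f in FINGERS for ax in "xyz"),
    "NPTD": FINGERS,
    "JA": tuple(f"{f}.{j}" for f in FINGERS for j in ("MCP", "PIP", "DIP")),
    "FHA": FINGERS,
    "FTE": FINGERS,
}

_GEOM_FUNCS = {
    "AFA": lambda fr, M: afa(fr),
    "ATD": lambda fr, M: atd(fr, M),
    "DPUV": lambda fr, M: dpuv(fr),
    "NPTD": lambda fr, M: nptd(fr, M),
    "JA": lambda fr, M: ja(fr),
    "FHA": lambda fr, M: fha(fr),
    "FTE": lambda fr, M: fte(fr, M),
}


def geometric_features(
    trial: TrialRecording,
    M: HandLengthM,
    names: tuple[str, ...] = GEOMETRIC_FEATURES,
) -> dict[str, FeatureBlock]:
    """Per-frame geometric feature blocks for one (HCS, filtered) trial."""
    unknown = set(names) - set(GEOMETRIC_FEATURES)
    if unknown:
        raise ValueError(f"unknown geometric features {sorted(unknown)}")
    rows: dict[str, list[np.ndarray]] = {n: [] for n in names}
    for raw in trial.frames:
        frame = structure_frame(raw)
        for n in names:
            rows[n].append(_GEOM_FUNCS[n](frame, M))
    return {
        n: FeatureBlock(
            name=n,
            values=np.vstack(rows[n]),
            column_names=tuple(f"{n}[{c}]" for c in _GEOM_COLUMNS[n]),
            sample_rate_kind="per_frame",
            trial_id=trial.trial_id,
        )
        for n in names
    }


# ---------------------------------------------------------------------------
# windowed time-domain and frequency-domain features


def _windows(x: np.ndarray, window: int) -> np.ndarray:
    """Split (n, c) into complete non-overlapping (n_win, window, c) blocks."""
    n = x.shape[0]
    n_win = n // window
    if n_win == 0:
        raise ValueError(f"trial has {n} frames, need at least {window} for one window")
    return x[: n_win * window].reshape(n_win, window, x.shape[1])


def _joint_channel_matrix(trial: TrialRecording) -> np.ndarray:
    if trial.coordinate_frame is not CoordinateFrame.HCS:
        raise ValueError("windowed features are defined on trials in HCS")
    return trial.frames[:, list(JOINT_CHANNELS)]


def windowed_td_features(
    trial: TrialRecording,
    M: HandLengthM,
    window: int = 15,
) -> dict[str, FeatureBlock]:
    """MAV/RMS/VAR/WL over non-overlapping windows of the 72 M-normalized
    joint coordinate channels (palm center and basis are constant in HCS
    and carry no signal, so they are dropped).

    Per window of N frames and channel x: MAV = mean|x|, RMS = sqrt(mean x^2),
    VAR = sum((x - mean x)^2) / (N - 1), WL = sum|x[n+1] - x[n]|.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    x = _joint_channel_matrix(trial) / M.M
    w = _windows(x, window)  # (n_win, window, 72)
    mav = np.mean(np.abs(w), axis=1)
    rms = np.sqrt(np.mean(w**2, axis=1))
    var = np.var(w, axis=1, ddof=1)
    wl = np.sum(np.abs(np.diff(w, axis=1)), axis=1)
    out = {}
    for name, vals in (("MAV", mav), ("RMS", rms), ("VAR", var), ("WL", wl)):
        out[name] = FeatureBlock(
            name=name,
            values=vals,
            column_names=tuple(f"{name}[{c}]" for c in JOINT_CHANNEL_NAMES),
            sample_rate_kind="per_window",
            trial_id=trial.trial_id,
        )
    return out


def dft_features(
    trial: TrialRecording,
    window: int = 15,
    kept_bins: int = 8,
) -> FeatureBlock:
    """DFT magnitude features: |X[k]|, k = 0..kept_bins-1, per channel per
    non-overlapping window.  Real input makes bins above N/2 redundant, so
    only the leading bins are kept."""
    if kept_bins < 1 or kept_bins > window:
        raise ValueError(f"kept_bins must be in [1, window], got {kept_bins}")
    x = _joint_channel_matrix(trial)
    w = _windows(x, window)  # (n_win, window, c)
    spectra = np.abs(np.fft.fft(w, axis=1))[:, :kept_bins, :]  # (n_win, k, c)
    n_win = w.shape[0]
    # column order: channel-major, bin-minor
    values = np.transpose(spectra, (0, 2, 1)).reshape(n_win, -1)
    cols = tuple(f"DFT[{c}|k={k}]" for c in JOINT_CHANNEL_NAMES for k in range(kept_bins))
    return FeatureBlock(
        name="DFT",
        values=values,
        column_names=cols,
        sample_rate_kind="per_window",
        trial_id=trial.trial_id,
    )


# ---------------------------------------------------------------------------
# assembly and standardization


def _window_mean(values: np.ndarray, window: int) -> np.ndarray:
    n_win = values.shape[0] // window
    if n_win == 0:
        raise ValueError("not enough per-frame rows for one window")
    return values[: n_win * window].reshape(n_win, window, -1).mean(axis=1)


def assemble(
    blocks: list[FeatureBlock],
    labels: np.ndarray,
    groups: np.ndarray,
    window: int = 15,
) -> FeatureMatrix:
    """Column-concatenate feature blocks of one trial into sample rows.

    Blocks must describe the same trial.  If per-frame and per-window blocks
    are mixed, per-frame blocks are averaged within each complete window so
    every block contributes one row per window.  ``labels``/``groups`` must
    match the resulting row count (scalars are broadcast).
    """
    if not blocks:
        raise ValueError("no feature blocks given")
    tids = {b.trial_id for b in blocks}
    if len(tids) > 1:
        raise ValueError(f"blocks from different trials cannot be assembled: {sorted(tids)}")
    kinds = {b.sample_rate_kind for b in blocks}
    if kinds == {"per_frame"}:
        mats = [b.values for b in blocks]
    else:
        # reconcile to per-window rows
        mats = [
            _window_mean(b.values, window) if b.sample_rate_kind == "per_frame" else b.values
            for b in blocks
        ]
    n_rows = {m.shape[0] for m in mats}
    if len(n_rows) > 1:
        detail = ", ".join(f"{b.name}:{m.shape[0]}" for b, m in zip(blocks, mats))
        raise ValueError(f"feature blocks have irreconcilable row counts ({detail})")
    n = n_rows.pop()
    labels = np.broadcast_to(np.asarray(labels), (n,)).copy()
    groups = np.broadcast_to(np.asarray(groups), (n,)).copy()
    return FeatureMatrix(
        values=np.hstack(mats),
        labels=labels,
        groups=groups,
        column_names=tuple(c for b in blocks for c in b.column_names),
    )


def standardize(fm: FeatureMatrix, fit_rows: np.ndarray | None = None) -> FeatureMatrix:
    """Zero-mean unit-variance columns, fitted on ``fit_rows`` (default all)
    and applied to every row.  Zero-variance columns become all-zeros with a
    warning.  Fitted (mean, sd) are stored on the result."""
    fit = fm.values if fit_rows is None else fm.values[fit_rows]
    if fit.shape[0] < 2:
        raise ValueError("need at least two fitting rows to standardize")
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=1)
    degenerate = sd < 1e-12
    if degenerate.any():
        names = [fm.column_names[i] for i in np.flatnonzero(degenerate)[:5]]
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance column(s) set to zero (e.g. {names})",
            stacklevel=2,
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    values = (fm.values - mean) / safe_sd
    values[:, degenerate] = 0.0
    return replace(fm, values=values, standardization=(mean, sd))


# ---------------------------------------------------------------------------
# dataset-level pipeline helper


def build_feature_matrix(
    trials: list[TrialRecording],
    hand_lengths: dict[str, HandLengthM],
    features: tuple[str, ...],
    window: int = 15,
    dft_bins: int = 8,
    vocabulary: TaskVocabulary | None = None,
) -> FeatureMatrix:
    """Compute the requested feature blocks for every (HCS, filtered) trial
    and stack them into one labeled classification matrix.

    ``hand_lengths`` maps subject id to that subject's calibration-derived M.
    """
    vocab = vocabulary or TaskVocabulary()
    geo = tuple(f for f in features if f in GEOMETRIC_FEATURES)
    win = tuple(f for f in features if f in WINDOWED_FEATURES)
    unknown = set(features) - set(GEOMETRIC_FEATURES) - set(WINDOWED_FEATURES)
    if unknown:
        raise ValueError(f"unknown features {sorted(unknown)}")
    per_trial: list[FeatureMatrix] = []
    for t in trials:
        M = hand_lengths[t.subject_id]
        blocks: list[FeatureBlock] = []
        if geo:
            gb = geometric_features(t, M, geo)
            blocks.extend(gb[n] for n in geo)
        for name in win:
            if name == "DFT":
                blocks.append(dft_features(t, window=window, kept_bins=dft_bins))
            else:
                blocks.append(windowed_td_features(t, M, window=window)[name])
        per_trial.append(
            assemble(blocks, labels=vocab.index(t.task_label), groups=t.trial_id, window=window)
        )
    cols = per_trial[0].column_names
    for fmat in per_trial[1:]:
        if fmat.column_names != cols:
            raise ValueError("trials produced inconsistent feature columns")
    return FeatureMatrix(
        values=np.vstack([f.values for f in per_trial]),
        labels=np.concatenate([f.labels for f in per_trial]),
        groups=np.concatenate([f.groups for f in per_trial]),
        column_names=cols,
    )
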