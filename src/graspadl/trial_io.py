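"""Plain-text on-disk trial format and multi-trial bundles.

A trial file is comma-separated text: a header block of ``# key=value`` lines
(subject_id, task_label, trial_index, fps, coordinate_frame, layout_version)
followed by one row of 84 numeric columns per frame.  Values are written with
17 significant digits so round-trips are bit-exact for doubles.

A *bundle* is a directory of trial files plus a ``manifest.tsv`` listing each
trial's file name and metadata; the manifest may flag one calibration trial
per subject (the trial used to compute the hand-length normalizer).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from graspadl.hand_model import N_VALUES, LAYOUT_VERSION
from graspadl.trial import TrialRecording, CoordinateFrame

__all__ = ["read_trial", "write_trial", "read_bundle", "write_bundle", "TrialFormatError"]

_HEADER_KEYS = ("subject_id", "task_label", "trial_index", "fps", "coordinate_frame", "layout_version")


class TrialFormatError(ValueError):
    """Malformed trial file (bad header, wrong column count, non-numeric cell)."""


def write_trial(trial: TrialRecording, path: str | Path) -> None:
    """Write a trial to ``path`` in the delimited-text trial format."""
    path = Path(path)
    if not np.all(np.isfinite(trial.frames)):
        raise ValueError("refusing to write trial containing non-finite values")
    with open(path, "w", newline="") as fh:
        fh.write(f"# subject_id={trial.subject_id}\n")
        fh.write(f"# task_label={trial.task_label}\n")
        fh.write(f"# trial_index={trial.trial_index}\n")
        fh.write(f"# fps={trial.fps!r}\n")
        fh.write(f"# coordinate_frame={trial.coordinate_frame.value}\n")
        fh.write(f"# layout_version={LAYOUT_VERSION}\n")
        np.savetxt(fh, trial.frames, fmt="%.17g", delimiter=",")


def read_trial(path: str | Path) -> TrialRecording:
    """Read a trial file written by :func:`write_trial`."""
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise TrialFormatError(f"{path}: malformed header at line {lineno}: {line!r}")
                key, _, value = body.partition("=")
                header[key.strip()] = value.strip()
                continue
            cells = line.split(",")
            if len(cells) != N_VALUES:
                raise TrialFormatError(
                    f"{path}: line {lineno} has {len(cells)} columns, expected {N_VALUES}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                bad = next(i for i, c in enumerate(cells) if not _is_float(c))
                raise TrialFormatError(
                    f"{path}: non-numeric cell at line {lineno}, column {bad}: {cells[bad]!r}"
                ) from exc
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise TrialFormatError(f"{path}: missing header keys {missing}")
    if header["layout_version"] != LAYOUT_VERSION:
        raise TrialFormatError(
            f"{path}: unsupported layout_version {header['layout_version']!r}"
        )
    if not rows:
        raise TrialFormatError(f"{path}: no data rows")
    return TrialRecording(
        frames=np.array(rows, dtype=float),
        task_label=header["task_label"],
        subject_id=header["subject_id"],
        trial_index=int(header["trial_index"]),
        fps=float(header["fps"]),
        coordinate_frame=CoordinateFrame(header["coordinate_frame"]),
    )


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


_MANIFEST_COLS = ("file", "subject_id", "task_label", "trial_index", "fps", "coordinate_frame", "is_calibration")


def write_bundle(
    trials: list[TrialRecording],
    directory: str | Path,
    calibration: set[str] | None = None,
) -> Path:
    """Write a list of trials into ``directory`` with a ``manifest.tsv``.

    ``calibration`` is a set of trial ids (``subject/task/index``) flagged as
    calibration trials for the hand-length normalizer.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    calibration = calibration or set()
    manifest = directory / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_MANIFEST_COLS)
        for t in trials:
            fname = f"{t.subject_id}_{t.task_label.replace(' ', '-')}_{t.trial_index}.csv"
            write_trial(t, directory / fname)
            writer.writerow(
                [fname, t.subject_id, t.task_label, t.trial_index, repr(t.fps),
                 t.coordinate_frame.value, int(t.trial_id in calibration)]
            )
    return manifest


def read_bundle(directory: str | Path) -> tuple[list[TrialRecording], set[str]]:
    """Read a bundle directory; returns (trials, calibration trial ids)."""
    directory = Path(directory)
    manifest = directory / "manifest.tsv"
    if not manifest.exists():
        raise TrialFormatError(f"no manifest.tsv in {directory}")
    trials: list[TrialRecording] = []
    calibration: set[str] = set()
    with open(manifest) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            t = read_trial(directory / rec["file"])
            trials.append(t)
            if rec.get("is_calibration") == "1":
                calibration.add(t.trial_id)
    return trials, calibration
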