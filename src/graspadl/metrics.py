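"""Confusion-matrix metrics with macro averaging."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["compute_metrics"]


def compute_metrics(confusion: np.ndarray) -> tuple[float, float, float, float]:
    """(accuracy, macro precision, macro recall, macro F1) from a count
    confusion matrix with true classes on rows and predictions on columns.

    Per class: precision = diag/column sum, recall = diag/row sum, F1 =
    harmonic mean; macro values are unweighted means over classes.  A class
    with a zero denominator contributes 0 to the macro mean, with a warning.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {cm.shape}")
    if (cm < 0).any():
        raise ValueError("confusion matrix contains negative counts")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(cm)
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)

    if (col == 0).any() or (row == 0).any():
        warnings.warn(
            "class with zero predictions or zero true samples contributes 0 to macro metrics",
            stacklevel=2,
        )
    accuracy = float(diag.sum() / total)
    return accuracy, float(precision.mean()), float(recall.mean()), float(f1.mean())
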