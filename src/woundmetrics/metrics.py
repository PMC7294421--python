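"""Segmentation and measurement evaluation metrics."""

from __future__ import annotations

import warnings

import numpy as np


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|) between binary
    masks.  Two empty masks score 1.0 (with a warning)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("dice of two empty masks: defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def sensitivity_precision(pred: np.ndarray, truth: np.ndarray) -> tuple[float | None, float | None]:
    """(sensitivity, precision) = (TP/(TP+FN), TP/(TP+FP)).

    An empty denominator yields None for that metric rather than NaN.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    tp = int((pred & truth).sum())
    fn = int((~pred & truth).sum())
    fp = int((pred & ~truth).sum())
    sens = tp / (tp + fn) if (tp + fn) else None
    prec = tp / (tp + fp) if (tp + fp) else None
    return sens, prec


def mae_rmse(measured, expected) -> tuple[float, float]:
    """Mean absolute error and root-mean-square error between paired value
    lists.  RMSE >= MAE holds for any sample (Jensen) and is asserted."""
    measured = np.asarray(measured, dtype=np.float64).ravel()
    expected = np.asarray(expected, dtype=np.float64).ravel()
    if measured.shape != expected.shape or measured.size == 0:
        raise ValueError("measured and expected must have equal nonzero lengths")
    err = measured - expected
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    assert rmse >= mae - 1e-12, "RMSE < MAE is mathematically impossible"
    return mae, rmse
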