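"""Segmentation quality metrics: Dice, Hausdorff distance, sensitivity,
specificity, and cohort summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "EvalMetrics",
    "dice",
    "boundary_pixels",
    "hausdorff_distance",
    "sensitivity_specificity",
    "summarize_cohort",
]


@dataclass(frozen=True)
class EvalMetrics:
    """Metrics of one segmentation against ground truth.

    ``hd`` is in pixels; ``sensitivity``/``specificity`` are percentages.
    Undefined quantities (empty masks) are NaN.
    """

    dice: float
    hd: float
    sensitivity: float
    specificity: float


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 1 when both masks are empty."""
    ma = np.asarray(a, dtype=bool)
    mb = np.asarray(b, dtype=bool)
    if ma.shape != mb.shape:
        raise ValueError("mask dimensions differ")
    sa, sb = int(ma.sum()), int(mb.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / (sa + sb)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (row, col) of mask pixels with a 4-neighbour outside the
    mask; the image border counts as outside."""
    m = np.asarray(mask, dtype=bool)
    inside = np.zeros_like(m)
    inside[1:-1, 1:-1] = m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
    edge = m & ~inside
    return np.argwhere(edge)


def hausdorff_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in pixels.

    The classic max of the two directed distances (not a percentile),
    Euclidean metric on boundary pixel coordinates. NaN if either mask is
    empty.
    """
    pa = boundary_pixels(a)
    pb = boundary_pixels(b)
    if len(pa) == 0 or len(pb) == 0:
        return float("nan")
    d1 = directed_hausdorff(pa, pb)[0]
    d2 = directed_hausdorff(pb, pa)[0]
    return float(max(d1, d2))


def sensitivity_specificity(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float]:
    """(sensitivity %, specificity %) of a predicted mask vs ground truth.

    Specificity is computed over all ground-truth-negative pixels of the
    slice, including black background. Sensitivity is NaN for empty ground
    truth; specificity is NaN if the ground truth covers the whole slice.
    """
    p = np.asarray(pred, dtype=bool)
    g = np.asarray(gt, dtype=bool)
    if p.shape != g.shape:
        raise ValueError("mask dimensions differ")
    tp = int((p & g).sum())
    fn = int((~p & g).sum())
    tn = int((~p & ~g).sum())
    fp = int((p & ~g).sum())
    sens = float("nan") if tp + fn == 0 else 100.0 * tp / (tp + fn)
    spec = float("nan") if tn + fp == 0 else 100.0 * tn / (tn + fp)
    return sens, spec


def summarize_cohort(
    metrics: list[EvalMetrics], group: list[str] | None = None
) -> pd.DataFrame:
    """Mean ± sample-sd table per group plus an ALL row (Table-1 shape)."""
    if not metrics:
        raise ValueError("no metrics to summarize")
    df = pd.DataFrame(
        {
            "dice": [m.dice for m in metrics],
            "hd": [m.hd for m in metrics],
            "sensitivity": [m.sensitivity for m in metrics],
            "specificity": [m.specificity for m in metrics],
        }
    )
    df["group"] = group if group is not None else "ALL"
    rows = {}
    groups = sorted(df["group"].unique()) if group is not None else []
    for g in groups:
        sub = df[df["group"] == g]
        rows[g] = _mean_sd_row(sub)
    rows["ALL"] = _mean_sd_row(df)
    return pd.DataFrame(rows).T


def _mean_sd_row(sub: pd.DataFrame) -> dict:
    out = {}
    for col in ("dice", "hd", "sensitivity", "specificity"):
        vals = sub[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        out[f"{col}_mean"] = vals.mean() if len(vals) else float("nan")
        out[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
    out["n"] = len(sub)
    return out
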