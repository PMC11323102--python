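"""Segmentation evaluation: confusion counts, overlap metrics, reporting.

Foreground is the positive class.  Metrics follow the universal definitions
(Dice = 2TP/(2TP+FP+FN), Jaccard/IoU = TP/(TP+FP+FN)) and are computed per
sample, then aggregated as mean +/- sample standard deviation per fold and
pooled — matching the usual reporting format for cross-validated studies.
Degenerate cases use explicit conventions: when both masks are empty every
metric is 1 (perfect agreement); an empty prediction against a non-empty
truth has recall 0 and precision 1 by convention (no positive calls to be
wrong about), flagged in the record.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "confusion", "metrics", "aggregate", "overlay"]


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred_mask: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts for binary masks."""
    pred_mask = np.asarray(pred_mask)
    truth = np.asarray(truth)
    if pred_mask.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred_mask.shape} vs {truth.shape}")
    for name, arr in (("pred", pred_mask), ("truth", truth)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    p = pred_mask.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Dice, Jaccard, precision, recall from confusion counts (with conventions)."""
    record: dict[str, float] = {}
    both_empty = c.tp == 0 and c.fp == 0 and c.fn == 0
    record["dice"] = 1.0 if both_empty else 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    record["jaccard"] = 1.0 if both_empty else c.tp / (c.tp + c.fp + c.fn)
    record["precision"] = 1.0 if c.tp + c.fp == 0 else c.tp / (c.tp + c.fp)
    record["recall"] = 1.0 if c.tp + c.fn == 0 else c.tp / (c.tp + c.fn)
    record["degenerate"] = float(both_empty or c.tp + c.fp == 0 or c.tp + c.fn == 0)
    return record


def aggregate(per_sample: list[dict], folds: list[int] | None = None) -> pd.DataFrame:
    """Mean +/- sample sd per fold and overall, one row per summary group."""
    if not per_sample:
        raise ValueError("no records to aggregate")
    df = pd.DataFrame(per_sample)
    df["fold"] = folds if folds is not None else df.get("fold", 0)
    cols = [c for c in ("dice", "jaccard", "precision", "recall") if c in df.columns]
    rows = []
    groups = [(f"fold{f}", sub) for f, sub in df.groupby("fold")] + [("overall", df)]
    for name, sub in groups:
        row: dict[str, object] = {"group": name, "n": len(sub)}
        for col in cols:
            row[f"{col}_mean"] = sub[col].mean()
            row[f"{col}_sd"] = sub[col].std(ddof=1) if len(sub) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def overlay(
    image: np.ndarray,
    truth: np.ndarray,
    pred: np.ndarray,
    out_path: str | Path | None = None,
):
    """Render prediction vs truth: green = correct foreground, blue = missed
    (FN), red = spurious (FP); mis-segmented regions are the red/blue pixels.

    Returns the RGB array; writes a PNG when ``out_path`` is given.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        image = image.mean(axis=2)
    truth = np.asarray(truth).astype(bool)
    pred = np.asarray(pred).astype(bool)
    if image.shape != truth.shape or truth.shape != pred.shape:
        raise ValueError("image, truth and pred must share shape")
    lo, hi = image.min(), image.max()
    base = np.zeros_like(image) if hi <= lo else (image - lo) / (hi - lo)
    rgb = np.stack([base, base, base], axis=2)
    rgb[pred & truth] = [0.0, 0.8, 0.0]
    rgb[~pred & truth] = [0.0, 0.2, 1.0]
    rgb[pred & ~truth] = [1.0, 0.1, 0.1]
    if out_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(rgb, interpolation="nearest")
        ax.set_axis_off()
        fig.savefig(out_path, bbox_inches="tight", dpi=120)
        plt.close(fig)
    return rgb
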