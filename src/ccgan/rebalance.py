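"""Region-level rebalancing (RRM).

Instead of reweighting individual pixels — which are spatially correlated and
therefore a poor unit for frequency-based rebalancing — label maps are tiled
into fixed-size regions.  An auxiliary classifier predicts each region's
class, and its cross-entropy is reweighted by dataset-level region class
frequencies multiplied *into* the softmax (a logit-adjustment: adding
``log F(k)`` to the logits during training biases the learning signal so the
learned logits themselves become prior-corrected).  The module is used only
during training; inference never executes it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .autodiff import Tensor, log_softmax
from .layers import Conv2d, Dense, Module

__all__ = [
    "RegionBatch",
    "RegionFrequencies",
    "extract_regions",
    "region_frequencies",
    "region_loss",
    "region_loss_t",
    "combined_seg_loss",
    "RegionClassifier",
]

LabelRule = str  # "any_foreground" | "majority"


@dataclasses.dataclass
class RegionBatch:
    """Fixed-size tiles with per-tile class labels."""

    features: list[np.ndarray]  # each (rf, rf, c), the tile cut from the feature map
    labels: list[int]
    region_size: int  # tile side on the label map


@dataclasses.dataclass
class RegionFrequencies:
    """Dataset-level region class counts F(C), with additive smoothing."""

    counts: np.ndarray  # (L,) integers
    smoothing: float = 1.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.smoothing < 0:
            raise ValueError("smoothing must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        return self.counts.astype(np.float64) + self.smoothing

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"counts": self.counts.tolist(), "smoothing": self.smoothing}
        ))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionFrequencies":
        obj = json.loads(Path(path).read_text())
        return cls(np.asarray(obj["counts"]), obj["smoothing"])


def _pad_to_multiple(arr: np.ndarray, r: int) -> np.ndarray:
    h, w = arr.shape[:2]
    ph, pw = (-h) % r, (-w) % r
    if ph == 0 and pw == 0:
        return arr
    width = ((0, ph), (0, pw)) + ((0, 0),) * (arr.ndim - 2)
    return np.pad(arr, width)  # background padding


def _tile_label(tile: np.ndarray, rule: LabelRule) -> int:
    if rule == "any_foreground":
        return int(tile.any())
    if rule == "majority":
        values, counts = np.unique(tile, return_counts=True)
        return int(values[np.argmax(counts)])  # ties break to the smaller label
    raise ValueError(f"unknown label rule {rule!r}")


def extract_regions(
    mask: np.ndarray,
    feature: np.ndarray | None = None,
    r: int = 32,
    label_rule: LabelRule = "any_foreground",
) -> RegionBatch:
    """Cut the mask (and optionally an aligned feature map) into r x r tiles.

    Tiles are non-overlapping, row-major; masks not divisible by ``r`` are
    padded with background.  The feature map may live at a coarser resolution
    than the mask as long as the ratio is integral — its tile size scales
    accordingly.
    """
    if r <= 0:
        raise ValueError("region size must be positive")
    mask = _pad_to_multiple(np.asarray(mask), r)
    h, w = mask.shape
    gh, gw = h // r, w // r
    feats: list[np.ndarray] = []
    labels: list[int] = []
    if feature is not None:
        feature = np.asarray(feature)
        if h % feature.shape[0] != 0 or w % feature.shape[1] != 0:
            raise ValueError(
                f"feature shape {feature.shape[:2]} does not evenly divide "
                f"mask shape {(h, w)}"
            )
        rf_h = feature.shape[0] // gh
        rf_w = feature.shape[1] // gw
    for i in range(gh):
        for j in range(gw):
            labels.append(_tile_label(mask[i * r : (i + 1) * r, j * r : (j + 1) * r],
                                      label_rule))
            if feature is not None:
                feats.append(feature[i * rf_h : (i + 1) * rf_h,
                                     j * rf_w : (j + 1) * rf_w])
    return RegionBatch(feats, labels, r)


def region_frequencies(
    dataset_masks: list[np.ndarray],
    r: int = 32,
    label_rule: LabelRule = "any_foreground",
    n_classes: int | None = None,
    smoothing: float = 1.0,
) -> RegionFrequencies:
    """Count, over the whole dataset, the regions associated with each class.

    Under ``any_foreground`` a region increments the count of *every* class
    present in its tile (the literal membership reading of F); under
    ``majority`` each region counts once, toward its majority label.  Computed
    once on the training fold, before training.
    """
    if not dataset_masks:
        raise ValueError("dataset_masks must be non-empty")
    if n_classes is None:
        n_classes = max(2, max(int(np.max(m)) for m in dataset_masks) + 1)
    counts = np.zeros(n_classes, dtype=np.int64)
    for mask in dataset_masks:
        mask = _pad_to_multiple(np.asarray(mask), r)
        h, w = mask.shape
        for i in range(h // r):
            for j in range(w // r):
                tile = mask[i * r : (i + 1) * r, j * r : (j + 1) * r]
                if label_rule == "majority":
                    counts[_tile_label(tile, "majority")] += 1
                else:
                    for value in np.unique(tile):
                        counts[int(value)] += 1
    return RegionFrequencies(counts, smoothing)


def region_loss(
    logits: np.ndarray, labels: np.ndarray, freq: RegionFrequencies
) -> float:
    """Frequency-weighted region cross-entropy.

    ``-mean_i log( F(y_i) exp(z_iy) / sum_k F(k) exp(z_ik) )``, evaluated in a
    numerically stable form by folding ``log F`` into the logits.
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    weights = freq.weights
    if np.any(weights[labels] <= 0):
        raise ValueError(
            "a region label has zero frequency and smoothing is 0; "
            "the rebalanced loss is undefined"
        )
    if np.any(weights <= 0):
        # classes with F=0 simply drop out of the partition sum
        weights = np.where(weights <= 0, np.nan, weights)
        shifted = logits + np.log(weights)
        shifted = np.where(np.isnan(shifted), -np.inf, shifted)
    else:
        shifted = logits + np.log(weights)
    lse = logsumexp(shifted, axis=1)
    picked = shifted[np.arange(len(labels)), labels]
    return float(np.mean(lse - picked))


def region_loss_t(logits: Tensor, labels: np.ndarray, freq: RegionFrequencies) -> Tensor:
    """Autodiff twin of :func:`region_loss` for the training path."""
    labels = np.asarray(labels, dtype=np.int64)
    shifted = logits + Tensor(np.log(freq.weights)[None, :])
    logp = log_softmax(shifted, axis=1)
    onehot = np.zeros(logits.shape, dtype=np.float32)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / len(labels))


def combined_seg_loss(pixel_loss, region_loss, region_weight: float = 1.0):
    """Total segmentation objective: pixel term plus (optionally scaled) region term."""
    return pixel_loss + region_weight * region_loss


class RegionClassifier(Module):
    """Auxiliary region head: 3x3 conv + ReLU, global average pool, dense.

    Training-only; detaching it leaves the segmentation path untouched.
    """

    def __init__(self, in_channels: int, n_classes: int, rng: np.random.Generator,
                 hidden: int = 32):
        super().__init__()
        self.conv = Conv2d(in_channels, hidden, 3, rng)
        self.fc = Dense(hidden, n_classes, rng)

    def forward(self, regions: Tensor) -> Tensor:
        """(m, rf, rf, c) region features -> (m, L) logits."""
        h = self.conv(regions).relu()
        pooled = h.mean(axis=(1, 2))
        return self.fc(pooled)
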