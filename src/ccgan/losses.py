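"""Objectives: conditional contrastive (2C) loss, L1 segmentation term,
SCoLN supervised contrastive loss, false-negative/false-positive correction
maps, and the final corrected objective.

Each loss has a vectorised numpy form (the public API, returning floats) and,
where the training loop needs gradients, an autodiff twin suffixed ``_t``.
The numpy forms are pinned against naive scalar loop oracles in the tests.

The 2C loss couples each image's projection l(I_i) with a learned class
embedding e(y_i) (data-to-class) and with the projections of same-class batch
mates (data-to-data):

    -log [ exp(<l_i, e_{y_i}>/t) + sum_{j!=i, y_j=y_i} exp(<l_i, l_j>/t) ]
         / [ exp(<l_i, e_{y_i}>/t) + sum_{j!=i}          exp(<l_i, l_j>/t) ]

The numerator's index set is a subset of the denominator's, so the loss is
non-negative and vanishes exactly when every cross-class similarity term does.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import logsumexp as np_logsumexp

from .autodiff import Tensor

__all__ = [
    "EmbeddingBatch",
    "CorrectionMaps",
    "two_c_loss",
    "two_c_loss_t",
    "l1_seg_loss",
    "adversarial_seg_loss",
    "scoln_contrastive_loss",
    "scoln_contrastive_loss_t",
    "correction_maps",
    "final_objective",
    "corrected_mask",
]


@dataclasses.dataclass
class EmbeddingBatch:
    """Projections and class embeddings consumed by the 2C loss."""

    image_proj: np.ndarray  # (n, d) rows l(I_i)
    class_embed: dict[int, np.ndarray]  # class id -> e vector (d,)
    labels: np.ndarray  # (n,) integer class ids
    temperature: float = 3.0

    def __post_init__(self):
        self.image_proj = np.asarray(self.image_proj, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not np.all(np.isfinite(self.image_proj)):
            raise ValueError("image projections contain non-finite entries")
        if len(self.labels) != len(self.image_proj):
            raise ValueError("labels and image_proj lengths differ")


@dataclasses.dataclass
class CorrectionMaps:
    """False-negative and false-positive maps, both in [0, 1].

    For binary prediction and truth the two supports are disjoint, so the
    pointwise product vanishes.
    """

    fn_map: np.ndarray  # C_ln: missed foreground
    fp_map: np.ndarray  # C_lp: spurious foreground

    def __post_init__(self):
        self.fn_map = np.asarray(self.fn_map, dtype=np.float64)
        self.fp_map = np.asarray(self.fp_map, dtype=np.float64)
        if self.fn_map.shape != self.fp_map.shape:
            raise ValueError("fn_map and fp_map shapes differ")


# ---------------------------------------------------------------------------
# 2C conditional contrastive loss


def _two_c_anchor_terms(batch: EmbeddingBatch, i: int) -> tuple[np.ndarray, np.ndarray]:
    proj, labels, t = batch.image_proj, batch.labels, batch.temperature
    li = proj[i]
    anchor_class = np_asint(labels[i])
    s_class = float(li @ batch.class_embed[anchor_class]) / t
    others = np.delete(np.arange(len(labels)), i)
    sims = (proj[others] @ li) / t
    num = np.concatenate([[s_class], sims[labels[others] == labels[i]]])
    den = np.concatenate([[s_class], sims])
    return num, den


def np_asint(x) -> int:
    return int(np.asarray(x))


def two_c_loss(batch: EmbeddingBatch, anchor: int | None = None) -> float:
    """2C loss for one anchor, or the mean over all anchors when ``anchor`` is None."""
    n = len(batch.labels)
    if n == 0:
        raise ValueError("empty batch")
    anchors = range(n) if anchor is None else [anchor]
    total = 0.0
    for i in anchors:
        num, den = _two_c_anchor_terms(batch, i)
        total += float(np_logsumexp(den) - np_logsumexp(num))
    return total / len(list(anchors))


def two_c_loss_t(
    proj: Tensor, class_embed: Tensor, labels: np.ndarray, temperature: float = 3.0
) -> Tensor:
    """Autodiff 2C loss: proj (n, d), class_embed (L, d), labels (n,)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    labels = np.asarray(labels, dtype=np.int64)
    n = proj.shape[0]
    sims = proj.matmul(proj.transpose(1, 0)) * (1.0 / temperature)  # (n, n)
    e_y = class_embed[labels]  # gather rows -> (n, d)
    class_sim = (proj * e_y).sum(axis=1, keepdims=True) * (1.0 / temperature)  # (n, 1)
    # column 0: data-to-class term; columns 1..n: data-to-data terms
    all_terms = _masked_lse_matrix(class_sim, sims, labels, same_class_only=False)
    pos_terms = _masked_lse_matrix(class_sim, sims, labels, same_class_only=True)
    return (all_terms - pos_terms).sum() * (1.0 / n)


def _masked_lse_matrix(class_sim: Tensor, sims: Tensor, labels: np.ndarray,
                       same_class_only: bool) -> Tensor:
    """Row-wise log-sum-exp over {class term} + masked off-diagonal similarities."""
    n = sims.shape[0]
    from .autodiff import concat

    mask = np.ones((n, n), dtype=np.float32)
    np.fill_diagonal(mask, 0.0)
    if same_class_only:
        mask *= (labels[:, None] == labels[None, :]).astype(np.float32)
    full = concat([class_sim, sims], axis=1)  # (n, n+1)
    full_mask = np.concatenate([np.ones((n, 1), dtype=np.float32), mask], axis=1)
    shift = Tensor(np.where(full_mask > 0, full.data, -np.inf).max(axis=1, keepdims=True))
    summed = ((full - shift).exp() * Tensor(full_mask)).sum(axis=1)
    return summed.log() + shift.reshape(n)


# ---------------------------------------------------------------------------
# L1 and adversarial segmentation terms


def l1_seg_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute difference between predicted and true segmentation maps."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.abs(pred - target).mean())


def l1_seg_loss_t(pred: Tensor, target: Tensor) -> Tensor:
    diff = pred - target
    return (diff.relu() + (-diff).relu()).mean()


def adversarial_seg_loss(two_c, l1, lambda_l1: float = 1.0):
    """m_seg = 2C term + lambda * L1 term (unit weight by default)."""
    return two_c + lambda_l1 * l1


# ---------------------------------------------------------------------------
# SCoLN supervised contrastive loss


def _similarities(anchor: np.ndarray, vectors: np.ndarray, sim: str) -> np.ndarray:
    if sim == "dot":
        return vectors @ anchor
    if sim == "cosine":
        denom = np.linalg.norm(vectors, axis=1) * np.linalg.norm(anchor)
        denom = np.where(denom < 1e-12, 1.0, denom)
        return (vectors @ anchor) / denom
    raise ValueError(f"unknown similarity {sim!r}")


def scoln_contrastive_loss(
    anchor: np.ndarray,
    positives: np.ndarray,
    negatives: np.ndarray,
    sim: str = "cosine",
    as_printed: bool = False,
) -> float:
    """Supervised contrastive loss pulling the anchor toward positives.

    Default (corrected) form:
        -log( sum_p exp(s(a, p)) / [sum_p exp(s(a, p)) + sum_n exp(s(a, n))] ).

    ``as_printed=True`` evaluates the uncorrected published form,
    log(pos_softmax * neg_softmax) over the pooled candidate set; it is kept
    for comparison only and rewards similarity to negatives.
    """
    anchor = np.asarray(anchor, dtype=np.float64)
    positives = np.atleast_2d(np.asarray(positives, dtype=np.float64))
    negatives = np.atleast_2d(np.asarray(negatives, dtype=np.float64))
    if positives.size == 0 or negatives.size == 0:
        raise ValueError("positives and negatives must both be non-empty")
    sp = _similarities(anchor, positives, sim)
    sn = _similarities(anchor, negatives, sim)
    lse_pos = np_logsumexp(sp)
    lse_all = np_logsumexp(np.concatenate([sp, sn]))
    if as_printed:
        lse_neg = np_logsumexp(sn)
        return float((lse_pos - lse_all) + (lse_neg - lse_all))
    return float(lse_all - lse_pos)


def scoln_contrastive_loss_t(
    anchor: Tensor, positives: Tensor, negatives: Tensor, sim: str = "cosine"
) -> Tensor:
    """Autodiff twin of the corrected SCoLN contrastive loss."""
    from .autodiff import logsumexp

    def sim_vec(vecs: Tensor) -> Tensor:
        scores = vecs.matmul(anchor.reshape(-1, 1)).reshape(vecs.shape[0])
        if sim == "cosine":
            norms = np.linalg.norm(vecs.data, axis=1) * np.linalg.norm(anchor.data)
            scale = 1.0 / np.where(norms < 1e-12, 1.0, norms)
            # norms treated as constants: cosine used as a bounded score here
            scores = scores * Tensor(scale)
        return scores

    from .autodiff import concat

    sp = sim_vec(positives)
    sn = sim_vec(negatives)
    return logsumexp(concat([sp, sn], axis=0), axis=0) - logsumexp(sp, axis=0)


# ---------------------------------------------------------------------------
# Correction maps and final objective


def correction_maps(pred: np.ndarray, g: np.ndarray) -> CorrectionMaps:
    """FN map = clamp(g - pred, 0, 1); FP map = clamp(pred - g, 0, 1)."""
    pred = np.asarray(pred, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if pred.shape != g.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {g.shape}")
    if pred.min() < 0.0 or pred.max() > 1.0:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return CorrectionMaps(
        fn_map=np.clip(g - pred, 0.0, 1.0),
        fp_map=np.clip(pred - g, 0.0, 1.0),
    )


def final_objective(m_seg: float, maps: CorrectionMaps, raw_counts: bool = False) -> float:
    """Final loss: m_seg - FP term + FN term.

    The FN/FP "counts" enter as spatial means by default so the objective does
    not scale with image resolution; ``raw_counts=True`` uses plain sums.
    """
    reduce = np.sum if raw_counts else np.mean
    return float(m_seg - reduce(maps.fp_map) + reduce(maps.fn_map))


def corrected_mask(pred: np.ndarray, maps: CorrectionMaps, threshold: float = 0.5) -> np.ndarray:
    """Final mask: threshold clamp(pred + FN - FP, 0, 1).

    With oracle maps computed from the ground truth this reproduces the truth
    exactly for any prediction in [0, 1].
    """
    pred = np.asarray(pred, dtype=np.float64)
    if pred.shape != maps.fn_map.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {maps.fn_map.shape}")
    corrected = np.clip(pred + maps.fn_map - maps.fp_map, 0.0, 1.0)
    return (corrected >= threshold).astype(np.int64)
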