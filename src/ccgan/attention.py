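"""Class-specific channel attention.

The mechanism dedicates ``x`` feature channels to each of the ``L`` classes.
A depth-wise separable 3x3 convolution (plus batch norm and ReLU) maps the
incoming representation to ``x*L`` channels grouped contiguously by class;
global max pooling and within-class averaging then yield a per-class score
vector and a per-class semantic map, whose score-weighted mean is a single
spatial attention map that multiplicatively reweights the input features.

Two surfaces are provided: pure-numpy functions on single ``(h, w, c)``
feature maps (the reference semantics, used by oracle tests) and
:class:`AttentionBlock`, the autodiff module the generator trains.  The test
suite pins the block to the functional reference.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor
from .layers import BatchNorm2d, Module, SeparableConv2d

__all__ = [
    "AttentionConfig",
    "AttentionParams",
    "transform",
    "class_scores",
    "class_semantic_map",
    "attention_map",
    "apply_attention",
    "AttentionBlock",
]


@dataclasses.dataclass
class AttentionConfig:
    channels_per_class: int  # x: channels dedicated to each class
    num_classes: int  # L
    levels: frozenset[int] = frozenset({2, 6})

    def __post_init__(self):
        if self.channels_per_class < 1:
            raise ValueError("channels_per_class must be >= 1")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")

    @property
    def out_channels(self) -> int:
        return self.channels_per_class * self.num_classes


@dataclasses.dataclass
class AttentionParams:
    """Weights for the functional :func:`transform` (numpy reference path)."""

    depthwise: np.ndarray  # (k, k, c_in)
    pointwise: np.ndarray  # (c_in, x*L)
    bias: np.ndarray  # (x*L,)
    bn_mean: np.ndarray | None = None  # None bypasses normalisation
    bn_var: np.ndarray | None = None
    bn_gamma: np.ndarray | None = None
    bn_beta: np.ndarray | None = None
    bn_eps: float = 1e-5


def _check_grouping(channels: int, cfg: AttentionConfig) -> None:
    if channels % cfg.num_classes != 0:
        raise ValueError(
            f"channel count {channels} is not divisible by num_classes {cfg.num_classes}"
        )
    if channels != cfg.out_channels:
        raise ValueError(
            f"expected {cfg.out_channels} channels "
            f"({cfg.channels_per_class} per class x {cfg.num_classes} classes), got {channels}"
        )


def transform(inp: np.ndarray, cfg: AttentionConfig, params: AttentionParams) -> np.ndarray:
    """ReLU(BN(separable 3x3 conv)) mapping (h, w, c) -> (h, w, x*L)."""
    inp = np.asarray(inp, dtype=np.float64)
    if not np.all(np.isfinite(inp)):
        raise ValueError("input feature map contains non-finite entries")
    h, w, c = inp.shape
    k = params.depthwise.shape[0]
    pad = (k - 1) // 2
    xp = np.pad(inp, ((pad, pad), (pad, pad), (0, 0)))
    dw = np.zeros_like(inp)
    for dy in range(k):
        for dx in range(k):
            dw += xp[dy : dy + h, dx : dx + w, :] * params.depthwise[dy, dx]
    out = dw @ params.pointwise + params.bias
    if params.bn_mean is not None:
        out = (out - params.bn_mean) / np.sqrt(params.bn_var + params.bn_eps)
        out = out * params.bn_gamma + params.bn_beta
    _check_grouping(out.shape[2], cfg)
    return np.maximum(out, 0.0)


def class_scores(transformed: np.ndarray, cfg: AttentionConfig) -> np.ndarray:
    """Per-class score: mean over the class's channels of the global spatial max."""
    transformed = np.asarray(transformed)
    _check_grouping(transformed.shape[2], cfg)
    h, w, _ = transformed.shape
    grouped = transformed.reshape(h, w, cfg.num_classes, cfg.channels_per_class)
    return grouped.max(axis=(0, 1)).mean(axis=1)


def class_semantic_map(transformed: np.ndarray, cfg: AttentionConfig) -> np.ndarray:
    """Average each class's channel group into one plane: (h, w, L)."""
    transformed = np.asarray(transformed)
    _check_grouping(transformed.shape[2], cfg)
    h, w, _ = transformed.shape
    grouped = transformed.reshape(h, w, cfg.num_classes, cfg.channels_per_class)
    return grouped.mean(axis=3)


def attention_map(scores: np.ndarray, semantic: np.ndarray) -> np.ndarray:
    """Score-weighted mean of the class semantic planes: (h, w)."""
    scores = np.asarray(scores, dtype=np.float64)
    semantic = np.asarray(semantic, dtype=np.float64)
    if semantic.shape[2] != scores.shape[0]:
        raise ValueError(
            f"semantic map has {semantic.shape[2]} planes but scores has "
            f"length {scores.shape[0]}"
        )
    return (semantic * scores).mean(axis=2)


def apply_attention(inp: np.ndarray, att: np.ndarray) -> np.ndarray:
    """Element-wise product of every input channel with the attention map."""
    inp = np.asarray(inp)
    att = np.asarray(att)
    if inp.shape[:2] != att.shape:
        raise ValueError(
            f"spatial shapes differ: input {inp.shape[:2]} vs attention {att.shape}"
        )
    return inp * att[:, :, None]


class AttentionBlock(Module):
    """Trainable class-specific attention; output shape equals input shape."""

    def __init__(self, in_channels: int, cfg: AttentionConfig, rng: np.random.Generator,
                 sigmoid_gate: bool = False):
        super().__init__()
        self.cfg = cfg
        self.sigmoid_gate = sigmoid_gate
        self.conv = SeparableConv2d(in_channels, cfg.out_channels, rng)
        self.bn = BatchNorm2d(cfg.out_channels)

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, _ = x.shape
        L, cpc = self.cfg.num_classes, self.cfg.channels_per_class
        transformed = self.bn(self.conv(x)).relu()
        grouped = transformed.reshape(n, h, w, L, cpc)
        semantic = grouped.mean(axis=4)  # (n, h, w, L)
        scores = grouped.max(axis=(1, 2)).mean(axis=2)  # (n, L)
        att = (semantic * scores.reshape(n, 1, 1, L)).mean(axis=3)  # (n, h, w)
        att = att.reshape(n, h, w, 1)
        if self.sigmoid_gate:
            att = att.sigmoid()
        return x * att
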