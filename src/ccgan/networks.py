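"""The three networks: conditional generator, discriminator, and SCoLN.

All are small, fully convolutional encoder--decoder CNNs (NHWC) built on the
package's autodiff core.  The generator is a UNet-style conditional network:
a 5x5 first encoder block, 3x3 blocks below, stride-2 downsampling, factor-2
upsampling with skip concatenations joining encoder level ``l`` to decoder
level ``t - l``, class-specific attention at configurable levels, and an
auxiliary region-classifier head used only during training.  Latent noise
``n`` is realised as train-time dropout (the pix2pix convention).  The
discriminator mirrors the encoder and emits a real/fake probability plus the
projection l(.) the 2C loss consumes.  SCoLN is a UNet corrector predicting
the generator's false-negative and false-positive maps, with a bottleneck
embedding head for its contrastive term.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .attention import AttentionBlock, AttentionConfig
from .autodiff import Tensor, concat
from .layers import Conv2d, ConvBlock, Dense, Dropout, Module, Parameter
from .rebalance import RegionClassifier

__all__ = [
    "GeneratorConfig",
    "SegResult",
    "Generator",
    "Discriminator",
    "SCoLN",
    "build_generator",
    "build_discriminator",
    "build_scoln",
]


@dataclasses.dataclass
class GeneratorConfig:
    """Architecture knobs; defaults are the desk-scale configuration."""

    levels: int = 4
    base_filters: int = 16
    in_channels: int = 1
    attention_levels: frozenset[int] = frozenset({2, 6})
    attention_channels_per_class: int = 4
    rrm_enabled: bool = True
    region_size: int = 32
    dropout_rate: float = 0.3
    proj_dim: int = 64
    sigmoid_attention: bool = False

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        bad = {l for l in self.attention_levels if not 1 <= l <= 2 * self.levels}
        if bad:
            raise ValueError(
                f"attention levels {sorted(bad)} outside valid blocks "
                f"1..{2 * self.levels}"
            )

    def filters(self, level: int) -> int:
        return self.base_filters * 2 ** (level - 1)


@dataclasses.dataclass
class SegResult:
    """Per-pixel class probabilities, the binarised mask, and optional correction."""

    prob: np.ndarray  # (h, w, L), rows sum to 1
    mask: np.ndarray  # (h, w) integer labels
    correction: object | None = None  # CorrectionMaps when SCoLN ran
    id: str = ""


def _check_divisible(h: int, w: int, levels: int) -> None:
    d = 2**levels
    if h % d or w % d:
        raise ValueError(
            f"spatial size {(h, w)} must be divisible by 2^levels = {d}"
        )


class Generator(Module):
    """Conditional encoder--decoder segmentation generator."""

    def __init__(self, cfg: GeneratorConfig, n_classes: int, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.n_classes = n_classes
        f = cfg.filters
        self.enc_blocks: list[ConvBlock] = []
        self.down_blocks: list[ConvBlock] = []
        self.enc_attention: dict[int, AttentionBlock] = {}
        self.dec_attention: dict[int, AttentionBlock] = {}
        in_ch = cfg.in_channels
        for level in range(1, cfg.levels + 1):
            kernel = 5 if level == 1 else 3
            self.enc_blocks.append(ConvBlock(in_ch, f(level), kernel, rng))
            self.down_blocks.append(ConvBlock(f(level), f(level), 3, rng, stride=2))
            in_ch = f(level)
        self.bottleneck = ConvBlock(f(cfg.levels), f(cfg.levels), 3, rng)
        self.dec_blocks: list[ConvBlock] = []
        self.dec_merge: list[ConvBlock] = []
        for level in range(cfg.levels, 0, -1):
            up_in = f(level) if level == cfg.levels else f(level + 1)
            self.dec_blocks.append(ConvBlock(up_in, f(level), 3, rng))
            self.dec_merge.append(ConvBlock(2 * f(level), f(level), 3, rng))
        att_cfg = AttentionConfig(cfg.attention_channels_per_class, n_classes,
                                  frozenset(cfg.attention_levels))
        t = 2 * cfg.levels
        for idx in sorted(cfg.attention_levels):
            if idx <= cfg.levels:  # encoder side: level idx carries f(idx) channels
                self.enc_attention[idx] = AttentionBlock(
                    f(idx), att_cfg, rng, cfg.sigmoid_attention)
            else:  # decoder block idx emits the skip-partner level's channel count
                self.dec_attention[idx] = AttentionBlock(
                    f(t - idx + 1), att_cfg, rng, cfg.sigmoid_attention)
        # registered via lists/dicts below so Module.parameters() sees them
        self._att_modules = list(self.enc_attention.values()) + list(
            self.dec_attention.values())
        self.dropout = Dropout(cfg.dropout_rate, rng)
        self.head = Conv2d(f(1), n_classes, 3, rng)
        self.region_head = (
            RegionClassifier(f(cfg.levels), n_classes, rng) if cfg.rrm_enabled else None
        )

    def forward(self, x: Tensor, return_features: bool = False):
        cfg = self.cfg
        _check_divisible(x.shape[1], x.shape[2], cfg.levels)
        skips: list[Tensor] = []
        h = x
        for level in range(1, cfg.levels + 1):
            h = self.enc_blocks[level - 1](h)
            if level in self.enc_attention:
                h = self.enc_attention[level](h)
            skips.append(h)
            h = self.down_blocks[level - 1](h)
        deepest = h
        h = self.dropout(self.bottleneck(h))
        t = 2 * cfg.levels
        for i, level in enumerate(range(cfg.levels, 0, -1)):
            h = self.dec_blocks[i](h.upsample2x_nearest())
            h = self.dec_merge[i](concat([h, skips[level - 1]], axis=3))
            dec_idx = t - level + 1
            if dec_idx in self.dec_attention:
                h = self.dec_attention[dec_idx](h)
        logits = self.head(h)
        if return_features:
            return logits, deepest
        return logits

    def probabilities(self, logits: Tensor) -> Tensor:
        from .autodiff import log_softmax

        return log_softmax(logits, axis=3).exp()


class Discriminator(Module):
    """Encoder-shaped conditional discriminator with a projection head."""

    def __init__(self, cfg: GeneratorConfig, n_classes: int, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        f = cfg.filters
        in_ch = cfg.in_channels + n_classes  # conditioned on (image, mask probs)
        self.blocks: list[ConvBlock] = []
        for level in range(1, cfg.levels + 1):
            kernel = 5 if level == 1 else 3
            self.blocks.append(ConvBlock(in_ch, f(level), kernel, rng, stride=2))
            in_ch = f(level)
        self.judge = Dense(f(cfg.levels), 1, rng)
        self.project = Dense(f(cfg.levels), cfg.proj_dim, rng)
        # learned class embeddings e(.) for the 2C loss; owned by the
        # discriminator so the D phase is the one that updates them
        self.class_embed = Parameter(
            (0.1 * rng.standard_normal((n_classes, cfg.proj_dim))).astype(np.float32)
        )

    def forward(self, image: Tensor, mask_probs: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (real probability (n,), projection l(.) (n, d))."""
        h = concat([image, mask_probs], axis=3)
        _check_divisible(h.shape[1], h.shape[2], self.cfg.levels)
        for block in self.blocks:
            h = block(h)
        pooled = h.mean(axis=(1, 2))  # (n, f)
        prob = self.judge(pooled).sigmoid().reshape(h.shape[0])
        return prob, self.project(pooled)


class SCoLN(Module):
    """UNet-style corrector predicting (FN, FP) maps from (image, generator prob)."""

    def __init__(self, cfg: GeneratorConfig, n_classes: int, rng: np.random.Generator,
                 levels: int = 3):
        super().__init__()
        self.levels = levels
        f = cfg.filters
        in_ch = cfg.in_channels + n_classes
        self.enc_blocks: list[ConvBlock] = []
        self.down_blocks: list[ConvBlock] = []
        for level in range(1, levels + 1):
            self.enc_blocks.append(ConvBlock(in_ch, f(level), 3, rng))
            self.down_blocks.append(ConvBlock(f(level), f(level), 3, rng, stride=2))
            in_ch = f(level)
        self.bottleneck = ConvBlock(f(levels), f(levels), 3, rng)
        self.embed = Dense(f(levels), cfg.proj_dim, rng)
        self.dec_blocks: list[ConvBlock] = []
        self.dec_merge: list[ConvBlock] = []
        for level in range(levels, 0, -1):
            up_in = f(level) if level == levels else f(level + 1)
            self.dec_blocks.append(ConvBlock(up_in, f(level), 3, rng))
            self.dec_merge.append(ConvBlock(2 * f(level), f(level), 3, rng))
        self.head = Conv2d(f(1), 2, 3, rng)

    def forward(self, image: Tensor, gen_probs: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (fn_map, fp_map) in [0, 1] plus the bottleneck embedding."""
        h = concat([image, gen_probs], axis=3)
        _check_divisible(h.shape[1], h.shape[2], self.levels)
        skips = []
        for level in range(self.levels):
            h = self.enc_blocks[level](h)
            skips.append(h)
            h = self.down_blocks[level](h)
        h = self.bottleneck(h)
        embedding = self.embed(h.mean(axis=(1, 2)))
        for i, level in enumerate(range(self.levels, 0, -1)):
            h = self.dec_blocks[i](h.upsample2x_bilinear())
            h = self.dec_merge[i](concat([h, skips[level - 1]], axis=3))
        maps = self.head(h).sigmoid()  # (n, h, w, 2)
        return maps[:, :, :, 0], maps[:, :, :, 1], embedding


def build_generator(cfg: GeneratorConfig, L: int, seed: int = 0) -> Generator:
    return Generator(cfg, L, np.random.default_rng(seed))


def build_discriminator(cfg: GeneratorConfig, L: int, seed: int = 0) -> Discriminator:
    return Discriminator(cfg, L, np.random.default_rng(seed))


def build_scoln(cfg: GeneratorConfig, L: int = 2, seed: int = 0, levels: int = 3) -> SCoLN:
    return SCoLN(cfg, L, np.random.default_rng(seed), levels=levels)
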