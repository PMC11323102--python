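"""Three-phase adversarial training and cross-validated orchestration.

Each batch runs up to three phases, every phase updating only its own
network's parameters:

1. **Discriminator** — binary real/fake loss on (image, mask) pairs plus the
   2C conditional contrastive loss on *real* images; updates the
   discriminator and the class embeddings it owns.
2. **Generator** — the non-saturating fool-the-discriminator term, the 2C
   loss on *generated* probability maps, the L1 term, and, when the region
   rebalance module is enabled, the pixel cross-entropy plus the
   frequency-weighted region loss on tiles of the deepest encoder features.
3. **SCoLN** — pixelwise binary cross-entropy against the oracle
   false-negative / false-positive maps of the current generator output, plus
   a supervised contrastive term over bottleneck embeddings grouped by
   prediction-error quantile.

``fit`` wraps this in seeded k-fold cross-validation with early stopping on
validation Dice; ``predict`` runs inference (the region head is never
executed) with optional SCoLN correction.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .metrics import aggregate as aggregate_metrics
from .metrics import confusion as confusion_counts
from .metrics import metrics as seg_metrics
from .autodiff import Tensor, log_softmax, no_grad
from .data import ImageSample, split_folds
from .layers import Adadelta, Adam, Optimizer
from .losses import (CorrectionMaps, correction_maps, corrected_mask,
                     l1_seg_loss_t, scoln_contrastive_loss_t, two_c_loss_t)
from .networks import (Discriminator, Generator, GeneratorConfig, SCoLN,
                       SegResult, build_discriminator, build_generator,
                       build_scoln)
from .rebalance import RegionFrequencies, extract_regions, region_frequencies, region_loss_t

__all__ = [
    "TrainConfig",
    "TrainState",
    "CCGANNets",
    "build_nets",
    "train_step",
    "fit",
    "predict",
    "FitResult",
    "FoldResult",
]

_EPS = 1e-6


@dataclasses.dataclass
class TrainConfig:
    """Training hyper-parameters.

    Published-scale values are epochs=450, batch_size=32, Adadelta with
    lr=0.001 and weight decay 1e-4, temperature 3, five folds; the desk-scale
    epoch default is 30.
    """

    epochs: int = 30
    batch_size: int = 32
    lr: float = 0.001
    weight_decay: float = 1e-4
    temperature: float = 3.0
    optimizer: str = "adadelta"  # or "adam"
    early_stop_patience: int = 20
    seed: int = 0
    folds: int = 5
    lambda_l1: float = 1.0
    lambda_adv: float = 1.0
    region_weight: float = 1.0
    scoln_contrast_weight: float = 0.1
    threshold: float = 0.5
    ablation: frozenset[str] = frozenset()
    class_id_rule: str = "foreground_present"

    def __post_init__(self):
        bad = set(self.ablation) - {"attention", "rrm", "scoln"}
        if bad:
            raise ValueError(f"unknown ablation entries: {sorted(bad)}")
        for field in ("epochs", "batch_size", "temperature", "folds"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if self.lr < 0:  # lr=0 is allowed: it freezes learning (used by tests)
            raise ValueError("lr must be non-negative")


@dataclasses.dataclass
class TrainState:
    epoch: int = 0
    histories: dict = dataclasses.field(
        default_factory=lambda: {"discriminator": [], "generator": [], "scoln": []}
    )
    best_val_dsc: float = -np.inf
    epochs_since_improve: int = 0
    best_weights: dict | None = None


@dataclasses.dataclass
class CCGANNets:
    generator: Generator
    discriminator: Discriminator
    scoln: SCoLN
    frequencies: RegionFrequencies | None = None

    def train(self):
        for net in (self.generator, self.discriminator, self.scoln):
            net.train()

    def eval(self):
        for net in (self.generator, self.discriminator, self.scoln):
            net.eval()


def build_nets(cfg: TrainConfig, gen_cfg: GeneratorConfig, n_classes: int = 2) -> CCGANNets:
    """Build the three networks, honouring ablation flags, seeded from cfg.seed."""
    if "attention" in cfg.ablation:
        gen_cfg = dataclasses.replace(gen_cfg, attention_levels=frozenset())
    if "rrm" in cfg.ablation:
        gen_cfg = dataclasses.replace(gen_cfg, rrm_enabled=False)
    return CCGANNets(
        generator=build_generator(gen_cfg, n_classes, seed=cfg.seed),
        discriminator=build_discriminator(gen_cfg, n_classes, seed=cfg.seed + 1),
        scoln=build_scoln(gen_cfg, n_classes, seed=cfg.seed + 2),
    )


def make_optimizers(nets: CCGANNets, cfg: TrainConfig) -> dict[str, Optimizer]:
    def make(params):
        if cfg.optimizer == "adadelta":
            return Adadelta(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
        if cfg.optimizer == "adam":
            return Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    return {
        "discriminator": make(nets.discriminator.parameters()),
        "generator": make(nets.generator.parameters()),
        "scoln": make(nets.scoln.parameters()),
    }


# ---------------------------------------------------------------------------
# Batch plumbing


def _to_batch(samples: Sequence[ImageSample], n_classes: int):
    x = np.stack([s.image for s in samples]).astype(np.float32)
    masks = np.stack([s.mask for s in samples])
    onehot = np.eye(n_classes, dtype=np.float32)[masks]
    return Tensor(x), masks, Tensor(onehot)


def _image_labels(masks: np.ndarray, rule: str) -> np.ndarray:
    if rule != "foreground_present":
        raise ValueError(f"unknown class_id_rule {rule!r}")
    return (masks.reshape(len(masks), -1).max(axis=1) > 0).astype(np.int64)


def _bce(p: Tensor, target: Tensor | float) -> Tensor:
    p = p.clip(_EPS, 1.0 - _EPS)
    if isinstance(target, Tensor):
        return -(target * p.log() + (1.0 - target) * (1.0 - p).log()).mean()
    if target == 1.0:
        return -(p.log()).mean()
    if target == 0.0:
        return -((1.0 - p).log()).mean()
    raise ValueError("scalar target must be 0 or 1")


def _pixel_ce(logits: Tensor, onehot: Tensor) -> Tensor:
    logp = log_softmax(logits, axis=3)
    n, h, w, _ = logits.shape
    return -(logp * onehot).sum() * (1.0 / (n * h * w))


def _region_tiles(deepest: Tensor, masks: np.ndarray, region_size: int):
    """Tile deepest features into the grid induced by r x r mask regions."""
    n, hd, wd, c = deepest.shape
    h, w = masks.shape[1:]
    gh, gw = max(h // region_size, 1), max(w // region_size, 1)
    rf_h, rf_w = hd // gh, wd // gw
    if rf_h == 0 or rf_w == 0:
        raise ValueError(
            f"region size {region_size} too small for feature map {(hd, wd)}"
        )
    tiles = deepest.reshape(n, gh, rf_h, gw, rf_w, c)
    tiles = tiles.transpose(0, 1, 3, 2, 4, 5).reshape(n * gh * gw, rf_h, rf_w, c)
    labels = []
    for mask in masks:
        labels.extend(extract_regions(mask, None, region_size).labels)
    return tiles, np.asarray(labels)


def _check_finite(value: float, phase: str) -> float:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss in {phase} phase: {value}")
    return float(value)


# ---------------------------------------------------------------------------
# One optimisation step (all three phases)


def train_step(
    batch: Sequence[ImageSample],
    nets: CCGANNets,
    cfg: TrainConfig,
    state: TrainState,
    optimizers: dict[str, Optimizer] | None = None,
    phases: Sequence[str] = ("discriminator", "generator", "scoln"),
) -> TrainState:
    """Run the D -> G -> SCoLN phases on one batch, updating ``state`` in place.

    ``phases`` restricts which phases execute (tests use this to verify that a
    phase touches only its own network's parameters).
    """
    if not batch:
        raise ValueError("empty batch")
    if optimizers is None:
        optimizers = make_optimizers(nets, cfg)
    gen, disc, scoln = nets.generator, nets.discriminator, nets.scoln
    n_classes = gen.n_classes
    x, masks, onehot = _to_batch(batch, n_classes)
    labels = _image_labels(masks, cfg.class_id_rule)
    nets.train()

    def zero_all():
        for net in (gen, disc, scoln):
            net.zero_grad()

    # One generator forward serves all three phases: the live graph feeds the
    # G phase, a detached copy of its probabilities feeds D and SCoLN.
    logits, deepest = gen(x, return_features=True)
    prob = gen.probabilities(logits)
    fake_prob_const = Tensor(prob.data)

    # ---- phase 1: discriminator -------------------------------------------
    if "discriminator" in phases:
        zero_all()
        d_real, proj_real = disc(x, onehot)
        d_fake, _ = disc(x, fake_prob_const)
        loss_d = _bce(d_real, 1.0) + _bce(d_fake, 0.0)
        loss_d = loss_d + two_c_loss_t(proj_real, disc.class_embed, labels, cfg.temperature)
        loss_d.backward()
        optimizers["discriminator"].step()
        state.histories["discriminator"].append(
            _check_finite(loss_d.item(), "discriminator"))

    # ---- phase 2: generator ------------------------------------------------
    if "generator" not in phases:
        if "scoln" in phases and "scoln" not in cfg.ablation:
            _scoln_phase(nets, cfg, state, optimizers, x, masks, fake_prob_const)
        return state
    zero_all()
    d_on_fake, proj_fake = disc(x, prob)
    adv = _bce(d_on_fake, 1.0)  # non-saturating: G wants D to call it real
    two_c_gen = two_c_loss_t(proj_fake, disc.class_embed, labels, cfg.temperature)
    l1 = l1_seg_loss_t(prob, onehot)
    loss_g = cfg.lambda_adv * adv + two_c_gen + cfg.lambda_l1 * l1
    if gen.region_head is not None and nets.frequencies is not None:
        tiles, tile_labels = _region_tiles(deepest, masks, gen.cfg.region_size)
        region_logits = gen.region_head(tiles)
        loss_all = _pixel_ce(logits, onehot) + cfg.region_weight * region_loss_t(
            region_logits, tile_labels, nets.frequencies
        )
        loss_g = loss_g + loss_all
    loss_g.backward()
    optimizers["generator"].step()
    state.histories["generator"].append(_check_finite(loss_g.item(), "generator"))

    # ---- phase 3: SCoLN ----------------------------------------------------
    if "scoln" in phases and "scoln" not in cfg.ablation:
        _scoln_phase(nets, cfg, state, optimizers, x, masks, fake_prob_const)
    return state


def _scoln_phase(nets, cfg, state, optimizers, x, masks, fake_prob_const):
    gen, scoln = nets.generator, nets.scoln
    for net in (gen, nets.discriminator, scoln):
        net.zero_grad()
    gen_prob = fake_prob_const.data
    n_classes = gen.n_classes
    fg_prob = gen_prob[..., 1] if n_classes == 2 else 1.0 - gen_prob[..., 0]
    fg_truth = (masks > 0).astype(np.float32)
    target_fn = np.clip(fg_truth - fg_prob, 0.0, 1.0)
    target_fp = np.clip(fg_prob - fg_truth, 0.0, 1.0)
    fn_pred, fp_pred, emb = scoln(x, Tensor(gen_prob))
    loss_s = _bce(fn_pred, Tensor(target_fn)) + _bce(fp_pred, Tensor(target_fp))
    contrast = _scoln_contrast(emb, fg_prob, fg_truth, cfg)
    if contrast is not None:
        loss_s = loss_s + cfg.scoln_contrast_weight * contrast
    loss_s.backward()
    optimizers["scoln"].step()
    state.histories["scoln"].append(_check_finite(loss_s.item(), "scoln"))


def _scoln_contrast(emb: Tensor, fg_prob: np.ndarray, fg_truth: np.ndarray,
                    cfg: TrainConfig) -> Tensor | None:
    """Contrastive term over bottleneck embeddings.

    Samples are grouped by whether their pixel error exceeds the batch median
    (the pair-construction rule is not canonical; this quantile grouping is the
    package's choice, exposed via config elsewhere).  Needs two per group.
    """
    errors = np.abs(fg_prob - fg_truth).mean(axis=(1, 2))
    hi = errors > np.median(errors)
    if hi.sum() < 1 or (~hi).sum() < 2:
        return None
    total = None
    idx_all = np.arange(len(errors))
    for i in idx_all:
        same = (hi == hi[i]) & (idx_all != i)
        other = hi != hi[i]
        if same.sum() == 0 or other.sum() == 0:
            continue
        term = scoln_contrastive_loss_t(
            emb[int(i)], emb[np.flatnonzero(same)], emb[np.flatnonzero(other)]
        )
        total = term if total is None else total + term
    if total is None:
        return None
    return total * (1.0 / len(idx_all))


# ---------------------------------------------------------------------------
# Fitting with k-fold cross-validation


@dataclasses.dataclass
class FoldResult:
    fold: int
    nets: CCGANNets
    best_val_dsc: float
    epochs_run: int
    records: list[dict]
    histories: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class FitResult:
    folds: list[FoldResult]
    table: pd.DataFrame


def _batches(n: int, batch_size: int, rng: np.random.Generator) -> Iterable[np.ndarray]:
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def fit(
    dataset: list[ImageSample],
    cfg: TrainConfig,
    gen_cfg: GeneratorConfig | None = None,
    folds_to_run: Sequence[int] | None = None,
    verbose: bool = False,
) -> FitResult:
    """k-fold cross-validated training with early stopping on validation Dice."""
    if len(dataset) < cfg.folds:
        raise ValueError(f"dataset of {len(dataset)} samples cannot fill {cfg.folds} folds")
    if gen_cfg is None:
        gen_cfg = GeneratorConfig(in_channels=dataset[0].image.shape[2])
    if any(s.fold < 0 for s in dataset):
        dataset = split_folds(dataset, cfg.folds, cfg.seed)
    n_classes = max(2, max(int(s.mask.max()) for s in dataset) + 1)
    fold_ids = sorted({s.fold for s in dataset})
    if folds_to_run is not None:
        fold_ids = [f for f in fold_ids if f in set(folds_to_run)]
    results: list[FoldResult] = []
    all_records: list[dict] = []
    for fold in fold_ids:
        train_set = [s for s in dataset if s.fold != fold]
        val_set = [s for s in dataset if s.fold == fold]
        if not train_set or not val_set:
            raise ValueError(f"fold {fold} yields an empty train or validation split")
        fold_cfg = dataclasses.replace(cfg, seed=cfg.seed + 1000 * fold)
        nets = build_nets(fold_cfg, gen_cfg, n_classes)
        if nets.generator.region_head is not None:
            nets.frequencies = region_frequencies(
                [s.mask for s in train_set], r=gen_cfg.region_size,
                n_classes=n_classes,
            )  # training fold only: no leakage into validation
        optimizers = make_optimizers(nets, fold_cfg)
        state = TrainState()
        rng = np.random.default_rng(fold_cfg.seed + 500_000)
        for epoch in range(cfg.epochs):
            state.epoch = epoch
            for idx in _batches(len(train_set), cfg.batch_size, rng):
                if len(idx) < 2:
                    continue  # batch statistics need at least two samples
                train_step([train_set[i] for i in idx], nets, fold_cfg, state, optimizers)
            val_dsc = _validate(nets, val_set, cfg)
            if verbose:
                print(f"fold {fold} epoch {epoch}: val DSC {val_dsc:.4f}")
            if val_dsc > state.best_val_dsc + 1e-6:
                state.best_val_dsc = val_dsc
                state.epochs_since_improve = 0
                state.best_weights = {
                    "generator": nets.generator.state_dict(),
                    "discriminator": nets.discriminator.state_dict(),
                    "scoln": nets.scoln.state_dict(),
                }
            else:
                state.epochs_since_improve += 1
                if state.epochs_since_improve >= cfg.early_stop_patience:
                    break
        if state.best_weights is not None:
            nets.generator.load_state_dict(state.best_weights["generator"])
            nets.discriminator.load_state_dict(state.best_weights["discriminator"])
            nets.scoln.load_state_dict(state.best_weights["scoln"])
        records = _evaluate(nets, val_set, cfg)
        all_records.extend(records)
        results.append(FoldResult(fold, nets, state.best_val_dsc, state.epoch + 1,
                                  records, state.histories))
    table = aggregate_metrics(all_records, [r["fold"] for r in all_records])
    return FitResult(results, table)


def _validate(nets: CCGANNets, val_set: list[ImageSample], cfg: TrainConfig) -> float:
    use_corr = "scoln" not in cfg.ablation
    preds = predict(nets.generator, nets.scoln, val_set, use_correction=use_corr,
                    threshold=cfg.threshold)
    scores = [
        seg_metrics(confusion_counts(p.mask, (s.mask > 0).astype(int)))["dice"]
        for p, s in zip(preds, val_set)
    ]
    return float(np.mean(scores))


def _evaluate(nets: CCGANNets, val_set: list[ImageSample], cfg: TrainConfig) -> list[dict]:
    use_corr = "scoln" not in cfg.ablation
    preds = predict(nets.generator, nets.scoln, val_set, use_correction=use_corr,
                    threshold=cfg.threshold)
    records = []
    for p, s in zip(preds, val_set):
        rec = seg_metrics(confusion_counts(p.mask, (s.mask > 0).astype(int)))
        rec.update(id=s.id, fold=s.fold)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Inference


def predict(
    gen: Generator,
    scoln: SCoLN | None,
    samples: Sequence[ImageSample],
    use_correction: bool = True,
    threshold: float = 0.5,
    batch_size: int = 16,
) -> list[SegResult]:
    """Segment samples; the region head never runs, SCoLN correction optional."""
    gen.eval()
    if scoln is not None:
        scoln.eval()
    div = 2**gen.cfg.levels
    results: list[SegResult] = []
    for start in range(0, len(samples), batch_size):
        chunk = list(samples[start : start + batch_size])
        h, w = chunk[0].mask.shape
        ph, pw = (-h) % div, (-w) % div
        if ph >= div or pw >= div:
            raise ValueError("padding would exceed one downsampling stride")
        x = np.stack([s.image for s in chunk]).astype(np.float32)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="edge")
        with no_grad():
            xt = Tensor(x)
            prob = gen.probabilities(gen(xt)).data
            if use_correction and scoln is not None:
                fn_map, fp_map, _ = scoln(xt, Tensor(prob))
                fn_map, fp_map = fn_map.data, fp_map.data
        prob = prob[:, :h, :w, :]
        for i, s in enumerate(chunk):
            p = prob[i]
            if gen.n_classes == 2:
                fg = p[..., 1]
                if use_correction and scoln is not None:
                    maps = CorrectionMaps(fn_map[i, :h, :w], fp_map[i, :h, :w])
                    mask = corrected_mask(np.clip(fg, 0, 1), maps, threshold)
                else:
                    maps = None
                    mask = (fg >= threshold).astype(np.int64)
            else:
                maps = None
                mask = p.argmax(axis=2).astype(np.int64)
            results.append(SegResult(prob=p, mask=mask, correction=maps, id=s.id))
    return results
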