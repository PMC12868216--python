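"""Training loop: Jaccard loss, cosine annealing, epoch aggregation,
checkpointing, and CSV logging.

Epoch metrics use micro-aggregation: per-class intersection and union
counts are accumulated across every batch of the epoch and divided once
at the end, which is stable against batch-size effects.
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import VERSION_STRING
from .dataset import (
    AugmentationPolicy,
    PatchSpec,
    SplitPlan,
    augment_geometric,
    augment_intensity,
    draw_intensity_params,
    sample_patch_origins,
)
from .models import ModelSpec, build_model
from .nn import Adam, TinyUNet
from .volume_io import LabelMask, NormalizationStats, ScanVolume, compute_norm_stats, normalize

#: Smoothing constant of the soft Jaccard loss (library-default style).
JACCARD_SMOOTH = 1.0


@dataclass
class FitConfig:
    epochs: int = 25
    batch_size: int = 64
    lr0: float = 0.001
    lr_min: float = 0.0
    optimizer: str = "adam"
    loss: str = "jaccard"
    normalization: str = "zscore"
    patch: PatchSpec = field(default_factory=PatchSpec)
    augment: bool = True
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    ce_warmup_epochs: int = 1
    seed: int = 42
    deterministic: bool = True
    mixed_precision: bool = False  # pass-through flag; CPU path is float32
    fit_mode: str = "2D"  # "2.5D"/"3D" accepted in config but not implemented
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "jaccard":
            raise ValueError("only jaccard loss is supported")
        if self.ce_warmup_epochs < 0:
            raise ValueError("ce_warmup_epochs must be >= 0")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_miou: float
    val_loss: float
    val_miou: float
    lr: float
    improved: bool

    def __post_init__(self) -> None:
        for name in ("train_loss", "val_loss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("train_miou", "val_miou"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class Checkpoint:
    """Model weights plus the metadata needed to reuse them for prediction."""

    weights: dict[str, np.ndarray]
    metadata: dict

    REQUIRED_META = ("architecture", "backbone", "fit_mode", "normalization",
                     "patch_px", "version")


def save_checkpoint(ckpt: Checkpoint, path: str | os.PathLike) -> None:
    """Weights and JSON metadata bundled into one ``.npz`` file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __metadata__=json.dumps(ckpt.metadata), **ckpt.weights)


def load_checkpoint(path: str | os.PathLike) -> Checkpoint:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__metadata__"]))
        weights = {k: data[k] for k in data.files if k != "__metadata__"}
    return Checkpoint(weights=weights, metadata=meta)


def model_from_checkpoint(ckpt: Checkpoint):
    """Rebuild the model described by checkpoint metadata and load weights."""
    missing = [k for k in Checkpoint.REQUIRED_META if k not in ckpt.metadata]
    if missing:
        raise ValueError(f"checkpoint metadata incomplete, missing {missing}")
    if ckpt.metadata["architecture"] != "tiny_unet":
        raise ValueError(
            f"cannot rebuild architecture {ckpt.metadata['architecture']!r} without torch"
        )
    model = TinyUNet(
        in_channels=ckpt.metadata.get("in_channels", 1),
        n_classes=ckpt.metadata.get("n_classes", 3),
        base_channels=ckpt.metadata.get("base_channels", 16),
    )
    model.load_state_dict(ckpt.weights)
    return model


# ---------------------------------------------------------------------------
# loss and schedule
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def soft_jaccard_loss(probs: np.ndarray, target_onehot: np.ndarray,
                      smooth: float = JACCARD_SMOOTH) -> float:
    """``1 - mean_c (<p,t> + s) / (sum p + sum t - <p,t> + s)``.

    *probs* are per-class probabilities (sum to 1 over the class axis) of
    shape ``(N, C, H, W)``; *target_onehot* has the same shape. Zero at a
    perfect hard match.
    """
    if probs.shape != target_onehot.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {target_onehot.shape}")
    axes = (0, 2, 3)
    inter = (probs * target_onehot).sum(axis=axes)
    union = probs.sum(axis=axes) + target_onehot.sum(axis=axes) - inter
    return float(1.0 - np.mean((inter + smooth) / (union + smooth)))


def _cross_entropy_grad(probs: np.ndarray, target_onehot: np.ndarray) -> np.ndarray:
    """Per-pixel cross-entropy gradient w.r.t. logits.

    Used only as an optional warmup gradient: a pure region loss applied
    from random initialization on few CPU steps entrenches early
    confident errors (saturated softmax pixels receive vanishing
    probability-space gradients); a brief cross-entropy warmup avoids
    that, after which the Jaccard objective takes over.
    """
    n_px = probs[:, 0].size
    return ((probs - target_onehot) / n_px).astype(np.float32)


def _jaccard_loss_and_grad(logits: np.ndarray, target_onehot: np.ndarray,
                           smooth: float = JACCARD_SMOOTH) -> tuple[float, np.ndarray]:
    """Loss plus its gradient w.r.t. the logits (softmax included)."""
    p = softmax(logits)
    t = target_onehot
    axes = (0, 2, 3)
    inter = (p * t).sum(axis=axes)
    union = p.sum(axis=axes) + t.sum(axis=axes) - inter
    num = inter + smooth
    den = union + smooth
    loss = float(1.0 - np.mean(num / den))
    c = logits.shape[1]
    # d/dp of -(1/C) * num/den, with dI/dp = t and dU/dp = 1 - t
    num_b = num[None, :, None, None]
    den_b = den[None, :, None, None]
    dp = -(t * den_b - num_b * (1.0 - t)) / (c * den_b * den_b)
    dz = p * (dp - (dp * p).sum(axis=1, keepdims=True))
    return loss, dz.astype(np.float32)


def cosine_lr(t: int, epochs: int, lr0: float, lr_min: float = 0.0) -> float:
    """Single-cycle cosine annealing without restarts, stepped per epoch."""
    if not 0 <= t <= epochs:
        raise ValueError("epoch index out of range")
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * t / epochs))


# ---------------------------------------------------------------------------
# epoch aggregation
# ---------------------------------------------------------------------------

class _IoUAccumulator:
    """Micro-aggregated per-class intersection/union counts."""

    def __init__(self, n_classes: int = 3):
        self.inter = np.zeros(n_classes, dtype=np.int64)
        self.union = np.zeros(n_classes, dtype=np.int64)

    def update(self, pred: np.ndarray, target: np.ndarray) -> None:
        for c in range(len(self.inter)):
            pc, tc = pred == c, target == c
            self.inter[c] += int(np.logical_and(pc, tc).sum())
            self.union[c] += int(np.logical_or(pc, tc).sum())

    def miou(self) -> float:
        present = self.union > 0
        if not present.any():
            return 1.0
        return float(np.mean(self.inter[present] / self.union[present]))


# ---------------------------------------------------------------------------
# patch pipeline helpers
# ---------------------------------------------------------------------------

def _reflect_pad_to(tile: np.ndarray, size: int) -> np.ndarray:
    py, px = max(size - tile.shape[0], 0), max(size - tile.shape[1], 0)
    if py or px:
        tile = np.pad(tile, ((0, py), (0, px)), mode="reflect")
    return tile


def _tile_patches(scan_tile, mask_tile, stats: NormalizationStats, spec: PatchSpec,
                  augment: bool, policy: AugmentationPolicy, rng) -> list:
    p = spec.patch_px
    scan_tile = _reflect_pad_to(scan_tile, p)
    mask_tile = _reflect_pad_to(mask_tile, p)
    out = []
    for y, x in sample_patch_origins(scan_tile.shape, spec, rng):
        sp = normalize(scan_tile[y:y + p, x:x + p], stats)
        mp = mask_tile[y:y + p, x:x + p]
        if augment:
            sp, mp, _ = augment_geometric(sp, mp, policy, rng)
        out.append((sp, mp))
    return out


def _one_hot(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    n, h, w = labels.shape
    out = np.zeros((n, n_classes, h, w), dtype=np.float32)
    for c in range(n_classes):
        out[:, c][labels == c] = 1.0
    return out


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

def fit(
    pool: list[tuple[ScanVolume, LabelMask]],
    split: SplitPlan,
    spec: ModelSpec,
    cfg: FitConfig,
) -> tuple[Checkpoint, list[EpochRecord]]:
    """Train a model on *pool* under the scan-level *split*.

    Per epoch: training tiles are shuffled and consumed without
    replacement with augmentation; validation runs on held-out scans
    without augmentation; metrics are micro-aggregated; the best
    checkpoint is rewritten whenever validation mIoU improves; the cosine
    schedule steps at epoch end. Returns the best checkpoint and one
    :class:`EpochRecord` per epoch.
    """
    if cfg.fit_mode != "2D":
        raise NotImplementedError(f"fit_mode {cfg.fit_mode!r} is not implemented (2D only)")
    by_id = {vol.scan_id: (vol, mask) for vol, mask in pool}
    if len(by_id) != len(pool):
        raise ValueError("duplicate scan ids in pool")
    for vol, mask in pool:
        if vol.shape != mask.shape:
            raise ValueError(f"scan/mask shape mismatch for {vol.scan_id}")
    missing = (set(split.train_ids) | set(split.val_ids)) - set(by_id)
    if missing:
        raise ValueError(f"split references scans not in pool: {sorted(missing)}")

    stats = {sid: compute_norm_stats(by_id[sid][0], cfg.normalization) for sid in by_id}

    model = build_model(spec, seed=cfg.seed)
    if not isinstance(model, TinyUNet):
        raise NotImplementedError("the NumPy fitting loop supports tiny_unet only")
    opt = Adam(model.parameters(), lr=cfg.lr0)

    root = np.random.SeedSequence(cfg.seed)
    train_rng = np.random.default_rng(root.spawn(1)[0])
    val_rng_seq = root.spawn(1)[0]

    n_classes = spec.n_classes
    records: list[EpochRecord] = []
    best = Checkpoint(
        weights={k: v.copy() for k, v in model.state_dict().items()},
        metadata=_checkpoint_metadata(model, spec, cfg),
    )
    best_miou = -1.0
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    log_rows: list[str] = []

    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg.epochs, cfg.lr0, cfg.lr_min)
        opt.lr = lr

        train_loss, train_miou = _run_epoch(
            model, opt, by_id, stats, split.train_ids, cfg, train_rng,
            n_classes, training=True,
            warmup=epoch < cfg.ce_warmup_epochs,
        )
        # validation patches are re-drawn deterministically per epoch
        val_rng = np.random.default_rng(np.random.SeedSequence(
            entropy=val_rng_seq.entropy, spawn_key=(*val_rng_seq.spawn_key, epoch)))
        val_loss, val_miou = _run_epoch(
            model, None, by_id, stats, split.val_ids, cfg, val_rng,
            n_classes, training=False,
        )

        improved = val_miou > best_miou
        if improved:
            best_miou = val_miou
            best = Checkpoint(
                weights={k: v.copy() for k, v in model.state_dict().items()},
                metadata=_checkpoint_metadata(model, spec, cfg),
            )
        rec = EpochRecord(epoch, train_loss, train_miou, val_loss, val_miou, lr, improved)
        records.append(rec)
        log_rows.append(
            f"{epoch},{train_loss:.6f},{train_miou:.6f},{val_loss:.6f},"
            f"{val_miou:.6f},{lr:.8f},{int(improved)}"
        )

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(best, out_dir / "best.npz")
        final = Checkpoint(
            weights={k: v.copy() for k, v in model.state_dict().items()},
            metadata=_checkpoint_metadata(model, spec, cfg),
        )
        save_checkpoint(final, out_dir / "final.npz")
        write_epoch_log(out_dir / "fit_log.csv", log_rows, cfg, spec, split)
    return best, records


def _run_epoch(model, opt, by_id, stats, scan_ids, cfg: FitConfig, rng,
               n_classes: int, training: bool, warmup: bool = False) -> tuple[float, float]:
    if not scan_ids:
        raise ValueError("empty scan set for epoch")
    tiles = [(sid, z) for sid in scan_ids for z in range(by_id[sid][0].n_tiles)]
    if training:
        rng.shuffle(tiles)
    acc = _IoUAccumulator(n_classes)
    loss_sum, n_batches = 0.0, 0
    buf: list = []
    augment = cfg.augment and training

    def flush(buf):
        nonlocal loss_sum, n_batches
        xs = np.stack([s for s, _ in buf])[:, None].astype(np.float32)
        ys = np.stack([m for _, m in buf]).astype(np.int64)
        if augment:
            params = draw_intensity_params(cfg.augmentation, rng)
            xs = augment_intensity(xs, cfg.augmentation, cfg.normalization, params=params)
        target = _one_hot(ys, n_classes)
        if training:
            logits = model.forward(xs, train=True)
            loss, dlogits = _jaccard_loss_and_grad(logits, target)
            if warmup:
                dlogits = _cross_entropy_grad(softmax(logits), target)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at batch {n_batches}; aborting fit"
                )
            model.backward(dlogits)
            opt.step()
        else:
            logits = model.forward(xs, train=False)
            loss = soft_jaccard_loss(softmax(logits), target)
        acc.update(np.argmax(logits, axis=1), ys)
        loss_sum += loss
        n_batches += 1

    for sid, z in tiles:
        vol, mask = by_id[sid]
        buf.extend(_tile_patches(vol.voxels[z], mask.labels[z], stats[sid],
                                 cfg.patch, augment, cfg.augmentation, rng))
        while len(buf) >= cfg.batch_size:
            flush(buf[:cfg.batch_size])
            buf = buf[cfg.batch_size:]
    if buf:
        flush(buf)
    return loss_sum / max(n_batches, 1), acc.miou()


def _checkpoint_metadata(model: TinyUNet, spec: ModelSpec, cfg: FitConfig) -> dict:
    return {
        "architecture": spec.architecture,
        "backbone": spec.backbone,
        "fit_mode": cfg.fit_mode,
        "normalization": cfg.normalization,
        "patch_px": cfg.patch.patch_px,
        "in_channels": spec.in_channels,
        "n_classes": spec.n_classes,
        "base_channels": model.base_channels,
        "hyperparameters": {
            "epochs": cfg.epochs,
            "batch_size": cfg.batch_size,
            "lr0": cfg.lr0,
            "optimizer": cfg.optimizer,
            "loss": cfg.loss,
            "seed": cfg.seed,
        },
        "version": VERSION_STRING,
    }


def write_epoch_log(path: str | os.PathLike, rows: list[str], cfg: FitConfig,
                    spec: ModelSpec, split: SplitPlan) -> None:
    """CSV epoch log with a commented header carrying the version string."""
    buf = io.StringIO()
    buf.write(f"# osteoseg {VERSION_STRING}\n")
    buf.write(f"# model: {spec.architecture}/{spec.backbone}\n")
    cfg_echo = {k: v for k, v in asdict(cfg).items() if k not in ("augmentation",)}
    buf.write(f"# config: {json.dumps(cfg_echo, default=str)}\n")
    buf.write(f"# split: train={list(split.train_ids)} val={list(split.val_ids)} "
              f"seed={split.seed}\n")
    buf.write("epoch,train_loss,train_miou,val_loss,val_miou,lr,improved\n")
    for row in rows:
        buf.write(row + "\n")
    Path(path).write_text(buf.getvalue())
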