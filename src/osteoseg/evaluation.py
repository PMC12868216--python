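"""Class-wise and mean IoU, Dice conversion, and cross-validation
orchestration."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .dataset import FoldPlan, split_scans
from .fitting import FitConfig, fit
from .models import ModelSpec
from .prediction import predict_volume
from .volume_io import LabelMask, ScanVolume


@dataclass
class IoUReport:
    per_class_iou: dict[int, float]
    miou: float
    per_class_dice: dict[int, float]
    mdice: float
    class_set_used: str

    def __post_init__(self) -> None:
        for c, v in self.per_class_iou.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"IoU for class {c} out of [0, 1]: {v}")


def confusion_counts(ref: LabelMask | np.ndarray, pred: LabelMask | np.ndarray,
                     n_classes: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Per-class (intersection, union) voxel counts between two masks."""
    r = ref.labels if isinstance(ref, LabelMask) else np.asarray(ref)
    p = pred.labels if isinstance(pred, LabelMask) else np.asarray(pred)
    if r.shape != p.shape:
        raise ValueError(f"mask shape mismatch: {r.shape} vs {p.shape}")
    inter = np.zeros(n_classes, dtype=np.int64)
    union = np.zeros(n_classes, dtype=np.int64)
    for c in range(n_classes):
        rc, pc = r == c, p == c
        inter[c] = int(np.logical_and(rc, pc).sum())
        union[c] = int(np.logical_or(rc, pc).sum())
    return inter, union


def confusion_counts_reference(ref, pred, n_classes: int = 3):
    """Slow set-arithmetic implementation used as an independent check.

    Mirrors the dual compute paths of the original (device tensor vs
    plain array): counts must agree bit-wise with :func:`confusion_counts`.
    """
    r = (ref.labels if isinstance(ref, LabelMask) else np.asarray(ref)).ravel()
    p = (pred.labels if isinstance(pred, LabelMask) else np.asarray(pred)).ravel()
    inter = np.zeros(n_classes, dtype=np.int64)
    union = np.zeros(n_classes, dtype=np.int64)
    for c in range(n_classes):
        rset = {i for i, v in enumerate(r) if v == c}
        pset = {i for i, v in enumerate(p) if v == c}
        inter[c] = len(rset & pset)
        union[c] = len(rset | pset)
    return inter, union


def iou_to_dice(iou: float, ndigits: int | None = None) -> float:
    """Jaccard-to-Dice identity ``2x / (1 + x)``.

    *ndigits* applies half-up decimal rounding for reporting (tables use 4).
    """
    if not 0.0 <= iou <= 1.0:
        raise ValueError(f"iou must be in [0, 1], got {iou}")
    dice = 2.0 * iou / (1.0 + iou)
    if ndigits is not None:
        dice = round_half_up(dice, ndigits)
    return dice


def round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def iou_report(ref: LabelMask | np.ndarray, pred: LabelMask | np.ndarray,
               class_set: str = "all_classes", n_classes: int = 3) -> IoUReport:
    """Per-class IoU plus the unweighted mean over *class_set*.

    Classes absent from both masks (union 0) are excluded from per-class
    results and from the mean — 0/0 is undefined, and a scan without
    pores should not be penalized. ``class_set`` is ``all_classes``
    (default, includes background) or ``foreground_only``.
    """
    if class_set not in ("all_classes", "foreground_only"):
        raise ValueError(f"unknown class_set {class_set!r}")
    inter, union = confusion_counts(ref, pred, n_classes)
    per_class = {c: float(inter[c] / union[c]) for c in range(n_classes) if union[c] > 0}
    mean_classes = [c for c in per_class if class_set == "all_classes" or c != 0]
    if not mean_classes:
        raise ValueError("no classes present for the requested class set")
    miou = float(np.mean([per_class[c] for c in mean_classes]))
    per_dice = {c: iou_to_dice(v) for c, v in per_class.items()}
    mdice = float(np.mean([per_dice[c] for c in mean_classes]))
    return IoUReport(
        per_class_iou=per_class,
        miou=miou,
        per_class_dice=per_dice,
        mdice=mdice,
        class_set_used=class_set,
    )


@dataclass
class CrossValSummary:
    """Scan-level mIoU bookkeeping across folds and seeds."""

    scan_mious: dict[tuple[int, int, str], float]  # (fold, seed, scan_id) -> mIoU
    fold_stats: dict[tuple[int, int], tuple[float, float]]  # (fold, seed) -> (mean, sd)
    grand_mean: float
    grand_sd: float
    k: int
    seeds: tuple[int, ...] = field(default_factory=tuple)


def summarize_fold_table(fold_means: dict[tuple[int, int], float]) -> tuple[float, float]:
    """Grand mean +/- sample SD over all (fold, seed) mean mIoUs."""
    values = np.array(list(fold_means.values()), dtype=np.float64)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return float(values.mean()), sd


def cross_validate(
    scans: list[tuple[ScanVolume, LabelMask]],
    fold_plan: FoldPlan,
    seeds: list[int],
    spec: ModelSpec,
    cfg: FitConfig,
    train_fraction: float = 0.75,
    chunk_px: int = 64,
    threshold: float = 0.5,
    class_set: str = "all_classes",
) -> CrossValSummary:
    """Fit and evaluate one model per (fold, seed) combination.

    For each pair: the fold's pool is split internally at the scan level,
    a model is fitted, every test scan is predicted and scored once, and
    the fold statistic is the mean +/- SD over its test scans. The grand
    statistic aggregates all fold x seed means.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    by_id = {vol.scan_id: (vol, mask) for vol, mask in scans}
    missing = set(fold_plan.ordered_ids) - set(by_id)
    if missing:
        raise ValueError(f"fold plan references unknown scans: {sorted(missing)}")

    scan_mious: dict[tuple[int, int, str], float] = {}
    fold_stats: dict[tuple[int, int], tuple[float, float]] = {}
    for seed in seeds:
        for fold in range(fold_plan.k):
            try:
                pool_ids = fold_plan.pool_ids(fold)
                split = split_scans(list(pool_ids), train_fraction, seed)
                pool = [by_id[sid] for sid in pool_ids]
                run_cfg = FitConfig(**{**cfg.__dict__, "seed": seed, "out_dir": None})
                ckpt, _ = fit(pool, split, spec, run_cfg)
                fold_values = []
                for sid in fold_plan.test_ids(fold):
                    vol, ref = by_id[sid]
                    pred, _ = predict_volume(ckpt, vol, chunk_px=chunk_px,
                                             threshold=threshold)
                    miou = iou_report(ref, pred, class_set=class_set).miou
                    scan_mious[(fold, seed, sid)] = miou
                    fold_values.append(miou)
                arr = np.array(fold_values)
                sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
                fold_stats[(fold, seed)] = (float(arr.mean()), sd)
            except Exception as exc:
                raise RuntimeError(f"cross-validation failed at fold={fold} seed={seed}") from exc

    grand_mean, grand_sd = summarize_fold_table(
        {k: v[0] for k, v in fold_stats.items()}
    )
    return CrossValSummary(
        scan_mious=scan_mious,
        fold_stats=fold_stats,
        grand_mean=grand_mean,
        grand_sd=grand_sd,
        k=fold_plan.k,
        seeds=tuple(seeds),
    )
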