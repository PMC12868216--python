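"""Scan-level splitting, k-fold partitioning, patch sampling, augmentation.

Splitting operates on whole scans, never on slices, so no slice of a
validation scan can leak into training batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Raised for invalid split/fold/patch configuration."""


@dataclass(frozen=True)
class SplitPlan:
    """Scan-level train/validation assignment."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    requested_fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.val_ids)
        if overlap:
            raise ConfigurationError(f"scan ids in both train and val: {sorted(overlap)}")
        if not self.train_ids or not self.val_ids:
            raise ConfigurationError("train and validation sets must both be non-empty")


@dataclass(frozen=True)
class FoldPlan:
    """Ordered k-fold partition: consecutive equal-size blocks of a fixed order."""

    ordered_ids: tuple[str, ...]
    k: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")
        if len(self.ordered_ids) % self.k != 0:
            raise ConfigurationError(
                f"k={self.k} does not divide the number of scans ({len(self.ordered_ids)})"
            )

    @property
    def fold_size(self) -> int:
        return len(self.ordered_ids) // self.k

    def test_ids(self, fold_index: int) -> tuple[str, ...]:
        """Test scans of fold *fold_index* (0-based): block i of the fixed order."""
        s = self.fold_size
        return self.ordered_ids[fold_index * s:(fold_index + 1) * s]

    def pool_ids(self, fold_index: int) -> tuple[str, ...]:
        """Training/validation pool: the ordered complement of the test fold."""
        test = set(self.test_ids(fold_index))
        return tuple(sid for sid in self.ordered_ids if sid not in test)


@dataclass(frozen=True)
class PatchSpec:
    patch_px: int = 256
    patches_per_tile: int = 4
    max_overlap: float = 1.0

    def __post_init__(self) -> None:
        if self.patch_px < 1 or self.patches_per_tile < 1:
            raise ConfigurationError("patch_px and patches_per_tile must be >= 1")
        if not 0.0 <= self.max_overlap <= 1.0:
            raise ConfigurationError("max_overlap must be in [0, 1]")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Default augmentation probabilities.

    Geometric branches are mutually exclusive (one uniform draw against
    cumulative thresholds): horizontal flip 16.6%, vertical flip 16.6%,
    90/180/270-degree rotation 50%, no-op 16.8%. Intensity transforms are
    independent: contrast rescale and brightness shift each 40%.
    """

    p_hflip: float = 0.166
    p_vflip: float = 0.166
    p_rot90s: float = 0.5
    p_none: float = 0.168
    p_brightness: float = 0.4
    p_contrast: float = 0.4
    shift_range: tuple[float, float] = (-0.15, 0.15)
    scale_range: tuple[float, float] = (0.75, 1.25)

    def __post_init__(self) -> None:
        total = self.p_hflip + self.p_vflip + self.p_rot90s + self.p_none
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"geometric branch probabilities sum to {total}, expected 1")


def split_scans(ids: list[str], fraction: float, seed: int) -> SplitPlan:
    """Shuffle scan ids and split them train/val as close to *fraction* as possible.

    The training count is ``clamp(round(N * fraction), 1, N - 1)``, which
    minimizes ``|count/N - fraction|`` while keeping both sets non-empty.
    """
    ids = list(ids)
    if len(ids) < 2:
        raise ConfigurationError("need at least 2 scans to split")
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate scan ids")
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n = len(order)
    n_train = int(np.clip(round(n * fraction), 1, n - 1))
    return SplitPlan(
        train_ids=tuple(order[:n_train]),
        val_ids=tuple(order[n_train:]),
        requested_fraction=fraction,
        seed=seed,
    )


def build_folds(ordered_ids: list[str], k: int) -> FoldPlan:
    """Partition an already fixed scan order into k consecutive test folds."""
    return FoldPlan(ordered_ids=tuple(ordered_ids), k=k)


def _overlap_fraction(a: tuple[int, int], b: tuple[int, int], patch_px: int) -> float:
    dy = max(0, patch_px - abs(a[0] - b[0]))
    dx = max(0, patch_px - abs(a[1] - b[1]))
    return (dy * dx) / float(patch_px * patch_px)


#: Rejection-sampling retry budget per patch origin.
MAX_ORIGIN_RETRIES = 200


def sample_patch_origins(
    tile_shape: tuple[int, int],
    spec: PatchSpec,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Draw ``patches_per_tile`` top-left origins for square patches.

    Pairwise patch-area overlap is kept below ``spec.max_overlap`` by
    rejection sampling (up to 200 retries per origin); when the constraint
    is unsatisfiable (e.g. patch fills the tile) the last candidate is
    accepted and a warning is emitted. Identical origins must be applied to
    the scan patch and its mask patch.
    """
    h, w = tile_shape
    p = spec.patch_px
    max_y, max_x = max(h - p, 0), max(w - p, 0)
    origins: list[tuple[int, int]] = []
    for _ in range(spec.patches_per_tile):
        candidate = None
        for attempt in range(MAX_ORIGIN_RETRIES):
            candidate = (int(rng.integers(0, max_y + 1)), int(rng.integers(0, max_x + 1)))
            if all(_overlap_fraction(candidate, o, p) <= spec.max_overlap for o in origins):
                break
        else:
            warnings.warn(
                f"patch overlap constraint {spec.max_overlap} unsatisfiable after "
                f"{MAX_ORIGIN_RETRIES} retries; accepting origin {candidate}",
                stacklevel=2,
            )
        origins.append(candidate)
    return origins


def _draw_geometric_branch(policy: AugmentationPolicy, rng: np.random.Generator) -> str:
    """One uniform draw against cumulative branch thresholds."""
    u = rng.random()
    if u < policy.p_hflip:
        return "hflip"
    if u < policy.p_hflip + policy.p_vflip:
        return "vflip"
    if u < policy.p_hflip + policy.p_vflip + policy.p_rot90s:
        return "rot"
    return "none"


def augment_geometric(
    scan_patch: np.ndarray,
    mask_patch: np.ndarray,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Apply exactly one geometric branch, identically to scan and mask.

    Rotation is restricted to 90-degree increments so the mask is never
    interpolated. Returns the transformed pair and the branch name.
    """
    if scan_patch.shape[-2] != scan_patch.shape[-1]:
        raise ValueError("geometric augmentation requires square patches")
    branch = _draw_geometric_branch(policy, rng)
    if branch == "hflip":
        out = (scan_patch[..., :, ::-1], mask_patch[..., :, ::-1])
    elif branch == "vflip":
        out = (scan_patch[..., ::-1, :], mask_patch[..., ::-1, :])
    elif branch == "rot":
        turns = int(rng.integers(1, 4))  # 90, 180, or 270 degrees, uniform
        out = (
            np.rot90(scan_patch, turns, axes=(-2, -1)),
            np.rot90(mask_patch, turns, axes=(-2, -1)),
        )
    else:
        out = (scan_patch, mask_patch)
    return np.ascontiguousarray(out[0]), np.ascontiguousarray(out[1]), branch


#: Clip range per normalization mode: minmax data lives in [0, 1]; z-scored
#: data has no hard bound, so a generous symmetric window is used.
_CLIP_RANGE = {"minmax": (0.0, 1.0), "zscore": (-5.0, 5.0)}


def draw_intensity_params(
    policy: AugmentationPolicy, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw the (scale, shift) pair shared by all scan patches of one batch.

    Contrast rescale and brightness shift fire independently (each with
    probability 0.4); a transform that does not fire contributes the
    identity (scale 1, shift 0).
    """
    scale = 1.0
    shift = 0.0
    if rng.random() < policy.p_contrast:
        scale = float(rng.uniform(*policy.scale_range))
    if rng.random() < policy.p_brightness:
        shift = float(rng.uniform(*policy.shift_range))
    return scale, shift


def augment_intensity(
    norm_patch: np.ndarray,
    policy: AugmentationPolicy,
    mode: str,
    rng: np.random.Generator | None = None,
    *,
    params: tuple[float, float] | None = None,
) -> np.ndarray:
    """Contrast-then-brightness intensity augmentation of a normalized patch.

    ``x -> clip(x * scale + shift)`` with the clip window set by the
    normalization mode. Masks are never intensity-augmented. Pass *params*
    to reuse one (scale, shift) draw across a batch.
    """
    if params is None:
        if rng is None:
            raise ValueError("either rng or params must be given")
        params = draw_intensity_params(policy, rng)
    scale, shift = params
    lo, hi = _CLIP_RANGE[mode]
    return np.clip(np.asarray(norm_patch, dtype=np.float32) * scale + shift, lo, hi)


def patches_per_epoch(
    plan_or_pool: SplitPlan | list[str] | tuple[str, ...],
    tile_counts: dict[str, int],
    per_tile: int,
) -> tuple[int, int, int]:
    """Patch bookkeeping: ``per_tile`` random patches from every 2D tile.

    Returns ``(n_train, n_val, n_total)``; for a plain pool of ids everything
    counts as training. ``n_total`` depends only on the pool, not on the
    train/val assignment.
    """
    if isinstance(plan_or_pool, SplitPlan):
        train_ids, val_ids = plan_or_pool.train_ids, plan_or_pool.val_ids
    else:
        train_ids, val_ids = tuple(plan_or_pool), ()
    for sid in (*train_ids, *val_ids):
        if sid not in tile_counts:
            raise KeyError(f"unknown scan id {sid!r}")
        if tile_counts[sid] <= 0:
            raise ConfigurationError(f"tile count for {sid!r} must be positive")
    n_train = per_tile * sum(tile_counts[s] for s in train_ids)
    n_val = per_tile * sum(tile_counts[s] for s in val_ids)
    return n_train, n_val, n_train + n_val


def serialize_split(plan: SplitPlan) -> str:
    """Plain-text serialization of a split plan for run logs."""
    lines = [
        f"seed\t{plan.seed}",
        f"requested_fraction\t{plan.requested_fraction}",
    ]
    lines += [f"train\t{sid}" for sid in plan.train_ids]
    lines += [f"val\t{sid}" for sid in plan.val_ids]
    return "\n".join(lines) + "\n"
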