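"""Chunked sliding-window inference with overlap-aware probability averaging
and confidence-thresholded label assignment.

Each Z slice is reflect-padded to the chunk grid, cut into overlapping
square chunks, pushed through the model in batches, and reassembled by
averaging class probabilities wherever chunks overlap. Voxels whose
maximum class probability falls below the confidence threshold are
reassigned to background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import Checkpoint, model_from_checkpoint, softmax
from .volume_io import LabelMask, ScanVolume, compute_norm_stats, normalize

#: Default fraction of chunk size shared between neighboring chunks.
DEFAULT_OVERLAP = 0.25

#: Rough per-chunk cost budget (pixels) used for adaptive batch sizing.
DEFAULT_PIXEL_BUDGET = 2**22


@dataclass(frozen=True)
class ChunkGrid:
    """Deterministic chunk layout covering one (padded) tile."""

    tile_shape: tuple[int, int]
    chunk_px: int
    overlap_fraction: float
    origins: tuple[tuple[int, int], ...]
    padded_shape: tuple[int, int]


@dataclass
class ProbabilityMap:
    """Per-class probability accumulator with per-pixel coverage counts."""

    accumulator: np.ndarray  # (C, H, W)
    count: np.ndarray  # (H, W)

    def finalized(self) -> np.ndarray:
        if (self.count < 1).any():
            raise ValueError("probability map has uncovered pixels")
        return self.accumulator / self.count[None]


def _axis_origins(dim: int, chunk: int, stride: int) -> list[int]:
    if dim <= chunk:
        return [0]
    origins = list(range(0, dim - chunk + 1, stride))
    if origins[-1] != dim - chunk:
        origins.append(dim - chunk)  # align last chunk to the far edge
    return origins


def plan_chunks(tile_shape: tuple[int, int], chunk_px: int,
                overlap_fraction: float = DEFAULT_OVERLAP) -> ChunkGrid:
    """Plan a full-coverage grid of square chunks over a tile.

    Stride is ``floor(chunk * (1 - overlap))``; tiles smaller than the
    chunk in either dimension are handled by padding that dimension up to
    the chunk size (callers crop outputs back).
    """
    if chunk_px < 1:
        raise ValueError("chunk_px must be >= 1")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    h, w = tile_shape
    stride = max(int(chunk_px * (1.0 - overlap_fraction)), 1)
    ph, pw = max(h, chunk_px), max(w, chunk_px)
    origins = tuple(
        (y, x)
        for y in _axis_origins(ph, chunk_px, stride)
        for x in _axis_origins(pw, chunk_px, stride)
    )
    return ChunkGrid(
        tile_shape=(h, w),
        chunk_px=chunk_px,
        overlap_fraction=overlap_fraction,
        origins=origins,
        padded_shape=(ph, pw),
    )


def extract_chunks(tile: np.ndarray, grid: ChunkGrid) -> np.ndarray:
    """Cut the (reflect-padded) tile into chunks, one per grid origin."""
    ph, pw = grid.padded_shape
    py, px = ph - tile.shape[0], pw - tile.shape[1]
    padded = np.pad(tile, ((0, py), (0, px)), mode="reflect") if (py or px) else tile
    c = grid.chunk_px
    return np.stack([padded[y:y + c, x:x + c] for y, x in grid.origins])


def merge_chunks(chunk_probs: list[np.ndarray] | np.ndarray, grid: ChunkGrid) -> ProbabilityMap:
    """Average per-class chunk probabilities into a full-tile map.

    Overlapping regions take the arithmetic mean over all covering chunks,
    so normalized inputs stay normalized.
    """
    chunk_probs = np.asarray(chunk_probs, dtype=np.float64)
    if chunk_probs.shape[0] != len(grid.origins):
        raise ValueError(
            f"got {chunk_probs.shape[0]} chunks for {len(grid.origins)} grid origins"
        )
    n_classes = chunk_probs.shape[1]
    ph, pw = grid.padded_shape
    acc = np.zeros((n_classes, ph, pw))
    count = np.zeros((ph, pw))
    c = grid.chunk_px
    for block, (y, x) in zip(chunk_probs, grid.origins):
        acc[:, y:y + c, x:x + c] += block
        count[y:y + c, x:x + c] += 1
    h, w = grid.tile_shape
    return ProbabilityMap(accumulator=acc[:, :h, :w], count=count[:h, :w])


def assign_labels(pmap: ProbabilityMap | np.ndarray, threshold: float = 0.5,
                  scan_id: str = "") -> np.ndarray:
    """Argmax labels with confidence-based background reassignment.

    Ties go to the lowest class index (background wins); any voxel whose
    maximum probability is below *threshold* is set to background.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    probs = pmap.finalized() if isinstance(pmap, ProbabilityMap) else np.asarray(pmap)
    labels = np.argmax(probs, axis=0).astype(np.uint8)
    labels[probs.max(axis=0) < threshold] = 0
    return labels


def estimate_batch_size(chunk_px: int, pixel_budget: int = DEFAULT_PIXEL_BUDGET) -> int:
    """Number of chunks processed per forward pass for a given memory budget."""
    return max(int(pixel_budget) // (chunk_px * chunk_px), 1)


@dataclass
class ConfidenceSummary:
    mean_confidence: float
    min_confidence: float


def predict_volume(
    ckpt: Checkpoint,
    vol: ScanVolume,
    chunk_px: int = 512,
    threshold: float = 0.5,
    overlap_fraction: float = DEFAULT_OVERLAP,
    pixel_budget: int = DEFAULT_PIXEL_BUDGET,
    model=None,
) -> tuple[LabelMask, ConfidenceSummary]:
    """Segment a whole scan slice by slice with the checkpointed model.

    Normalization statistics are computed on the input scan using the
    mode stored in the checkpoint metadata (an unseen scan has no stored
    statistics). Pass *model* to override checkpoint reconstruction,
    e.g. with a deterministic stub; it must map (N,1,H,W) to logits
    (N,C,H,W).
    """
    if model is None:
        model = model_from_checkpoint(ckpt)
    mode = ckpt.metadata.get("normalization")
    if mode is None:
        raise ValueError("checkpoint metadata missing normalization mode")
    stats = compute_norm_stats(vol, mode)
    # chunk must satisfy the network's spatial-divisibility contract
    grid = plan_chunks(vol.shape[1:], chunk_px, overlap_fraction)
    batch = estimate_batch_size(chunk_px, pixel_budget)

    out = np.zeros(vol.shape, dtype=np.uint8)
    conf_mean_sum, conf_min = 0.0, 1.0
    for z in range(vol.shape[0]):
        tile = normalize(vol.voxels[z], _StatsProxy(stats, mode))
        chunks = extract_chunks(tile, grid)[:, None]  # (n, 1, c, c)
        probs = []
        for i in range(0, len(chunks), batch):
            logits = model.forward(chunks[i:i + batch], train=False)
            probs.append(softmax(np.asarray(logits, dtype=np.float64), axis=1))
        pmap = merge_chunks(np.concatenate(probs), grid)
        final = pmap.finalized()
        out[z] = assign_labels(pmap, threshold)
        max_prob = final.max(axis=0)
        conf_mean_sum += float(max_prob.mean())
        conf_min = min(conf_min, float(max_prob.min()))
    summary = ConfidenceSummary(
        mean_confidence=conf_mean_sum / vol.shape[0],
        min_confidence=conf_min,
    )
    return LabelMask(scan_id=vol.scan_id, labels=out), summary


def _StatsProxy(stats, mode):
    # compute_norm_stats already embeds the mode; kept as a seam for clarity
    assert stats.mode == mode
    return stats
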