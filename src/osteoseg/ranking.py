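"""Normalized performance-efficiency weighted scoring of fitted models.

Seven metrics per model: mIoU, batch size B, GPU utilization U (higher is
better) and FLOPs F, parameter count P, peak VRAM V, fitting time T
(lower is better). Each column is min-max normalized over the supplied
record set, the lower-is-better columns are inverted, and the weighted
score is a dot product with a weight vector that defaults to
``(0.85, 0.025 x 6)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Metric order used everywhere: (mIoU, B, U, F, P, V, T).
METRIC_NAMES = ("miou", "batch_size", "gpu_util", "flops", "params", "vram", "fit_time")

#: Higher-is-better flags aligned with METRIC_NAMES.
_HIGHER_IS_BETTER = (True, True, True, False, False, False, False)

DEFAULT_MIOU_WEIGHT = 0.85


class RankingError(ValueError):
    pass


@dataclass(frozen=True)
class EfficiencyRecord:
    """Raw metrics for one model configuration.

    Hardware numbers (GPU utilization, VRAM, time) are user-supplied or
    probe-filled; the toolkit never fabricates them.
    """

    label: str
    miou: float
    batch_size: float
    gpu_util: float
    flops: float
    params: float
    vram: float
    fit_time: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.miou <= 1.0:
            raise RankingError(f"{self.label}: mIoU must be in [0, 1]")
        if not 0.0 <= self.gpu_util <= 100.0:
            raise RankingError(f"{self.label}: gpu_util must be in [0, 100]")
        for name in ("batch_size", "flops", "params", "vram", "fit_time"):
            if getattr(self, name) <= 0:
                raise RankingError(f"{self.label}: {name} must be > 0")

    def values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in METRIC_NAMES], dtype=np.float64)


@dataclass
class WeightedScoreTable:
    labels: list[str]
    normalized: np.ndarray  # (n_models, 7), METRIC_NAMES order
    scores: np.ndarray
    ranking: list[int]  # indices into labels, best first
    weights: tuple[float, ...]

    def top(self, k: int = 3) -> list[tuple[str, float]]:
        return [(self.labels[i], float(self.scores[i])) for i in self.ranking[:k]]


def default_weights(miou_weight: float = DEFAULT_MIOU_WEIGHT) -> tuple[float, ...]:
    """mIoU weight plus the remainder spread equally over the six
    efficiency metrics: each gets ``(1 - miou_weight) / 6``."""
    if not 0.0 <= miou_weight <= 1.0:
        raise RankingError("miou_weight must be in [0, 1]")
    eff = (1.0 - miou_weight) / 6.0
    return (miou_weight,) + (eff,) * 6


def normalize_metrics(records: list[EfficiencyRecord]) -> np.ndarray:
    """Min-max normalize each metric column to [0, 1] over *records*.

    Lower-is-better columns (F, P, V, T) are inverted so 1 is always
    best. A degenerate column (max == min) carries no discriminating
    information and normalizes to 1 for every record.
    """
    if len(records) < 2:
        raise RankingError("need at least 2 records to normalize")
    raw = np.stack([r.values() for r in records])
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    span = hi - lo
    out = np.ones_like(raw)
    for j, higher in enumerate(_HIGHER_IS_BETTER):
        if span[j] == 0:
            continue  # degenerate column: all records get 1
        scaled = (raw[:, j] - lo[j]) / span[j]
        out[:, j] = scaled if higher else 1.0 - scaled
    return out


def weighted_score(norm_row: np.ndarray, weights: tuple[float, ...] | np.ndarray) -> float:
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (len(METRIC_NAMES),):
        raise RankingError(f"expected {len(METRIC_NAMES)} weights, got {weights.shape}")
    if (weights < 0).any():
        raise RankingError("weights must be non-negative")
    return float(np.asarray(norm_row, dtype=np.float64) @ weights)


def rank_models(records: list[EfficiencyRecord],
                weights: tuple[float, ...] | None = None) -> WeightedScoreTable:
    """Score and order a record set; ties break on raw mIoU then label."""
    weights = tuple(weights) if weights is not None else default_weights()
    norm = normalize_metrics(records)
    scores = np.array([weighted_score(row, weights) for row in norm])
    order = sorted(
        range(len(records)),
        key=lambda i: (-scores[i], -records[i].miou, records[i].label),
    )
    return WeightedScoreTable(
        labels=[r.label for r in records],
        normalized=norm,
        scores=scores,
        ranking=order,
        weights=weights,
    )


def sensitivity_sweep(records: list[EfficiencyRecord],
                      miou_weights: list[float]) -> list[WeightedScoreTable]:
    """One ranked table per mIoU weight, efficiency weight ``(1 - w) / 6``."""
    return [rank_models(records, default_weights(w)) for w in miou_weights]


def format_table(table: WeightedScoreTable, top_k: int | None = None) -> str:
    lines = [f"# weights: {', '.join(f'{w:.6g}' for w in table.weights)}",
             "rank\tlabel\tscore"]
    picks = table.ranking if top_k is None else table.ranking[:top_k]
    for rank, i in enumerate(picks, start=1):
        lines.append(f"{rank}\t{table.labels[i]}\t{table.scores[i]:.4f}")
    return "\n".join(lines) + "\n"
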