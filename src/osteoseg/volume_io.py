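"""TIFF slice-stack I/O and per-scan normalization statistics.

Volumes are stored on disk as a directory of single-page grayscale TIFFs,
one file per Z slice, stacked in plain lexicographic filename order.
Masks use the same layout with u8 pixels and class codes
``{0: background, 1: bone, 2: pores}``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile

#: Guard against division by zero for degenerate std / intensity range.
EPSILON = 1e-8

CLASS_CODES = {0: "background", 1: "bone", 2: "pores"}

BitDepth = Literal["u8", "u16", "float"]
NormMode = Literal["zscore", "minmax"]

_TIFF_SUFFIXES = (".tif", ".tiff")


class FormatError(ValueError):
    """Raised when an on-disk stack violates the slice-stack contract."""


@dataclass
class ScanVolume:
    """A 3D grayscale scan: Z slices of identical Y x X shape."""

    scan_id: str
    voxels: np.ndarray
    voxel_size_um: float = 1.0
    bit_depth: BitDepth = "u16"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"voxels must be a non-empty 3D array, got shape {self.voxels.shape}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.bit_depth in ("u8", "u16"):
            hi = 255 if self.bit_depth == "u8" else 65535
            lo, up = self.voxels.min(), self.voxels.max()
            if lo < 0 or up > hi:
                raise ValueError(
                    f"intensities [{lo}, {up}] out of range for bit depth {self.bit_depth}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_tiles(self) -> int:
        """Number of 2D tiles (slices) available for patch sampling."""
        return self.voxels.shape[0]


@dataclass
class LabelMask:
    """Integer class mask congruent with its paired :class:`ScanVolume`."""

    scan_id: str
    labels: np.ndarray
    class_codes: dict = field(default_factory=lambda: dict(CLASS_CODES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        bad = set(np.unique(self.labels)) - set(self.class_codes)
        if bad:
            raise ValueError(f"unknown class codes {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class NormalizationStats:
    """Whole-scan intensity statistics used to normalize patches.

    Statistics are always computed over the full scan, never per patch,
    so every patch from one scan is normalized identically.
    """

    scan_id: str
    mode: NormMode
    mean: float
    std: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("std must be non-negative")
        if self.max < self.min:
            raise ValueError("max must be >= min")


def _infer_bit_depth(dtype: np.dtype) -> BitDepth:
    dtype = np.dtype(dtype)
    if dtype == np.uint8:
        return "u8"
    if dtype == np.uint16:
        return "u16"
    if dtype.kind == "f":
        return "float"
    raise FormatError(f"unsupported slice dtype {dtype}")


def _list_slices(dir_path: Path) -> list[Path]:
    files = sorted(
        p for p in dir_path.iterdir()
        if p.suffix.lower() in _TIFF_SUFFIXES and p.is_file()
    )
    if not files:
        raise FormatError(f"no TIFF slices found in {dir_path}")
    return files


def read_tiff_stack(dir_path: str | os.PathLike, scan_id: str | None = None,
                    voxel_size_um: float = 1.0) -> ScanVolume:
    """Stack every TIFF in *dir_path* (lexicographic order) into a volume.

    Raises :class:`FormatError` naming the offending file when slice shapes
    or dtypes disagree, and when the directory contains no TIFFs.
    """
    dir_path = Path(dir_path)
    files = _list_slices(dir_path)
    first = tifffile.imread(files[0])
    if first.ndim != 2:
        raise FormatError(f"{files[0]}: expected a single-page 2D slice, got shape {first.shape}")
    slices = [first]
    for f in files[1:]:
        sl = tifffile.imread(f)
        if sl.shape != first.shape:
            raise FormatError(f"{f}: slice shape {sl.shape} differs from {first.shape}")
        if sl.dtype != first.dtype:
            raise FormatError(f"{f}: slice dtype {sl.dtype} differs from {first.dtype}")
        slices.append(sl)
    voxels = np.stack(slices, axis=0)
    return ScanVolume(
        scan_id=scan_id if scan_id is not None else dir_path.name,
        voxels=voxels,
        voxel_size_um=voxel_size_um,
        bit_depth=_infer_bit_depth(voxels.dtype),
    )


def read_mask_stack(dir_path: str | os.PathLike, scan_id: str | None = None) -> LabelMask:
    """Read a label mask stored as a u8 TIFF stack."""
    vol = read_tiff_stack(dir_path, scan_id=scan_id)
    return LabelMask(scan_id=vol.scan_id, labels=vol.voxels.astype(np.uint8))


def write_tiff_stack(vol: ScanVolume | LabelMask, dir_path: str | os.PathLike) -> None:
    """Write one TIFF per slice as ``slice_###.tif`` with zero-padded names.

    Masks are stored as u8 (three classes); scan dtype is preserved.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    data = vol.labels.astype(np.uint8) if isinstance(vol, LabelMask) else vol.voxels
    width = max(3, len(str(data.shape[0] - 1)))
    for z in range(data.shape[0]):
        path = dir_path / f"slice_{z:0{width}d}.tif"
        try:
            tifffile.imwrite(path, data[z])
        except OSError as exc:  # pragma: no cover - environment dependent
            raise OSError(f"failed writing slice to {path}: {exc}") from exc


def compute_norm_stats(vol: ScanVolume, mode: NormMode = "zscore") -> NormalizationStats:
    """Population mean/std and global min/max over all voxels of the scan."""
    if mode not in ("zscore", "minmax"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    v = vol.voxels.astype(np.float64)
    return NormalizationStats(
        scan_id=vol.scan_id,
        mode=mode,
        mean=float(v.mean()),
        std=float(v.std()),  # population std (ddof=0): normalization, not inference
        min=float(v.min()),
        max=float(v.max()),
    )


def normalize(patch: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Normalize a patch with its source scan's whole-scan statistics.

    ``zscore``: ``(x - mean) / max(std, eps)``.
    ``minmax``: ``(x - min) / max(max - min, eps)``, output within [0, 1].
    """
    x = np.asarray(patch, dtype=np.float32)
    if stats.mode == "zscore":
        return (x - stats.mean) / max(stats.std, EPSILON)
    if stats.mode == "minmax":
        return (x - stats.min) / max(stats.max - stats.min, EPSILON)
    raise ValueError(f"unknown normalization mode {stats.mode!r}")
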