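"""Synthetic long-bone phantom generator.

Produces paired scan volumes and exact label masks that emulate the
difficulty modes seen in real micro-CT material: closely packed bones,
composite scans with multiple intensity domains, dim low-contrast scans,
8-bit acquisition, drill holes, and growth-plate bands. Geometry is
procedural, so masks are correct by construction and every downstream
module can be exercised without external data.

Each bone is an elliptical cortical annulus extruded along Z (class 1)
around a marrow cavity; void pores (class 2) are dark blobs scattered
through the cavity; the remaining cavity is marrow-bright but belongs to
the background class, as does everything outside the bone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .volume_io import LabelMask, ScanVolume, write_tiff_stack


class PhantomError(ValueError):
    """Invalid or unsatisfiable phantom configuration."""


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (16, 64, 64)
    n_bones: int = 1
    cortex_radius_px: tuple[int, int] = (14, 20)
    cortex_thickness_px: tuple[int, int] = (4, 6)
    pore_density: float = 0.15
    pore_radius_px: tuple[int, int] = (2, 4)
    packing_gap_px: int = 6
    growth_plate: bool = False
    growth_plate_px: int = 2
    intensity_background: float = 0.08
    intensity_marrow: float = 0.45
    intensity_bone: float = 0.85
    intensity_pore: float | None = None  # default: between background and marrow
    noise_sigma: float = 0.02
    n_intensity_domains: int = 1
    dimming_factor: float = 1.0
    bit_depth: str = "u16"
    drill_hole: bool = False
    radial_ramp: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.intensity_bone > self.intensity_marrow > self.intensity_background):
            raise PhantomError("intensity levels must satisfy bone > marrow > background")
        if not 0.0 <= self.pore_density <= 1.0:
            raise PhantomError("pore_density must be in [0, 1]")
        if not 0.0 < self.dimming_factor <= 1.0:
            raise PhantomError("dimming_factor must be in (0, 1]")
        if self.bit_depth not in ("u8", "u16"):
            raise PhantomError("bit_depth must be u8 or u16")
        if self.n_intensity_domains < 1:
            raise PhantomError("n_intensity_domains must be >= 1")
        if self.intensity_pore is None:
            # partially marrow-filled voids: dimmer than marrow, brighter than air
            self.intensity_pore = self.intensity_background + 0.4 * (
                self.intensity_marrow - self.intensity_background
            )
        if not self.intensity_background <= self.intensity_pore < self.intensity_bone:
            raise PhantomError("pore intensity must lie in [background, bone)")
        _, y, x = self.shape
        if 2 * self.cortex_radius_px[1] >= min(y, x):
            raise PhantomError("cortex radius does not fit within the field of view")

    @classmethod
    def for_shape(cls, shape: tuple[int, int, int], seed: int = 0, **overrides) -> "PhantomConfig":
        """Config with bone geometry scaled to the field of view."""
        fov = min(shape[1], shape[2])
        r_hi = max(fov // 3 - 1, 4)
        r_lo = max(int(r_hi * 0.7), 3)
        th = max(r_lo // 3, 2)
        kw = dict(
            shape=shape,
            cortex_radius_px=(r_lo, r_hi),
            cortex_thickness_px=(th, th + 1),
            pore_radius_px=(1, max(2, th // 2)),
            packing_gap_px=max(fov // 12, 2),
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


def _place_bones(cfg: PhantomConfig, rng: np.random.Generator):
    """Place bone centers/radii so outlines keep the configured gap."""
    _, ny, nx = cfg.shape
    placed = []  # (cy, cx, ry, rx, thickness)
    for _ in range(cfg.n_bones):
        ok = False
        for _attempt in range(500):
            ry = int(rng.integers(cfg.cortex_radius_px[0], cfg.cortex_radius_px[1] + 1))
            rx = int(rng.integers(cfg.cortex_radius_px[0], cfg.cortex_radius_px[1] + 1))
            th = int(rng.integers(cfg.cortex_thickness_px[0], cfg.cortex_thickness_px[1] + 1))
            cy = int(rng.integers(ry + 1, ny - ry)) if ny - 2 * ry > 2 else ny // 2
            cx = int(rng.integers(rx + 1, nx - rx)) if nx - 2 * rx > 2 else nx // 2
            r_eff = max(ry, rx)
            if all(
                np.hypot(cy - py, cx - px) >= r_eff + max(pry, prx) + cfg.packing_gap_px
                for py, px, pry, prx, _ in placed
            ):
                ok = True
                break
        if not ok:
            raise PhantomError(
                f"could not place {cfg.n_bones} bones with gap {cfg.packing_gap_px}px "
                f"in a {ny}x{nx} field of view"
            )
        placed.append((cy, cx, ry, rx, th))
    return placed


def generate_phantom(cfg: PhantomConfig) -> tuple[ScanVolume, LabelMask]:
    """Build one scan/mask pair; identical config and seed give identical output."""
    rng = np.random.default_rng(cfg.seed)
    nz, ny, nx = cfg.shape
    labels = np.zeros(cfg.shape, dtype=np.uint8)
    intensity = np.full(cfg.shape, cfg.intensity_background, dtype=np.float64)

    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    bones = _place_bones(cfg, rng)
    cavity = np.zeros(cfg.shape, dtype=bool)

    for cy, cx, ry, rx, th in bones:
        outer = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        iry, irx = max(ry - th, 1), max(rx - th, 1)
        inner = ((yy - cy) / iry) ** 2 + ((xx - cx) / irx) ** 2 <= 1.0
        cortex = outer & ~inner
        labels[:, cortex] = 1
        intensity[:, cortex] = cfg.intensity_bone
        labels[:, inner] = 0
        intensity[:, inner] = cfg.intensity_marrow
        cavity[:, inner] = True

    # pores: dark void blobs filling ~pore_density of the cavity
    cavity_count = int(cavity.sum())
    if cfg.pore_density > 0 and cavity_count:
        target = cfg.pore_density * cavity_count
        zz3, yy3, xx3 = np.mgrid[0:nz, 0:ny, 0:nx].astype(np.float64)
        cav_idx = np.argwhere(cavity)
        pore = np.zeros(cfg.shape, dtype=bool)
        for _ in range(10_000):
            if pore.sum() >= target:
                break
            cz, cy, cx = cav_idx[rng.integers(len(cav_idx))]
            r = int(rng.integers(cfg.pore_radius_px[0], cfg.pore_radius_px[1] + 1))
            blob = ((zz3 - cz) ** 2 + (yy3 - cy) ** 2 + (xx3 - cx) ** 2) <= r * r
            pore |= blob & cavity
        labels[pore] = 2
        intensity[pore] = cfg.intensity_pore

    if cfg.growth_plate and nz >= cfg.growth_plate_px + 2:
        z0 = int(rng.integers(1, nz - cfg.growth_plate_px))
        band = slice(z0, z0 + cfg.growth_plate_px)
        band_cavity = cavity[band]
        labels[band][band_cavity] = 2
        intensity[band][band_cavity] = cfg.intensity_pore

    if cfg.drill_hole and bones:
        cy, cx, ry, rx, _ = bones[0]
        cz = nz // 2
        hole_r = 2
        zz3, yy3 = np.mgrid[0:nz, 0:ny].astype(np.float64)
        cyl = ((zz3 - cz) ** 2 + (yy3 - cy) ** 2) <= hole_r * hole_r  # along X
        labels[cyl, :] = np.where(labels[cyl, :] == 1, 0, labels[cyl, :])
        intensity[cyl, :] = np.where(
            labels[cyl, :] == 0, cfg.intensity_background, intensity[cyl, :]
        )

    # composite-scan emulation: per-domain additive offsets along Z
    if cfg.n_intensity_domains > 1:
        bounds = np.linspace(0, nz, cfg.n_intensity_domains + 1).astype(int)
        offsets = rng.uniform(-0.08, 0.08, cfg.n_intensity_domains)
        for d in range(cfg.n_intensity_domains):
            intensity[bounds[d]:bounds[d + 1]] += offsets[d]

    if cfg.radial_ramp:  # crude beam-hardening stand-in
        r = np.hypot(yy - ny / 2, xx - nx / 2)
        intensity += 0.05 * (r / r.max())[None]

    if cfg.dimming_factor < 1.0:
        intensity = cfg.intensity_background + (
            intensity - cfg.intensity_background
        ) * cfg.dimming_factor

    if cfg.noise_sigma > 0:
        intensity += rng.normal(0.0, cfg.noise_sigma, cfg.shape)

    intensity = np.clip(intensity, 0.0, 1.0)
    hi = 255 if cfg.bit_depth == "u8" else 65535
    voxels = np.round(intensity * hi).astype(np.uint8 if cfg.bit_depth == "u8" else np.uint16)

    scan_id = f"phantom_{cfg.seed:04d}"
    return (
        ScanVolume(scan_id=scan_id, voxels=voxels, voxel_size_um=10.0, bit_depth=cfg.bit_depth),
        LabelMask(scan_id=scan_id, labels=labels),
    )


#: Difficulty-mode overrides applied on top of the template config.
HARD_MODES: dict[str, dict] = {
    "easy": {},
    "packed": {"n_bones": 2, "packing_gap_px": 2, "cortex_radius_px": (10, 13)},
    "dim": {"dimming_factor": 0.35},
    "composite": {"n_intensity_domains": 3},
    "8bit": {"bit_depth": "u8"},
    "drill": {"drill_hole": True},
    "growth": {"growth_plate": True},
}


@dataclass
class DatasetManifest:
    scan_ids: list[str]
    tile_counts: dict[str, int]
    config_digests: dict[str, str]
    modes: dict[str, str] = field(default_factory=dict)


def generate_dataset(
    n_scans: int,
    cfg_template: PhantomConfig,
    out_dir: str | Path,
    modes: list[str] | None = None,
) -> DatasetManifest:
    """Write ``n_scans`` scan/mask TIFF-stack folder pairs plus a manifest.

    Seeds are varied per scan; difficulty *modes* (keys of
    :data:`HARD_MODES`) are cycled across scans. Scans land in
    ``<out>/<scan_id>/`` and masks in ``<out>/<scan_id>_mask/``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    modes = modes or ["easy"]
    unknown = set(modes) - set(HARD_MODES)
    if unknown:
        raise PhantomError(f"unknown modes {sorted(unknown)}; valid: {sorted(HARD_MODES)}")

    manifest = DatasetManifest(scan_ids=[], tile_counts={}, config_digests={})
    for i in range(n_scans):
        mode = modes[i % len(modes)]
        cfg = PhantomConfig(**{**asdict(cfg_template), **HARD_MODES[mode],
                               "seed": cfg_template.seed + i})
        vol, mask = generate_phantom(cfg)
        scan_id = f"{vol.scan_id}_{mode}"
        vol.scan_id = mask.scan_id = scan_id
        write_tiff_stack(vol, out_dir / scan_id)
        write_tiff_stack(mask, out_dir / f"{scan_id}_mask")
        digest = hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]
        manifest.scan_ids.append(scan_id)
        manifest.tile_counts[scan_id] = vol.shape[0]
        manifest.config_digests[scan_id] = digest
        manifest.modes[scan_id] = mode

    (out_dir / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2))
    return manifest
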