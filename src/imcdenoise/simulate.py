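"""Synthetic ion-count image generator with ground truth.

Produces the triplet the restoration pipeline assumes: a clean structured
intensity field (cell-like blobs and/or filaments), a Poisson-corrupted
count image, and a final image with injected single hot pixels and small
hot clusters, together with the injected-outlier mask and
foreground/background masks.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SimulationConfig",
    "SimulatedTriplet",
    "generate_clean",
    "add_shot_noise",
    "add_hot_pixels",
    "simulate_triplet",
    "simulate_benchmark",
]

_CLUSTER_GROWTH = ((0, 1), (1, 0), (0, -1), (-1, 0))


@dataclass
class SimulationConfig:
    shape: tuple[int, int] = (256, 256)
    kind: str = "blobs"  # blobs | filaments | mixed
    lambda_fg: float = 20.0
    lambda_bg: float = 1.0
    hot_pixel_density: float = 0.01
    hot_cluster_density: float = 0.0
    cluster_size_range: tuple[int, int] = (2, 4)
    hot_factor_range: tuple[float, float] = (5.0, 20.0)
    n_blobs_per_kpx: float = 3.0  # blob count per 1000 pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lambda_fg > self.lambda_bg >= 0):
            raise ValueError("require lambda_fg > lambda_bg >= 0")
        for d in (self.hot_pixel_density, self.hot_cluster_density):
            if not (0.0 <= d <= 0.05):
                raise ValueError("densities must lie in [0, 0.05]")
        if self.kind not in ("blobs", "filaments", "mixed"):
            raise ValueError(f"unknown structure kind {self.kind!r}")


@dataclass
class SimulatedTriplet:
    clean: np.ndarray        # noiseless intensity field X
    noisy: np.ndarray        # Poisson-corrupted counts P[X]
    hot: np.ndarray          # noisy + injected hot pixels
    hot_mask: np.ndarray     # bool, injected outlier positions Q
    fg_mask: np.ndarray      # bool, foreground of the clean field
    bg_mask: np.ndarray      # bool, complement of fg_mask
    config: SimulationConfig = field(repr=False, default=None)


def _blob_field(shape: tuple[int, int], n_blobs: int, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    field = np.zeros(shape, dtype=np.float64)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        sy, sx = rng.uniform(2.0, 8.0), rng.uniform(2.0, 8.0)
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(0.5, 1.5)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        field += amp * np.exp(-0.5 * ((u / sy) ** 2 + (v / sx) ** 2))
    return field


def _filament_field(shape: tuple[int, int], n_walks: int, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    field = np.zeros(shape, dtype=np.float64)
    n_steps = 4 * max(h, w)
    for _ in range(n_walks):
        y, x = rng.uniform(0, h), rng.uniform(0, w)
        angle = rng.uniform(0, 2 * np.pi)
        for _ in range(n_steps):
            angle += rng.normal(0, 0.25)
            y = (y + np.sin(angle)) % h
            x = (x + np.cos(angle)) % w
            field[int(y), int(x)] += 1.0
    return ndimage.gaussian_filter(field, sigma=1.2)


def generate_clean(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build a clean intensity field and its foreground/background masks.

    The field is scaled so the mean over the foreground mask matches
    ``lambda_fg``; masks come from thresholding the noiseless field at
    ``(lambda_fg + lambda_bg) / 2``.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    n_structures = max(1, int(round(cfg.n_blobs_per_kpx * h * w / 1000.0)))
    if cfg.kind == "blobs":
        base = _blob_field(cfg.shape, n_structures, rng)
    elif cfg.kind == "filaments":
        base = _filament_field(cfg.shape, max(1, n_structures // 10), rng)
    else:
        base = _blob_field(cfg.shape, max(1, n_structures // 2), rng) + _filament_field(
            cfg.shape, max(1, n_structures // 20), rng
        )
    if base.max() <= 0:
        field = np.full(cfg.shape, cfg.lambda_bg, dtype=np.float64)
        fg = np.zeros(cfg.shape, dtype=bool)
        return field, fg, ~fg

    base = base / base.max()
    thresh = (cfg.lambda_fg + cfg.lambda_bg) / 2.0
    # fixed-point rescale so the foreground-mask mean of the field hits lambda_fg
    scale = cfg.lambda_fg - cfg.lambda_bg
    field = cfg.lambda_bg + scale * base
    for _ in range(25):
        fg = field > thresh
        if not fg.any():
            scale *= 1.5
            field = cfg.lambda_bg + scale * base
            continue
        mean_fg = field[fg].mean()
        if abs(mean_fg - cfg.lambda_fg) < 1e-9:
            break
        scale *= (cfg.lambda_fg - cfg.lambda_bg) / max(mean_fg - cfg.lambda_bg, 1e-12)
        field = cfg.lambda_bg + scale * base
    fg = field > thresh
    return field, fg, ~fg


def add_shot_noise(clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Poisson draw per pixel with mean equal to the clean value."""
    clean = np.asarray(clean, dtype=np.float64)
    if np.any(clean < 0):
        raise ValueError("clean field must be >= 0")
    return rng.poisson(clean).astype(np.int64)


def add_hot_pixels(
    img: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Inject single hot pixels and small hot clusters into a count image.

    Each injected value is ``max(local 3x3 maximum, lambda_fg)`` times a
    factor drawn uniformly from ``hot_factor_range``, so injected pixels
    strictly exceed their pre-injection neighbourhood.  Returns the
    modified image and the boolean mask of every altered pixel.
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    mask = np.zeros(img.shape, dtype=bool)

    # single hot pixels: Bernoulli per pixel
    if cfg.hot_pixel_density > 0:
        mask |= rng.random(img.shape) < cfg.hot_pixel_density

    # cluster seeds grown by short random walks to 2-4 connected pixels
    if cfg.hot_cluster_density > 0:
        seeds = np.argwhere(rng.random(img.shape) < cfg.hot_cluster_density)
        lo, hi = cfg.cluster_size_range
        for y, x in seeds:
            size = int(rng.integers(lo, hi + 1))
            cy, cx = int(y), int(x)
            mask[cy, cx] = True
            for _ in range(size - 1):
                dy, dx = _CLUSTER_GROWTH[rng.integers(0, 4)]
                cy = min(max(cy + dy, 0), h - 1)
                cx = min(max(cx + dx, 0), w - 1)
                mask[cy, cx] = True

    if not mask.any():
        return img.copy(), mask

    local_max = ndimage.maximum_filter(img, size=3, mode="nearest")
    base = np.maximum(local_max, cfg.lambda_fg)
    factors = rng.uniform(*cfg.hot_factor_range, size=int(mask.sum()))
    out = img.copy()
    out[mask] = np.ceil(base[mask] * factors)
    return out, mask


def simulate_triplet(cfg: SimulationConfig) -> SimulatedTriplet:
    """Generate a full clean/noisy/hot triplet from one seeded config."""
    clean, fg, bg = generate_clean(cfg)
    rng = np.random.default_rng(cfg.seed + 1)  # independent of the structure draw
    noisy = add_shot_noise(clean, rng)
    hot, hot_mask = add_hot_pixels(noisy, cfg, rng)
    return SimulatedTriplet(
        clean=clean, noisy=noisy.astype(np.float64), hot=hot,
        hot_mask=hot_mask, fg_mask=fg, bg_mask=bg, config=cfg,
    )


def simulate_benchmark(configs: list[SimulationConfig], out_dir: str | Path) -> "pandas.DataFrame":
    """Write triplets as TIFF layers plus a CSV manifest; returns the manifest."""
    import pandas as pd

    from .io import write_tiff

    if not configs:
        raise ValueError("config grid must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, cfg in enumerate(configs):
        trip = simulate_triplet(cfg)
        names = {}
        for layer in ("clean", "noisy", "hot"):
            path = out_dir / f"sim{idx:04d}_{layer}.tiff"
            write_tiff(getattr(trip, layer), path)
            names[layer] = path.name
        mask_path = out_dir / f"sim{idx:04d}_hotmask.tiff"
        write_tiff(trip.hot_mask.astype(np.float32), mask_path)
        row = {"index": idx, **{k: v for k, v in asdict(cfg).items()}}
        row.update({f"file_{k}": v for k, v in names.items()})
        row["file_hotmask"] = mask_path.name
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
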