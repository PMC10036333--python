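"""Adaptive hot-pixel detection and removal via differential intensity maps.

Stage 1 of the pipeline.  Per iteration:

1. variance-stabilize the counts (Anscombe transform);
2. build 8 directional difference maps ``d_i = t(p) - t(neighbour_i(p))``
   over a 3x3 window (edge replication at borders) and drop low-intensity
   pixels (transformed value below a background cutoff, default 4) from
   candidacy and from the robust centre estimates;
3. for every valid pixel, sum the ``l`` signed differences whose distances
   to the per-direction medians are smallest (default ``l = 4``), giving
   the aggregate statistic ``t_l``;
4. fit a Gaussian kernel density estimate to the ``t_l`` sample on a
   unit-spaced grid and locate the right-tail threshold where the density
   flattens (first derivative ~ 0) or turns from convex to concave;
5. flag pixels with ``t_l`` beyond the threshold and replace them with
   their full 3x3 median (computed on the pre-replacement image).

Iteration stops early when nothing is flagged; the final image is mapped
back to count scale with the algebraic inverse Anscombe transform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .transforms import anscombe_forward, anscombe_inverse_algebraic

__all__ = [
    "NEIGHBOR_OFFSETS",
    "DifferenceMapSet",
    "AggregateStatistic",
    "KDECurve",
    "HotPixelReport",
    "compute_difference_maps",
    "aggregate_min_differences",
    "fit_kde",
    "find_threshold",
    "median_replace",
    "dimr",
]

logger = logging.getLogger(__name__)

# 3x3 window neighbours, row-major order; index = direction i
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass
class DifferenceMapSet:
    """8 directional neighbour-difference maps plus validity bookkeeping."""

    maps: np.ndarray            # (8, H, W)
    valid_mask: np.ndarray      # (H, W) bool
    robust_centers: np.ndarray  # (8,) medians over valid pixels


@dataclass
class AggregateStatistic:
    values: np.ndarray      # (H, W), NaN outside valid_mask
    valid_mask: np.ndarray
    l: int

    def sample(self) -> np.ndarray:
        """The 1D sample of aggregate values over valid pixels."""
        return self.values[self.valid_mask]


@dataclass
class KDECurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


@dataclass
class HotPixelReport:
    """Per-iteration record of a hot-pixel removal run."""

    masks: list = field(default_factory=list)        # boolean masks per iteration
    thresholds: list = field(default_factory=list)   # x_T per iteration (may be inf)
    flagged_counts: list = field(default_factory=list)
    iterations_run: int = 0
    n_pixels: int = 0

    @property
    def total_flagged(self) -> int:
        if not self.masks:
            return 0
        return int(np.logical_or.reduce(self.masks).sum())

    @property
    def fraction_flagged(self) -> float:
        return self.total_flagged / self.n_pixels if self.n_pixels else 0.0

    @property
    def combined_mask(self) -> np.ndarray:
        return np.logical_or.reduce(self.masks)

    def to_dict(self) -> dict:
        return {
            "iterations_run": self.iterations_run,
            "n_pixels": self.n_pixels,
            "flagged_counts": [int(c) for c in self.flagged_counts],
            "thresholds": [float(t) for t in self.thresholds],
            "total_flagged": self.total_flagged,
            "fraction_flagged": self.fraction_flagged,
        }


def _shifted(t: np.ndarray, di: int, dj: int) -> np.ndarray:
    """Neighbour image under edge replication."""
    padded = np.pad(t, 1, mode="edge")
    h, w = t.shape
    return padded[1 + di : 1 + di + h, 1 + dj : 1 + dj + w]


def compute_difference_maps(t: np.ndarray, bg_cutoff: float = 4.0) -> DifferenceMapSet:
    """Build the 8 directional difference maps of a transformed image.

    Pixels with transformed value below ``bg_cutoff`` are excluded from
    the valid mask (neither outlier candidates nor contributors to the
    robust centres) but still serve as neighbours of valid pixels.
    """
    t = np.asarray(t, dtype=np.float64)
    if t.ndim != 2 or t.shape[0] < 3 or t.shape[1] < 3:
        raise ValueError(f"image must be 2D and at least 3x3, got shape {t.shape}")
    maps = np.empty((8,) + t.shape, dtype=np.float64)
    for i, (di, dj) in enumerate(NEIGHBOR_OFFSETS):
        maps[i] = t - _shifted(t, di, dj)
    valid = t >= bg_cutoff
    if valid.any():
        centers = np.median(maps[:, valid], axis=1)
    else:
        centers = np.zeros(8)
    return DifferenceMapSet(maps=maps, valid_mask=valid, robust_centers=centers)


def aggregate_min_differences(dm: DifferenceMapSet, l: int = 4) -> AggregateStatistic:
    """Sum, per valid pixel, the ``l`` signed differences closest to the medians.

    Distances ``|d_i - median_i|`` are sorted ascending with a stable sort
    (ties broken by direction index) and the *signed* ``d_i`` of the ``l``
    smallest are summed.
    """
    if not (1 <= l <= 8):
        raise ValueError(f"l must be in [1, 8], got {l}")
    d = dm.maps[:, dm.valid_mask]                     # (8, n_valid)
    delta = np.abs(d - dm.robust_centers[:, None])    # (8, n_valid)
    order = np.argsort(delta, axis=0, kind="stable")  # direction-index tie-break
    picked = np.take_along_axis(d, order[:l], axis=0)
    out = np.full(dm.valid_mask.shape, np.nan)
    out[dm.valid_mask] = picked.sum(axis=0)
    return AggregateStatistic(values=out, valid_mask=dm.valid_mask, l=l)


def _silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n**(-1/5)."""
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread_candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    spread = min(spread_candidates) if spread_candidates else 0.0
    if spread == 0.0:
        return 1.0  # degenerate sample; any positive bandwidth works
    return 0.9 * spread * n ** (-0.2)


def fit_kde(values: np.ndarray, min_samples: int = 10,
            min_bandwidth: float = 0.0) -> KDECurve | None:
    """Gaussian KDE on a unit-spaced grid spanning [min - 3h, max + 3h].

    The bandwidth is Silverman's rule, optionally floored at
    ``min_bandwidth``.  The outlier-detection pipeline floors it at its
    grid spacing: the right-tail threshold criteria assume a curve that is
    smooth at the evaluation resolution, and a narrower kernel turns
    isolated tail samples into spurious curvature flips.

    Returns ``None`` (detection skipped) when fewer than ``min_samples``
    values are supplied.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < min_samples:
        logger.warning("fit_kde: only %d samples (< %d); detection skipped", x.size, min_samples)
        return None
    h = max(_silverman_bandwidth(x), min_bandwidth)
    lo = math.floor(x.min() - 3.0 * h)
    hi = math.ceil(x.max() + 3.0 * h)
    grid = np.arange(lo, hi + 1, dtype=np.float64)
    density = np.zeros_like(grid)
    norm = 1.0 / (x.size * h * math.sqrt(2.0 * math.pi))
    # chunk over samples to bound memory on large images
    for start in range(0, x.size, 16384):
        chunk = x[start : start + 16384]
        z = (grid[:, None] - chunk[None, :]) / h
        density += norm * np.exp(-0.5 * z * z).sum(axis=1)
    return KDECurve(grid=grid, density=density, bandwidth=h)


def find_threshold(curve: KDECurve, dx: float = 1.0, eps_deriv_rel: float = 1e-6) -> float:
    """Locate the right-tail cut point of a fitted density.

    Scanning rightward from the global mode, return the first grid point
    where either the first derivative (central difference) vanishes
    (``|g'| <= eps_deriv_rel * peak``) or the curvature turns from convex
    to concave (``g''(x - dx) >= 0`` and ``g''(x) <= 0``).  Returns
    ``+inf`` when no point qualifies (nothing detected).
    """
    g = curve.density
    n = g.size
    if n < 3:
        return float("inf")
    mode = int(np.argmax(g))
    eps = eps_deriv_rel * float(g[mode])
    d1 = np.gradient(g, dx)
    d2 = np.empty_like(g)
    d2[1:-1] = (g[2:] - 2.0 * g[1:-1] + g[:-2]) / (dx * dx)
    d2[0], d2[-1] = d2[1], d2[-2]
    for i in range(mode + 1, n):
        if abs(d1[i]) <= eps:
            return float(curve.grid[i])
        if i >= 1 and d2[i - 1] >= 0.0 and d2[i] <= 0.0:
            return float(curve.grid[i])
    return float("inf")


def median_replace(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace flagged pixels with their full 3x3 median (centre included).

    Medians are computed on the pre-replacement image with edge
    replication, so adjacent flagged pixels are handled order-independently.
    """
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        return img.copy()
    med = ndimage.median_filter(img, size=3, mode="nearest")
    out = img.copy()
    out[mask] = med[mask]
    return out


def dimr(
    raw: np.ndarray,
    n_iter: int = 3,
    l: int = 4,
    bg_cutoff: float = 4.0,
    eps_deriv_rel: float = 1e-6,
) -> tuple[np.ndarray, HotPixelReport]:
    """Run the full iterative hot-pixel removal on a raw count image.

    Returns the restored (real-valued) count image together with a
    :class:`HotPixelReport`.
    """
    raw = np.asarray(raw, dtype=np.float64)
    t = anscombe_forward(raw)
    report = HotPixelReport(n_pixels=int(t.size))
    for _ in range(n_iter):
        dm = compute_difference_maps(t, bg_cutoff=bg_cutoff)
        stat = aggregate_min_differences(dm, l=l)
        sample = stat.sample()
        curve = fit_kde(sample, min_bandwidth=1.0)  # floor = unit grid spacing
        if curve is None:
            x_t = float("inf")
        else:
            x_t = find_threshold(curve, eps_deriv_rel=eps_deriv_rel)
        flag = np.zeros(t.shape, dtype=bool)
        if np.isfinite(x_t):
            with np.errstate(invalid="ignore"):
                flag = np.where(stat.valid_mask, stat.values > x_t, False)
        n_flagged = int(flag.sum())
        report.masks.append(flag)
        report.thresholds.append(x_t)
        report.flagged_counts.append(n_flagged)
        report.iterations_run += 1
        if n_flagged == 0:
            break
        t = median_replace(t, flag)
    out = anscombe_inverse_algebraic(t)
    np.clip(out, 0.0, None, out=out)
    return out, report
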