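"""Reference filters used to benchmark the adaptive pipeline.

NTHM clips pixels that exceed their 8-neighbour maximum by more than a
fixed threshold; MTHM replaces pixels whose excess over a local window
median exceeds a threshold; GAUSS is a normalized Gaussian blur
(defaults 5x5 kernel, sigma 0.8).  Thresholds are in count units and are
meant to be tuned per dataset.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["nthm", "mthm", "gaussian_smooth", "gaussian_kernel"]

_NEIGHBOR_FOOTPRINT = np.array(
    [[1, 1, 1],
     [1, 0, 1],
     [1, 1, 1]], dtype=bool
)


def nthm(raw: np.ndarray, threshold: float = 50.0) -> np.ndarray:
    """Neighbour-based threshold hot-pixel removal (single pass).

    A pixel exceeding the maximum of its 8 neighbours by more than
    ``threshold`` is clipped to that neighbour maximum.  Adjacent hot
    pixels shield each other and survive.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    img = np.asarray(raw, dtype=np.float64)
    nbr_max = ndimage.maximum_filter(img, footprint=_NEIGHBOR_FOOTPRINT, mode="nearest")
    out = img.copy()
    hot = img > nbr_max + threshold
    out[hot] = nbr_max[hot]
    return out


def mthm(raw: np.ndarray, threshold: float = 50.0, window: int = 3) -> np.ndarray:
    """Median-based threshold hot-pixel removal (single pass).

    Pixels whose excess over the ``window`` x ``window`` median exceeds
    ``threshold`` are replaced by that median.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    img = np.asarray(raw, dtype=np.float64)
    med = ndimage.median_filter(img, size=window, mode="nearest")
    out = img.copy()
    hot = img - med > threshold
    out[hot] = med[hot]
    return out


def gaussian_kernel(kernel_size: int = 5, sigma: float = 0.8) -> np.ndarray:
    """Discretized, sum-normalized 2D Gaussian kernel."""
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise ValueError("kernel_size must be odd and >= 1")
    half = kernel_size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-0.5 * (ax / sigma) ** 2)
    kernel = np.outer(g1, g1)
    return kernel / kernel.sum()


def gaussian_smooth(img: np.ndarray, kernel_size: int = 5, sigma: float = 0.8) -> np.ndarray:
    """Gaussian blur with an explicitly truncated, normalized kernel.

    Borders use edge replication, so constant images are exact fixed
    points.
    """
    kernel = gaussian_kernel(kernel_size, sigma)
    return ndimage.convolve(np.asarray(img, dtype=np.float64), kernel, mode="nearest")
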