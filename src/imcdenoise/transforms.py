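"""Variance stabilization and intensity normalization.

Ion-count images carry Poisson statistics; the Anscombe transform
``x -> 2*sqrt(x + 3/8)`` maps them to approximately unit variance so that
downstream neighbour-difference statistics behave like (generalized)
Gaussians.  The inverse used everywhere in this package is the direct
algebraic inverse ``y -> (y/2)**2 - 3/8``, not the exact-unbiased inverse.

Percentile normalization rescales an image by the intensity at a high
percentile (linear interpolation between order statistics, numpy's
default convention).  Values above 1 are deliberately *not* clipped; the
:class:`NormalizationRecord` keeps the scale so the mapping is exactly
invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormalizationRecord",
    "anscombe_forward",
    "anscombe_inverse_algebraic",
    "percentile_normalize",
    "denormalize",
]

#: minimum of the Anscombe transform, attained at x = 0
ANSCOMBE_MIN = 2.0 * np.sqrt(3.0 / 8.0)


@dataclass(frozen=True)
class NormalizationRecord:
    """Bookkeeping needed to undo a percentile normalization."""

    percentile: float
    scale_value: float
    channel_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.percentile <= 100.0):
            raise ValueError(f"percentile must be in [0, 100], got {self.percentile}")
        if not (self.scale_value > 0 and np.isfinite(self.scale_value)):
            raise ValueError(f"scale_value must be finite and > 0, got {self.scale_value}")


def _check_counts(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("input contains non-finite values")
    if np.any(arr < 0):
        raise ValueError("input contains negative values; counts must be >= 0")
    return arr


def anscombe_forward(img: np.ndarray) -> np.ndarray:
    """Apply the Anscombe variance-stabilizing transform ``2*sqrt(x + 3/8)``.

    Parameters
    ----------
    img : array_like
        Non-negative, finite count image (any shape).

    Returns
    -------
    numpy.ndarray of float64, same shape as the input.
    """
    arr = _check_counts(img)
    return 2.0 * np.sqrt(arr + 0.375)


def anscombe_inverse_algebraic(t: np.ndarray) -> np.ndarray:
    """Direct algebraic inverse of :func:`anscombe_forward`: ``(y/2)**2 - 3/8``."""
    arr = np.asarray(t, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("input contains non-finite values")
    if np.any(arr < 0):
        raise ValueError("transformed values must be >= 0")
    return (arr / 2.0) ** 2 - 0.375


def percentile_normalize(
    img: np.ndarray,
    percentile: float = 99.99,
    channel_id: str = "",
) -> tuple[np.ndarray, NormalizationRecord]:
    """Divide an image by the intensity at ``percentile``.

    Values above 1 are not clipped.  Raises a ``ValueError`` on an
    all-zero image (degenerate scale).
    """
    if not (99.0 <= percentile <= 100.0):
        raise ValueError(f"percentile must be in [99, 100], got {percentile}")
    arr = np.asarray(img, dtype=np.float64)
    if not np.any(arr > 0):
        raise ValueError("degenerate scale: image has no positive pixels")
    scale = float(np.percentile(arr, percentile))
    if scale <= 0:
        # pathological distribution: fall back to the max so the record stays valid
        scale = float(arr.max())
    record = NormalizationRecord(percentile=percentile, scale_value=scale, channel_id=channel_id)
    return arr / scale, record


def denormalize(img: np.ndarray, record: NormalizationRecord) -> np.ndarray:
    """Undo :func:`percentile_normalize` using its record."""
    return np.asarray(img, dtype=np.float64) * record.scale_value
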