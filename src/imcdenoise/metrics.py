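"""Image-quality and overlap metrics.

RMSE/PSNR/SSIM score restorations against simulated ground truth; STDB
(background standard deviation) and CNR (contrast-to-noise ratio) score
real images via annotated signal/background masks; PCC compares paired
acquisitions; binarization plus F1/Jaccard evaluate background removal.

Conventions: STDB uses the population (divide-by-N) standard deviation;
binarization is >=-inclusive; SSIM uses an 11-point Gaussian window with
K1 = 0.01, K2 = 0.03 and the image pair's joint dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "OverlapCounts",
    "rmse",
    "psnr",
    "ssim",
    "stdb",
    "cnr",
    "pcc",
    "binarize",
    "overlap_scores",
]


@dataclass(frozen=True)
class OverlapCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def rmse(a, b) -> float:
    a, b = _pair(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(a, b, peak: float) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    if peak <= 0:
        raise ValueError("peak must be > 0")
    a, b = _pair(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak**2 / mse)


def ssim(a, b) -> float:
    a, b = _pair(a, b)
    joint = np.concatenate([a.ravel(), b.ravel()])
    data_range = float(joint.max() - joint.min())
    if data_range == 0.0:
        return 1.0
    return float(
        structural_similarity(
            a, b, win_size=11, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03, data_range=data_range,
        )
    )


def stdb(img, bg_mask) -> float:
    """Population standard deviation of the pixels under the background mask."""
    img = np.asarray(img, dtype=np.float64)
    bg_mask = np.asarray(bg_mask, dtype=bool)
    if bg_mask.shape != img.shape:
        raise ValueError("mask shape must match image shape")
    if not bg_mask.any():
        raise ValueError("background mask is empty")
    return float(np.std(img[bg_mask]))


def cnr(img, signal_mask, bg_mask) -> float:
    """Contrast-to-noise ratio: (mean signal - mean background) / STDB."""
    img = np.asarray(img, dtype=np.float64)
    signal_mask = np.asarray(signal_mask, dtype=bool)
    if not signal_mask.any():
        raise ValueError("signal mask is empty")
    sigma_bg = stdb(img, bg_mask)
    if sigma_bg == 0.0:
        raise ValueError("undefined CNR: zero background standard deviation")
    return float((img[signal_mask].mean() - img[np.asarray(bg_mask, dtype=bool)].mean()) / sigma_bg)


def pcc(y, y_ref) -> float:
    """Pearson correlation coefficient of two equally sized samples."""
    y = np.asarray(y, dtype=np.float64).ravel()
    y_ref = np.asarray(y_ref, dtype=np.float64).ravel()
    if y.size != y_ref.size or y.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    if np.std(y) == 0.0 or np.std(y_ref) == 0.0:
        raise ValueError("undefined PCC: zero variance input")
    return float(np.corrcoef(y, y_ref)[0, 1])


def binarize(img, threshold: float) -> np.ndarray:
    """Inclusive thresholding: pixel >= threshold -> True."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(img, dtype=np.float64) >= threshold


def overlap_scores(pred_mask, truth_mask) -> tuple[OverlapCounts, float, float]:
    """Pixel-overlap counts plus F1 and Jaccard scores.

    Empty truth with empty prediction counts as perfect (1.0); empty truth
    with a non-empty prediction scores 0.
    """
    pred = np.asarray(pred_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes must match")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    counts = OverlapCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    denom_f1 = 2 * tp + fp + fn
    denom_j = tp + fp + fn
    if denom_j == 0:  # both masks empty
        return counts, 1.0, 1.0
    f1 = 2.0 * tp / denom_f1 if denom_f1 else 0.0
    jaccard = tp / denom_j
    return counts, float(f1), float(jaccard)
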