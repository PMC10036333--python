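"""Training-patch preparation: tiling, background filtering, augmentation,
percentile normalization and the train/validation split."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..transforms import NormalizationRecord, percentile_normalize

__all__ = ["PatchSet", "extract_patches", "PATCH_SIZE"]

logger = logging.getLogger(__name__)

PATCH_SIZE = 64
MIN_RECOMMENDED_PATCHES = 5000
TRAIN_FRACTION = 0.85


@dataclass
class PatchSet:
    patches: np.ndarray               # (N, 64, 64) float32, normalized
    train_idx: np.ndarray
    val_idx: np.ndarray
    record: NormalizationRecord
    n_base: int = 0                   # retained tiles before augmentation

    @property
    def train(self) -> np.ndarray:
        return self.patches[self.train_idx]

    @property
    def validation(self) -> np.ndarray:
        return self.patches[self.val_idx]


def _tile(img: np.ndarray, size: int) -> list[np.ndarray]:
    h, w = img.shape
    return [
        img[i:i + size, j:j + size]
        for i in range(0, h - size + 1, size)
        for j in range(0, w - size + 1, size)
    ]


def _augment(patch: np.ndarray) -> list[np.ndarray]:
    """The 8 dihedral orientations: rotations by 0/90/180/270 and their mirrors."""
    out = []
    for k in range(4):
        rot = np.rot90(patch, k)
        out.append(rot)
        out.append(np.fliplr(rot))
    return out


def extract_patches(
    images: list[np.ndarray],
    rho: float = 0.8,
    percentile: float = 99.99,
    seed: int = 0,
    augment: bool = True,
    channel_id: str = "",
) -> PatchSet:
    """Build a :class:`PatchSet` from restored (hot-pixel-free) images.

    Each image is tiled into non-overlapping 64x64 patches; a patch whose
    zero-pixel fraction exceeds ``rho`` is discarded as background.
    Retained patches are augmented with the 8 dihedral orientations,
    percentile-normalized with a single shared record, and split 85/15
    with a seeded shuffle.
    """
    if not (0.0 < rho <= 1.0):
        raise ValueError("rho must be in (0, 1]")
    base = []
    for img in images:
        img = np.asarray(img, dtype=np.float64)
        if img.ndim != 2:
            raise ValueError("images must be 2D")
        for patch in _tile(img, PATCH_SIZE):
            zero_frac = float(np.mean(patch == 0))
            if zero_frac <= rho:
                base.append(patch)
    if not base:
        raise ValueError("empty training set: every patch was background-dominated")
    patches = []
    for patch in base:
        patches.extend(_augment(patch) if augment else [patch])
    if len(patches) < MIN_RECOMMENDED_PATCHES:
        logger.warning(
            "only %d patches; at least %d are recommended for good generalization",
            len(patches), MIN_RECOMMENDED_PATCHES,
        )
    stack = np.stack(patches)
    normalized, record = percentile_normalize(stack, percentile, channel_id=channel_id)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patches))
    n_train = int(round(TRAIN_FRACTION * len(patches)))
    n_train = max(1, min(len(patches) - 1, n_train))
    return PatchSet(
        patches=normalized.astype(np.float32),
        train_idx=order[:n_train],
        val_idx=order[n_train:],
        record=record,
        n_base=len(base),
    )
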