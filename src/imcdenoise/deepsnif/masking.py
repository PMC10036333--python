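"""Blind-spot masking: stratified pixel selection and neighbour replacement.

A fixed fraction of pixels (default 0.2%, i.e. 8 pixels of a 64x64 patch)
is hidden from the network: the patch is partitioned into an even grid of
strata, one pixel is drawn per stratum, and each drawn pixel's value is
replaced by a uniformly chosen neighbour from its 5x5 window (centre
excluded).  The loss is evaluated only at these pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaskPlan", "make_mask"]

_WINDOW = 2  # replacement window half-width (5x5)


@dataclass
class MaskPlan:
    mask: np.ndarray                      # bool (H, W)
    offsets: list[tuple[int, int]]        # replacement source offset per masked pixel
    rate: float


def _strata_grid(n_strata: int, h: int, w: int) -> tuple[int, int]:
    """Factor n_strata into a (rows, cols) grid as square as possible."""
    best = (1, n_strata)
    best_score = float("inf")
    for rows in range(1, n_strata + 1):
        if n_strata % rows:
            continue
        cols = n_strata // rows
        score = abs((h / rows) - (w / cols))
        if score < best_score:
            best_score = score
            best = (rows, cols)
    return best


def make_mask(
    patch: np.ndarray, rate: float = 0.002, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, MaskPlan]:
    """Return a neighbour-replaced copy of ``patch`` and its mask plan."""
    if not (0.0 < rate < 0.1):
        raise ValueError("rate must be in (0, 0.1)")
    if rng is None:
        rng = np.random.default_rng()
    patch = np.asarray(patch)
    h, w = patch.shape
    n_mask = max(1, int(round(rate * patch.size)))
    rows, cols = _strata_grid(n_mask, h, w)
    y_edges = np.linspace(0, h, rows + 1).astype(int)
    x_edges = np.linspace(0, w, cols + 1).astype(int)

    mask = np.zeros((h, w), dtype=bool)
    offsets: list[tuple[int, int]] = []
    out = patch.copy()
    for iy in range(rows):
        for ix in range(cols):
            y = int(rng.integers(y_edges[iy], y_edges[iy + 1]))
            x = int(rng.integers(x_edges[ix], x_edges[ix + 1]))
            while True:
                dy = int(rng.integers(-_WINDOW, _WINDOW + 1))
                dx = int(rng.integers(-_WINDOW, _WINDOW + 1))
                if dy == 0 and dx == 0:
                    continue
                sy, sx = y + dy, x + dx
                if 0 <= sy < h and 0 <= sx < w:
                    break
            mask[y, x] = True
            offsets.append((dy, dx))
            out[y, x] = patch[sy, sx]
    return out, MaskPlan(mask=mask, offsets=offsets, rate=rate)
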