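"""Training objective: masked I-divergence plus Hessian-norm regularization.

The data term is the Csiszar I-divergence ``sum_p M_p [r log(r/F) - r + F]``
normalized by the number of masked pixels, with the zero-count convention
``0 * log(0/F) = 0``.  It is evaluated only on masked pixels, which is
what makes the blind-spot training self-supervised.

The regularizer penalizes per-pixel second derivatives of the prediction:
``|f_xx| + |f_yy| + 2|f_xy|`` by central finite differences, averaged over
interior pixels (boundary pixels are excluded) and, for batches, over
images.  Gradients are analytic so no autodiff machinery is needed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["i_divergence", "i_divergence_grad", "hessian_norm", "hessian_norm_grad",
           "total_loss", "total_loss_grad"]

_LOG_FLOOR = 1e-8


def _as_batch(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        return x[None]
    if x.ndim == 3:
        return x
    raise ValueError(f"expected 2D or batched-2D input, got ndim={x.ndim}")


def i_divergence(pred, target, mask) -> float:
    """Masked-pixel I-divergence, normalized by the masked-pixel count."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if np.any(pred <= 0):
        raise ValueError("predictions must be strictly positive")
    if np.any(target < 0):
        raise ValueError("targets must be non-negative")
    n_masked = m.sum()
    if n_masked == 0:
        return 0.0
    r = target[m]
    f = np.maximum(pred[m], _LOG_FLOOR)
    terms = np.where(r > 0, r * np.log(np.maximum(r, _LOG_FLOOR) / f), 0.0) - r + f
    return float(terms.sum() / n_masked)


def i_divergence_grad(pred, target, mask) -> np.ndarray:
    """d(i_divergence)/d(pred) = M * (1 - r/F) / sum(M)."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    grad = np.zeros_like(pred)
    n_masked = m.sum()
    if n_masked == 0:
        return grad
    f = np.maximum(pred[m], _LOG_FLOOR)
    grad[m] = (1.0 - target[m] / f) / n_masked
    return grad


def _second_diffs(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Central second differences on the interior of a 2D image."""
    fxx = img[1:-1, 2:] - 2.0 * img[1:-1, 1:-1] + img[1:-1, :-2]
    fyy = img[2:, 1:-1] - 2.0 * img[1:-1, 1:-1] + img[:-2, 1:-1]
    fxy = (img[2:, 2:] - img[2:, :-2] - img[:-2, 2:] + img[:-2, :-2]) / 4.0
    return fxx, fyy, fxy


def hessian_norm(pred) -> float:
    """Mean over interior pixels (and batch) of |f_xx| + |f_yy| + 2|f_xy|."""
    batch = _as_batch(pred)
    if batch.shape[1] < 3 or batch.shape[2] < 3:
        return 0.0
    total = 0.0
    n_interior = (batch.shape[1] - 2) * (batch.shape[2] - 2)
    for img in batch:
        fxx, fyy, fxy = _second_diffs(img)
        total += (np.abs(fxx) + np.abs(fyy) + 2.0 * np.abs(fxy)).sum() / n_interior
    return float(total / batch.shape[0])


def hessian_norm_grad(pred) -> np.ndarray:
    """Analytic (sub)gradient of :func:`hessian_norm` w.r.t. the prediction."""
    batch = _as_batch(pred)
    grads = np.zeros_like(batch)
    if batch.shape[1] < 3 or batch.shape[2] < 3:
        return grads.reshape(np.asarray(pred).shape)
    n_interior = (batch.shape[1] - 2) * (batch.shape[2] - 2)
    scale = 1.0 / (n_interior * batch.shape[0])
    for b, img in enumerate(batch):
        fxx, fyy, fxy = _second_diffs(img)
        g = grads[b]
        sx = np.sign(fxx) * scale
        g[1:-1, 2:] += sx
        g[1:-1, 1:-1] += -2.0 * sx
        g[1:-1, :-2] += sx
        sy = np.sign(fyy) * scale
        g[2:, 1:-1] += sy
        g[1:-1, 1:-1] += -2.0 * sy
        g[:-2, 1:-1] += sy
        sxy = 2.0 * np.sign(fxy) * scale / 4.0
        g[2:, 2:] += sxy
        g[2:, :-2] -= sxy
        g[:-2, 2:] -= sxy
        g[:-2, :-2] += sxy
    return grads.reshape(np.asarray(pred).shape)


def total_loss(pred, target, mask, lambda_hessian: float) -> float:
    """Masked I-divergence plus ``lambda_hessian`` times the Hessian norm."""
    if lambda_hessian < 0:
        raise ValueError("lambda_hessian must be >= 0")
    loss = i_divergence(pred, target, mask)
    if lambda_hessian > 0:
        loss += lambda_hessian * hessian_norm(pred)
    return loss


def total_loss_grad(pred, target, mask, lambda_hessian: float) -> np.ndarray:
    grad = i_divergence_grad(pred, target, mask)
    if lambda_hessian > 0:
        grad = grad + lambda_hessian * hessian_norm_grad(pred)
    return grad
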