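"""Minimal NumPy CNN core: layers with explicit forward/backward passes.

No deep-learning framework is assumed at runtime, so the denoising
network is built from hand-written layers operating on float32 NHWC
arrays (channel-last keeps the im2col/scatter memory traffic
cache-friendly).  Each layer caches what its backward pass needs;
``backward`` must be called after ``forward`` with gradients of the same
shape as the forward output.

The residual U-Net (:class:`ResUNet`) has a fixed depth of four 2x
down-samplings, which is why inference inputs must have spatial
dimensions divisible by 16.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "BatchNorm2D", "ReLU", "Softplus", "MaxPool2", "Upsample2",
           "Dropout", "ResBlock", "ResUNet", "Adam"]

_DTYPE = np.float32


class Layer:
    """Base class; layers expose ``params()`` as (name, array, grad) triples."""

    def params(self):
        return []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """'same' convolution (zero padding) with kernel size 1 or 3, NHWC.

    Weights are stored flat as (k*k*c_in, c_out) in (ki, kj, c) order so the
    forward pass is a single GEMM against the im2col matrix.
    """

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        if ksize not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.c_in, self.c_out, self.k = c_in, c_out, ksize
        fan_in = c_in * ksize * ksize
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(fan_in, c_out)).astype(_DTYPE)
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    @staticmethod
    def _strips(xp: np.ndarray, ki: int, h: int, w: int) -> np.ndarray:
        """Row-shifted 1x3 window matrix of a padded NHWC array.

        Returns a contiguous (n*h*w, 3c) matrix whose row (n, i, j) holds
        the 3c values xp[n, ki+i, j:j+3, :]; the overlapping window is a
        zero-copy strided view, materialized in one cache-friendly pass.
        """
        n = xp.shape[0]
        c = xp.shape[3]
        base = xp[:, ki:ki + h]
        s = base.strides
        view = np.lib.stride_tricks.as_strided(
            base, shape=(n, h, w, 3 * c), strides=(s[0], s[1], s[2], s[3]),
            writeable=False)
        return np.ascontiguousarray(view).reshape(-1, 3 * c)

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        self._shape = x.shape
        if self.k == 1:
            self._cols = x.reshape(-1, c)
            out = self._cols @ self.w + self.b
            return out.reshape(n, h, w, self.c_out)
        # decompose the 3x3 conv into 3 row shifts x (1x3 conv along W):
        # three GEMMs with K = 3c on large contiguous strips
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self._xp = xp
        wk = self.w.reshape(3, 3 * c, self.c_out)
        out = None
        for ki in range(3):
            r = self._strips(xp, ki, h, w) @ wk[ki]
            out = r if out is None else np.add(out, r, out=out)
        out += self.b
        return out.reshape(n, h, w, self.c_out)

    def backward(self, gout):
        gflat = gout.reshape(-1, self.c_out)
        self.gb += gflat.sum(axis=0)
        if self.k == 1:
            self.gw += self._cols.T @ gflat
            return (gflat @ self.w.T).reshape(self._shape)
        n, h, w, c = self._shape
        # weight gradient: same strips as the forward pass
        gwk = self.gw.reshape(3, 3 * c, self.c_out)
        for ki in range(3):
            gwk[ki] += self._strips(self._xp, ki, h, w).T @ gflat
        # input gradient: 'same' correlation of gout with spatially flipped,
        # channel-transposed weights, using the identical strip scheme
        w4 = self.w.reshape(3, 3, c, self.c_out)
        wb = np.ascontiguousarray(
            w4[::-1, ::-1].transpose(0, 1, 3, 2)).reshape(3, 3 * self.c_out, c)
        gp = np.pad(gout, ((0, 0), (1, 1), (1, 1), (0, 0)))
        dx = None
        for ki in range(3):
            r = self._strips(gp, ki, h, w) @ wb[ki]
            dx = r if dx is None else np.add(dx, r, out=dx)
        return dx.reshape(self._shape)


class BatchNorm2D(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=_DTYPE)
        self.beta = np.zeros(c, dtype=_DTYPE)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=_DTYPE)
        self.running_var = np.ones(c, dtype=_DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [("gamma", self.gamma, self.ggamma), ("beta", self.beta, self.gbeta)]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(_DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(_DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(_DTYPE)
        xhat = ((x - mean) * inv_std).astype(_DTYPE)
        self._cache = (xhat, inv_std, training, x.shape)
        return xhat * self.gamma + self.beta

    def backward(self, gout):
        xhat, inv_std, training, shape = self._cache
        self.ggamma += (gout * xhat).sum(axis=(0, 1, 2))
        self.gbeta += gout.sum(axis=(0, 1, 2))
        gxhat = gout * self.gamma
        if not training:
            return gxhat * inv_std
        n = shape[0] * shape[1] * shape[2]
        sum_g = gxhat.sum(axis=(0, 1, 2))
        sum_gx = (gxhat * xhat).sum(axis=(0, 1, 2))
        return (inv_std / n * (n * gxhat - sum_g - xhat * sum_gx)).astype(_DTYPE)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(_DTYPE)

    def backward(self, gout):
        return np.where(self._mask, gout, 0).astype(_DTYPE)


class Softplus(Layer):
    """log(1 + exp(x)), numerically stable; final activation (output > 0)."""

    def forward(self, x, training=False):
        self._sig = (1.0 / (1.0 + np.exp(-x))).astype(_DTYPE)
        return (np.logaddexp(0.0, x)).astype(_DTYPE)

    def backward(self, gout):
        return (gout * self._sig).astype(_DTYPE)


class MaxPool2(Layer):
    def forward(self, x, training=False):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        self._cache = (mask, counts, x.shape)
        return out

    def backward(self, gout):
        mask, counts, shape = self._cache
        g = gout[:, :, None, :, None, :] * (mask / counts)
        return g.reshape(shape).astype(_DTYPE)


class Upsample2(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x, training=False):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, gout):
        n, h, w, c = gout.shape
        return gout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(_DTYPE)


class Dropout(Layer):
    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng: np.random.Generator | None = None):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_DTYPE) / keep
        return (x * self._mask).astype(_DTYPE)

    def backward(self, gout):
        if self._mask is None:
            return gout
        return (gout * self._mask).astype(_DTYPE)


class ResBlock(Layer):
    """conv3x3 -> BN -> (+ shortcut) -> ReLU; 1x1 projection if widths differ."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv = Conv2D(c_in, c_out, 3, rng)
        self.bn = BatchNorm2D(c_out)
        self.relu = ReLU()
        self.proj = Conv2D(c_in, c_out, 1, rng) if c_in != c_out else None

    def params(self):
        out = [(f"conv.{n}", p, g) for n, p, g in self.conv.params()]
        out += [(f"bn.{n}", p, g) for n, p, g in self.bn.params()]
        if self.proj is not None:
            out += [(f"proj.{n}", p, g) for n, p, g in self.proj.params()]
        return out

    def forward(self, x, training=False):
        h = self.bn.forward(self.conv.forward(x, training), training)
        s = self.proj.forward(x, training) if self.proj is not None else x
        return self.relu.forward(h + s, training)

    def backward(self, gout):
        g = self.relu.backward(gout)
        gx = self.proj.backward(g) if self.proj is not None else g.copy()
        gx += self.conv.backward(self.bn.backward(g))
        return gx


class ResUNet:
    """Residual U-Net: 4 pooled encoder levels, 2 bottleneck blocks with
    dropout, concatenating skip connections, softplus output.

    Batches are NHWC: ``(N, H, W, 1)`` in, same shape out, H and W
    divisible by 16.
    """

    DEPTH = 4

    def __init__(self, base_filters: int = 32, dropout_rate: float = 0.5, seed: int = 0,
                 in_channels: int = 1):
        rng = np.random.default_rng(seed)
        f = base_filters
        widths = [f * (2 ** i) for i in range(self.DEPTH)]          # 8,16,32,64 @ f=8
        bott = f * (2 ** self.DEPTH)                                # 128 @ f=8
        self.enc = []
        c = in_channels
        for width in widths:
            self.enc.append(ResBlock(c, width, rng))
            c = width
        self.pools = [MaxPool2() for _ in range(self.DEPTH)]
        self.bott1 = ResBlock(widths[-1], bott, rng)
        self.drop1 = Dropout(dropout_rate)
        self.bott2 = ResBlock(bott, bott, rng)
        self.drop2 = Dropout(dropout_rate)
        self.ups = [Upsample2() for _ in range(self.DEPTH)]
        self.dec = []
        c = bott
        for width in reversed(widths):
            self.dec.append(ResBlock(c + width, width, rng))
            c = width
        self.final = Conv2D(widths[0], 1, 1, rng)
        self.softplus = Softplus()
        self.base_filters = base_filters
        self.dropout_rate = dropout_rate
        self._skip_channels = list(reversed(widths))

    # -- parameter plumbing -------------------------------------------------
    def _blocks(self):
        named = [(f"enc{i}", b) for i, b in enumerate(self.enc)]
        named += [("bott1", self.bott1), ("bott2", self.bott2)]
        named += [(f"dec{i}", b) for i, b in enumerate(self.dec)]
        named += [("final", self.final)]
        return named

    def params(self):
        out = []
        for bname, block in self._blocks():
            out += [(f"{bname}.{n}", p, g) for n, p, g in block.params()]
        return out

    def zero_grad(self):
        for _, _, g in self.params():
            g[...] = 0.0

    def state_dict(self) -> dict:
        state = {name: p.copy() for name, p, _ in self.params()}
        for i, (_, block) in enumerate(self._blocks()):
            bn = getattr(block, "bn", None)
            if bn is not None:
                state[f"_running_mean_{i}"] = bn.running_mean.copy()
                state[f"_running_var_{i}"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, p, _ in self.params():
            p[...] = state[name]
        for i, (_, block) in enumerate(self._blocks()):
            bn = getattr(block, "bn", None)
            if bn is not None:
                bn.running_mean[...] = state[f"_running_mean_{i}"]
                bn.running_var[...] = state[f"_running_var_{i}"]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """x: (N, H, W, 1) float32 with H, W divisible by 16."""
        if x.ndim != 4:
            raise ValueError("expected a 4D NHWC batch")
        if x.shape[1] % 16 or x.shape[2] % 16:
            raise ValueError("spatial dims must be divisible by 16")
        x = x.astype(_DTYPE, copy=False)
        skips = []
        h = x
        for block, pool in zip(self.enc, self.pools):
            h = block.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        h = self.drop1.forward(self.bott1.forward(h, training), training, rng=rng)
        h = self.drop2.forward(self.bott2.forward(h, training), training, rng=rng)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, training)
            h = block.forward(np.concatenate([skip, h], axis=3), training)
        h = self.final.forward(h, training)
        return self.softplus.forward(h, training)

    def backward(self, gout: np.ndarray) -> None:
        g = self.softplus.backward(gout.astype(_DTYPE, copy=False))
        g = self.final.backward(g)
        skip_grads = []
        for i in range(self.DEPTH - 1, -1, -1):
            c_skip = self._skip_channels[i]
            g = self.dec[i].backward(g)
            skip_grads.append(g[..., :c_skip])
            g = self.ups[i].backward(g[..., c_skip:])
        g = self.bott2.backward(self.drop2.backward(g))
        g = self.bott1.backward(self.drop1.backward(g))
        # skip_grads were appended while walking dec[DEPTH-1] .. dec[0], i.e.
        # in encoder order already
        for i in range(self.DEPTH - 1, -1, -1):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc[i].backward(g)


class Adam:
    def __init__(self, net: ResUNet, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(p) for name, p, _ in net.params()}
        self.v = {name: np.zeros_like(p) for name, p, _ in net.params()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for name, p, g in self.net.params():
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
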