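"""Self-supervised training loop and padding-aware inference.

Per epoch, fresh blind-spot masks are drawn for every patch; the network
is optimized with Adam on the masked I-divergence + Hessian objective and
evaluated on the held-out split, with learning-rate decay on a validation
plateau.  Everything is driven by one seeded generator, so runs are
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..transforms import NormalizationRecord
from .losses import total_loss, total_loss_grad
from .masking import make_mask
from .nn import Adam, ResUNet
from .patches import PatchSet

__all__ = ["NetworkSpec", "TrainConfig", "TrainedDenoiser", "train", "predict",
           "save_model", "load_model"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture knobs; depth is fixed at 4 by the x16 size constraint."""

    base_filters: int = 32
    dropout_rate: float = 0.5
    depth: int = 4

    def __post_init__(self) -> None:
        if self.depth != 4:
            raise ValueError("depth is fixed at 4 (inputs padded to multiples of 16)")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")


@dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 200
    batch_size: int = 128
    lr_factor: float = 0.6
    lr_patience: int = 20
    lambda_hessian: float = 3e-6
    masking_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_hessian < 0:
            raise ValueError("lambda_hessian must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainedDenoiser:
    network: ResUNet
    spec: NetworkSpec
    record: NormalizationRecord
    history: dict = field(default_factory=dict)


def _masked_batch(patches: np.ndarray, rate: float, rng: np.random.Generator):
    """Draw fresh blind-spot masks for a batch of patches."""
    inputs = np.empty_like(patches)
    masks = np.zeros(patches.shape, dtype=bool)
    for i, patch in enumerate(patches):
        masked, plan = make_mask(patch, rate=rate, rng=rng)
        inputs[i] = masked
        masks[i] = plan.mask
    return inputs, masks


def _run_batch(net, opt, patches, cfg, rng, training):
    inputs, masks = _masked_batch(patches, cfg.masking_rate, rng)
    pred = net.forward(inputs[..., None], training=training, rng=rng)
    pred2d = pred[..., 0].astype(np.float64)
    target = patches.astype(np.float64)
    loss = total_loss(pred2d, target, masks, cfg.lambda_hessian)
    if training:
        grad = total_loss_grad(pred2d, target, masks, cfg.lambda_hessian)
        net.zero_grad()
        net.backward(grad[..., None].astype(np.float32))
        opt.step()
    return loss


def train(patchset: PatchSet, spec: NetworkSpec | None = None,
          cfg: TrainConfig | None = None) -> TrainedDenoiser:
    """Train a denoiser on a :class:`PatchSet`; returns weights + history."""
    spec = spec or NetworkSpec()
    cfg = cfg or TrainConfig()
    if patchset.train_idx.size == 0 or patchset.val_idx.size == 0:
        raise ValueError("patch set must contain both training and validation patches")
    rng = np.random.default_rng(cfg.seed)
    net = ResUNet(base_filters=spec.base_filters, dropout_rate=spec.dropout_rate,
                  seed=cfg.seed)
    opt = Adam(net, lr=cfg.lr)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    stale = 0
    train_patches = patchset.train
    val_patches = patchset.validation
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_patches.shape[0])
        epoch_losses = []
        for start in range(0, order.size, cfg.batch_size):
            batch = train_patches[order[start:start + cfg.batch_size]]
            loss = _run_batch(net, opt, batch, cfg, rng, training=True)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"divergent training loss at epoch {epoch}: {loss}")
            epoch_losses.append(loss)
        val_losses = [
            _run_batch(net, None, val_patches[s:s + cfg.batch_size], cfg, rng,
                       training=False)
            for s in range(0, val_patches.shape[0], cfg.batch_size)
        ]
        train_loss = float(np.mean(epoch_losses))
        val_loss = float(np.mean(val_losses))
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.lr_patience:
                opt.lr *= cfg.lr_factor
                stale = 0
                logger.info("epoch %d: lr decayed to %.3g", epoch, opt.lr)
    return TrainedDenoiser(network=net, spec=spec, record=patchset.record,
                           history=history)


def predict(model: TrainedDenoiser, img: np.ndarray) -> np.ndarray:
    """Denoise one image: pad to multiples of 16, normalize, forward, rescale."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2D image")
    h, w = img.shape
    ph = (-h) % 16
    pw = (-w) % 16
    padded = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    norm = (padded / model.record.scale_value).astype(np.float32)
    out = model.network.forward(norm[None, :, :, None], training=False)
    return out[0, :h, :w, 0].astype(np.float64) * model.record.scale_value


def save_model(model: TrainedDenoiser, path: str | Path) -> None:
    """Serialize weights + spec + normalization record to an .npz file."""
    meta = {
        "spec": asdict(model.spec),
        "record": {
            "percentile": model.record.percentile,
            "scale_value": model.record.scale_value,
            "channel_id": model.record.channel_id,
        },
        "history": model.history,
    }
    state = model.network.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_model(path: str | Path) -> TrainedDenoiser:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    spec = NetworkSpec(**meta["spec"])
    net = ResUNet(base_filters=spec.base_filters, dropout_rate=spec.dropout_rate)
    net.load_state_dict(state)
    record = NormalizationRecord(**meta["record"])
    return TrainedDenoiser(network=net, spec=spec, record=record,
                           history=meta.get("history", {}))
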