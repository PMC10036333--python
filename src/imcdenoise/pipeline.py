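"""Umbrella pipeline: hot-pixel removal, per-channel training, prediction.

``run_pipeline`` executes stage 1 on every manifest channel, optionally
trains one denoiser per channel on the restored images, predicts, writes
denoised TIFFs and emits a JSON provenance record sufficient to re-run
each stage.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np

from . import __version__
from .deepsnif import NetworkSpec, TrainConfig, extract_patches, predict, train
from .dimr import dimr
from .io import ChannelManifest, RunConfig, read_tiff, write_tiff

__all__ = ["run_pipeline"]


def _stage(name: str, channel: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise RuntimeError(f"stage {name!r} failed on channel {channel!r}: {exc}") from exc


def run_pipeline(cfg: RunConfig, manifest: ChannelManifest, out_dir: str | Path) -> dict:
    """Run DIMR (and optionally DeepSNiF) over all manifest channels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": cfg.__dict__ | {
            "sim_lambda_fg": list(cfg.sim_lambda_fg),
            "sim_densities": list(cfg.sim_densities),
        },
        "channels": {},
    }
    for path, channel in zip(manifest.paths, manifest.channels):
        raw = _stage("read", channel, read_tiff, path)
        restored, report = _stage(
            "dimr", channel, dimr, raw,
            n_iter=cfg.dimr_n_iter, l=cfg.dimr_l, bg_cutoff=cfg.dimr_bg_cutoff,
        )
        entry = {"input": str(path), "dimr": report.to_dict()}
        if cfg.skip_deepsnif:
            out_path = out_dir / f"{channel}_dimr.tiff"
            write_tiff(restored, out_path)
            entry["output"] = str(out_path)
        else:
            patchset = _stage(
                "extract_patches", channel, extract_patches, [restored],
                rho=cfg.rho, percentile=cfg.percentile, seed=cfg.seed,
                channel_id=channel,
            )
            model = _stage(
                "train", channel, train, patchset,
                NetworkSpec(base_filters=cfg.base_filters),
                TrainConfig(lr=cfg.lr, epochs=cfg.epochs, batch_size=cfg.batch_size,
                            lambda_hessian=cfg.lambda_hessian,
                            masking_rate=cfg.masking_rate, seed=cfg.seed),
            )
            denoised = _stage("predict", channel, predict, model, restored)
            out_path = out_dir / f"{channel}_denoised.tiff"
            write_tiff(denoised, out_path)
            entry["output"] = str(out_path)
            entry["training"] = {
                "n_patches": int(patchset.patches.shape[0]),
                "final_train_loss": model.history["train_loss"][-1],
                "final_val_loss": model.history["val_loss"][-1],
                "normalization_scale": model.record.scale_value,
            }
        provenance["channels"][channel] = entry
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return provenance
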