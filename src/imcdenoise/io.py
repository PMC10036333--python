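"""File formats and run configuration.

Single-channel TIFF in/out (uint16 or float32), a CSV channel manifest,
and a YAML-serialized run configuration covering every stage parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["read_tiff", "write_tiff", "ChannelManifest", "RunConfig"]

_SUPPORTED_DTYPES = {np.dtype(np.uint16), np.dtype(np.float32)}


def read_tiff(path: str | Path) -> np.ndarray:
    """Read a single-channel 2D TIFF; rejects multi-page and RGB layouts."""
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(
                f"unsupported format: {path} is a multi-page TIFF "
                f"({len(tif.pages)} pages); expected a single 2D channel")
        arr = tif.pages[0].asarray()
    if arr.ndim != 2:
        raise ValueError(
            f"unsupported format: {path} has shape {arr.shape}; expected a "
            "single-channel 2D image (RGB/stacked layouts are not supported)")
    return arr


def write_tiff(img: np.ndarray, path: str | Path, dtype: str = "float32") -> None:
    """Write a 2D image; float32 by default (restored images are real-valued)."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("only 2D single-channel images are written")
    np_dtype = np.dtype(dtype)
    if np_dtype not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported dtype {dtype}; use uint16 or float32")
    tifffile.imwrite(path, img.astype(np_dtype))


@dataclass
class ChannelManifest:
    """Rows of (path, channel name, metal tag), one per marker image."""

    paths: list[str]
    channels: list[str]
    metals: list[str]

    def __post_init__(self) -> None:
        if not (len(self.paths) == len(self.channels) == len(self.metals)):
            raise ValueError("manifest columns must have equal length")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")

    @classmethod
    def read_csv(cls, path: str | Path, check_paths: bool = True) -> "ChannelManifest":
        import pandas as pd

        df = pd.read_csv(path)
        required = {"path", "channel", "metal"}
        if not required.issubset(df.columns):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        base = Path(path).parent
        resolved = [str((base / p)) if not Path(p).is_absolute() else p
                    for p in df["path"]]
        if check_paths:
            missing = [p for p in resolved if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"manifest references missing files: {missing}")
        return cls(paths=resolved, channels=list(df["channel"].astype(str)),
                   metals=list(df["metal"].astype(str)))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"path": self.paths, "channel": self.channels, "metal": self.metals}
        ).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Every stage parameter, serializable to YAML (unknown keys rejected)."""

    # DIMR
    dimr_n_iter: int = 3
    dimr_l: int = 4
    dimr_bg_cutoff: float = 4.0
    # DeepSNiF
    rho: float = 0.8
    percentile: float = 99.99
    lambda_hessian: float = 3e-6
    epochs: int = 200
    batch_size: int = 128
    lr: float = 1e-3
    base_filters: int = 32
    masking_rate: float = 0.002
    seed: int = 0
    skip_deepsnif: bool = False
    # simulator grid
    sim_lambda_fg: list = field(default_factory=lambda: [5.0, 10.0, 20.0, 50.0])
    sim_densities: list = field(default_factory=lambda: [0.001, 0.005, 0.01])

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
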