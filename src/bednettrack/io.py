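"""Frame-stack and table I/O.

Frame stacks are 8-bit greyscale, stored either as a multi-page TIFF or as a
directory of numbered PNGs.  Detection/track tables are CSV with leading
``#`` provenance comment lines (config hash and seed), metrics are JSON with
an explicit provenance block.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from bednettrack.config import DataError


def _validate_stack(frames: np.ndarray, source: str) -> np.ndarray:
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise DataError(f"{source}: expected greyscale frames, got shape {frames.shape}")
    if frames.dtype != np.uint8:
        raise DataError(f"{source}: expected 8-bit greyscale input, got {frames.dtype}")
    return frames


def read_frames(path) -> np.ndarray:
    """Read an ordered frame stack from a multi-page TIFF or a PNG directory."""
    p = Path(path)
    if p.is_dir():
        files = sorted(p.glob("*.png"))
        if not files:
            raise DataError(f"{p}: no .png frames found in directory")
        imgs = []
        shape = None
        for f in files:
            img = iio.imread(f)
            if img.ndim == 3:  # greyscale stored with redundant channels
                if not (img == img[..., :1]).all():
                    raise DataError(f"{f}: expected greyscale PNG")
                img = img[..., 0]
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise DataError(f"{f}: frame dimensions differ ({img.shape} vs {shape})")
            imgs.append(img)
        return _validate_stack(np.stack(imgs), str(p))
    if p.suffix.lower() in (".tif", ".tiff"):
        if not p.exists():
            raise DataError(f"{p}: no such file")
        return _validate_stack(tifffile.imread(p), str(p))
    raise DataError(f"{p}: expected a .tif/.tiff stack or a directory of PNGs")


def write_frames(path, frames: np.ndarray) -> None:
    """Write a uint8 frame stack as multi-page TIFF (or PNG dir if ``path`` has no suffix)."""
    frames = _validate_stack(np.asarray(frames), str(path))
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, frames)
    else:
        p.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(p / f"frame_{i:05d}.png", frame)


def provenance_header(config_hash: str, seed: int) -> str:
    from bednettrack import __version__

    return f"# bednettrack {__version__} config={config_hash} seed={seed}"


def write_table(df: pd.DataFrame, path, config_hash: str = "none", seed: int = 0) -> None:
    """CSV with a leading provenance comment line."""
    with open(path, "w") as fh:
        fh.write(provenance_header(config_hash, seed) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_metrics_json(metrics: dict, path, config_hash: str = "none", seed: int = 0) -> None:
    from bednettrack import __version__

    payload = {
        "provenance": {
            "package": f"bednettrack {__version__}",
            "config": config_hash,
            "seed": seed,
        },
        "metrics": metrics,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
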