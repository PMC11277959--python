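"""Reading and writing the pipeline's file formats.

Images: 8-bit PNG/TIFF (Pillow / tifffile).  Masks: PNG with 0/255.
Tables: CSV with a provenance header comment carrying the config hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = ["read_image", "write_image", "write_mask", "read_mask",
           "write_csv", "config_hash"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/TIFF; multi-channel inputs are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(str(path))
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:
        raise ValueError(f"cannot read image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        if not (arr[..., 0] == arr[..., 1]).all():
            raise ValueError(f"{path}: expected single-channel image")
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected 2D image, got shape {arr.shape}")
    return arr.astype(np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), np.asarray(image))
    else:
        Image.fromarray(np.asarray(image)).save(path)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    write_image(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path) > 0


def config_hash(config) -> str:
    """Stable short hash of a config's canonical JSON rendering."""
    if hasattr(config, "to_dict"):
        payload = config.to_dict()
    else:
        payload = dict(config)
    # provenance covers analysis parameters, not where results are written
    payload.pop("out_dir", None)
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_csv(path: str | Path, frame: pd.DataFrame,
              cfg_hash: str | None = None, float_format: str = "%.10g") -> None:
    """Write a CSV with an optional provenance header comment; float
    formatting is fixed so identical runs are byte-identical."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if cfg_hash:
            fh.write(f"# config_hash: {cfg_hash}\n")
        frame.to_csv(fh, index=False, float_format=float_format,
                     lineterminator="\n")
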