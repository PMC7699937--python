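"""Image and CSV I/O helpers.

Images load as float RGB in [0,1] (8- and 16-bit integer depths divided by
their dtype maximum; grey images are promoted to three channels). Point
CSVs use the convention: header ``x,y``, origin top-left, x = column,
y = row, 0-based.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["load_image", "save_image", "read_points_csv", "write_points_csv"]


def load_image(path) -> np.ndarray:
    """Read PNG/TIFF/JPEG into an (h, w, 3) float array in [0,1]."""
    arr = iio.imread(Path(path))
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"unsupported image shape {arr.shape}")
    return arr


def save_image(path, img: np.ndarray, depth: int = 8) -> None:
    """Write a float image in [0,1] (grey or RGB) as an 8- or 16-bit PNG."""
    if depth not in (8, 16):
        raise ValueError("depth must be 8 or 16")
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    if depth == 8:
        iio.imwrite(Path(path), (np.round(arr * 255)).astype(np.uint8))
    else:
        iio.imwrite(Path(path), (np.round(arr * 65535)).astype(np.uint16))


def read_points_csv(path) -> np.ndarray:
    """Read an (x, y) point table; raises ValueError naming the offending
    line for malformed content."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    xy = df[["x", "y"]].apply(pd.to_numeric, errors="coerce")
    bad = xy.isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(bad.idxmax()) + 2
        raise ValueError(f"{path}: non-numeric coordinate at line {line}")
    return xy.to_numpy(dtype=np.float64)


def write_points_csv(path, points: np.ndarray, extra: dict | None = None) -> None:
    """Write points (and optional extra columns) with x, y to 3 decimals."""
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    df = pd.DataFrame({"x": np.round(pts[:, 0], 3),
                       "y": np.round(pts[:, 1], 3)})
    for name, vals in (extra or {}).items():
        df[name] = vals
    df.to_csv(path, index=False, lineterminator="\n")
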