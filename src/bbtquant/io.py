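"""Image, mask and table readers/writers with strict format contracts.

Images are 8-bit grayscale PNG/TIFF; anything deeper raises an explicit
error rather than silently rescaling (pass ``allow_rescale=True`` to opt
in).  Masks are 0/255 PNG on disk, boolean in memory; round trips are
lossless.  Tables are CSV with documented headers, validated on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from ._util import as_binary_mask


def read_image(path, allow_rescale: bool = False) -> np.ndarray:
    """Read an 8-bit grayscale image; reject deeper bit depths by default."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4) and np.ptp(arr[..., :3], axis=2).max() == 0:
            arr = arr[..., 0]  # gray stored as RGB
        else:
            raise ValueError(f"{path}: expected grayscale, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr
    if allow_rescale:
        arr = arr.astype(float)
        rng = arr.max() - arr.min()
        if rng == 0:
            return np.zeros(arr.shape, dtype=np.uint8)
        return np.rint((arr - arr.min()) / rng * 255).astype(np.uint8)
    raise ValueError(
        f"{path}: unsupported bit depth {arr.dtype}; pass allow_rescale=True "
        "(CLI: --allow-rescale) to convert to 8-bit"
    )


def write_image(path, image: np.ndarray) -> None:
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError("write_image expects uint8")
    iio.imwrite(path, arr)


def read_mask(path) -> np.ndarray:
    """Read a 0/255 (or 0/1) PNG mask as a boolean array."""
    return as_binary_mask(iio.imread(path))


def write_mask(path, mask) -> None:
    m = as_binary_mask(mask)
    iio.imwrite(path, (m.astype(np.uint8)) * 255)


def read_table(path, required_columns=("case", "width_mm", "height_mm")) -> pd.DataFrame:
    """Read a CSV table, checking each required column by name."""
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
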