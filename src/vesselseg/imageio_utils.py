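"""Reading and writing images as float arrays in [0, 1]."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np


def read_image(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF/PPM/GIF into float [0, 1]; RGBA is reduced to RGB."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(float), 0.0, 1.0)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask: any channel above half intensity counts as 1."""
    arr = read_image(path)
    if arr.ndim == 3:
        arr = arr.max(axis=2)
    return arr > 0.5


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float [0,1] or boolean image as 8-bit PNG/TIFF."""
    arr = np.asarray(image)
    if arr.dtype == bool:
        out = arr.astype(np.uint8) * 255
    else:
        out = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, out)
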