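"""Image and table I/O.

Reads RGB/grayscale microscopy images (TIFF or PNG), converts RGB to
luminance grayscale, and writes masks and CSV tables.  Conventions:

* pixels are 8-bit; 16-bit inputs are rescaled by integer division by 257
  (a fixed rescale, so feature values stay comparable across images);
* coordinates are row-major, 0-based, (row, col), top-left origin;
* binary masks on disk are 0/255 8-bit PNG, label masks 16-bit PNG.
"""

from __future__ import annotations

import logging
import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: ITU-R BT.601 luminance weights (the MATLAB ``rgb2gray`` convention).
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a TIFF or PNG image as an 8-bit array.

    Returns a 2-D array for single-channel inputs or an ``(H, W, 3)``
    array for RGB.  A 4th (alpha) channel is dropped with a logged
    warning; 2- or >4-channel inputs are rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise IOError(f"empty image file: {path}")
    img = np.asarray(iio.imread(path))
    if img.dtype == np.uint16:
        img = (img // 257).astype(np.uint8)
    elif img.dtype == bool:
        img = img.astype(np.uint8) * 255
    elif img.dtype != np.uint8:
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if img.ndim == 2:
        return img
    if img.ndim == 3:
        if img.shape[2] == 3:
            return img
        if img.shape[2] == 4:
            log.warning("dropping alpha channel of %s", path)
            return img[:, :, :3]
        if img.shape[2] == 1:
            return img[:, :, 0]
    raise ValueError(f"unsupported image layout {img.shape} in {path}")


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """RGB -> 8-bit luminance, ``0.2989 R + 0.5870 G + 0.1140 B``.

    Rounds half-up to the nearest integer and clips to [0, 255].
    Grayscale input is returned unchanged (as uint8).
    """
    img = np.asarray(img)
    if img.ndim == 2:
        return img.astype(np.uint8, copy=True)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    lum = img[..., 0] * LUMA_WEIGHTS[0] + img[..., 1] * LUMA_WEIGHTS[1] + img[..., 2] * LUMA_WEIGHTS[2]
    return np.clip(np.floor(lum + 0.5), 0, 255).astype(np.uint8)


def write_image(path: str | os.PathLike, arr: np.ndarray) -> None:
    """Write an image or mask.  Boolean masks become 0/255 uint8."""
    arr = np.asarray(arr)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    iio.imwrite(os.fspath(path), arr)


def write_table(rows, path: str | os.PathLike, columns=None) -> None:
    """Write records to CSV with a header row and 6-significant-digit
    floats, preserving the given row order.

    ``rows`` may be a DataFrame or a list of mappings sharing one schema;
    ``columns`` fixes the header for an empty row list.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        rows = list(rows)
        if not rows and columns is None:
            raise ValueError("columns required to write an empty table")
        frame = pd.DataFrame(rows, columns=columns if columns is not None else list(rows[0]))
    frame.to_csv(path, index=False, float_format="%.6g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
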