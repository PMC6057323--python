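"""Core data container for a segmented nucleus.

A :class:`NucleusRegion` is one 8-connected component cut out of the
segmented image: its binary mask, bounding box (half-open, row-major,
0-based, top-left origin) and the masked grayscale crop in which every
pixel outside the mask is exactly zero -- the "segmented nucleus image"
that all texture features are computed from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

#: 8-connectivity structuring element used for component labeling everywhere.
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


class DegenerateRegionError(ValueError):
    """Raised when a region cannot support a feature family (e.g. no
    co-occurring pixel pair, or no interior pixel for LBP codes)."""


@dataclass
class NucleusRegion:
    """One segmented nucleus.

    Parameters
    ----------
    label : int
        Positive component label, unique within the source image.
    mask : ndarray of bool
        Binary mask cropped to the bounding box; a single 8-connected
        component.
    bbox : tuple of int
        ``(row0, col0, row1, col1)`` half-open bounding box in the frame
        of the source image.
    pixels : ndarray of uint8
        Masked grayscale crop; zero outside the mask.
    """

    label: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    pixels: np.ndarray
    area_px: int = field(default=0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.pixels = np.asarray(self.pixels)
        if self.mask.shape != self.pixels.shape:
            raise ValueError("mask and pixels must share one shape")
        if self.mask.ndim != 2:
            raise ValueError("region mask must be 2-D")
        if not self.mask.any():
            raise ValueError("region mask is empty")
        n_comp = ndi.label(self.mask, structure=EIGHT_CONNECTED)[1]
        if n_comp != 1:
            raise ValueError(f"region mask has {n_comp} components, expected 1")
        if np.any(self.pixels[~self.mask] != 0):
            raise ValueError("pixels outside the mask must be exactly 0")
        if not self.area_px:
            self.area_px = int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        """Mask centroid in source-image coordinates (row, col)."""
        rr, cc = np.nonzero(self.mask)
        return (float(rr.mean()) + self.bbox[0], float(cc.mean()) + self.bbox[1])

    def masked_values(self) -> np.ndarray:
        """In-mask intensities as a flat float array."""
        return self.pixels[self.mask].astype(float)


def region_from_mask(mask: np.ndarray, gray: np.ndarray, label: int = 1) -> NucleusRegion:
    """Build a :class:`NucleusRegion` from a full-frame mask and image.

    Convenience for tests and for constructing regions from ground-truth
    label masks; crops to the tight bounding box of ``mask``.
    """
    mask = np.asarray(mask, dtype=bool)
    gray = np.asarray(gray)
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("empty mask")
    r0, r1 = int(rr.min()), int(rr.max()) + 1
    c0, c1 = int(cc.min()), int(cc.max()) + 1
    m = mask[r0:r1, c0:c1]
    px = np.where(m, gray[r0:r1, c0:c1], 0).astype(gray.dtype)
    return NucleusRegion(label=label, mask=m, bbox=(r0, c0, r1, c1), pixels=px)
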