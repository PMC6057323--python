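"""Morphological features of a nucleus mask (items 55-63).

Six size descriptors (area, perimeter, equivalent diameter, convex area,
major and minor axis length) and three shape descriptors (eccentricity,
solidity, extent).  Conventions:

* perimeter is the chain length of the 8-connected outer contour with
  axial steps weighted 1 and diagonal steps sqrt(2);
* the convex hull is taken over pixel centres and rasterized by
  centre-inclusion, so digitally convex shapes reach solidity 1;
* axis lengths and eccentricity come from the ellipse with the same
  normalized second central moments as the pixel set, with the +1/12
  per-pixel variance correction (a 1-px line has a nonzero minor axis).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import convex_hull_image

from .regions import EIGHT_CONNECTED

MORPHOLOGY_NAMES = (
    "nucleus_area", "nucleus_perimeter", "nucleus_equivalent_diameter",
    "nucleus_convex_area", "nucleus_major_axis_length", "nucleus_minor_axis_length",
    "nucleus_eccentricity", "nucleus_solidity", "nucleus_extent",
)

# Moore neighbourhood in clockwise order starting West (image coords,
# row increasing downward).
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_contour(mask: np.ndarray) -> list[tuple[int, int]]:
    """Outer boundary of a single 8-connected component, in order
    (Moore-neighbour tracing with Jacob's stopping criterion)."""
    m = np.pad(np.asarray(mask, dtype=bool), 1)
    rs, cs = np.nonzero(m)
    start = (int(rs[0]), int(cs[0]))  # topmost, then leftmost
    if len(rs) == 1:
        return [(start[0] - 1, start[1] - 1)]
    contour = [start]
    cur = start
    back = (start[0], start[1] - 1)  # background by choice of start
    seen = {(cur, back)}
    for _ in range(8 * len(rs) + 8):
        db = (back[0] - cur[0], back[1] - cur[1])
        i0 = _MOORE.index(db)
        for k in range(1, 9):
            d = _MOORE[(i0 + k) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if m[cand]:
                prev = _MOORE[(i0 + k - 1) % 8]
                back = (cur[0] + prev[0], cur[1] + prev[1])
                cur = cand
                break
        else:  # isolated pixel; already handled
            break
        if (cur, back) in seen:  # trace state repeats -> loop closed
            break
        seen.add((cur, back))
        contour.append(cur)
    return [(r - 1, c - 1) for r, c in contour]


def chain_perimeter(mask: np.ndarray) -> float:
    """Closed chain length of the outer contour (1 / sqrt(2) steps)."""
    contour = trace_contour(mask)
    if len(contour) < 2:
        return 0.0
    pts = np.array(contour + [contour[0]], dtype=float)
    steps = np.diff(pts, axis=0)
    return float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))


def _moment_axes(mask: np.ndarray) -> tuple[float, float, float]:
    """(major, minor, eccentricity) of the equal-second-moment ellipse."""
    rr, cc = np.nonzero(mask)
    r = rr - rr.mean()
    c = cc - cc.mean()
    uyy = np.mean(r ** 2) + 1.0 / 12.0   # row variance
    uxx = np.mean(c ** 2) + 1.0 / 12.0   # col variance
    uxy = np.mean(r * c)
    common = np.sqrt((uxx - uyy) ** 2 + 4 * uxy ** 2)
    major = 2.0 * np.sqrt(2.0) * np.sqrt(uxx + uyy + common)
    minor = 2.0 * np.sqrt(2.0) * np.sqrt(uxx + uyy - common)
    ecc = np.sqrt(1.0 - (minor / major) ** 2) if major > 0 else 0.0
    return float(major), float(minor), float(ecc)


def morphology_vector(mask: np.ndarray) -> dict[str, float]:
    """All nine morphology features of a single-component binary mask.

    Raises ``ValueError`` for an empty or multi-component input.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    labels, n = ndi.label(mask, structure=EIGHT_CONNECTED)
    if n != 1:
        raise ValueError(f"expected exactly one component, found {n}")
    rr, cc = np.nonzero(mask)
    tight = mask[rr.min():rr.max() + 1, cc.min():cc.max() + 1]

    area = float(mask.sum())
    perimeter = chain_perimeter(tight)
    eq_diam = float(np.sqrt(4.0 * area / np.pi))
    convex_area = float(convex_hull_image(tight, offset_coordinates=False).sum())
    major, minor, ecc = _moment_axes(tight)
    solidity = area / convex_area
    extent = area / tight.size
    vals = (area, perimeter, eq_diam, convex_area, major, minor, ecc, solidity, extent)
    return dict(zip(MORPHOLOGY_NAMES, vals))
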