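"""Textural features of a segmented nucleus (items 1-54 of the 63-value
feature vector).

Six families are computed from the masked grayscale crop of a
:class:`~nucleograde.regions.NucleusRegion`:

* first-order histogram statistics (mean, population SD, skewness and
  non-excess kurtosis) over the 256 raw gray values;
* 13 Haralick features from a gray-level co-occurrence matrix pooled
  over the four directions 0/45/90/135 degrees at inter-pixel distance 1,
  with intensities quantized into 16 equal-width bins of [0, 255];
* 5 run-length features (SRE, LRE, GLNU, RLNU, RP), one value per
  direction averaged over the same four directions;
* 24 statistics of the level-2 Daubechies-2 wavelet detail coefficients
  (horizontal, diagonal, vertical; 8 statistics each);
* 6 Tamura features (coarseness mean + 3-bin histogram, contrast,
  roughness) with window scales k = 0..5;
* mean and population SD of the 8-neighbour radius-1 local binary
  pattern code distribution.

Masked-domain convention: point statistics, co-occurrence pairs, runs,
LBP codes and Tamura summaries use only in-mask pixels (pairs and runs
require every participating pixel in-mask; runs break at the mask
boundary); the wavelet transform, which needs a rectangular grid,
operates on the zero-background bounding-box crop.  Degenerate
statistics yield NaN ("missing"), never abort a batch.

All entropies use the natural logarithm with the convention
``0 * log 0 = 0``.
"""

from __future__ import annotations

import numpy as np
import pywt

from .regions import DegenerateRegionError, NucleusRegion

N_GRAY_LEVELS = 16  # co-occurrence / run-length quantization
TAMURA_K_RANGE = range(0, 6)  # window scales 2**k, k = 0..5
TAMURA_CONTRAST_EXPONENT = 0.25
LBP_RADIUS = 1
LBP_NEIGHBORS = 8

#: Directions as (drow, dcol) steps: 0, 45, 90, 135 degrees.
DIRECTIONS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

HISTOGRAM_NAMES = ("mean_value", "standard_deviation", "skewness", "kurtosis")
GLCM_NAMES = (
    "angular_second_moment", "contrast", "inverse_difference_moment", "entropy",
    "correlation", "sum_of_squares", "sum_average", "sum_entropy", "sum_variance",
    "difference_variance", "difference_entropy",
    "information_measure_of_correlation_1", "information_measure_of_correlation_2",
)
RLM_NAMES = (
    "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
    "run_length_nonuniformity", "run_percentage",
)
_WAVELET_STATS = (
    "mean_value", "median_value", "max_value", "min_value", "range_of_values",
    "standard_deviation", "median_absolute_deviation", "mean_absolute_deviation",
)
WAVELET_NAMES = tuple(
    f"dwt2{d}_{s}" for d in ("h", "d", "v") for s in _WAVELET_STATS
)
TAMURA_NAMES = (
    "tamura_coarseness_1", "tamura_coarseness_2", "tamura_coarseness_3",
    "tamura_coarseness_4", "tamura_contrast", "tamura_roughness",
)
LBP_NAMES = ("local_binary_pattern_mean_value", "local_binary_pattern_standard_deviation")

TEXTURE_NAMES = HISTOGRAM_NAMES + GLCM_NAMES + RLM_NAMES + WAVELET_NAMES + TAMURA_NAMES + LBP_NAMES


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    pos = p > 0
    out[pos] = p[pos] * np.log(p[pos])
    return out


def quantize(pixels: np.ndarray, levels: int = N_GRAY_LEVELS) -> np.ndarray:
    """Fixed equal-width binning of [0, 255] into ``levels`` bins,
    returning level indices 0 .. levels-1."""
    width = 256 // levels
    return np.minimum(np.asarray(pixels, dtype=np.int64) // width, levels - 1)


# ---------------------------------------------------------------- histogram

def histogram_features(region: NucleusRegion) -> dict[str, float]:
    """First-order statistics over in-mask pixels with population (1/N)
    denominators; kurtosis is the non-excess form (Gaussian ~ 3).

    A constant region has SD 0 and undefined (NaN) skewness/kurtosis.
    """
    v = region.masked_values()
    if v.size < 2:
        raise DegenerateRegionError("histogram features need >= 2 in-mask pixels")
    m = v.mean()
    d = v - m
    std = np.sqrt(np.mean(d ** 2))
    if std == 0:
        sk = kur = np.nan
    else:
        sk = np.mean(d ** 3) / std ** 3
        kur = np.mean(d ** 4) / std ** 4
    return dict(zip(HISTOGRAM_NAMES, (float(m), float(std), float(sk), float(kur))))


# ------------------------------------------------------------ co-occurrence

def glcm(region: NucleusRegion, directions=tuple(DIRECTIONS), distance: int = 1,
         levels: int = N_GRAY_LEVELS) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix.

    Pairs are counted only when both pixels are in-mask; the directional
    matrices are symmetrized, summed over the requested directions and
    normalized to total mass 1.
    """
    q = quantize(region.pixels, levels)
    mask = region.mask
    mat = np.zeros((levels, levels), dtype=float)
    for ang in directions:
        dr, dc = DIRECTIONS[ang]
        dr, dc = dr * distance, dc * distance
        h, w = mask.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a_m = mask[r0:r1, c0:c1]
        b_m = mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = a_m & b_m
        a = q[r0:r1, c0:c1][valid]
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc][valid]
        np.add.at(mat, (a, b), 1.0)
        np.add.at(mat, (b, a), 1.0)
    total = mat.sum()
    if total == 0:
        raise DegenerateRegionError("no valid co-occurring pixel pair")
    return mat / total


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """The 13 Haralick features of a normalized co-occurrence matrix.

    Gray levels are indexed 1..N_g for the moment-type features.
    ``correlation`` is defined 0 when a marginal SD vanishes and the
    first information measure of correlation is 0 when both marginal
    entropies vanish.
    """
    P = np.asarray(P, dtype=float)
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    asm = float(np.sum(P ** 2))
    con = float(np.sum((ii - jj) ** 2 * P))
    idm = float(np.sum(P / (1.0 + (ii - jj) ** 2)))
    ent = float(-np.sum(_xlogx(P)))

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mx = float(np.sum(i * px))
    my = float(np.sum(i * py))
    sx = float(np.sqrt(np.sum((i - mx) ** 2 * px)))
    sy = float(np.sqrt(np.sum((i - my) ** 2 * py)))
    cor = float((np.sum(ii * jj * P) - mx * my) / (sx * sy)) if sx * sy > 0 else 0.0
    ssq = float(np.sum((ii - mx) ** 2 * P))

    # diagonal distributions p_{x+y} (k = 2..2Ng) and p_{x-y} (k = 0..Ng-1)
    pxy_sum = np.zeros(2 * ng + 1)
    np.add.at(pxy_sum, (ii + jj).ravel(), P.ravel())
    k_sum = np.arange(2 * ng + 1)
    pxy_dif = np.zeros(ng)
    np.add.at(pxy_dif, np.abs(ii - jj).ravel(), P.ravel())
    k_dif = np.arange(ng)

    save = float(np.sum(k_sum * pxy_sum))
    sent = float(-np.sum(_xlogx(pxy_sum)))
    svar = float(np.sum((k_sum - sent) ** 2 * pxy_sum))
    dmean = float(np.sum(k_dif * pxy_dif))
    dvar = float(np.sum((k_dif - dmean) ** 2 * pxy_dif))
    dent = float(-np.sum(_xlogx(pxy_dif)))

    hx = float(-np.sum(_xlogx(px)))
    hy = float(-np.sum(_xlogx(py)))
    hxy = ent
    pxpy = np.outer(px, py)
    pos = (P > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(P[pos] * np.log(pxpy[pos])))
    hxy2 = float(-np.sum(_xlogx(pxpy)))
    denom = max(hx, hy)
    icm1 = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    icm2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    vals = (asm, con, idm, ent, cor, ssq, save, sent, svar, dvar, dent, icm1, icm2)
    return dict(zip(GLCM_NAMES, vals))


# ------------------------------------------------------------- run length

def _scan_lines(arr: np.ndarray, angle: int):
    """Yield the 1-D scan lines of ``arr`` parallel to ``angle``."""
    if angle == 0:
        yield from arr
    elif angle == 90:
        yield from arr.T
    elif angle == 135:  # lines along (1, 1)
        h, w = arr.shape
        for off in range(-(h - 1), w):
            yield np.diagonal(arr, offset=off)
    elif angle == 45:  # lines along (1, -1)
        flipped = np.fliplr(arr)
        h, w = arr.shape
        for off in range(-(h - 1), w):
            yield np.diagonal(flipped, offset=off)
    else:
        raise ValueError(f"unsupported direction {angle}")


def run_length_matrix(region: NucleusRegion, angle: int,
                      levels: int = N_GRAY_LEVELS) -> np.ndarray:
    """Run-length matrix ``Q[i, j]`` = number of maximal runs of level
    ``i`` (0-based) and length ``j+1`` along one direction, runs broken
    at the mask boundary."""
    q = quantize(region.pixels, levels)
    max_run = max(region.mask.shape)
    Q = np.zeros((levels, max_run), dtype=float)
    coded = np.where(region.mask, q, -1)
    for line in _scan_lines(coded, angle):
        line = np.asarray(line)
        if line.size == 0:
            continue
        # split at level changes / mask breaks
        breaks = np.flatnonzero(np.diff(line) != 0) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [line.size]))
        for s, e in zip(starts, ends):
            lev = line[s]
            if lev >= 0:
                Q[lev, e - s - 1] += 1
    return Q


def rlm_features(region: NucleusRegion, directions=tuple(DIRECTIONS),
                 levels: int = N_GRAY_LEVELS) -> dict[str, float]:
    """The five run-length ratios, computed per direction and averaged
    over the requested directions.  ``P`` is the in-mask pixel count."""
    n_pixels = int(region.mask.sum())
    if n_pixels == 0:
        raise DegenerateRegionError("empty region")
    acc = np.zeros(5)
    for ang in directions:
        Q = run_length_matrix(region, ang, levels)
        n_runs = Q.sum()
        if n_runs == 0:
            raise DegenerateRegionError("no runs traced")
        j = np.arange(1, Q.shape[1] + 1, dtype=float)
        per_level = Q.sum(axis=1)
        per_length = Q.sum(axis=0)
        sre = np.sum(per_length / j ** 2) / n_runs
        lre = np.sum(per_length * j ** 2) / n_runs
        glnu = np.sum(per_level ** 2) / n_runs
        rlnu = np.sum(per_length ** 2) / n_runs
        rp = n_runs / n_pixels
        acc += (sre, lre, glnu, rlnu, rp)
    return dict(zip(RLM_NAMES, acc / len(directions)))


# --------------------------------------------------------------- wavelets

def wavelet_features(region: NucleusRegion) -> dict[str, float]:
    """Eight statistics of each level-2 Daubechies-2 detail matrix
    (horizontal, diagonal, vertical), computed on the zero-background
    bounding-box crop with symmetric boundary extension.

    The standard deviation uses the sample (n-1) denominator; the two
    absolute deviations are taken about the median and the mean
    respectively.  Crops smaller than 8x8 are flagged undefined.
    """
    crop = region.pixels.astype(float)
    if min(crop.shape) < 8:
        return {name: np.nan for name in WAVELET_NAMES}
    coeffs = pywt.wavedec2(crop, "db2", mode="symmetric", level=2)
    cH, cV, cD = coeffs[1]
    out: dict[str, float] = {}
    for prefix, W in (("dwt2h", cH), ("dwt2d", cD), ("dwt2v", cV)):
        w = W.ravel()
        med = float(np.median(w))
        mean = float(np.mean(w))
        stats = (
            mean, med, float(w.max()), float(w.min()), float(w.max() - w.min()),
            float(np.std(w, ddof=1)), float(np.median(np.abs(w - med))),
            float(np.mean(np.abs(w - mean))),
        )
        for s_name, val in zip(_WAVELET_STATS, stats):
            out[f"{prefix}_{s_name}"] = val
    return out


# ----------------------------------------------------------------- Tamura

def _window_means(padded: np.ndarray, k: int) -> np.ndarray:
    """Mean over 2**k x 2**k windows; for k >= 1 the window at (i, j)
    spans rows i-h .. i+h-1 and cols j-h .. j+h-1 with h = 2**(k-1)."""
    if k == 0:
        return padded
    h = 2 ** (k - 1)
    I = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1))
    I[1:, 1:] = np.cumsum(np.cumsum(padded, axis=0), axis=1)
    H, W = padded.shape
    out = np.full(padded.shape, np.nan)
    r = np.arange(h, H - h + 1)
    c = np.arange(h, W - h + 1)
    if r.size == 0 or c.size == 0:
        return out
    rr, cc = np.meshgrid(r, c, indexing="ij")
    s = I[rr + h, cc + h] - I[rr - h, cc + h] - I[rr + h, cc - h] + I[rr - h, cc - h]
    out[h:H - h + 1, c[0]:c[-1] + 1] = s / (2 * h) ** 2
    return out


def tamura_sbest(region: NucleusRegion) -> np.ndarray:
    """Per-pixel best window size ``S_best = 2**k`` maximizing the larger
    of the two directional neighbourhood-average differences, ties broken
    toward the smallest k.  Boundaries are handled by reflective padding
    of the zero-background crop."""
    crop = region.pixels.astype(float)
    pad = 32  # covers the largest window half-size plus offset at k = 5
    padded = np.pad(crop, pad, mode="reflect")
    H, W = crop.shape
    e_best = np.zeros((len(TAMURA_K_RANGE), H, W))
    for idx, k in enumerate(TAMURA_K_RANGE):
        A = _window_means(padded, k)
        d = 2 ** (k - 1) if k >= 1 else 1
        core = (slice(pad, pad + H), slice(pad, pad + W))
        up = A[pad - d:pad - d + H, pad:pad + W]
        down = A[pad + d:pad + d + H, pad:pad + W]
        left = A[pad:pad + H, pad - d:pad - d + W]
        right = A[pad:pad + H, pad + d:pad + d + W]
        eh = np.abs(down - up)
        ev = np.abs(right - left)
        e_best[idx] = np.maximum(eh, ev)
    best_k = np.argmax(e_best, axis=0)  # first max -> smallest k on ties
    return (2.0 ** best_k).astype(float)


def tamura_features(region: NucleusRegion) -> dict[str, float]:
    """Tamura coarseness (mean of S_best and its 3-bin histogram as
    percentages of in-mask pixels, equal-width bins over [1, 32]),
    contrast sigma / kurtosis**(1/4), and roughness = coarseness + contrast."""
    sbest = tamura_sbest(region)[region.mask]
    crs1 = float(sbest.mean())
    counts, _ = np.histogram(sbest, bins=3, range=(1.0, 32.0))
    crs_hist = counts * (100.0 / sbest.size)
    v = region.masked_values()
    d = v - v.mean()
    sigma = float(np.sqrt(np.mean(d ** 2)))
    if sigma == 0:
        contrast = 0.0
    else:
        a4 = float(np.mean(d ** 4) / sigma ** 4)
        contrast = sigma / a4 ** TAMURA_CONTRAST_EXPONENT
    vals = (crs1, float(crs_hist[0]), float(crs_hist[1]), float(crs_hist[2]),
            contrast, crs1 + contrast)
    return dict(zip(TAMURA_NAMES, vals))


# -------------------------------------------------------------------- LBP

def _snap(x: float) -> float:
    """Snap near-integer trigonometric values so the four axial
    neighbours sample exact pixel positions."""
    return round(x) if abs(x - round(x)) < 1e-9 else x


#: Sampling offsets of the 8 circular neighbours at radius 1,
#: neighbour p at angle 2*pi*p/8 -> (drow, dcol) = (sin, cos).
_LBP_OFFSETS = [
    (_snap(np.sin(2 * np.pi * p / LBP_NEIGHBORS)) * LBP_RADIUS,
     _snap(np.cos(2 * np.pi * p / LBP_NEIGHBORS)) * LBP_RADIUS)
    for p in range(LBP_NEIGHBORS)
]


def lbp_codes(region: NucleusRegion) -> np.ndarray:
    """8-bit LBP codes of qualifying pixels: in-mask pixels whose 8
    bilinear sampling positions all fall inside the crop.

    The sign function follows the convention ``s(x) = 1 for x >= 0``, so
    a perfectly flat neighbourhood yields code 255.  Bilinear sampling is
    computed on centred differences (neighbour minus centre) so that an
    exactly constant patch thresholds to zero without rounding noise.
    """
    crop = region.pixels.astype(float)
    h, w = crop.shape
    if h < 3 or w < 3:
        raise DegenerateRegionError("crop too small for radius-1 LBP")
    interior = np.zeros_like(region.mask)
    interior[1:h - 1, 1:w - 1] = region.mask[1:h - 1, 1:w - 1]
    if not interior.any():
        raise DegenerateRegionError("no qualifying pixel for LBP")
    centre = crop[1:h - 1, 1:w - 1]
    code = np.zeros(centre.shape, dtype=np.int64)
    for p, (dr, dc) in enumerate(_LBP_OFFSETS):
        r0, c0 = int(np.floor(dr)), int(np.floor(dc))
        fr, fc = dr - r0, dc - c0
        acc = np.zeros(centre.shape)
        for (ar, ac, wgt) in (
            (r0, c0, (1 - fr) * (1 - fc)),
            (r0, c0 + 1, (1 - fr) * fc),
            (r0 + 1, c0, fr * (1 - fc)),
            (r0 + 1, c0 + 1, fr * fc),
        ):
            if wgt == 0.0:
                continue
            nb = crop[1 + ar:h - 1 + ar, 1 + ac:w - 1 + ac]
            acc += wgt * (nb - centre)
        code += (acc >= 0).astype(np.int64) << p
    return code[interior[1:h - 1, 1:w - 1]]


def lbp_features(region: NucleusRegion) -> dict[str, float]:
    """Mean and population standard deviation of the LBP code values."""
    codes = lbp_codes(region).astype(float)
    return dict(zip(LBP_NAMES, (float(codes.mean()), float(codes.std()))))


# ------------------------------------------------------------- assembly

def texture_vector(region: NucleusRegion) -> dict[str, float]:
    """All 54 textural features in canonical order.

    Family-level degeneracies are carried as NaN entries rather than
    aborting, so a batch of nuclei always yields one row per nucleus.
    """
    out: dict[str, float] = {}
    families = (
        (HISTOGRAM_NAMES, histogram_features),
        (GLCM_NAMES, lambda r: glcm_features(glcm(r))),
        (RLM_NAMES, rlm_features),
        (WAVELET_NAMES, wavelet_features),
        (TAMURA_NAMES, tamura_features),
        (LBP_NAMES, lbp_features),
    )
    for names, fn in families:
        try:
            out.update(fn(region))
        except DegenerateRegionError:
            out.update({name: np.nan for name in names})
    return out
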