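"""Independent brute-force oracles used by the test suite.

Every routine here re-derives a feature family directly from its
definition with literal per-pixel / per-pair / per-run loops, sharing no
code path with the package implementation.
"""

from __future__ import annotations

from itertools import combinations
from math import exp, log, sqrt

import numpy as np
import pywt

DIRS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def quantize16(v: int) -> int:
    return min(int(v) // 16, 15)


# ------------------------------------------------------------------ GLCM

def glcm_oracle(pixels, mask, directions=(0, 45, 90, 135)):
    """Pairwise enumeration of co-occurring in-mask pixels."""
    h, w = mask.shape
    mat = np.zeros((16, 16))
    for ang in directions:
        dr, dc = DIRS[ang]
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    i, j = quantize16(pixels[r, c]), quantize16(pixels[r2, c2])
                    mat[i, j] += 1
                    mat[j, i] += 1
    total = mat.sum()
    return mat / total if total else mat


def glcm_features_oracle(P):
    """Literal double-loop evaluation of the 13 co-occurrence features,
    gray levels indexed 1..16, natural logs, 0 log 0 = 0."""
    ng = P.shape[0]
    asm = con = idm = ent = ssq = 0.0
    px = [sum(P[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i][j] for i in range(ng)) for j in range(ng)]
    mx = sum((i + 1) * px[i] for i in range(ng))
    my = sum((j + 1) * py[j] for j in range(ng))
    sx = sqrt(sum((i + 1 - mx) ** 2 * px[i] for i in range(ng)))
    sy = sqrt(sum((j + 1 - my) ** 2 * py[j] for j in range(ng)))
    num = 0.0
    for i in range(ng):
        for j in range(ng):
            p = P[i][j]
            asm += p * p
            con += (i - j) ** 2 * p
            idm += p / (1 + (i - j) ** 2)
            if p > 0:
                ent -= p * log(p)
            ssq += (i + 1 - mx) ** 2 * p
            num += (i + 1) * (j + 1) * p
    cor = (num - mx * my) / (sx * sy) if sx * sy > 0 else 0.0

    psum = [0.0] * (2 * ng + 1)
    pdif = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            psum[(i + 1) + (j + 1)] += P[i][j]
            pdif[abs(i - j)] += P[i][j]
    save = sum(k * psum[k] for k in range(len(psum)))
    sent = -sum(p * log(p) for p in psum if p > 0)
    svar = sum((k - sent) ** 2 * psum[k] for k in range(len(psum)))
    dmean = sum(k * pdif[k] for k in range(ng))
    dvar = sum((k - dmean) ** 2 * pdif[k] for k in range(ng))
    dent = -sum(p * log(p) for p in pdif if p > 0)

    hx = -sum(p * log(p) for p in px if p > 0)
    hy = -sum(p * log(p) for p in py if p > 0)
    hxy = ent
    hxy1 = hxy2 = 0.0
    for i in range(ng):
        for j in range(ng):
            q = px[i] * py[j]
            if q > 0:
                if P[i][j] > 0:
                    hxy1 -= P[i][j] * log(q)
                hxy2 -= q * log(q)
    icm1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    icm2 = sqrt(max(0.0, 1.0 - exp(-2.0 * (hxy2 - hxy))))
    return (asm, con, idm, ent, cor, ssq, save, sent, svar, dvar, dent, icm1, icm2)


# ----------------------------------------------------------- run lengths

def _lines(h, w, ang):
    if ang == 0:
        return [[(r, c) for c in range(w)] for r in range(h)]
    if ang == 90:
        return [[(r, c) for r in range(h)] for c in range(w)]
    if ang == 45:  # direction (1, -1)
        lines = []
        for s in range(h + w - 1):
            lines.append([(r, s - r) for r in range(h) if 0 <= s - r < w])
        return lines
    if ang == 135:  # direction (1, 1)
        lines = []
        for d in range(-(h - 1), w):
            lines.append([(r, r + d) for r in range(h) if 0 <= r + d < w])
        return lines
    raise ValueError(ang)


def rlm_features_oracle(pixels, mask, directions=(0, 45, 90, 135)):
    """Literal run tracer: walk each scan line, break runs at mask
    boundaries and level changes, evaluate the five printed ratios."""
    h, w = mask.shape
    n_pix = int(mask.sum())
    feats = np.zeros(5)
    for ang in directions:
        runs = []
        for line in _lines(h, w, ang):
            cur_level, cur_len = None, 0
            for (r, c) in line:
                lev = quantize16(pixels[r, c]) if mask[r, c] else None
                if lev is not None and lev == cur_level:
                    cur_len += 1
                else:
                    if cur_level is not None:
                        runs.append((cur_level, cur_len))
                    cur_level, cur_len = lev, (1 if lev is not None else 0)
            if cur_level is not None:
                runs.append((cur_level, cur_len))
        n = len(runs)
        sre = sum(1.0 / l ** 2 for _, l in runs) / n
        lre = sum(float(l ** 2) for _, l in runs) / n
        by_level = {}
        by_len = {}
        for lev, l in runs:
            by_level[lev] = by_level.get(lev, 0) + 1
            by_len[l] = by_len.get(l, 0) + 1
        glnu = sum(v ** 2 for v in by_level.values()) / n
        rlnu = sum(v ** 2 for v in by_len.values()) / n
        rp = n / n_pix
        feats += np.array([sre, lre, glnu, rlnu, rp])
    return feats / len(directions)


# --------------------------------------------------------------- wavelet

def _dwt1d_oracle(x, filt):
    """Single-level DWT by explicit symmetric extension + convolution."""
    L = len(filt)
    ext = np.pad(np.asarray(x, float), (L - 1, L - 1), mode="symmetric")
    full = np.convolve(ext, filt)
    out_len = (len(x) + L - 1) // 2
    return full[L::2][:out_len]


def dwt2_level2_details_oracle(crop):
    """(cH2, cV2, cD2) by separable row/column filtering applied twice."""
    w = pywt.Wavelet("db2")
    lo, hi = np.array(w.dec_lo), np.array(w.dec_hi)

    def dwt2(a):
        rows_lo = np.array([_dwt1d_oracle(r, lo) for r in a])
        rows_hi = np.array([_dwt1d_oracle(r, hi) for r in a])
        cA = np.array([_dwt1d_oracle(c, lo) for c in rows_lo.T]).T
        cH = np.array([_dwt1d_oracle(c, hi) for c in rows_lo.T]).T
        cV = np.array([_dwt1d_oracle(c, lo) for c in rows_hi.T]).T
        cD = np.array([_dwt1d_oracle(c, hi) for c in rows_hi.T]).T
        return cA, (cH, cV, cD)

    cA1, _ = dwt2(np.asarray(crop, float))
    _, details = dwt2(cA1)
    return details


# ---------------------------------------------------------------- Tamura

def tamura_sbest_oracle(pixels, mask, k_max=5):
    """Literal windowed-average / directed-difference evaluation with
    reflective padding (pad 32), ties to the smallest k."""
    crop = np.asarray(pixels, float)
    pad = 32
    padded = np.pad(crop, pad, mode="reflect")
    H, W = crop.shape

    def A(k, i, j):  # i, j in padded coords
        if k == 0:
            return padded[i, j]
        hw = 2 ** (k - 1)
        s = 0.0
        for r in range(i - hw, i + hw):
            for c in range(j - hw, j + hw):
                s += padded[r, c]
        return s / (2 * hw) ** 2

    sbest = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            i, j = r + pad, c + pad
            best_val, best_k = -1.0, 0
            for k in range(k_max + 1):
                d = 2 ** (k - 1) if k >= 1 else 1
                eh = abs(A(k, i + d, j) - A(k, i - d, j))
                ev = abs(A(k, i, j + d) - A(k, i, j - d))
                e = max(eh, ev)
                if e > best_val + 1e-15:  # strictly greater: ties keep smallest k
                    best_val, best_k = e, k
            sbest[r, c] = 2.0 ** best_k
    return sbest


# ------------------------------------------------------------------- LBP

def lbp_codes_oracle(pixels, mask):
    """Per-pixel, per-neighbour evaluation of the radius-1, 8-neighbour
    code with bilinear sampling on centred differences."""
    crop = np.asarray(pixels, float)
    h, w = crop.shape
    codes = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            ok = True
            code = 0
            for p in range(8):
                dr = np.sin(2 * np.pi * p / 8)
                dc = np.cos(2 * np.pi * p / 8)
                # angles 0/90/180/270 sample exact pixel positions
                dr = round(dr) if abs(dr - round(dr)) < 1e-9 else dr
                dc = round(dc) if abs(dc - round(dc)) < 1e-9 else dc
                rr, cc = r + dr, c + dc
                if not (0 <= rr <= h - 1 + 1e-9 and 0 <= cc <= w - 1 + 1e-9):
                    ok = False
                    break
                # fractional weights taken from the offsets themselves so a
                # knife-edge zero difference is exact, not rounding noise
                r0 = r + int(np.floor(dr))
                c0 = c + int(np.floor(dc))
                fr, fc = dr - np.floor(dr), dc - np.floor(dc)
                diff = 0.0
                for (ar, ac, wgt) in ((r0, c0, (1 - fr) * (1 - fc)),
                                      (r0, c0 + 1, (1 - fr) * fc),
                                      (r0 + 1, c0, fr * (1 - fc)),
                                      (r0 + 1, c0 + 1, fr * fc)):
                    if wgt == 0.0:
                        continue
                    ar = min(ar, h - 1)
                    ac = min(ac, w - 1)
                    diff += wgt * (crop[ar, ac] - crop[r, c])
                if diff >= 0:
                    code += 2 ** p
            if ok:
                codes.append(code)
    return np.array(codes)


# ---------------------------------------------------------------- stats

def wilcoxon_exact_oracle(x, y):
    """Two-sided rank-sum p by full enumeration of all label
    assignments (tie-free samples only)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    stats = [sum(idx) for idx in combinations(range(1, len(pooled) + 1), n1)]
    total = len(stats)
    lo = sum(1 for s in stats if s <= obs) / total
    hi = sum(1 for s in stats if s >= obs) / total
    return min(1.0, 2.0 * min(lo, hi))
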