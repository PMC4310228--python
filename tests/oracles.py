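"""Independent brute-force oracles for the texture and moment features.

Everything here is written as plain nested Python loops, directly from
the defining formulas, deliberately sharing no code with the package
implementation.  Used to pin the vectorized implementations on small
seeded images.
"""

from __future__ import annotations

import math

import numpy as np


def moments_oracle(values, levels=256):
    """Dynamic range + four moments via a per-level loop."""
    values = list(int(v) for v in np.asarray(values).ravel())
    n = len(values)
    counts = [0] * levels
    for v in values:
        counts[v] += 1
    p = [c / n for c in counts]
    m = sum(z * p[z] for z in range(levels))
    var = sum((z - m) ** 2 * p[z] for z in range(levels))
    skew = sum((z - m) ** 3 * p[z] for z in range(levels))
    if var == 0:
        kurt = 0.0
    else:
        kurt = sum((z - m) ** 4 * p[z] for z in range(levels)) / var**2 - 3.0
    dr = max(values) - min(values)
    return float(dr), m, var, skew, kurt


def glcm_oracle(image, mask=None, levels=16, offsets=((0, 1), (-1, 1), (-1, 0), (-1, -1)),
                intensity_levels=256):
    """All-pairs double-loop co-occurrence counting, symmetric."""
    image = np.asarray(image)
    h, w = image.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    q = [[min(levels - 1, (int(image[r, c]) * levels) // intensity_levels)
          for c in range(w)] for r in range(h)]
    counts = [[0] * levels for _ in range(levels)]
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                    counts[q[r][c]][q[r2][c2]] += 1
                    counts[q[r2][c2]][q[r][c]] += 1
    total = sum(sum(row) for row in counts)
    return np.array([[counts[i][j] / total for j in range(levels)]
                     for i in range(levels)])


def _log2(x):
    return math.log(x, 2)


def haralick_oracle(p):
    """The 11 statistics from direct formula sums (1-based levels)."""
    ng = p.shape[0]
    lev = [i + 1 for i in range(ng)]

    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum(lev[i] * px[i] for i in range(ng))
    mu_y = sum(lev[j] * py[j] for j in range(ng))
    sig_x = math.sqrt(sum((lev[i] - mu_x) ** 2 * px[i] for i in range(ng)))
    sig_y = math.sqrt(sum((lev[j] - mu_y) ** 2 * py[j] for j in range(ng)))

    p_sum = {s: 0.0 for s in range(2, 2 * ng + 1)}
    p_diff = {d: 0.0 for d in range(ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[lev[i] + lev[j]] += p[i][j]
            p_diff[abs(lev[i] - lev[j])] += p[i][j]

    hf1 = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    hf2 = sum((lev[i] - lev[j]) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    if sig_x * sig_y == 0:
        hf3 = 0.0
    else:
        hf3 = (sum(lev[i] * lev[j] * p[i][j] for i in range(ng) for j in range(ng))
               - mu_x * mu_y) / (sig_x * sig_y)
    hf4 = sum((lev[i] - mu_x) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    hf5 = sum(p[i][j] / (1 + (lev[i] - lev[j]) ** 2)
              for i in range(ng) for j in range(ng))
    hf6 = sum(s * p_sum[s] for s in p_sum)
    hf8 = -sum(v * _log2(v) for v in p_sum.values() if v > 0)
    hf7 = sum((s - hf8) ** 2 * p_sum[s] for s in p_sum)
    hf9 = -sum(p[i][j] * _log2(p[i][j]) for i in range(ng) for j in range(ng)
               if p[i][j] > 0)
    mu_d = sum(d * p_diff[d] for d in p_diff)
    hf10 = sum((d - mu_d) ** 2 * p_diff[d] for d in p_diff)
    hf11 = -sum(v * _log2(v) for v in p_diff.values() if v > 0)
    return np.array([hf1, hf2, hf3, hf4, hf5, hf6, hf7, hf8, hf9, hf10, hf11])


def lbp_codes_oracle(image, mask=None, P=8, R=1.0):
    """Per-pixel, per-neighbor loop with manual bilinear interpolation."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    margin = int(math.ceil(R))
    codes = []
    for r in range(margin, h - margin):
        for c in range(margin, w - margin):
            if not mask[r, c]:
                continue
            gc = image[r, c]
            code = 0
            for p in range(P):
                theta = 2 * math.pi * p / P
                rr = r + R * math.sin(theta)
                cc = c + R * math.cos(theta)
                r0, c0 = int(math.floor(rr)), int(math.floor(cc))
                fr, fc = rr - r0, cc - c0
                r1 = min(r0 + 1, h - 1)  # zero-weight corner at integer coords
                c1 = min(c0 + 1, w - 1)
                gp = (image[r0, c0] * (1 - fr) * (1 - fc)
                      + image[r0, c1] * (1 - fr) * fc
                      + image[r1, c0] * fr * (1 - fc)
                      + image[r1, c1] * fr * fc)
                if gp - gc >= -1e-9:  # s(0) = 1, with interpolation-noise guard
                    code += 2**p
            codes.append(code)
    return codes


def coarseness_oracle(crop, kmax=5):
    """Nested-loop window averages and directional differences."""
    crop = np.asarray(crop, dtype=float)
    h, w = crop.shape

    def window_mean(r, c, half):
        total = 0.0
        for rr in range(r - half, r + half):
            for cc in range(c - half, c + half):
                total += crop[rr, cc]
        return total / (2 * half) ** 2

    s_vals = []
    for r in range(h):
        for c in range(w):
            best_e = None
            best_s = None
            for k in range(1, kmax + 1):
                half = 2 ** (k - 1)
                m = 2 * half
                if not (m <= r < h - m and m <= c < w - m):
                    continue
                e_h = abs(window_mean(r, c + half, half) - window_mean(r, c - half, half))
                e_v = abs(window_mean(r + half, c, half) - window_mean(r - half, c, half))
                e = max(e_h, e_v)
                if best_e is None or e > best_e:
                    best_e = e
                    best_s = 2**k
            if best_s is not None:
                s_vals.append(best_s)
    return sum(s_vals) / len(s_vals)


def contrast_oracle(values):
    """Tamura contrast from loop-computed raw moments."""
    values = [float(v) for v in np.asarray(values).ravel()]
    n = len(values)
    m = sum(values) / n
    var = sum((v - m) ** 2 for v in values) / n
    if var == 0:
        return 0.0
    mu4 = sum((v - m) ** 4 for v in values) / n
    alpha4 = mu4 / var**2
    return math.sqrt(var) / alpha4**0.25


_PREWITT_H = [[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]]
_PREWITT_V = [[1, 1, 1], [0, 0, 0], [-1, -1, -1]]
_SOBEL_H = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
_SOBEL_V = [[1, 2, 1], [0, 0, 0], [-1, -2, -1]]


def _apply3x3(crop, r, c, kernel):
    total = 0.0
    for dr in range(3):
        for dc in range(3):
            total += kernel[dr][dc] * crop[r - 1 + dr, c - 1 + dc]
    return total


def directionality_histogram_oracle(crop, bins=16, threshold=12.0):
    """Per-pixel gradient-orientation histogram (Prewitt-style kernels)."""
    crop = np.asarray(crop, dtype=float)
    h, w = crop.shape
    hist = [0.0] * bins
    total = 0
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            dh = _apply3x3(crop, r, c, _PREWITT_H)
            dv = _apply3x3(crop, r, c, _PREWITT_V)
            mag = (abs(dh) + abs(dv)) / 2.0
            if mag < threshold:
                continue
            theta = math.atan2(dv, dh) % math.pi
            idx = min(int(theta / math.pi * bins), bins - 1)
            hist[idx] += 1.0
            total += 1
    if total == 0:
        return np.zeros(bins)
    return np.array(hist) / total


def eoh_oracle(crop, bins=8, threshold=0.0):
    """Per-pixel Sobel orientation histogram over (-90, 90] degrees."""
    crop = np.asarray(crop, dtype=float)
    h, w = crop.shape
    counts = [0.0] * bins
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            gh = _apply3x3(crop, r, c, _SOBEL_H)
            gv = _apply3x3(crop, r, c, _SOBEL_V)
            if math.hypot(gh, gv) < threshold:
                continue
            if gh != 0.0:
                deg = math.degrees(math.atan(gv / gh))
            else:
                deg = 90.0
            if deg <= -90.0:
                deg = 90.0
            idx = int(math.ceil((deg + 90.0) / (180.0 / bins))) - 1
            idx = min(max(idx, 0), bins - 1)
            counts[idx] += 1.0
    return np.array(counts)
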