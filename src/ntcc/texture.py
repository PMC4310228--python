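"""Second-order texture features (sets F4-F7).

Four classical texture descriptors computed over a masked region of a
grayscale image:

* **F4 — Haralick features** from a gray-level co-occurrence matrix
  (GLCM): the first 11 of Haralick's statistics (angular second moment,
  contrast, correlation, sum of squares, inverse difference moment, sum
  average, sum variance, sum entropy, entropy, difference variance,
  difference entropy).
* **F5 — Local binary patterns**: per-pixel codes obtained by
  thresholding P circular neighbors at radius R against the center,
  ``code = sum_p s(g_p - g_c) 2^p`` with ``s(x) = 1 for x >= 0``
  (so a flat patch codes to 2^P - 1), summarized as a normalized
  histogram (raw or uniform-pattern binning).
* **F6 — Tamura features**: coarseness (dominant pattern scale from
  dyadic window averages), contrast (sigma corrected by kurtosis), and
  directionality (concentration of the gradient-orientation histogram).
* **F7 — Edge orientation histogram**: distribution of Sobel gradient
  directions ``arctan(V/H)`` over edge pixels.

Conventions used throughout: entropies in bits (log base 2) with
``0*log 0 := 0``; gray levels in GLCM formulas are 1-based (i = bin + 1)
so the pair-sum distribution spans 2..2Ng; difference entropy carries
the standard leading minus sign so it is non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "GLCM",
    "HaralickFeatures",
    "LBPHistogram",
    "TamuraFeatures",
    "EOH",
    "compute_glcm",
    "haralick_features",
    "lbp_codes",
    "lbp_histogram",
    "tamura_coarseness",
    "tamura_contrast",
    "tamura_directionality",
    "edge_orientation_histogram",
]

#: Default GLCM displacement vectors: distance 1 at 0, 45, 90, 135 degrees.
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def _entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0*log0 := 0 convention."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


# ---------------------------------------------------------------------------
# F4: GLCM and Haralick features
# ---------------------------------------------------------------------------

@dataclass
class GLCM:
    """Normalized symmetric gray-level co-occurrence matrix.

    ``p[i, j]`` is the probability of the (1-based) quantized level pair
    (i+1, j+1) at any of the configured offsets, accumulated in both
    directions.  Marginals and the pair-sum/pair-difference
    distributions are derived on construction: ``p_sum[k]`` holds
    p_{x+y}(k+2) for k = 0..2Ng-2 and ``p_diff[k]`` holds p_{x-y}(k)
    for k = 0..Ng-1.
    """

    p: np.ndarray
    levels: int
    offsets: tuple[tuple[int, int], ...]
    mu_x: float = field(init=False)
    mu_y: float = field(init=False)
    sigma_x: float = field(init=False)
    sigma_y: float = field(init=False)
    p_sum: np.ndarray = field(init=False)
    p_diff: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ng = self.levels
        if self.p.shape != (ng, ng):
            raise ValueError("GLCM shape must be (levels, levels)")
        total = float(self.p.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"GLCM must be normalized, sums to {total}")
        i = np.arange(1, ng + 1, dtype=float)
        px = self.p.sum(axis=1)
        py = self.p.sum(axis=0)
        self.mu_x = float(np.sum(i * px))
        self.mu_y = float(np.sum(i * py))
        self.sigma_x = float(np.sqrt(np.sum((i - self.mu_x) ** 2 * px)))
        self.sigma_y = float(np.sqrt(np.sum((i - self.mu_y) ** 2 * py)))
        # p_{x+y}: sums of levels run 2..2Ng; p_{x-y}: |i-j| runs 0..Ng-1
        self.p_sum = np.zeros(2 * ng - 1)
        self.p_diff = np.zeros(ng)
        ii, jj = np.meshgrid(np.arange(ng), np.arange(ng), indexing="ij")
        np.add.at(self.p_sum, (ii + jj).ravel(), self.p.ravel())
        np.add.at(self.p_diff, np.abs(ii - jj).ravel(), self.p.ravel())


def quantize(image: np.ndarray, levels: int, intensity_levels: int = 256) -> np.ndarray:
    """Linear quantization of [0, intensity_levels-1] into ``levels`` bins."""
    image = np.asarray(image)
    q = (image.astype(np.int64) * levels) // intensity_levels
    return np.clip(q, 0, levels - 1)


def compute_glcm(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    levels: int = 16,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    intensity_levels: int = 256,
) -> GLCM:
    """Build a symmetric normalized GLCM over the masked region.

    Intensities are linearly quantized to ``levels`` gray levels;
    co-occurrences are accumulated over every pixel pair whose two
    endpoints both lie inside the mask, in both directions, summed over
    all offsets, then normalized to probabilities.
    """
    image = np.asarray(image)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if not offsets:
        raise ValueError("at least one offset is required")
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    q = quantize(image, levels, intensity_levels)

    counts = np.zeros((levels, levels), dtype=np.int64)
    h, w = image.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        np.add.at(counts, (a[valid], b[valid]), 1)
    counts = counts + counts.T  # symmetric accumulation
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs in the masked region")
    return GLCM(p=counts / total, levels=levels, offsets=tuple(offsets))


@dataclass
class HaralickFeatures:
    """The 11 GLCM statistics Hf1..Hf11."""

    asm: float
    contrast: float
    correlation: float
    sum_of_squares: float
    idm: float
    sum_average: float
    sum_variance: float
    sum_entropy: float
    entropy: float
    difference_variance: float
    difference_entropy: float

    NAMES = (
        "Hf1", "Hf2", "Hf3", "Hf4", "Hf5", "Hf6",
        "Hf7", "Hf8", "Hf9", "Hf10", "Hf11",
    )

    def as_array(self) -> np.ndarray:
        return np.array([
            self.asm, self.contrast, self.correlation, self.sum_of_squares,
            self.idm, self.sum_average, self.sum_variance, self.sum_entropy,
            self.entropy, self.difference_variance, self.difference_entropy,
        ])


def haralick_features(g: GLCM) -> HaralickFeatures:
    """Compute Hf1..Hf11 from a normalized GLCM.

    Correlation is defined as 0 when either marginal is degenerate
    (sigma_x * sigma_y = 0); sum variance is taken about the sum entropy
    (the classic reading of the "f8" appearing inside it); difference
    variance is the variance of the pair-difference distribution.
    """
    ng = g.levels
    p = g.p
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    asm = float(np.sum(p**2))
    contrast = float(np.sum((ii - jj) ** 2 * p))
    if g.sigma_x * g.sigma_y == 0.0:
        correlation = 0.0
    else:
        correlation = float(
            (np.sum(ii * jj * p) - g.mu_x * g.mu_y) / (g.sigma_x * g.sigma_y)
        )
    sum_of_squares = float(np.sum((ii - g.mu_x) ** 2 * p))
    idm = float(np.sum(p / (1.0 + (ii - jj) ** 2)))

    k_sum = np.arange(2, 2 * ng + 1, dtype=float)  # values of i+j
    sum_average = float(np.sum(k_sum * g.p_sum))
    sum_entropy = _entropy_bits(g.p_sum)
    sum_variance = float(np.sum((k_sum - sum_entropy) ** 2 * g.p_sum))

    entropy = _entropy_bits(p)

    k_diff = np.arange(ng, dtype=float)  # values of |i-j|
    mu_diff = float(np.sum(k_diff * g.p_diff))
    difference_variance = float(np.sum((k_diff - mu_diff) ** 2 * g.p_diff))
    difference_entropy = _entropy_bits(g.p_diff)

    return HaralickFeatures(
        asm=asm,
        contrast=contrast,
        correlation=correlation,
        sum_of_squares=sum_of_squares,
        idm=idm,
        sum_average=sum_average,
        sum_variance=sum_variance,
        sum_entropy=sum_entropy,
        entropy=entropy,
        difference_variance=difference_variance,
        difference_entropy=difference_entropy,
    )


# ---------------------------------------------------------------------------
# F5: local binary patterns
# ---------------------------------------------------------------------------

def _uniform_lookup(P: int) -> np.ndarray:
    """Map each raw P-bit code to a uniform-pattern bin.

    Codes with at most two 0/1 circular transitions ("uniform" patterns,
    P*(P-1)+2 of them) each get their own bin, in increasing code order;
    all remaining codes share one final bin.
    """
    codes = np.arange(2**P)
    bits = (codes[:, None] >> np.arange(P)) & 1
    transitions = np.sum(bits != np.roll(bits, -1, axis=1), axis=1)
    uniform = transitions <= 2
    lut = np.full(2**P, -1, dtype=np.int64)
    lut[uniform] = np.arange(int(uniform.sum()))
    lut[~uniform] = int(uniform.sum())
    return lut


def lbp_codes(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    P: int = 8,
    R: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw LBP codes for every masked pixel with a full neighborhood.

    Neighbor p sits at angle 2*pi*p/P (p=0 pointing along +columns,
    angles advancing toward +rows) at radius R, sampled with bilinear
    interpolation.  The comparison is ``s(g_p - g_c)`` with s(0) = 1.
    Returns ``(codes, pixel_mask)`` where ``pixel_mask`` marks the
    pixels that produced a code.
    """
    if P < 4:
        raise ValueError("P must be >= 4")
    if R < 1:
        raise ValueError("R must be >= 1")
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    margin = int(np.ceil(R))
    valid = np.zeros_like(mask)
    valid[margin:h - margin, margin:w - margin] = True
    valid &= mask
    rows, cols = np.nonzero(valid)
    if rows.size == 0:
        raise ValueError("region too small for any full LBP neighborhood")

    gc = image[rows, cols]
    code = np.zeros(rows.size, dtype=np.int64)
    for p in range(P):
        theta = 2.0 * np.pi * p / P
        dr = R * np.sin(theta)
        dc = R * np.cos(theta)
        rr = rows + dr
        cc = cols + dc
        r0 = np.floor(rr).astype(np.int64)
        c0 = np.floor(cc).astype(np.int64)
        fr = rr - r0
        fc = cc - c0
        # far corners carry zero weight when the sample hits an integer
        # coordinate; clip them so the gather stays in bounds
        r1 = np.minimum(r0 + 1, h - 1)
        c1 = np.minimum(c0 + 1, w - 1)
        gp = (
            image[r0, c0] * (1 - fr) * (1 - fc)
            + image[r0, c1] * (1 - fr) * fc
            + image[r1, c0] * fr * (1 - fc)
            + image[r1, c1] * fr * fc
        )
        # s(x) = 1 for x >= 0; the tolerance absorbs float noise from the
        # interpolation so exactly-equal neighbors (flat patches) count as 1
        code += ((gp - gc) >= -1e-9).astype(np.int64) << p
    return code, valid


@dataclass
class LBPHistogram:
    """Normalized histogram of LBP codes."""

    P: int
    R: float
    scheme: str
    counts: np.ndarray

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def entropy(self) -> float:
        """Shannon entropy of the normalized histogram, in bits."""
        return _entropy_bits(self.frequencies)


def lbp_histogram(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    P: int = 8,
    R: float = 1.0,
    scheme: str = "uniform",
) -> LBPHistogram:
    """LBP code histogram over the masked region.

    ``scheme="raw"`` uses 2^P bins (one per code); ``scheme="uniform"``
    uses the standard uniform-pattern binning (P*(P-1)+2 uniform codes
    plus one bin for all non-uniform codes).
    """
    codes, _ = lbp_codes(image, mask, P=P, R=R)
    if scheme == "raw":
        counts = np.bincount(codes, minlength=2**P).astype(float)
    elif scheme == "uniform":
        lut = _uniform_lookup(P)
        nbins = int(lut.max()) + 1
        counts = np.bincount(lut[codes], minlength=nbins).astype(float)
    else:
        raise ValueError(f"unknown LBP scheme {scheme!r}")
    return LBPHistogram(P=P, R=R, scheme=scheme, counts=counts)


# ---------------------------------------------------------------------------
# F6: Tamura features
# ---------------------------------------------------------------------------

def _mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    if rows.size == 0:
        raise ValueError("empty mask")
    return int(rows.min()), int(rows.max()) + 1, int(cols.min()), int(cols.max()) + 1


def _crop(image: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    """Rectangular bounding-box crop of the mask (Tamura windows are
    rectangular, so the support is the bbox rather than the exact mask)."""
    image = np.asarray(image, dtype=float)
    if mask is None:
        return image
    r0, r1, c0, c1 = _mask_bbox(mask)
    return image[r0:r1, c0:c1]


def tamura_coarseness(
    image: np.ndarray, mask: np.ndarray | None = None, kmax: int = 5
) -> float:
    """Tamura coarseness: mean best window size 2^k over the region.

    For each scale k = 1..kmax, 2^k x 2^k window averages A_k are
    computed wherever the window fits inside the region crop, and the
    directional differences E_k(r, c) = max(|A_k(r, c+2^(k-1)) -
    A_k(r, c-2^(k-1))|, vertical analogue) wherever both averages exist
    (margin 2^k from every border).  Each pixel picks the scale with the
    largest E_k among its valid scales — first maximum on ties — and
    coarseness is the mean of 2^k_best over all pixels that have at
    least one valid scale.
    """
    crop = _crop(image, mask)
    h, w = crop.shape

    # integral image for O(1) window sums
    integ = np.zeros((h + 1, w + 1))
    integ[1:, 1:] = np.cumsum(np.cumsum(crop, axis=0), axis=1)

    best_e = np.full((h, w), -np.inf)
    best_s = np.zeros((h, w))
    any_valid = np.zeros((h, w), dtype=bool)

    for k in range(1, kmax + 1):
        half = 2 ** (k - 1)
        m = 2 * half  # validity margin = 2^k
        if h < 2 * m + 1 or w < 2 * m + 1:
            break
        # A_k(r, c) = mean of crop[r-half : r+half, c-half : c+half],
        # defined for r in [half, h-half], c in [half, w-half]
        size = (2 * half) ** 2

        def window_mean(r: np.ndarray, c: np.ndarray) -> np.ndarray:
            r0, r1 = r - half, r + half
            c0, c1 = c - half, c + half
            return (
                integ[r1, c1] - integ[r0, c1] - integ[r1, c0] + integ[r0, c0]
            ) / size

        rr, cc = np.meshgrid(
            np.arange(m, h - m), np.arange(m, w - m), indexing="ij"
        )
        e_h = np.abs(window_mean(rr, cc + half) - window_mean(rr, cc - half))
        e_v = np.abs(window_mean(rr + half, cc) - window_mean(rr - half, cc))
        e_k = np.maximum(e_h, e_v)

        sub = (slice(m, h - m), slice(m, w - m))
        # strict comparison: the first maximum wins ties; best_e starts at
        # -inf so the first valid scale always initializes a pixel
        take = e_k > best_e[sub]
        best_e[sub] = np.where(take, e_k, best_e[sub])
        best_s[sub] = np.where(take, 2.0**k, best_s[sub])
        any_valid[sub] = True

    if not any_valid.any():
        raise ValueError("region smaller than the minimum Tamura window support")
    return float(best_s[any_valid].mean())


def tamura_contrast(image: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Tamura contrast Fcon = sigma / alpha4^(1/4), alpha4 = mu4/sigma^4
    (raw fourth standardized moment).  A constant region returns 0."""
    image = np.asarray(image, dtype=float)
    if mask is None:
        vals = image.ravel()
    else:
        vals = image[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty region")
    m = vals.mean()
    var = np.mean((vals - m) ** 2)
    if var == 0.0:
        return 0.0
    mu4 = np.mean((vals - m) ** 4)
    alpha4 = mu4 / var**2
    return float(np.sqrt(var) / alpha4**0.25)


# 3x3 difference operators for the directionality estimate
_PREWITT_H = np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], dtype=float)
_PREWITT_V = np.array([[1, 1, 1], [0, 0, 0], [-1, -1, -1]], dtype=float)


def _convolve3x3_valid(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Cross-correlate with a 3x3 kernel, interior (valid) pixels only."""
    h, w = image.shape
    out = np.zeros((h - 2, w - 2))
    for dr in range(3):
        for dc in range(3):
            out += kernel[dr, dc] * image[dr:h - 2 + dr, dc:w - 2 + dc]
    return out


def directionality_histogram(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    bins: int = 16,
    threshold: float = 12.0,
) -> np.ndarray:
    """Normalized gradient-orientation histogram H_D over [0, pi).

    Gradients come from 3x3 horizontal/vertical difference operators on
    the region crop (interior pixels only); a pixel contributes when its
    magnitude (|dH| + |dV|)/2 reaches ``threshold``.  Returns the
    normalized ``bins``-vector (all zeros when no pixel qualifies).
    """
    crop = _crop(image, mask)
    if crop.shape[0] < 3 or crop.shape[1] < 3:
        raise ValueError("region too small for gradient operators")
    dh = _convolve3x3_valid(crop, _PREWITT_H)
    dv = _convolve3x3_valid(crop, _PREWITT_V)
    mag = (np.abs(dh) + np.abs(dv)) / 2.0
    theta = np.mod(np.arctan2(dv, dh), np.pi)  # orientation in [0, pi)
    sel = mag >= threshold
    hist = np.zeros(bins)
    if not sel.any():
        return hist
    idx = np.minimum((theta[sel] / np.pi * bins).astype(np.int64), bins - 1)
    np.add.at(hist, idx, 1.0)
    return hist / hist.sum()


def tamura_directionality(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    bins: int = 16,
    threshold: float = 12.0,
) -> float:
    """Tamura directionality in [0, 1]; 1 means a single sharp
    orientation peak, 0 means no preferred direction (or no edges).

    Peaks of the orientation histogram are strict circular local maxima
    above the mean bin height; each peak's window extends to the nearest
    valley on either side.  The second moment of H_D about the peaks is
    normalized as ``1 - bins * n_peaks * sum`` and clipped to [0, 1].
    """
    hist = directionality_histogram(image, mask, bins=bins, threshold=threshold)
    if hist.sum() == 0:
        return 0.0
    centers = (np.arange(bins) + 0.5) * np.pi / bins

    mean_h = hist.mean()
    left = np.roll(hist, 1)
    right = np.roll(hist, -1)
    peaks = np.nonzero((hist > left) & (hist > right) & (hist > mean_h))[0]
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(hist))])

    total = 0.0
    for pk in peaks:
        # window: walk outwards while the histogram is non-increasing
        lo = pk
        while True:
            nxt = (lo - 1) % bins
            if nxt == pk or hist[nxt] > hist[lo]:
                break
            lo = nxt
        hi = pk
        while True:
            nxt = (hi + 1) % bins
            if nxt == pk or hist[nxt] > hist[hi]:
                break
            hi = nxt
        idx = lo
        while True:
            d = centers[idx] - centers[pk]
            # circular distance on orientations (period pi)
            d = (d + np.pi / 2) % np.pi - np.pi / 2
            total += d * d * hist[idx]
            if idx == hi:
                break
            idx = (idx + 1) % bins
    fdir = 1.0 - bins * peaks.size * total
    return float(np.clip(fdir, 0.0, 1.0))


@dataclass
class TamuraFeatures:
    coarseness: float
    contrast: float
    directionality: float


def tamura_features(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    kmax: int = 5,
    bins: int = 16,
    threshold: float = 12.0,
) -> TamuraFeatures:
    return TamuraFeatures(
        coarseness=tamura_coarseness(image, mask, kmax=kmax),
        contrast=tamura_contrast(image, mask),
        directionality=tamura_directionality(image, mask, bins=bins, threshold=threshold),
    )


# ---------------------------------------------------------------------------
# F7: edge orientation histogram
# ---------------------------------------------------------------------------

_SOBEL_H = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_V = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)


@dataclass
class EOH:
    """Edge orientation histogram over (-90, 90] degrees."""

    bins: int
    counts: np.ndarray
    threshold: float

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros(self.bins)
        return self.counts / total

    @property
    def entropy(self) -> float:
        return _entropy_bits(self.frequencies)


def edge_orientation_histogram(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    bins: int = 8,
    threshold: float | None = None,
) -> EOH:
    """Histogram of Sobel edge orientations arctan(V/H) in (-90, 90].

    Only interior pixels of the region crop (full 3x3 Sobel support)
    with gradient magnitude >= threshold contribute; when ``threshold``
    is None it is set by Otsu's method on the magnitudes.  An image with
    no edge pixels yields an all-zero histogram (entropy 0).
    """
    crop = _crop(image, mask)
    if crop.shape[0] < 3 or crop.shape[1] < 3:
        raise ValueError("region too small for Sobel operators")
    gh = _convolve3x3_valid(crop, _SOBEL_H)
    gv = _convolve3x3_valid(crop, _SOBEL_V)
    mag = np.hypot(gh, gv)
    if threshold is None:
        if np.unique(mag).size < 2:
            threshold = np.inf  # no contrast: nothing qualifies as an edge
        else:
            threshold = float(threshold_otsu(mag))
    sel = mag >= threshold

    counts = np.zeros(bins)
    if sel.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = np.where(gh[sel] != 0.0, np.arctan(gv[sel] / gh[sel]), np.pi / 2)
        deg = np.degrees(theta)  # in [-90, 90]
        deg = np.where(deg <= -90.0, 90.0, deg)  # fold to (-90, 90]
        # bin b covers (-90 + b*180/bins, -90 + (b+1)*180/bins]
        idx = np.ceil((deg + 90.0) / (180.0 / bins)).astype(np.int64) - 1
        idx = np.clip(idx, 0, bins - 1)
        np.add.at(counts, idx, 1.0)
    return EOH(bins=bins, counts=counts, threshold=float(threshold))
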