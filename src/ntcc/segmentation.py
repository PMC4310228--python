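"""Rough nucleus/cytoplasm segmentation of single-cell images.

The pipeline follows the classical morphological recipe for stained
cytology crops: the image is inverted (nuclei are the darkest structures,
so they become the brightest), thresholded into background / cytoplasm /
nucleus classes, and the nucleus mask is cleaned up with a binary closing
(disk structuring element, radius 5 px by default) followed by hole
filling; only the largest connected component of each region is kept.
The cytoplasm mask is the cell region minus the nucleus.

When an image carries ground-truth masks, :func:`segment_cell` can return
them directly (``use_ground_truth=True``), which is how downstream feature
extraction is run against reference segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk, square

from .types import CellImage


class SegmentationError(RuntimeError):
    """Raised when no usable cell foreground can be found."""


@dataclass
class SegmentationParams:
    """Tunable parameters of the rough segmentation.

    threshold_method
        ``"multiotsu"`` (default): 3-class Otsu on the inverted image,
        separating background / cytoplasm / nucleus in one step.
        ``"otsu2"``: single Otsu for the cell foreground, then a second
        Otsu inside the cell for the nucleus.
    se_shape, se_radius
        Structuring element of the nucleus closing step; "radius 5 disk"
        is the default reading of a "structuring element of five".
    use_ground_truth
        Return ground-truth masks verbatim when the image has them.
    min_cytoplasm_area
        Below this pixel count the visible cytoplasm is considered
        negligible (columnar-type cells); cytoplasm-dependent quantities
        fall back to the whole cell region.
    """

    threshold_method: str = "multiotsu"
    se_shape: str = "disk"
    se_radius: int = 5
    use_ground_truth: bool = False
    min_cytoplasm_area: int = 25

    def structuring_element(self) -> np.ndarray:
        if self.se_shape == "disk":
            return disk(self.se_radius)
        if self.se_shape == "square":
            return square(2 * self.se_radius + 1)
        raise ValueError(f"unknown structuring element shape {self.se_shape!r}")


@dataclass
class SegmentationResult:
    """Boolean nucleus/cytoplasm masks plus derived region properties.

    ``cytoplasm_mask`` excludes nucleus pixels, so the two masks are
    disjoint and their union is the cell region.  ``cytoplasm_diameter``
    is the equivalent-circle diameter of the *full* cell region
    (nucleus plus cytoplasm), the denominator of the relative nucleus
    displacement.  When the visible cytoplasm is negligible
    (``cytoplasm_fallback``), the cytoplasm centroid is taken from the
    whole cell region.
    """

    nucleus_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    nucleus_area: int
    cytoplasm_area: int
    nucleus_centroid: tuple[float, float]
    cytoplasm_centroid: tuple[float, float]
    cytoplasm_diameter: float
    cytoplasm_fallback: bool = False
    from_ground_truth: bool = field(default=False, repr=False)

    @property
    def cell_mask(self) -> np.ndarray:
        return self.nucleus_mask | self.cytoplasm_mask

    @property
    def cell_area(self) -> int:
        return int(self.nucleus_area + self.cytoplasm_area)


def region_properties(mask: np.ndarray) -> tuple[int, tuple[float, float], float]:
    """Area, centroid and equivalent-circle diameter of a boolean mask.

    The centroid is the mean of the true-pixel (row, col) coordinates and
    the equivalent diameter is ``2*sqrt(area/pi)``.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask has no region properties")
    area = int(rows.size)
    centroid = (float(rows.mean()), float(cols.mean()))
    diameter = 2.0 * float(np.sqrt(area / np.pi))
    return area, centroid, diameter


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected component; ties go to the component whose
    first pixel comes earliest in row-major scan order (labelling order)."""
    labels = cc_label(mask, connectivity=2)
    n = labels.max()
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1  # argmax returns first max -> scan order
    return labels == best


def _result_from_masks(
    nucleus: np.ndarray,
    cytoplasm: np.ndarray,
    params: SegmentationParams,
    from_gt: bool = False,
) -> SegmentationResult:
    nucleus = np.asarray(nucleus, dtype=bool)
    cytoplasm = np.asarray(cytoplasm, dtype=bool) & ~nucleus
    cell = nucleus | cytoplasm
    if not cell.any():
        raise SegmentationError("segmentation failed: no foreground found")
    if not nucleus.any():
        raise SegmentationError("segmentation failed: no nucleus found")

    n_area, n_centroid, _ = region_properties(nucleus)
    _, _, cell_diam = region_properties(cell)
    c_area = int(cytoplasm.sum())
    fallback = c_area < params.min_cytoplasm_area
    if fallback:
        _, c_centroid, _ = region_properties(cell)
    else:
        _, c_centroid, _ = region_properties(cytoplasm)
    return SegmentationResult(
        nucleus_mask=nucleus,
        cytoplasm_mask=cytoplasm,
        nucleus_area=n_area,
        cytoplasm_area=c_area,
        nucleus_centroid=n_centroid,
        cytoplasm_centroid=c_centroid,
        cytoplasm_diameter=cell_diam,
        cytoplasm_fallback=fallback,
        from_ground_truth=from_gt,
    )


def segment_cell(
    image: CellImage, params: Optional[SegmentationParams] = None
) -> SegmentationResult:
    """Segment nucleus and cytoplasm of a single-cell crop.

    Steps: invert intensities; 3-class thresholding (background /
    cytoplasm / nucleus — the nucleus is brightest after inversion);
    binary closing of the nucleus with the configured structuring
    element; hole filling; keep the largest connected component per
    region.  Raises :class:`SegmentationError` on contrast-free input.
    """
    params = params or SegmentationParams()

    if params.use_ground_truth and image.has_ground_truth:
        return _result_from_masks(
            image.gt_nucleus_mask, image.gt_cytoplasm_mask, params, from_gt=True
        )

    inverted = (image.levels - 1) - image.pixels.astype(np.int64)
    if np.unique(inverted).size < 3:
        raise SegmentationError("segmentation failed: not enough intensity contrast")

    if params.threshold_method == "multiotsu":
        try:
            t_lo, t_hi = threshold_multiotsu(inverted, classes=3)
        except ValueError as exc:
            raise SegmentationError(f"segmentation failed: {exc}") from exc
        cell_raw = inverted > t_lo
        nucleus_raw = inverted > t_hi
    elif params.threshold_method == "otsu2":
        t_cell = threshold_otsu(inverted)
        cell_raw = inverted > t_cell
        if not cell_raw.any():
            raise SegmentationError("segmentation failed: no foreground found")
        t_nuc = threshold_otsu(inverted[cell_raw])
        nucleus_raw = cell_raw & (inverted > t_nuc)
    else:
        raise ValueError(f"unknown threshold method {params.threshold_method!r}")

    se = params.structuring_element()
    nucleus = ndi.binary_closing(nucleus_raw, structure=se)
    nucleus = ndi.binary_fill_holes(nucleus)
    nucleus = _largest_component(nucleus)

    cell = ndi.binary_closing(cell_raw, structure=se)
    cell = ndi.binary_fill_holes(cell)
    cell = _largest_component(cell)
    cell |= nucleus  # nucleus is part of the cell by definition

    return _result_from_masks(nucleus, cell & ~nucleus, params)
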