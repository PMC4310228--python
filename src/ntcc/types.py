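"""Core domain types for the single-cell Pap-smear pipeline.

The class scheme follows the seven-class Herlev convention: three normal
cell types (normal squamous, intermediate squamous, columnar) and four
abnormal types of increasing severity (mild, moderate and severe dysplasia,
carcinoma in situ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Canonical class-id -> name mapping (Herlev seven-class scheme).
CLASS_NAMES: dict[int, str] = {
    1: "normal_squamous",
    2: "intermediate_squamous",
    3: "columnar",
    4: "mild_dysplasia",
    5: "moderate_dysplasia",
    6: "severe_dysplasia",
    7: "carcinoma_in_situ",
}

#: Inverse mapping, name -> id.
CLASS_IDS: dict[str, int] = {v: k for k, v in CLASS_NAMES.items()}

#: Published per-class cell counts of the 917-cell Herlev reference set.
HERLEV_CLASS_COUNTS: dict[int, int] = {
    1: 74, 2: 70, 3: 98, 4: 182, 5: 146, 6: 197, 7: 150,
}


def class_category(class_id: int) -> str:
    """Return ``"normal"`` for ids 1-3 and ``"abnormal"`` for ids 4-7."""
    if class_id not in CLASS_NAMES:
        raise ValueError(f"unknown class id {class_id}")
    return "normal" if class_id <= 3 else "abnormal"


@dataclass
class ClassLabel:
    """A cervical-cell class: integer id 1..7 plus its name and category."""

    id: int

    def __post_init__(self) -> None:
        if self.id not in CLASS_NAMES:
            raise ValueError(f"class id must be in 1..7, got {self.id}")

    @property
    def name(self) -> str:
        return CLASS_NAMES[self.id]

    @property
    def category(self) -> str:
        return class_category(self.id)


@dataclass
class CellImage:
    """A single-cell grayscale raster with optional ground truth.

    Parameters
    ----------
    pixels
        2-D integer intensity raster with values in ``[0, levels-1]``.
    label
        Class id in 1..7, or ``None`` for unlabeled images.
    source_path
        Where the image came from (informational).
    gt_nucleus_mask, gt_cytoplasm_mask
        Optional boolean ground-truth masks, same shape as ``pixels``.
    levels
        Number of gray levels L (default 256, i.e. 8-bit).
    resolution_um_per_px
        Physical pixel size carried as metadata; unused by computation.
    """

    pixels: np.ndarray
    label: Optional[int] = None
    source_path: str = ""
    gt_nucleus_mask: Optional[np.ndarray] = None
    gt_cytoplasm_mask: Optional[np.ndarray] = None
    levels: int = 256
    resolution_um_per_px: Optional[float] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("pixels must be a 2-D raster with >= 2 rows and columns")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixels must be an integer raster")
        if px.min() < 0 or px.max() > self.levels - 1:
            raise ValueError(f"pixel values must lie in [0, {self.levels - 1}]")
        self.pixels = px
        if self.label is not None and self.label not in CLASS_NAMES:
            raise ValueError(f"label must be in 1..7, got {self.label}")
        for name in ("gt_nucleus_mask", "gt_cytoplasm_mask"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=bool)
                if m.shape != px.shape:
                    raise ValueError(f"{name} shape {m.shape} != pixels shape {px.shape}")
                setattr(self, name, m)

    @property
    def has_ground_truth(self) -> bool:
        return self.gt_nucleus_mask is not None and self.gt_cytoplasm_mask is not None

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]
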