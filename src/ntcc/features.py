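"""Assembly of the seven feature sets F1-F7 into named feature vectors.

The compact default vector has 28 scalar columns:

====  =========================================================  ======
set   columns                                                    count
====  =========================================================  ======
F1    F1_NC (relative nucleus size)                              1
F2    F2_{nucleus,cytoplasm}_{dr,mean,var,skew,kurt}             10
F3    F3_RD (relative nucleus displacement)                      1
F4    F4_Hf1 .. F4_Hf11 (Haralick GLCM statistics)               11
F5    F5_lbp_entropy (entropy of the LBP histogram)              1
F6    F6_coarseness, F6_contrast, F6_directionality              3
F7    F7_eoh_entropy (entropy of the edge orientation histogram) 1
====  =========================================================  ======

F5 and F7 can alternatively be expanded to their full histograms
(``lbp_scheme``/``eoh`` config), which multiplies the column count; the
scalar entropy projection is the default used in compact vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import texture
from .region_features import intensity_stats, relative_displacement, relative_nucleus_size
from .segmentation import SegmentationParams, SegmentationResult, segment_cell
from .types import CellImage

ALL_SETS: tuple[str, ...] = ("F1", "F2", "F3", "F4", "F5", "F6", "F7")


@dataclass
class FeatureConfig:
    """Parameters of the texture feature extractors.

    ``texture_region`` selects the support of F4-F7: the whole cell
    (default), the nucleus only, or the cytoplasm only.
    """

    glcm_levels: int = 16
    glcm_offsets: tuple[tuple[int, int], ...] = texture.DEFAULT_OFFSETS
    lbp_P: int = 8
    lbp_R: float = 1.0
    lbp_scheme: str = "uniform"
    lbp_projection: str = "entropy"  # "entropy" | "histogram"
    tamura_kmax: int = 5
    tamura_bins: int = 16
    tamura_threshold: float = 12.0
    eoh_bins: int = 8
    eoh_threshold: Optional[float] = None  # None -> Otsu on magnitudes
    eoh_projection: str = "entropy"  # "entropy" | "histogram"
    texture_region: str = "cell"  # "cell" | "nucleus" | "cytoplasm"
    f2_regions: tuple[str, ...] = ("nucleus", "cytoplasm")

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown feature config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class FeatureVector:
    """Ordered, named feature values grouped by set identifier."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names and values must have equal length")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def columns_for_sets(names: Sequence[str], sets: Iterable[str]) -> list[str]:
    """Expand feature-set ids (F1..F7) to the concrete column names."""
    sets = list(sets)
    unknown = set(sets) - set(ALL_SETS)
    if unknown:
        raise ValueError(f"unknown feature sets: {sorted(unknown)}")
    if not sets:
        raise ValueError("feature selection must be non-empty")
    prefixes = tuple(f"{s}_" for s in sets)
    return [n for n in names if n.startswith(prefixes)]


def _texture_mask(seg: SegmentationResult, region: str) -> np.ndarray:
    if region == "cell":
        return seg.cell_mask
    if region == "nucleus":
        return seg.nucleus_mask
    if region == "cytoplasm":
        mask = seg.cytoplasm_mask
        return mask if mask.any() else seg.cell_mask
    raise ValueError(f"unknown texture region {region!r}")


def extract_features(
    image: CellImage,
    seg: SegmentationResult,
    config: Optional[FeatureConfig] = None,
    sets: Iterable[str] = ALL_SETS,
) -> FeatureVector:
    """Compute the selected feature sets for one segmented cell."""
    config = config or FeatureConfig()
    sets = list(sets)
    names: list[str] = []
    values: list[float] = []
    px = image.pixels

    if "F1" in sets:
        names.append("F1_NC")
        values.append(relative_nucleus_size(seg))

    if "F2" in sets:
        for region in config.f2_regions:
            if region == "nucleus":
                region_mask = seg.nucleus_mask
            else:
                mask = seg.cytoplasm_mask
                region_mask = mask if mask.any() else seg.cell_mask
            stats = intensity_stats(px[region_mask], levels=image.levels)
            for stat_name, v in zip(("dr", "mean", "var", "skew", "kurt"), stats.as_tuple()):
                names.append(f"F2_{region}_{stat_name}")
                values.append(v)

    if "F3" in sets:
        names.append("F3_RD")
        values.append(relative_displacement(seg))

    tex_mask = _texture_mask(seg, config.texture_region)

    if "F4" in sets:
        glcm = texture.compute_glcm(
            px, tex_mask, levels=config.glcm_levels,
            offsets=config.glcm_offsets, intensity_levels=image.levels,
        )
        hf = texture.haralick_features(glcm)
        for n, v in zip(texture.HaralickFeatures.NAMES, hf.as_array()):
            names.append(f"F4_{n}")
            values.append(float(v))

    if "F5" in sets:
        lbp = texture.lbp_histogram(
            px, tex_mask, P=config.lbp_P, R=config.lbp_R, scheme=config.lbp_scheme
        )
        if config.lbp_projection == "entropy":
            names.append("F5_lbp_entropy")
            values.append(lbp.entropy)
        elif config.lbp_projection == "histogram":
            freqs = lbp.frequencies
            for i, v in enumerate(freqs):
                names.append(f"F5_lbp_bin{i:03d}")
                values.append(float(v))
        else:
            raise ValueError(f"unknown LBP projection {config.lbp_projection!r}")

    if "F6" in sets:
        tam = texture.tamura_features(
            px, tex_mask, kmax=config.tamura_kmax,
            bins=config.tamura_bins, threshold=config.tamura_threshold,
        )
        names += ["F6_coarseness", "F6_contrast", "F6_directionality"]
        values += [tam.coarseness, tam.contrast, tam.directionality]

    if "F7" in sets:
        eoh = texture.edge_orientation_histogram(
            px, tex_mask, bins=config.eoh_bins, threshold=config.eoh_threshold
        )
        if config.eoh_projection == "entropy":
            names.append("F7_eoh_entropy")
            values.append(eoh.entropy)
        elif config.eoh_projection == "histogram":
            for i, v in enumerate(eoh.frequencies):
                names.append(f"F7_eoh_bin{i}")
                values.append(float(v))
        else:
            raise ValueError(f"unknown EOH projection {config.eoh_projection!r}")

    return FeatureVector(names=tuple(names), values=np.array(values))


def extract_dataset(
    images: Sequence[CellImage],
    seg_params: Optional[SegmentationParams] = None,
    config: Optional[FeatureConfig] = None,
    sets: Iterable[str] = ALL_SETS,
) -> pd.DataFrame:
    """Segment every image and extract features into one table.

    Returns a DataFrame with one row per cell, the feature columns, and
    a ``label`` column (NaN for unlabeled cells).
    """
    sets = list(sets)
    rows = []
    labels = []
    for img in images:
        seg = segment_cell(img, seg_params)
        fv = extract_features(img, seg, config, sets)
        rows.append(fv.as_series())
        labels.append(img.label if img.label is not None else np.nan)
    if not rows:
        raise ValueError("no images to extract features from")
    df = pd.DataFrame(rows).reset_index(drop=True)
    df["label"] = labels
    return df
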