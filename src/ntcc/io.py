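"""Reading and writing images, datasets, feature tables and reports.

Datasets follow a class-per-directory layout: each immediate
subdirectory of the root names a class (either the canonical class name,
e.g. ``normal_squamous``, optionally with a numeric prefix like
``3_columnar``, or a bare id ``1``..``7``) and contains one image file
per cell.  A companion file sharing the image basename plus a suffix
(default ``-d``) is treated as a ground-truth segmentation map whose
gray values encode background / cytoplasm / nucleus.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .types import CLASS_IDS, CellImage

logger = logging.getLogger("ntcc")

IMAGE_EXTENSIONS = {".bmp", ".png", ".tif", ".tiff"}

#: Default gray-value encoding of ground-truth maps.
DEFAULT_MASK_VALUES: dict[int, str] = {0: "background", 128: "cytoplasm", 255: "nucleus"}

#: Default suffix marking a ground-truth companion file.
DEFAULT_MASK_SUFFIX = "-d"

_LUMA_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])  # ITU-R 709 luminance


def _to_grayscale(raw: np.ndarray) -> np.ndarray:
    """Convert a decoded image to an 8-bit grayscale raster."""
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        arr = arr.astype(float) @ _LUMA_WEIGHTS
    arr = arr.astype(float)
    if arr.max() > 255:  # higher bit depth: rescale linearly into 8 bits
        arr = arr / arr.max() * 255.0
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read an image file as an 8-bit grayscale raster."""
    return _to_grayscale(iio.imread(Path(path)))


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(pixels, dtype=np.uint8))


def masks_to_map(
    nucleus: np.ndarray,
    cytoplasm: np.ndarray,
    mask_values: dict[int, str] = DEFAULT_MASK_VALUES,
) -> np.ndarray:
    """Encode nucleus/cytoplasm masks into a single gray-value map."""
    value_of = {role: v for v, role in mask_values.items()}
    out = np.full(nucleus.shape, value_of["background"], dtype=np.uint8)
    out[np.asarray(cytoplasm, dtype=bool)] = value_of["cytoplasm"]
    out[np.asarray(nucleus, dtype=bool)] = value_of["nucleus"]
    return out


def map_to_masks(
    gt_map: np.ndarray, mask_values: dict[int, str] = DEFAULT_MASK_VALUES
) -> tuple[np.ndarray, np.ndarray]:
    """Decode a ground-truth map into (nucleus, cytoplasm) boolean masks."""
    gt_map = np.asarray(gt_map)
    nucleus = np.zeros(gt_map.shape, dtype=bool)
    cytoplasm = np.zeros(gt_map.shape, dtype=bool)
    for value, role in mask_values.items():
        if role == "nucleus":
            nucleus |= gt_map == value
        elif role == "cytoplasm":
            cytoplasm |= gt_map == value
    return nucleus, cytoplasm


def _class_id_for_dir(name: str, class_map: Optional[dict[str, int]]) -> Optional[int]:
    if class_map and name in class_map:
        return class_map[name]
    if name.isdigit() and int(name) in range(1, 8):
        return int(name)
    stripped = name.split("_", 1)[-1] if name[:1].isdigit() and "_" in name else name
    for candidate in (name, stripped):
        if candidate in CLASS_IDS:
            return CLASS_IDS[candidate]
    return None


def load_dataset(
    root_dir: str | Path,
    class_map: Optional[dict[str, int]] = None,
    mask_suffix: str = DEFAULT_MASK_SUFFIX,
    mask_values: dict[int, str] = DEFAULT_MASK_VALUES,
) -> list[CellImage]:
    """Load a class-per-directory dataset of single-cell images.

    Images are converted to 8-bit grayscale by the standard luminance
    combination; ground-truth companion files (basename + suffix) are
    attached to their base image rather than returned separately.
    Unreadable files are skipped with a warning.  Directory traversal is
    lexicographic, so loading order is deterministic.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")

    cells: list[CellImage] = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        label = _class_id_for_dir(sub.name, class_map)
        if label is None:
            logger.warning("skipping directory %s: no class mapping", sub.name)
            continue
        files = sorted(p for p in sub.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS)
        mask_files = {p.stem[: -len(mask_suffix)]: p for p in files
                      if p.stem.endswith(mask_suffix)}
        for path in files:
            if path.stem.endswith(mask_suffix):
                continue
            try:
                pixels = read_image(path)
            except Exception as exc:  # unreadable file: warn and skip
                warnings.warn(f"skipping unreadable image {path}: {exc}")
                logger.warning("skipping unreadable image %s: %s", path, exc)
                continue
            gt_n = gt_c = None
            mask_path = mask_files.get(path.stem)
            if mask_path is not None:
                try:
                    gt_n, gt_c = map_to_masks(iio.imread(mask_path), mask_values)
                except Exception as exc:
                    warnings.warn(f"skipping unreadable mask {mask_path}: {exc}")
            cells.append(
                CellImage(
                    pixels=pixels,
                    label=label,
                    source_path=str(path),
                    gt_nucleus_mask=gt_n,
                    gt_cytoplasm_mask=gt_c,
                )
            )
    if not cells:
        raise ValueError(f"no images found under {root}")
    return cells


def write_feature_table(df: pd.DataFrame, out: str | Path) -> None:
    """Write a feature table (feature columns + ``label``) to CSV.

    The text round-trips losslessly: floats are serialized with the
    shortest representation that parses back to the same value.
    """
    if len(df) == 0:
        raise ValueError("refusing to write an empty feature table")
    if "label" not in df.columns:
        raise ValueError("feature table must contain a 'label' column")
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path} is not a feature table (no 'label' column)")
    return df


def feature_table_from_vectors(vectors: Sequence, labels: Sequence[int]) -> pd.DataFrame:
    """Assemble FeatureVectors + labels into a table, checking schemas."""
    if len(vectors) != len(labels):
        raise ValueError("vectors and labels must have equal length")
    if not vectors:
        raise ValueError("no feature vectors given")
    names = vectors[0].names
    for v in vectors[1:]:
        if v.names != names:
            raise ValueError("inconsistent feature schemas across vectors")
    df = pd.DataFrame([v.values for v in vectors], columns=list(names))
    df["label"] = list(labels)
    return df


def write_report(report: dict, out: str | Path) -> None:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
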