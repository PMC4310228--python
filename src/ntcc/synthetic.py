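"""Synthetic single-cell Pap-smear image generator with ground truth.

Each synthetic cell is a bright background, a mid-intensity cytoplasm
and a dark nucleus, both drawn as low-order-Fourier perturbed ellipses
(the perturbation amplitude models the increasingly irregular nuclear
outline of dysplastic cells).  Class presets control the
nucleus-to-cell area ratio (which rises monotonically from normal
squamous to carcinoma in situ), the nucleus displacement, mean
intensities, boundary irregularity and the spatial scale of a smooth
texture field added inside the cell.  The generator records the exact
pixel-counted NC ratio and relative displacement from the emitted
ground-truth masks, so every downstream estimate can be scored against
a known truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import DEFAULT_MASK_SUFFIX, masks_to_map, write_image
from .segmentation import region_properties
from .types import CLASS_NAMES, CellImage

PRESET_VERSION = 1


@dataclass(frozen=True)
class ClassPreset:
    """Generative parameters of one cell class."""

    label: int
    nc_ratio_range: tuple[float, float]
    displacement_range: tuple[float, float]  # fraction of cell diameter
    nucleus_intensity: float
    cytoplasm_intensity: float
    background_intensity: float
    noise_sd: float
    texture_scale: int  # pixels; smaller -> higher-frequency texture
    texture_amplitude: float
    irregularity: float  # relative boundary perturbation amplitude

    def __post_init__(self) -> None:
        lo, hi = self.nc_ratio_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("nc_ratio_range must lie inside (0, 1)")
        if not (self.nucleus_intensity < self.cytoplasm_intensity
                < self.background_intensity):
            raise ValueError(
                "intensities must be ordered nucleus < cytoplasm < background"
            )


#: Default presets for the seven classes.  NC ranges increase with class
#: id; presets 6 and 7 overlap in NC and share intensity/texture settings
#: so that the hardest distinction (severe dysplasia vs carcinoma in
#: situ) is genuinely ambiguous, mirroring where real graders disagree.
DEFAULT_PRESETS: tuple[ClassPreset, ...] = (
    ClassPreset(1, (0.04, 0.08), (0.00, 0.04), 80, 160, 230, 3.0, 16, 10.0, 0.03),
    ClassPreset(2, (0.08, 0.13), (0.00, 0.05), 75, 155, 230, 3.0, 12, 10.0, 0.03),
    ClassPreset(3, (0.28, 0.36), (0.00, 0.06), 70, 150, 230, 3.0, 8, 10.0, 0.04),
    ClassPreset(4, (0.38, 0.46), (0.02, 0.08), 65, 145, 230, 3.0, 6, 12.0, 0.05),
    ClassPreset(5, (0.48, 0.56), (0.03, 0.10), 60, 140, 230, 3.0, 5, 12.0, 0.06),
    ClassPreset(6, (0.60, 0.68), (0.04, 0.12), 50, 135, 230, 3.0, 3, 14.0, 0.08),
    ClassPreset(7, (0.64, 0.72), (0.04, 0.12), 50, 135, 230, 3.0, 3, 14.0, 0.09),
)


@dataclass
class SyntheticCell:
    """A generated cell image plus its generative ground truth."""

    image: CellImage
    true_nc: float
    true_rd: float
    preset: ClassPreset
    seed: int


def _perturbed_radius(theta: np.ndarray, r0: float, amplitude: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Radius profile r(theta) of a low-order-Fourier perturbed ellipse."""
    r = np.full_like(theta, r0)
    for h in (2, 3, 4):
        a = rng.uniform(0.3, 1.0) * amplitude * r0 / h
        phi = rng.uniform(0, 2 * np.pi)
        r = r + a * np.cos(h * theta + phi)
    return r


def _blob_mask(shape: tuple[int, int], center: tuple[float, float],
               r0: float, aspect: float, angle: float, amplitude: float,
               rng: np.random.Generator) -> np.ndarray:
    """Rasterize a perturbed ellipse: pixels whose (elliptically scaled)
    polar radius falls below the perturbed radius profile."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dy = rr - center[0]
    dx = cc - center[1]
    # rotate into the ellipse frame and squeeze one axis
    u = np.cos(angle) * dx + np.sin(angle) * dy
    v = -np.sin(angle) * dx + np.cos(angle) * dy
    u = u / aspect
    rad = np.hypot(u, v)
    theta = np.arctan2(v, u)
    # evaluate the perturbation on a dense angular grid, then look up
    grid = np.linspace(-np.pi, np.pi, 721)
    prof = _perturbed_radius(grid, r0, amplitude, rng)
    boundary = np.interp(theta, grid, prof, period=2 * np.pi)
    return rad <= boundary


def _texture_field(shape: tuple[int, int], scale: int, amplitude: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth random field: coarse white noise bilinearly upsampled to
    pixel resolution; ``scale`` is the correlation length in pixels."""
    h, w = shape
    gh = max(2, h // scale + 2)
    gw = max(2, w // scale + 2)
    coarse = rng.normal(0.0, 1.0, size=(gh, gw))
    rows = np.linspace(0, gh - 1.001, h)
    cols = np.linspace(0, gw - 1.001, w)
    r0 = rows.astype(int)
    c0 = cols.astype(int)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    field = (
        coarse[np.ix_(r0, c0)] * (1 - fr) * (1 - fc)
        + coarse[np.ix_(r0, c0 + 1)] * (1 - fr) * fc
        + coarse[np.ix_(r0 + 1, c0)] * fr * (1 - fc)
        + coarse[np.ix_(r0 + 1, c0 + 1)] * fr * fc
    )
    return amplitude * field


def generate_cell(
    preset: ClassPreset,
    size: tuple[int, int] = (128, 128),
    seed: int = 0,
    noise_sd: Optional[float] = None,
) -> SyntheticCell:
    """Generate one synthetic cell; deterministic for a given seed.

    ``noise_sd`` overrides the preset's pixel-noise level (0 gives the
    noise-free images used for segmentation ground-truth checks).
    """
    h, w = size
    if h < 64 or w < 64:
        raise ValueError("image size must be at least 64x64")
    rng = np.random.default_rng(seed)
    sd = preset.noise_sd if noise_sd is None else noise_sd

    # cytoplasm: a large perturbed ellipse centered in the frame
    cyto_r = 0.36 * min(h, w) * rng.uniform(0.9, 1.05)
    aspect = rng.uniform(0.8, 1.0)
    angle = rng.uniform(0, np.pi)
    center = (h / 2 + rng.uniform(-2, 2), w / 2 + rng.uniform(-2, 2))
    cell_mask = _blob_mask((h, w), center, cyto_r, aspect, angle,
                           preset.irregularity, rng)

    # nucleus: drawn in the cell's own elliptical frame (same aspect and
    # orientation) with its radius set from the target NC ratio, so a
    # large nucleus scales with the cell instead of poking out of it
    nc_target = rng.uniform(*preset.nc_ratio_range)
    cell_area = cell_mask.sum()
    nuc_r = cyto_r * float(np.sqrt(nc_target))
    cell_diam = 2.0 * np.sqrt(cell_area / np.pi)
    if nuc_r * (1 + preset.irregularity) >= cyto_r * (1 - preset.irregularity) + 1:
        raise ValueError(
            f"nucleus cannot fit inside the cell at NC ratio {nc_target:.2f}"
        )
    disp_frac = rng.uniform(*preset.displacement_range)
    disp = disp_frac * cell_diam
    # clamp so the (perturbed) nucleus stays essentially inside; any
    # residual overhang is clipped to the cell mask below
    max_disp = max(0.0, (cyto_r * (1 - preset.irregularity)
                         - nuc_r * (1 + preset.irregularity)) * aspect - 1)
    disp = min(disp, max_disp)
    phi = rng.uniform(0, 2 * np.pi)
    nuc_center = (center[0] + disp * np.sin(phi), center[1] + disp * np.cos(phi))
    nucleus_mask = _blob_mask((h, w), nuc_center, nuc_r, aspect, angle,
                              preset.irregularity, rng)
    nucleus_mask &= cell_mask
    cyto_mask = cell_mask & ~nucleus_mask

    img = np.full((h, w), preset.background_intensity, dtype=float)
    img[cyto_mask] = preset.cytoplasm_intensity
    img[nucleus_mask] = preset.nucleus_intensity
    tex = _texture_field((h, w), preset.texture_scale, preset.texture_amplitude, rng)
    img[cell_mask] += tex[cell_mask]
    if sd > 0:
        img += rng.normal(0.0, sd, size=img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    # ground truth measured from the emitted masks (pixel-exact)
    n_area, n_centroid, _ = region_properties(nucleus_mask)
    c_area = int(cyto_mask.sum())
    _, c_centroid, cell_eqd = region_properties(cell_mask)
    true_nc = n_area / (n_area + c_area)
    _, cy_centroid, _ = region_properties(cyto_mask if c_area else cell_mask)
    dist = float(np.hypot(cy_centroid[0] - n_centroid[0],
                          cy_centroid[1] - n_centroid[1]))
    true_rd = dist / cell_eqd

    image = CellImage(
        pixels=pixels,
        label=preset.label,
        gt_nucleus_mask=nucleus_mask,
        gt_cytoplasm_mask=cyto_mask,
    )
    return SyntheticCell(image=image, true_nc=true_nc, true_rd=true_rd,
                         preset=preset, seed=seed)


def generate_cells(
    presets: Sequence[ClassPreset] = DEFAULT_PRESETS,
    n_per_class: int = 70,
    seed: int = 0,
    size: tuple[int, int] = (128, 128),
    noise_sd: Optional[float] = None,
) -> list[SyntheticCell]:
    """Generate ``n_per_class`` cells per preset, with per-cell seeds
    derived deterministically from the master seed."""
    master = np.random.default_rng(seed)
    cells = []
    for preset in presets:
        for _ in range(n_per_class):
            cell_seed = int(master.integers(0, 2**31 - 1))
            cells.append(generate_cell(preset, size=size, seed=cell_seed,
                                       noise_sd=noise_sd))
    return cells


def generate_dataset(
    out_dir: str | Path,
    presets: Sequence[ClassPreset] = DEFAULT_PRESETS,
    n_per_class: int = 70,
    seed: int = 0,
    size: tuple[int, int] = (128, 128),
    noise_sd: Optional[float] = None,
) -> pd.DataFrame:
    """Write a class-per-directory synthetic dataset to disk.

    Emits one PNG per cell plus a ground-truth map companion
    (``<name>-d.png``) and a ``manifest.csv`` recording the true
    parameters per cell.  Returns the manifest.
    """
    out = Path(out_dir)
    records = []
    cells = generate_cells(presets, n_per_class, seed, size, noise_sd)
    per_class_counter: dict[int, int] = {}
    for cell in cells:
        label = cell.preset.label
        idx = per_class_counter.get(label, 0)
        per_class_counter[label] = idx + 1
        sub = out / f"{label}_{CLASS_NAMES[label]}"
        name = f"cell_{idx:04d}"
        write_image(sub / f"{name}.png", cell.image.pixels)
        gt_map = masks_to_map(cell.image.gt_nucleus_mask, cell.image.gt_cytoplasm_mask)
        write_image(sub / f"{name}{DEFAULT_MASK_SUFFIX}.png", gt_map)
        rec = {
            "file": str(Path(sub.name) / f"{name}.png"),
            "class_id": label,
            "class_name": CLASS_NAMES[label],
            "cell_seed": cell.seed,
            "true_nc": cell.true_nc,
            "true_rd": cell.true_rd,
            "preset_version": PRESET_VERSION,
        }
        rec.update({f"preset_{k}": v for k, v in asdict(cell.preset).items()})
        records.append(rec)
    manifest = pd.DataFrame.from_records(records)
    out.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def preset_with(preset: ClassPreset, **overrides) -> ClassPreset:
    """Convenience: a copy of a preset with fields replaced."""
    return replace(preset, **overrides)
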