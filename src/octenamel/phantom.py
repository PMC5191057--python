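"""Synthetic layered tooth-phantom generator with known ground truth.

Clinical OCT stacks of tooth cross-sections show a bright, highly scattering
enamel band (~250 um physical depth in a healthy tooth), a thin
dentino-enamel junction (DEJ) band beneath it, and dentin below, all on a
dark background. Demineralization lowers the backscatter of the affected
region (mineral loss reduces the scattering coefficient) and, as caries
progresses, erodes enamel thickness. This module emulates those features
with a simple intensity model so that every analysis stage can be tested
against a known ground truth:

* within each layer, mean intensity decays exponentially with physical
  depth from the layer top (Beer-Lambert-like attenuation);
* a lesion multiplies backscatter by ``reflectivity_scale`` (< 1) over its
  lateral span and depth extent, and recedes the enamel surface by
  ``enamel_erosion_um``;
* the air-enamel interface produces a strong near-specular Fresnel
  reflection, rendered as a bright line (``surface_reflectivity``) at the
  first tissue row of every column — the feature that makes per-A-scan
  peak search a reliable surface detector on real B-scans;
* speckle is modelled as multiplicative gamma noise with unit mean, the
  standard first-order surrogate on display-scaled intensity images; the
  default shape (30, contrast ~0.18) reflects the reduced speckle contrast
  of log-compressed, display-scaled 8-bit B-scans rather than raw linear
  single-look speckle (which would have unit contrast);
* the surface may be tilted linearly across columns.

Depth bookkeeping: a pixel at image row ``r`` in a column whose surface row
is ``s`` sits at physical depth ``(r - s) * ly / n_tissue`` micrometres
(optical pitch divided by the tissue refractive index). Layer intervals are
half-open ``[top, top + thickness)``.

All randomness derives from the spec seed; per-frame RNG streams are keyed
by ``(seed, frame_index)`` so frames are independent of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._util import round_half_up
from .image_io import BScanImage, OCTVolume, VoxelGeometry

__all__ = [
    "LayerSpec",
    "LesionSpec",
    "PhantomSpec",
    "PhantomGroundTruth",
    "default_layers",
    "layers_with_enamel_thickness",
    "phantom_for_condition",
    "generate_bscan",
    "generate_volume",
    "write_ground_truth",
]

LAYER_NAMES = ("enamel", "dej", "dentin", "background")


@dataclass(frozen=True)
class LayerSpec:
    """One optical layer of the phantom.

    ``top_depth_um``/``thickness_um`` are physical depths below the tooth
    surface; ``base_reflectivity`` is the mean backscatter at the layer top
    on the 0-255 display scale; ``attenuation_per_um`` is the exponential
    decay coefficient of signal with depth inside the layer.
    """

    name: str
    top_depth_um: float
    thickness_um: float
    base_reflectivity: float
    attenuation_per_um: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in LAYER_NAMES:
            raise ValueError(f"unknown layer name {self.name!r}")
        if self.thickness_um < 0:
            raise ValueError("layer thickness must be >= 0")
        if not (0 <= self.base_reflectivity <= 255):
            raise ValueError("base_reflectivity must lie in [0, 255]")
        if self.attenuation_per_um < 0:
            raise ValueError("attenuation_per_um must be >= 0")


@dataclass(frozen=True)
class LesionSpec:
    """A demineralized patch: reduced backscatter and eroded enamel.

    Demineralization lowers backscatter, so ``reflectivity_scale`` must be
    <= 1. ``enamel_erosion_um`` recedes the surface: material is removed
    from the top of the enamel, the enamel bottom and deeper layers stay
    where they are. ``depth_extent_um`` bounds how deep below the (eroded)
    surface the backscatter reduction reaches.
    """

    center_lateral_px: int
    width_px: int
    depth_extent_um: float
    reflectivity_scale: float = 0.7
    enamel_erosion_um: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.reflectivity_scale <= 1):
            raise ValueError("reflectivity_scale must lie in (0, 1]")
        if self.width_px < 1:
            raise ValueError("lesion width must be >= 1 px")
        if self.depth_extent_um < 0 or self.enamel_erosion_um < 0:
            raise ValueError("lesion depth extents must be >= 0")

    @property
    def col_lo(self) -> int:
        return self.center_lateral_px - self.width_px // 2

    @property
    def col_hi(self) -> int:
        return self.col_lo + self.width_px


def default_layers() -> list[LayerSpec]:
    """Healthy-tooth default: enamel to 250 um, a thin bright DEJ band at
    the enamel bottom, dentin to 800 um physical depth."""
    return [
        LayerSpec("enamel", 0.0, 250.0, 200.0, 0.004),
        LayerSpec("dej", 250.0, 40.0, 150.0, 0.002),
        LayerSpec("dentin", 290.0, 510.0, 110.0, 0.003),
    ]


def layers_with_enamel_thickness(thickness_um: float) -> list[LayerSpec]:
    """Default layer stack with the enamel band set to ``thickness_um``;
    DEJ and dentin slide up/down so layers stay contiguous."""
    t = float(thickness_um)
    return [
        LayerSpec("enamel", 0.0, t, 200.0, 0.004),
        LayerSpec("dej", t, 40.0, 150.0, 0.002),
        LayerSpec("dentin", t + 40.0, 510.0, 110.0, 0.003),
    ]


@dataclass
class PhantomSpec:
    """Full parametric description of a synthetic tooth stack.

    Identical spec + seed yields a bit-identical stack on any platform.
    ``speckle_shape`` is the gamma shape parameter k of the multiplicative
    noise (mean 1, variance 1/k); ``None`` or 0 disables speckle.
    ``noise_floor`` is the mean background level outside tissue.
    """

    rows: int = 160
    cols: int = 64
    frames: int = 8
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    layers: list[LayerSpec] = field(default_factory=default_layers)
    lesions: list[LesionSpec] = field(default_factory=list)
    surface_offset_px: int = 10
    surface_tilt_px_per_col: float = 0.0
    surface_reflectivity: float = 250.0  # Fresnel line; 0 disables
    speckle_shape: float | None = 30.0
    noise_floor: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rows, self.cols, self.frames) < 1:
            raise ValueError("rows, cols and frames must all be >= 1")
        lay = sorted(self.layers, key=lambda l: l.top_depth_um)
        for a, b in zip(lay, lay[1:]):
            if not np.isclose(a.top_depth_um + a.thickness_um, b.top_depth_um):
                raise ValueError(
                    f"layers {a.name} and {b.name} are not contiguous in depth"
                )
        self.layers = lay
        if self.layers:
            max_surface = self.surface_offset_px + max(
                0.0, self.surface_tilt_px_per_col * (self.cols - 1)
            )
            last = self.layers[-1]
            depth_rows = (
                (last.top_depth_um + last.thickness_um)
                * self.geometry.n_tissue
                / self.geometry.ly_um
            )
            if max_surface >= self.rows:
                raise ValueError("surface offset/tilt pushes the tooth out of frame")
            if max_surface + depth_rows > 4 * self.rows:
                raise ValueError("layer stack vastly exceeds the image depth")

    def surface_rows(self) -> np.ndarray:
        """Surface row per column: offset plus the rounded linear tilt."""
        c = np.arange(self.cols)
        return (
            self.surface_offset_px
            + round_half_up(self.surface_tilt_px_per_col * c)
        ).astype(np.int64)


def _erosion_and_scale(spec: PhantomSpec):
    """Per-column enamel erosion (um) and the lesion scale/extent maps."""
    erosion = np.zeros(spec.cols)
    for les in spec.lesions:
        lo, hi = max(les.col_lo, 0), min(les.col_hi, spec.cols)
        if hi > lo:
            erosion[lo:hi] = np.maximum(erosion[lo:hi], les.enamel_erosion_um)
    return erosion


def _clean_frame(spec: PhantomSpec) -> np.ndarray:
    """Noise-free intensity model, float64, before speckle and quantization."""
    g = spec.geometry
    surface = spec.surface_rows()
    erosion = _erosion_and_scale(spec)
    # physical depth of each pixel's top edge below the (un-eroded) surface
    depth = (np.arange(spec.rows)[:, None] - surface[None, :]) * (
        g.ly_um / g.n_tissue
    )
    img = np.full((spec.rows, spec.cols), float(spec.noise_floor))
    tissue = np.zeros_like(img, dtype=bool)
    enamel_bottom = None
    for layer in spec.layers:
        top = np.full(spec.cols, layer.top_depth_um)
        bottom = layer.top_depth_um + layer.thickness_um
        if layer.name == "enamel":
            top = np.minimum(np.maximum(top, erosion), bottom)
            enamel_bottom = bottom
        mask = (depth >= top[None, :]) & (depth < bottom)
        if layer.attenuation_per_um:
            vals = layer.base_reflectivity * np.exp(
                -layer.attenuation_per_um * (depth - top[None, :])
            )
        else:
            vals = np.full_like(depth, float(layer.base_reflectivity))
        img[mask] = vals[mask]
        tissue |= mask
    # specular surface line at the first tissue row of each column
    if spec.surface_reflectivity:
        has_tissue = tissue.any(axis=0)
        first = tissue.argmax(axis=0)
        cols_idx = np.nonzero(has_tissue)[0]
        img[first[cols_idx], cols_idx] = float(spec.surface_reflectivity)
    # lesion backscatter reduction, measured from the eroded surface
    for les in spec.lesions:
        lo, hi = max(les.col_lo, 0), min(les.col_hi, spec.cols)
        if hi <= lo:
            continue
        sub = np.s_[:, lo:hi]
        rel = depth[sub] - erosion[None, lo:hi]
        hit = tissue[sub] & (rel < les.depth_extent_um)
        scaled = img[sub].copy()
        scaled[hit] *= les.reflectivity_scale
        img[sub] = scaled
    return img


def generate_bscan(spec: PhantomSpec, frame_index: int) -> BScanImage:
    """Generate one synthetic B-scan.

    Deterministic in ``(spec, spec.seed, frame_index)``. Speckle, when
    enabled, multiplies the clean model by i.i.d. gamma(k, 1/k) draws from
    an RNG stream keyed by (seed, frame_index); the result is clipped to
    [0, 255] and rounded half-up to 8 bits.
    """
    clean = _clean_frame(spec)
    if spec.speckle_shape:
        rng = np.random.default_rng([int(spec.seed), int(frame_index)])
        k = float(spec.speckle_shape)
        clean = clean * rng.gamma(shape=k, scale=1.0 / k, size=clean.shape)
    pix = np.clip(round_half_up(clean), 0, 255).astype(np.uint8)
    return BScanImage(pix, geometry=spec.geometry, frame_index=frame_index)


@dataclass
class PhantomGroundTruth:
    """What the generator actually drew, for parameter-recovery tests.

    Rows are image rows; ``enamel_bottom_row`` is exclusive. The voxel
    count and volume are the geometric (noise-free) enamel occupancy over
    the whole stack.
    """

    surface_row: np.ndarray
    enamel_top_row: np.ndarray
    enamel_bottom_row: np.ndarray
    enamel_thickness_um: float
    enamel_voxel_count: int
    enamel_volume_mm3: float

    def to_dict(self) -> dict:
        return {
            "surface_row": self.surface_row.tolist(),
            "enamel_top_row": self.enamel_top_row.tolist(),
            "enamel_bottom_row": self.enamel_bottom_row.tolist(),
            "enamel_thickness_um": self.enamel_thickness_um,
            "enamel_voxel_count": self.enamel_voxel_count,
            "enamel_volume_mm3": self.enamel_volume_mm3,
        }


def _enamel_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean (rows, cols) occupancy of the (possibly eroded) enamel band,
    built with the same depth bookkeeping as the intensity model."""
    g = spec.geometry
    surface = spec.surface_rows()
    erosion = _erosion_and_scale(spec)
    depth = (np.arange(spec.rows)[:, None] - surface[None, :]) * (
        g.ly_um / g.n_tissue
    )
    for layer in spec.layers:
        if layer.name == "enamel":
            bottom = layer.top_depth_um + layer.thickness_um
            top = np.minimum(np.maximum(layer.top_depth_um, erosion), bottom)
            return (depth >= top[None, :]) & (depth < bottom)
    return np.zeros((spec.rows, spec.cols), dtype=bool)


def generate_volume(spec: PhantomSpec) -> tuple[OCTVolume, PhantomGroundTruth]:
    """Generate the full stack plus its ground-truth record."""
    frames = np.stack(
        [generate_bscan(spec, i).pixels for i in range(spec.frames)], axis=0
    )
    vol = OCTVolume(frames, geometry=spec.geometry)

    mask = _enamel_mask(spec)
    per_col_count = mask.sum(axis=0)
    any_enamel = per_col_count > 0
    top = np.where(any_enamel, mask.argmax(axis=0), -1)
    bottom = np.where(any_enamel, top + per_col_count, -1)
    count = int(mask.sum()) * spec.frames
    g = spec.geometry
    enamel = next((l for l in spec.layers if l.name == "enamel"), None)
    gt = PhantomGroundTruth(
        surface_row=spec.surface_rows(),
        enamel_top_row=top.astype(np.int64),
        enamel_bottom_row=bottom.astype(np.int64),
        enamel_thickness_um=float(enamel.thickness_um) if enamel else 0.0,
        enamel_voxel_count=count,
        enamel_volume_mm3=count * g.voxel_volume_um3 * 1e-9,
    )
    return vol, gt


def phantom_for_condition(kind: str, seed: int = 0, **overrides) -> PhantomSpec:
    """Preset phantoms mirroring the study conditions.

    ``healthy``: intact 250 um enamel. ``partial``: demineralized, whole
    scan width, backscatter scaled by 0.7 and enamel eroded by 100 um
    (residual ~150 um). ``carious``: backscatter scaled by 0.4, erosion
    150 um (residual ~100 um).
    """
    presets = {
        "healthy": [],
        "partial": [
            LesionSpec(
                center_lateral_px=0,
                width_px=10_000,
                depth_extent_um=1000.0,
                reflectivity_scale=0.7,
                enamel_erosion_um=100.0,
            )
        ],
        "carious": [
            LesionSpec(
                center_lateral_px=0,
                width_px=10_000,
                depth_extent_um=1000.0,
                reflectivity_scale=0.4,
                enamel_erosion_um=150.0,
            )
        ],
    }
    if kind not in presets:
        raise ValueError(f"unknown condition {kind!r}; choose from {sorted(presets)}")
    lesions = [
        replace(les, center_lateral_px=overrides.get("cols", PhantomSpec.cols) // 2)
        for les in presets[kind]
    ]
    return PhantomSpec(lesions=lesions, seed=seed, **overrides)


def write_ground_truth(gt: PhantomGroundTruth, path) -> None:
    """Emit the ground truth as a JSON sidecar next to the generated stack."""
    Path(path).write_text(json.dumps(gt.to_dict(), indent=2))
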