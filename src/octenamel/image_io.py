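"""B-scan stack I/O, intensity normalization and source-power compensation.

A B-scan is a 2D cross-sectional OCT image: rows run along the axial (depth)
direction with row 0 on the tissue-surface side, columns along the lateral
sweep. Stacks of B-scans form a volume whose third axis is the slow scan
(frame) direction. Two on-disk formats are supported:

* multi-page 8-bit grayscale TIFF (canonical), one page per frame;
* raw binary with a JSON sidecar declaring ``{rows, cols, frames, dtype}``
  and optionally the voxel geometry.

Depth is stored in optical-path pixels; conversion to physical micrometres
(division by the tissue refractive index) happens only in the measurement
operations, never at I/O time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import tifffile

from ._util import round_half_up

log = logging.getLogger(__name__)

__all__ = [
    "VoxelGeometry",
    "BScanImage",
    "OCTVolume",
    "StackFormatError",
    "read_stack",
    "write_stack",
    "normalize_to_8bit",
    "compensate_power",
]


class StackFormatError(ValueError):
    """A stack on disk violates the format contract (e.g. mixed frame sizes)."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical pixel geometry of an OCT stack.

    Parameters
    ----------
    lx_um : float
        Lateral pixel pitch within a frame, micrometres.
    ly_um : float
        Axial (depth-direction) pixel pitch within a frame, micrometres of
        optical path length.
    lz_um : float
        Inter-frame (slow-scan) spacing, micrometres.
    n_tissue : float
        Refractive index used to convert optical to physical depth.
        Defaults to 1.63, the standard value for dental hard tissue.
    """

    lx_um: float = 12.0
    ly_um: float = 12.0
    lz_um: float = 7.0
    n_tissue: float = 1.63

    def __post_init__(self) -> None:
        if not (self.lx_um > 0 and self.ly_um > 0 and self.lz_um > 0):
            raise ValueError("pixel pitches lx, ly, lz must all be positive")
        if self.n_tissue < 1:
            raise ValueError("refractive index n_tissue must be >= 1")

    @property
    def axial_pitch_um(self) -> float:
        """Physical axial pixel pitch: optical pitch divided by n_tissue."""
        return self.ly_um / self.n_tissue

    @property
    def voxel_volume_um3(self) -> float:
        """Nominal voxel volume lx * ly * lz in cubic micrometres."""
        return self.lx_um * self.ly_um * self.lz_um

    def to_dict(self) -> dict:
        return {
            "lx_um": self.lx_um,
            "ly_um": self.ly_um,
            "lz_um": self.lz_um,
            "n_tissue": self.n_tissue,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGeometry":
        return cls(
            lx_um=float(d.get("lx_um", 12.0)),
            ly_um=float(d.get("ly_um", 12.0)),
            lz_um=float(d.get("lz_um", 7.0)),
            n_tissue=float(d.get("n_tissue", 1.63)),
        )


@dataclass
class BScanImage:
    """One 2D cross-sectional intensity frame.

    ``pixels`` is a (rows, cols) array; rows are axial with row 0 at the
    tissue-surface side, columns lateral. Intensities are expected on the
    0-255 scale after :func:`normalize_to_8bit`.
    """

    pixels: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("a B-scan must be a non-empty 2D array")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


@dataclass
class OCTVolume:
    """Ordered stack of B-scans sharing one geometry.

    ``data`` has shape (frames, rows, cols); the frame axis is the slow-scan
    (z) direction.
    """

    data: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("a volume must be a 3D (frames, rows, cols) array")

    @property
    def count(self) -> int:
        return self.data.shape[0]

    def __len__(self) -> int:
        return self.count

    def frame(self, i: int) -> BScanImage:
        return BScanImage(self.data[i], geometry=self.geometry, frame_index=i)

    def __iter__(self) -> Iterator[BScanImage]:
        for i in range(self.count):
            yield self.frame(i)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_stack(path, geometry: VoxelGeometry | None = None) -> OCTVolume:
    """Read a B-scan stack from a multi-page TIFF or a raw binary + sidecar.

    Frame order follows page/file order. Intensities are returned untouched;
    normalization is a separate, explicit step.

    Raises
    ------
    FileNotFoundError
        If the stack (or, for raw input, its JSON sidecar) is missing.
    StackFormatError
        If pages disagree in shape; the message names the offending page.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")

    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            pages = [p.asarray() for p in tf.pages]
        if not pages:
            raise StackFormatError(f"{path} contains no pages")
        shape0 = pages[0].shape
        for i, p in enumerate(pages):
            if p.ndim != 2:
                raise StackFormatError(f"{path}: page {i} is not 2D")
            if p.shape != shape0:
                raise StackFormatError(
                    f"{path}: page {i} has shape {p.shape}, expected {shape0}"
                )
        data = np.stack(pages, axis=0)
        return OCTVolume(data, geometry=geometry or VoxelGeometry())

    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"raw stack {path} requires JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    rows, cols, frames = int(meta["rows"]), int(meta["cols"]), int(meta["frames"])
    dtype = np.dtype(meta.get("dtype", "uint8"))
    raw = np.fromfile(path, dtype=dtype)
    expected = rows * cols * frames
    if raw.size != expected:
        raise StackFormatError(
            f"{path}: payload holds {raw.size} samples, sidecar declares {expected}"
        )
    if geometry is None:
        geometry = VoxelGeometry.from_dict(meta)
    return OCTVolume(raw.reshape(frames, rows, cols), geometry=geometry)


def write_stack(volume: OCTVolume, path) -> None:
    """Write a stack so that :func:`read_stack` reproduces it bit-exactly.

    TIFF output (``.tif``/``.tiff``) stores one 8-bit page per frame; any
    other suffix writes raw binary plus a JSON geometry sidecar.
    """
    if volume.count == 0:
        raise ValueError("refusing to write an empty volume")
    path = Path(path)
    data = volume.data
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data.astype(np.uint8), photometric="minisblack")
        return
    data.tofile(path)
    meta = {
        "rows": int(data.shape[1]),
        "cols": int(data.shape[2]),
        "frames": int(data.shape[0]),
        "dtype": str(data.dtype),
        **volume.geometry.to_dict(),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def normalize_to_8bit(
    frame, geometry: VoxelGeometry | None = None, frame_index: int = 0
) -> BScanImage:
    """Affinely map a raw intensity grid onto the 0-255 scale.

    [input min, input max] maps onto [0, 255], rounded half-up; the output
    therefore attains both 0 and 255. A constant input has no contrast to
    stretch: it maps to all zeros and a warning is logged.
    """
    arr = np.asarray(frame, dtype=np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        log.warning("normalize_to_8bit: constant input (%g), degenerate contrast", lo)
        out = np.zeros_like(arr, dtype=np.uint8)
    else:
        out = round_half_up((arr - lo) * (255.0 / (hi - lo))).astype(np.uint8)
    return BScanImage(out, geometry=geometry or VoxelGeometry(), frame_index=frame_index)


def compensate_power(frame: BScanImage, factor: float) -> BScanImage:
    """Rescale a frame for source-power drift, bounded at +/-5%.

    The OCT source power fluctuates by up to +/-5%, so every pixel is
    multiplied by ``factor`` (within [0.95, 1.05]), clipped to [0, 255] and
    rounded half-up. The factor is recorded in the processing log.
    """
    if not (0.95 <= factor <= 1.05):
        raise ValueError(
            f"power compensation factor {factor} outside the +/-5% bound [0.95, 1.05]"
        )
    scaled = np.clip(round_half_up(frame.pixels.astype(np.float64) * factor), 0, 255)
    log.info("compensate_power: frame %d scaled by %g", frame.frame_index, factor)
    return BScanImage(
        scaled.astype(np.uint8), geometry=frame.geometry, frame_index=frame.frame_index
    )
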