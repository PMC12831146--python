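"""Raster data model and file I/O for en-face OCT/OCTA slabs.

All images in this package are square or rectangular 2-D scalar rasters with
an isotropic physical pixel pitch.  Pixel (row, col) has its *center* at
physical position ``x = (col + 0.5) * pitch``, ``y = (row + 0.5) * pitch``
measured in mm from the top-left corner of the frame; x grows rightwards and
y grows downwards (image convention).  Scans are assumed centered on the
fovea, so the default foveal position is the frame center.

Images are held as float64 in [0, 1].  Files are written as 8/16-bit
grayscale TIFF or 8-bit PNG; loading divides by the dtype maximum, which is
a bijection on representable values, so write→read round-trips are lossless.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "Modality",
    "MaskLabel",
    "EnFaceImage",
    "RegionMask",
    "ScanGeometry",
    "FormatError",
    "GeometryError",
    "magnification_factor",
    "load_enface",
    "save_enface",
    "load_mask",
    "save_mask",
]


class FormatError(ValueError):
    """Raised for unsupported or malformed image files."""


class GeometryError(ValueError):
    """Raised when raster geometries that must match do not."""


class Modality(str, enum.Enum):
    """What an en-face slab depicts."""

    FLOW = "flow"
    STRUCTURE = "structure"
    SUPERFICIAL = "superficial"


class MaskLabel(str, enum.Enum):
    """Semantic role of a binary region mask."""

    PSV_ROI = "psv_roi"
    RING = "ring"
    VESSEL_EXCLUSION = "vessel_exclusion"
    TRUTH_DEFICIT = "truth_deficit"
    DEFICIT_BINARY = "deficit_binary"


def magnification_factor(axl_mm: float) -> float:
    """Bennett–Littmann ocular magnification factor.

    ``F = 3.48 * 0.01306 * (AXL - 1.82)`` converts nominal (image-plane)
    measurements into true ocular dimensions: linear measures scale by F and
    areas by F².  AXL is the axial length of the eye in mm; 1.82 mm is the
    model's anterior nodal-point offset, so the factor is only defined for
    AXL > 1.82 mm (any real eye).

    Parameters
    ----------
    axl_mm
        Axial length in mm; must exceed 1.82.

    Returns
    -------
    float
        Dimensionless magnification factor, ≈ 1.07 at AXL = 25.28 mm.
    """
    if not axl_mm > 1.82:
        raise ValueError(
            f"axial length must exceed 1.82 mm for a positive magnification "
            f"factor; got {axl_mm!r}"
        )
    return 3.48 * 0.01306 * (axl_mm - 1.82)


@dataclass(frozen=True)
class ScanGeometry:
    """Physical geometry of one en-face scan.

    Attributes
    ----------
    scan_mm
        Physical scan width (and height) in mm; 6 mm by default.
    raster_px
        Raster size in pixels per side.
    axl_mm
        Axial length of the scanned eye in mm, or None when magnification
        correction is not applied (F is then 1).
    """

    scan_mm: float = 6.0
    raster_px: int = 1024
    axl_mm: float | None = None

    def __post_init__(self) -> None:
        if self.scan_mm <= 0:
            raise ValueError("scan_mm must be positive")
        if self.raster_px < 1:
            raise ValueError("raster_px must be a positive integer")
        if self.axl_mm is not None and not self.axl_mm > 1.82:
            raise ValueError("axl_mm must exceed 1.82 mm")

    @property
    def pitch_um(self) -> float:
        """Isotropic pixel pitch in µm (1000·scan_mm / raster_px)."""
        return 1000.0 * self.scan_mm / self.raster_px

    @property
    def pitch_mm(self) -> float:
        return self.scan_mm / self.raster_px

    @property
    def F(self) -> float:
        """Bennett–Littmann magnification factor (1.0 when AXL is unset)."""
        if self.axl_mm is None:
            return 1.0
        return magnification_factor(self.axl_mm)

    @property
    def center_mm(self) -> tuple[float, float]:
        """Frame-center (x, y) in mm — the default foveal position."""
        return (self.scan_mm / 2.0, self.scan_mm / 2.0)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "scan_mm": self.scan_mm,
                    "raster_px": self.raster_px,
                    "axl_mm": self.axl_mm,
                    "F": self.F,
                    "pitch_um": self.pitch_um,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanGeometry":
        d = json.loads(Path(path).read_text())
        return cls(
            scan_mm=d["scan_mm"], raster_px=d["raster_px"], axl_mm=d.get("axl_mm")
        )


@dataclass
class EnFaceImage:
    """One en-face slab: a 2-D scalar raster plus physical metadata.

    ``pixels`` is float64 in [0, 1] (values loaded from integer files are
    divided by the dtype maximum).  ``pitch_um`` is the physical size of one
    pixel; the raster is assumed isotropic.
    """

    pixels: np.ndarray
    pitch_um: float
    modality: Modality

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.modality = Modality(self.modality)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected a 2-D raster, got shape {self.pixels.shape}")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixel values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def quantize(self, bits: int = 16) -> "EnFaceImage":
        """Snap pixel values to the n-bit integer grid (as written to file)."""
        if bits not in (8, 16):
            raise ValueError("bits must be 8 or 16")
        m = (1 << bits) - 1
        q = np.round(np.clip(self.pixels, 0.0, 1.0) * m) / m
        return replace(self, pixels=q)

    def same_geometry(self, other: "EnFaceImage | RegionMask") -> bool:
        return self.shape == other.shape and math.isclose(
            self.pitch_um, other.pitch_um, rel_tol=1e-9
        )


@dataclass
class RegionMask:
    """Binary region raster sharing geometry with a companion image."""

    pixels: np.ndarray
    pitch_um: float
    label: MaskLabel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        self.label = MaskLabel(self.label)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected a 2-D mask, got shape {self.pixels.shape}")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")
        if self.label is MaskLabel.PSV_ROI:
            self._check_roi()

    def _check_roi(self) -> None:
        # PSV ROIs must be nonempty and 4-connected (one traced structure).
        from scipy import ndimage

        if not self.pixels.any():
            raise ValueError("a psv_roi mask must be nonempty")
        _, n = ndimage.label(self.pixels, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        if n != 1:
            raise ValueError(f"a psv_roi mask must be 4-connected; found {n} parts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


def _read_gray(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
    else:
        raise FormatError(f"unsupported image format: {path.name}")
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(
            f"{path.name}: expected single-channel grayscale, got shape {arr.shape}"
        )
    if arr.dtype not in (np.uint8, np.uint16):
        raise FormatError(f"{path.name}: expected 8/16-bit data, got {arr.dtype}")
    return arr


def load_enface(
    path: str | Path, pitch_um: float, modality: Modality | str
) -> EnFaceImage:
    """Read a single-channel 8/16-bit grayscale TIFF or PNG as an en-face slab.

    Integer values are mapped to [0, 1] by dividing by the dtype maximum,
    which is exactly inverted by :func:`save_enface` — round-trips are
    lossless.
    """
    raw = _read_gray(path)
    scale = float(np.iinfo(raw.dtype).max)
    return EnFaceImage(raw.astype(np.float64) / scale, pitch_um, Modality(modality))


def save_enface(img: EnFaceImage, path: str | Path, bits: int = 16) -> None:
    """Write an en-face slab as n-bit grayscale TIFF (or 8-bit PNG)."""
    path = Path(path)
    if bits == 16:
        dtype, m = np.uint16, 65535
    elif bits == 8:
        dtype, m = np.uint8, 255
    else:
        raise ValueError("bits must be 8 or 16")
    raw = np.round(np.clip(img.pixels, 0.0, 1.0) * m).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, raw)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, raw)
    else:
        raise FormatError(f"unsupported output format: {path.name}")


def load_mask(
    path: str | Path, companion: EnFaceImage, label: MaskLabel | str
) -> RegionMask:
    """Read a binary mask raster and bind it to a companion image's geometry.

    Any nonzero pixel is foreground.  The raster must match the companion's
    dimensions exactly; a mismatch raises :class:`GeometryError`.
    """
    raw = _read_gray(path)
    if raw.shape != companion.shape:
        raise GeometryError(
            f"mask shape {raw.shape} does not match image shape {companion.shape}"
        )
    return RegionMask(raw > 0, companion.pitch_um, MaskLabel(label))


def save_mask(mask: RegionMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit image (0 / 255)."""
    path = Path(path)
    raw = np.where(mask.pixels, 255, 0).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, raw)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, raw)
    else:
        raise FormatError(f"unsupported output format: {path.name}")
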