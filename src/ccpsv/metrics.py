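"""Per-vessel metrics at perforating scleral vessel (PSV) entry sites.

A PSV's choroidal entry appears on the en-face slab as a small traced ROI.
This module computes the site's quantities: the magnification-corrected ROI
area, the flow-deficit percentage inside the ROI (FDPSV) and inside a
250-µm-wide concentric ring around it (FD250), and the vessel-to-fovea
distance (VFD) with its horizontal/vertical decomposition.

Magnification correction follows the Bennett–Littmann convention: all
quantities are first computed in nominal image units, then linear measures
are scaled by F and areas by F² post hoc.  Flow-deficit percentages are
ratios of pixel counts and are magnification-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import (
    MaskLabel,
    RegionMask,
    ScanGeometry,
    magnification_factor,
)
from .quantify import FDResult, fd_percent

__all__ = [
    "magnification_factor",
    "psv_area",
    "ring_mask",
    "fd_psv_metrics",
    "vfd",
    "VFDResult",
    "ct_axl_index",
]


def psv_area(roi: RegionMask, geom: ScanGeometry) -> float:
    """Magnification-corrected ROI area in mm².

    ``area = n_pixels · (pitch_mm)² · F²`` — the pixel count of the traced
    region converted to physical units, with the Bennett–Littmann area
    correction applied post hoc.
    """
    n = roi.area_px
    if n == 0:
        raise ValueError("cannot compute the area of an empty ROI")
    return n * geom.pitch_mm**2 * geom.F**2


def ring_mask(
    roi: RegionMask, geom: ScanGeometry, width_um: float = 250.0
) -> RegionMask:
    """Concentric ring of physical width ``width_um`` around an ROI.

    The ring is the set of pixels with Euclidean distance to the ROI in
    (0, width_um]; the distance is taken with the physical pixel pitch as
    sampling, so the ring width is isotropic in µm regardless of raster
    size.  The ROI itself is excluded.  Rings are clipped at the frame
    border; when clipping occurs the result carries
    ``meta["border_clipped"] = True``.
    """
    if roi.area_px == 0:
        raise ValueError("cannot build a ring around an empty ROI")
    if width_um <= 0:
        raise ValueError("ring width must be positive")
    pitch = roi.pitch_um
    dist = ndimage.distance_transform_edt(~roi.pixels, sampling=pitch)
    ring = (dist > 0) & (dist <= width_um)
    # Detect border clipping: would the ring extend past the frame?
    h, w = roi.shape
    rows, cols = np.nonzero(roi.pixels)
    margin_px = width_um / pitch
    clipped = (
        rows.min() < margin_px
        or cols.min() < margin_px
        or rows.max() >= h - margin_px
        or cols.max() >= w - margin_px
    )
    return RegionMask(
        ring, pitch, MaskLabel.RING, meta={"border_clipped": bool(clipped)}
    )


def fd_psv_metrics(
    deficit: RegionMask,
    exclusion: RegionMask | None,
    roi: RegionMask,
    geom: ScanGeometry,
    ring_width_um: float = 250.0,
) -> tuple[float, float]:
    """FDPSV and FD250 for one PSV site.

    FDPSV is the flow-deficit percentage of the evaluable area inside the
    ROI; FD250 is the same metric over the concentric ring of width
    ``ring_width_um`` around it.  Errors from :func:`~ccpsv.quantify.fd_percent`
    (e.g. a fully excluded ROI) propagate.
    """
    fd_roi: FDResult = fd_percent(deficit, exclusion, roi)
    ring = ring_mask(roi, geom, ring_width_um)
    fd_ring: FDResult = fd_percent(deficit, exclusion, ring)
    return fd_roi.ccfd_percent, fd_ring.ccfd_percent


@dataclass(frozen=True)
class VFDResult:
    """Vessel-to-fovea distance and its coordinate decomposition (mm).

    ``x_off_mm`` grows to the right and ``y_off_mm`` downwards (image
    convention).  ``n_cells`` is the number of grid cells that intersected
    the ROI; ``single_cell`` flags the fallback where the whole ROI fit in
    one cell and the VFD degenerates to a single centroid distance.
    """

    vfd_mm: float
    x_off_mm: float
    y_off_mm: float
    n_cells: int
    single_cell: bool


def vfd(
    roi: RegionMask,
    fovea_xy: tuple[float, float],
    geom: ScanGeometry,
    unit_area_mm2: float = 0.1,
) -> VFDResult:
    """Mean Euclidean grid-cell distance from a PSV ROI to the foveal center.

    The frame is overlaid with a calibrated square grid of cells of area
    ``unit_area_mm2`` (side √area), anchored so that the foveal center sits
    on a grid node.  For each cell intersecting the ROI, the centroid
    (Xᵢ, Yᵢ) of the intersection is computed from pixel centers, and
    dᵢ = √((Xᵢ−X₀)² + (Yᵢ−Y₀)²).  The VFD is the mean of the dᵢ; the X/Y
    offsets are the means of (Xᵢ−X₀) and (Yᵢ−Y₀).  All three are scaled by
    the magnification factor F post hoc.

    With ``unit_area_mm2`` equal to one pixel's area, every cell holds
    exactly one pixel center and the VFD equals the mean per-pixel distance
    to the fovea.

    Anchoring the grid at the fovea makes the result exactly invariant
    under joint whole-pixel translations of ROI and fovea.
    """
    if roi.area_px == 0:
        raise ValueError("cannot compute VFD of an empty ROI")
    if unit_area_mm2 <= 0:
        raise ValueError("unit_area_mm2 must be positive")
    x0, y0 = fovea_xy
    h, w = roi.shape
    pitch = geom.pitch_mm
    if not (0.0 <= x0 <= w * pitch and 0.0 <= y0 <= h * pitch):
        raise ValueError("foveal center must lie inside the frame")
    side = math.sqrt(unit_area_mm2)
    rows, cols = np.nonzero(roi.pixels)
    px = (cols + 0.5) * pitch  # pixel-center x in mm
    py = (rows + 0.5) * pitch
    ci = np.floor((px - x0) / side).astype(np.int64)
    cj = np.floor((py - y0) / side).astype(np.int64)
    # Group ROI pixels by grid cell and take per-cell centroids of the
    # ROI∩cell intersection.
    _, inverse, counts = np.unique(
        np.stack([ci, cj], axis=1), axis=0, return_inverse=True, return_counts=True
    )
    n_cells = len(counts)
    cx = np.bincount(inverse, weights=px, minlength=n_cells) / counts
    cy = np.bincount(inverse, weights=py, minlength=n_cells) / counts
    d = np.hypot(cx - x0, cy - y0)
    F = geom.F
    return VFDResult(
        vfd_mm=float(d.mean()) * F,
        x_off_mm=float((cx - x0).mean()) * F,
        y_off_mm=float((cy - y0).mean()) * F,
        n_cells=n_cells,
        single_cell=n_cells == 1,
    )


def ct_axl_index(ct_um: float, axl_mm: float) -> float:
    """Choroidal thickness normalized by globe size, in µm/mm."""
    if axl_mm <= 0:
        raise ValueError("axl_mm must be positive")
    return ct_um / axl_mm
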