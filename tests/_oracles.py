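"""Independent brute-force oracles used by the test suite.

These deliberately recompute quantities by explicit looping / direct set
definitions, sharing no code with the package implementation paths they
check.
"""

from __future__ import annotations

import math

import numpy as np


def phansalkar_oracle(
    x: np.ndarray,
    radius_px: int,
    k: float = 0.25,
    r: float = 0.5,
    p: float = 2.0,
    q: float = 10.0,
) -> np.ndarray:
    """Per-pixel loop re-implementation of the Phansalkar deficit mask.

    Circular window, population standard deviation, symmetric border
    padding (edge sample repeated, as in scipy.ndimage 'reflect').
    """
    h, w = x.shape
    pad = np.pad(x, radius_px, mode="symmetric")
    offsets = [
        (dy, dx)
        for dy in range(-radius_px, radius_px + 1)
        for dx in range(-radius_px, radius_px + 1)
        if dy * dy + dx * dx <= radius_px * radius_px
    ]
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            vals = [pad[i + radius_px + dy, j + radius_px + dx] for dy, dx in offsets]
            m = sum(vals) / len(vals)
            var = sum((v - m) ** 2 for v in vals) / len(vals)
            s = math.sqrt(var)
            t = m * (1.0 + p * math.exp(-q * m) + k * (s / r - 1.0))
            out[i, j] = x[i, j] <= t
    return out


def ring_oracle(roi: np.ndarray, pitch_um: float, width_um: float) -> np.ndarray:
    """Direct set definition: pixels with 0 < min Euclidean distance to the
    ROI ≤ width, distances measured between pixel centers in µm."""
    h, w = roi.shape
    rr, cc = np.nonzero(roi)
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            if roi[i, j]:
                continue
            d2 = ((rr - i) ** 2 + (cc - j) ** 2).min()
            d = math.sqrt(float(d2)) * pitch_um
            out[i, j] = 0 < d <= width_um
    return out


def vfd_pixel_oracle(
    roi: np.ndarray, fovea_xy: tuple[float, float], pitch_mm: float
) -> tuple[float, float, float]:
    """Mean per-pixel distance (and offsets) from ROI pixel centers to the
    fovea, in mm, without any grid machinery."""
    rr, cc = np.nonzero(roi)
    px = (cc + 0.5) * pitch_mm
    py = (rr + 0.5) * pitch_mm
    dx = px - fovea_xy[0]
    dy = py - fovea_xy[1]
    d = np.hypot(dx, dy)
    return float(d.mean()), float(dx.mean()), float(dy.mean())
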