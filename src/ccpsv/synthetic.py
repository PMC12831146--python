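"""Synthetic en-face scenes and cohorts with known ground truth.

Nothing in this package requires patient imaging: every downstream stage is
exercised on generated data whose truth is known by construction.

The image generator emulates the features the quantification chain cares
about:

* a quasi-regular granular choriocapillaris flow texture whose dark
  (no-flow) fraction is controlled exactly, with deficits forming
  contiguous blobs at a ~50-µm correlation length, as flow voids do on
  compensated slabs;
* one smooth multiplicative attenuation field applied to the flow and
  structural slabs alike, the artifact class that inverse-structure
  compensation removes;
* a superficial-plexus slab containing a bright large-vessel tree (with
  its ground-truth footprint) over a dim capillary background;
* disjoint elliptical PSV entry ROIs placed in an annulus around the
  fovea, avoiding the vessel tree.

The cohort generator simulates per-PSV records from a linear mixed model
with nested random intercepts (subject, eye-within-subject) and a
controllable correlation between axial length and global flow-deficit
burden, so that confounded univariable-vs-adjusted behaviour can be
produced on demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw
from skimage import morphology

from .images import EnFaceImage, MaskLabel, Modality, RegionMask, ScanGeometry

__all__ = [
    "SyntheticSceneParams",
    "SyntheticScene",
    "CohortSimParams",
    "PackingError",
    "generate_cc_scene",
    "generate_cohort",
    "DEFAULT_FIXED_EFFECTS",
]


class PackingError(RuntimeError):
    """Raised when the requested number of disjoint PSV ROIs cannot be placed."""


@dataclass(frozen=True)
class SyntheticSceneParams:
    """Controls for one synthetic scene.

    Defaults emulate a 6 × 6 mm swept-source OCTA scan centered on the
    fovea at 1024 px (5.86 µm pitch), with a global flow-deficit fraction
    of 0.18 (the scale reported for healthy myopic eyes), moderate
    attenuation and mild additive noise.
    """

    raster_px: int = 1024
    scan_mm: float = 6.0
    deficit_fraction_target: float = 0.18
    attenuation_amplitude: float = 0.3
    n_psv: int = 3
    psv_radius_um_range: tuple[float, float] = (60.0, 220.0)
    noise_sd: float = 0.02
    seed: int = 0
    texture_scale_um: float = 50.0  # correlation length of the CC granularity

    def __post_init__(self) -> None:
        if not 0.0 <= self.deficit_fraction_target <= 1.0:
            raise ValueError("deficit_fraction_target must lie in [0, 1]")
        if self.raster_px < 64:
            raise ValueError("raster_px must be at least 64")
        if not 0.0 <= self.attenuation_amplitude < 1.0:
            raise ValueError("attenuation_amplitude must lie in [0, 1)")
        lo, hi = self.psv_radius_um_range
        if not (0 < lo <= hi):
            raise ValueError("psv radii must be strictly positive and ordered")
        if hi >= self.scan_mm * 500.0:
            raise ValueError("psv radius must be smaller than half the scan width")
        if self.n_psv < 0:
            raise ValueError("n_psv must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticScene:
    """One generated scene, including ground truth not available on real data."""

    flow: EnFaceImage
    structure: EnFaceImage
    truth_deficit: RegionMask
    psv_rois: list[RegionMask]
    superficial: EnFaceImage
    fovea_xy: tuple[float, float]
    # Ground truth / provenance beyond the measurable surface:
    vessel_mask: RegionMask
    attenuation: np.ndarray
    flow_clean: EnFaceImage
    structure_clean: EnFaceImage
    geometry: ScanGeometry
    params: SyntheticSceneParams


def _smooth_noise(rng: np.random.Generator, n: int, sigma_px: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian-smoothed white noise."""
    z = rng.standard_normal((n, n))
    s = ndimage.gaussian_filter(z, sigma_px, mode="wrap")
    return (s - s.mean()) / s.std()


def _attenuation_field(
    rng: np.random.Generator, n: int, amplitude: float
) -> np.ndarray:
    """Smooth multiplicative attenuation in [1-amplitude, 1] (max is 1)."""
    if amplitude == 0.0:
        return np.ones((n, n))
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    g = np.zeros((n, n))
    for _ in range(rng.integers(2, 4)):
        cy, cx = rng.uniform(0.1 * n, 0.9 * n, size=2)
        sy, sx = rng.uniform(0.2 * n, 0.45 * n, size=2)
        g += np.exp(-(((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))
    g = (g - g.min()) / (g.max() - g.min())  # in [0, 1], max attenuation = amplitude
    return 1.0 - amplitude * g


def _vessel_tree(
    rng: np.random.Generator, n: int, pitch_um: float
) -> np.ndarray:
    """Bright large-vessel footprint: curved walks from the frame edges."""
    canvas = np.zeros((n, n), dtype=bool)
    n_main = 4
    for _ in range(n_main):
        edge = rng.integers(0, 4)
        t = rng.uniform(0.15, 0.85) * n
        if edge == 0:
            r, c, ang = 0.0, t, math.pi / 2
        elif edge == 1:
            r, c, ang = float(n - 1), t, -math.pi / 2
        elif edge == 2:
            r, c, ang = t, 0.0, 0.0
        else:
            r, c, ang = t, float(n - 1), math.pi
        ang += rng.uniform(-0.5, 0.5)
        width_um = rng.uniform(60.0, 110.0)
        radius_px = max(1, int(round(width_um / 2.0 / pitch_um)))
        path = np.zeros((n, n), dtype=bool)
        steps = int(1.1 * n)
        for _ in range(steps):
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < n and 0 <= ci < n):
                break
            path[ri, ci] = True
            ang += rng.normal(0.0, 0.06)
            r += math.sin(ang)
            c += math.cos(ang)
        canvas |= morphology.dilation(path, morphology.disk(radius_px))
    return canvas


def _place_psv_rois(
    rng: np.random.Generator,
    params: SyntheticSceneParams,
    geom: ScanGeometry,
    forbidden: np.ndarray,
    fovea_xy: tuple[float, float],
    max_tries_per_roi: int = 200,
) -> list[RegionMask]:
    """Disjoint elliptical ROIs in an annulus around the fovea.

    ROIs avoid each other, the ``forbidden`` footprint (the large-vessel
    tree — sites under large vessels are excluded from analysis), and the
    frame border.  Bounded retries; an infeasible packing raises
    :class:`PackingError`.
    """
    n = params.raster_px
    pitch_um = geom.pitch_um
    lo_um, hi_um = params.psv_radius_um_range
    occupied = forbidden.copy()
    rois: list[RegionMask] = []
    r_min_mm = min(0.8, 0.3 * params.scan_mm)
    r_max_mm = min(2.4, 0.45 * params.scan_mm)
    for _ in range(params.n_psv):
        for attempt in range(max_tries_per_roi):
            a_um = rng.uniform(lo_um, hi_um)       # semi-major axis
            b_um = a_um * rng.uniform(0.6, 1.0)    # semi-minor axis
            theta = rng.uniform(0.0, math.pi)
            rad_mm = rng.uniform(r_min_mm, r_max_mm)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            cx_mm = fovea_xy[0] + rad_mm * math.cos(phi)
            cy_mm = fovea_xy[1] + rad_mm * math.sin(phi)
            cr = cy_mm * 1000.0 / pitch_um
            cc = cx_mm * 1000.0 / pitch_um
            margin = a_um / pitch_um + 2
            if not (margin <= cr < n - margin and margin <= cc < n - margin):
                continue
            rr, cols = skdraw.ellipse(
                cr, cc, b_um / pitch_um, a_um / pitch_um, shape=(n, n),
                rotation=theta,
            )
            if rr.size == 0:
                continue
            cand = np.zeros((n, n), dtype=bool)
            cand[rr, cols] = True
            if (cand & occupied).any():
                continue
            occupied |= morphology.dilation(cand, morphology.disk(2))
            rois.append(RegionMask(cand, pitch_um, MaskLabel.PSV_ROI))
            break
        else:
            raise PackingError(
                f"could not place {params.n_psv} disjoint PSV ROIs "
                f"(placed {len(rois)}) after {max_tries_per_roi} tries each"
            )
    return rois


def generate_cc_scene(params: SyntheticSceneParams) -> SyntheticScene:
    """Generate one synthetic flow/structure/superficial scene.

    The flow slab is near-bimodal: bright where the choriocapillaris
    perfuses, dark on the ground-truth deficit blobs, with mild within-class
    texture.  The deficit mask is cut from band-pass-filtered noise at the
    exact quantile of ``deficit_fraction_target``, so the realized dark-area
    fraction matches the target up to quantization ties.  Flow and
    structure share one multiplicative attenuation field; their ratio is
    therefore attenuation-free.  Generation is fully reproducible from
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.raster_px
    geom = ScanGeometry(scan_mm=params.scan_mm, raster_px=n)
    pitch_um = geom.pitch_um
    sigma_px = max(1.0, params.texture_scale_um / pitch_um)

    # Granular CC texture: band-pass (smooth minus broader smooth) noise.
    fine = _smooth_noise(rng, n, sigma_px)
    coarse = _smooth_noise(rng, n, 4.0 * sigma_px)
    texture = fine - 0.5 * coarse
    texture = (texture - texture.mean()) / texture.std()

    f = params.deficit_fraction_target
    if f <= 0.0:
        deficit = np.zeros((n, n), dtype=bool)
    elif f >= 1.0:
        deficit = np.ones((n, n), dtype=bool)
    else:
        deficit = texture <= np.quantile(texture, f)

    # Clean flow: dark deficits, bright perfused CC, with soft (sub-pixel-
    # smoothed) void edges as on real compensated slabs, plus mild internal
    # modulation so no two pixels are exactly tied.  The soft edge band is
    # what makes an uncompensated attenuated slab binarize differently.
    alpha = ndimage.gaussian_filter(deficit.astype(np.float64), 0.8)
    wiggle = 0.04 * _smooth_noise(rng, n, 2.0 * sigma_px)
    flow_clean = 0.85 + (0.12 - 0.85) * alpha + wiggle
    flow_clean = np.clip(flow_clean, 0.02, 0.98)

    # Structural slab: bright, slowly varying reflectivity.
    struct_clean = 0.72 + 0.08 * _smooth_noise(rng, n, 8.0 * sigma_px)
    struct_clean = np.clip(struct_clean, 0.5, 0.95)

    atten = _attenuation_field(rng, n, params.attenuation_amplitude)
    flow_px = flow_clean * atten
    struct_px = struct_clean * atten
    if params.noise_sd > 0:
        flow_px = flow_px + rng.normal(0.0, params.noise_sd, (n, n))
        struct_px = struct_px + rng.normal(0.0, params.noise_sd, (n, n))
    flow_px = np.clip(flow_px, 0.0, 1.0)
    struct_px = np.clip(struct_px, 0.0, 1.0)

    # Superficial plexus: large-vessel tree over dim capillary background.
    vessels = _vessel_tree(rng, n, pitch_um)
    background = 0.15 + 0.04 * _smooth_noise(rng, n, 1.5)
    sup = np.where(vessels, 0.88, background)
    sup = np.clip(ndimage.gaussian_filter(sup, 0.8), 0.0, 1.0)

    fovea_xy = geom.center_mm
    vessel_margin = morphology.dilation(
        vessels, morphology.disk(max(1, int(round(60.0 / pitch_um))))
    )
    rois = _place_psv_rois(rng, params, geom, vessel_margin, fovea_xy)

    return SyntheticScene(
        flow=EnFaceImage(flow_px, pitch_um, Modality.FLOW),
        structure=EnFaceImage(struct_px, pitch_um, Modality.STRUCTURE),
        truth_deficit=RegionMask(deficit, pitch_um, MaskLabel.TRUTH_DEFICIT),
        psv_rois=rois,
        superficial=EnFaceImage(sup, pitch_um, Modality.SUPERFICIAL),
        fovea_xy=fovea_xy,
        vessel_mask=RegionMask(vessels, pitch_um, MaskLabel.VESSEL_EXCLUSION),
        attenuation=atten,
        flow_clean=EnFaceImage(np.clip(flow_clean, 0, 1), pitch_um, Modality.FLOW),
        structure_clean=EnFaceImage(struct_clean, pitch_um, Modality.STRUCTURE),
        geometry=geom,
        params=params,
    )


# Fixed-effect scale of the simulated cohort: coefficients on the order
# reported for adjusted PSV-site flow-deficit models (response in %).
DEFAULT_FIXED_EFFECTS: dict[str, float] = {
    "intercept": 48.5,
    "age_y": 0.23,
    "axl_mm": -2.37,
    "se_d": -0.43,
    "ct_um": 0.013,
    "global_ccfd_pct": 1.02,
    "area_mm2": 16.5,
    "vfd_mm": -1.15,
}


@dataclass(frozen=True)
class CohortSimParams:
    """Controls for the simulated per-PSV cohort.

    Defaults reflect the published healthy-myopia cohort scale: 31 subjects
    contributing one or both eyes (~52 eyes), 1–10 PSVs per eye (mean
    ≈ 2.3), covariates centered at the cohort means (age 28.3 ± 7.0 y,
    AXL 25.28 ± 1.09 mm, SE −4.0 ± 1.7 D, CT 187 ± 60 µm, global CCFD
    17.9 ± 10.6 %), and an AXL–CCFD correlation of 0.47.  The response is
    a linear predictor plus nested random intercepts (subject, eye within
    subject) plus residual noise.
    """

    n_subjects: int = 31
    p_both_eyes: float = 0.68
    psv_per_eye_mean: float = 2.3
    fixed_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS)
    )
    sd_subject: float = 5.0
    sd_eye: float = 3.0
    sd_resid: float = 7.0
    confound_axl_ccfd: float = 0.47
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0.0 <= self.p_both_eyes <= 1.0:
            raise ValueError("p_both_eyes must lie in [0, 1]")
        if self.psv_per_eye_mean <= 0:
            raise ValueError("psv_per_eye_mean must be positive")
        for name in ("sd_subject", "sd_eye", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not abs(self.confound_axl_ccfd) < 1.0:
            raise ValueError(
                "|confound_axl_ccfd| must be < 1 for a valid joint distribution"
            )


def generate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Simulate a per-PSV cohort table from a nested mixed-effects model.

    Each row is one PSV with subject/eye identifiers, covariates, and the
    simulated response ``fd_psv`` (plus an analogously simulated
    ``fd_250``).  The global-CCFD column is correlated with axial length at
    ``confound_axl_ccfd`` via a Gaussian copula on the standardized scales,
    which is what makes marginal (univariable) and adjusted AXL effects
    diverge when their true coefficients have opposite signs.

    Nesting is well-formed by construction: eye identifiers embed the
    subject identifier, so no eye can belong to two subjects.
    """
    rng = np.random.default_rng(params.seed)
    beta = {k: 0.0 for k in DEFAULT_FIXED_EFFECTS}
    beta.update(params.fixed_effects)
    unknown = set(params.fixed_effects) - set(DEFAULT_FIXED_EFFECTS)
    if unknown:
        raise ValueError(f"unknown fixed-effect names: {sorted(unknown)}")

    rho = params.confound_axl_ccfd
    rows: list[dict] = []
    for s in range(params.n_subjects):
        subject_id = f"S{s:04d}"
        age = rng.normal(28.3, 6.99)
        b_subject = rng.normal(0.0, params.sd_subject)
        axl_subject = rng.normal(0.0, 0.9)  # fellow-eye AXL correlation
        n_eyes = 2 if rng.random() < params.p_both_eyes else 1
        for e, laterality in zip(range(n_eyes), ("OD", "OS")):
            eye_id = f"{subject_id}_{laterality}"
            b_eye = rng.normal(0.0, params.sd_eye)
            z_eye = rng.normal(0.0, 1.0)
            axl = 25.28 + axl_subject + 0.62 * z_eye
            z_axl = (axl - 25.28) / math.sqrt(0.9**2 + 0.62**2)
            ccfd = 17.86 + 10.58 * (
                rho * z_axl + math.sqrt(1.0 - rho * rho) * rng.normal()
            )
            ccfd = max(ccfd, 0.5)
            se = -4.03 - 1.2 * (axl - 25.28) + rng.normal(0.0, 1.0)
            ct = max(rng.normal(187.0 - 25.0 * (axl - 25.28), 50.0), 40.0)
            n_psv = 1 + rng.poisson(max(params.psv_per_eye_mean - 1.0, 0.0))
            for k in range(n_psv):
                area = float(rng.lognormal(math.log(0.03), 0.9))
                vfd_mm = float(np.clip(rng.normal(1.50, 0.69), 0.2, 3.0))
                phi = rng.uniform(0.0, 2.0 * math.pi)
                lp = (
                    beta["intercept"]
                    + beta["age_y"] * age
                    + beta["axl_mm"] * axl
                    + beta["se_d"] * se
                    + beta["ct_um"] * ct
                    + beta["global_ccfd_pct"] * ccfd
                    + beta["area_mm2"] * area
                    + beta["vfd_mm"] * vfd_mm
                )
                rows.append(
                    {
                        "subject_id": subject_id,
                        "eye_id": eye_id,
                        "psv_id": f"{eye_id}_P{k:02d}",
                        "fd_psv": lp + b_subject + b_eye
                        + rng.normal(0.0, params.sd_resid),
                        "fd_250": lp + b_subject + b_eye
                        + rng.normal(0.0, params.sd_resid),
                        "area_mm2": area,
                        "vfd_mm": vfd_mm,
                        "x_off_mm": vfd_mm * math.cos(phi),
                        "y_off_mm": vfd_mm * math.sin(phi),
                        "age_y": age,
                        "axl_mm": axl,
                        "se_d": se,
                        "ct_um": ct,
                        "global_ccfd_pct": ccfd,
                        "ct_axl": ct / axl,
                    }
                )
    return pd.DataFrame(rows)
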