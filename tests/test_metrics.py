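"""PSV-site metrics: magnification, area, ring, FDPSV/FD250, VFD."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from _oracles import ring_oracle, vfd_pixel_oracle
from ccpsv import (
    MaskLabel,
    RegionMask,
    ScanGeometry,
    UndefinedMetricError,
    fd_psv_metrics,
    magnification_factor,
    psv_area,
    ring_mask,
    vfd,
)

GEOM = ScanGeometry(scan_mm=6.0, raster_px=1024)  # pitch 5.859375 µm


def _roi(px, pitch=GEOM.pitch_um):
    return RegionMask(px, pitch, MaskLabel.PSV_ROI)


def _deficit(px, pitch=GEOM.pitch_um):
    return RegionMask(px, pitch, MaskLabel.DEFICIT_BINARY)


# ---- magnification ----


def test_magnification_factor_at_cohort_mean_axl():
    assert magnification_factor(25.28) == pytest.approx(
        3.48 * 0.01306 * (25.28 - 1.82)
    )
    assert magnification_factor(25.28) == pytest.approx(1.06623, abs=1e-4)


def test_magnification_factor_domain_and_monotonicity():
    with pytest.raises(ValueError):
        magnification_factor(1.82)
    with pytest.raises(ValueError):
        magnification_factor(0.5)
    assert magnification_factor(26.0) > magnification_factor(24.0)


# ---- area ----


def test_psv_area_pixel_arithmetic():
    px = np.zeros((64, 64), dtype=bool)
    px[10:20, 10:20] = True  # 100 px
    area = psv_area(_roi(px), GEOM)
    assert area == pytest.approx(100 * (6.0 / 1024) ** 2)
    assert area == pytest.approx(0.003434, abs=2e-5)


def test_psv_area_scales_with_f_squared():
    px = np.zeros((64, 64), dtype=bool)
    px[5:9, 5:9] = True
    a1 = psv_area(_roi(px), GEOM)
    g = ScanGeometry(scan_mm=6.0, raster_px=1024, axl_mm=25.28)
    assert psv_area(_roi(px), g) == pytest.approx(a1 * g.F**2)


def test_full_frame_roi_area_is_scan_area():
    g = ScanGeometry(scan_mm=3.0, raster_px=128)
    px = np.ones((128, 128), dtype=bool)
    assert psv_area(RegionMask(px, g.pitch_um, MaskLabel.RING), g) == pytest.approx(9.0)


# ---- ring ----


def test_single_pixel_ring_of_one_pitch_is_the_4_neighbour_shell():
    g = ScanGeometry(scan_mm=1.0, raster_px=32)
    px = np.zeros((32, 32), dtype=bool)
    px[16, 16] = True
    ring = ring_mask(_roi(px, g.pitch_um), g, width_um=g.pitch_um)
    expected = np.zeros_like(px)
    expected[15, 16] = expected[17, 16] = expected[16, 15] = expected[16, 17] = True
    assert np.array_equal(ring.pixels, expected)


def test_ring_matches_brute_force_distance_definition():
    rng = np.random.default_rng(21)
    for n, width in ((64, 90.0), (128, 250.0)):
        g = ScanGeometry(scan_mm=n * 11.7 / 1000.0, raster_px=n)
        px = np.zeros((n, n), dtype=bool)
        rr, cc = draw_disk((n // 2 + 3, n // 2 - 2), 4 + rng.integers(0, 3))
        px[rr, cc] = True
        ring = ring_mask(_roi(px, g.pitch_um), g, width_um=width)
        want = ring_oracle(px, g.pitch_um, width)
        assert np.array_equal(ring.pixels, want)
        assert not (ring.pixels & px).any()


def test_ring_area_approximates_annulus():
    # circular ROI r=100 µm, ring width 250 µm → area ≈ π(350² − 100²) µm²
    r_px = 100.0 / GEOM.pitch_um
    px = np.zeros((1024, 1024), dtype=bool)
    rr, cc = draw_disk((512, 512), r_px)
    px[rr, cc] = True
    ring = ring_mask(_roi(px), GEOM, width_um=250.0)
    got_um2 = ring.area_px * GEOM.pitch_um**2
    want_um2 = np.pi * (350.0**2 - 100.0**2)
    assert abs(got_um2 - want_um2) / want_um2 < 0.05
    assert ring.meta["border_clipped"] is False


def test_border_touching_ring_is_clipped_and_flagged():
    px = np.zeros((64, 64), dtype=bool)
    px[0:4, 0:4] = True
    g = ScanGeometry(scan_mm=0.375, raster_px=64)
    ring = ring_mask(RegionMask(px, g.pitch_um, MaskLabel.PSV_ROI), g, width_um=100.0)
    assert ring.meta["border_clipped"] is True
    assert ring.area_px > 0


# ---- FDPSV / FD250 ----


def test_deficit_confined_to_roi():
    px = np.zeros((256, 256), dtype=bool)
    rr, cc = draw_disk((128, 128), 10)
    px[rr, cc] = True
    fd_psv, fd_250 = fd_psv_metrics(_deficit(px), None, _roi(px), GEOM)
    assert fd_psv == 100.0
    assert fd_250 == 0.0


def test_uniform_random_deficit_gives_fraction_in_roi_and_ring():
    rng = np.random.default_rng(17)
    f = 0.3
    deficit = rng.random((512, 512)) < f
    px = np.zeros((512, 512), dtype=bool)
    rr, cc = draw_disk((256, 256), 40)
    px[rr, cc] = True
    fd_psv, fd_250 = fd_psv_metrics(_deficit(deficit), None, _roi(px), GEOM)
    # binomial tolerance: 4·sd on ~5000 (roi) and ~47000 (ring) pixels
    assert abs(fd_psv - 100 * f) < 400 * np.sqrt(f * (1 - f) / px.sum())
    assert abs(fd_250 - 100 * f) < 3.0


def test_fully_excluded_roi_is_an_error():
    px = np.zeros((64, 64), dtype=bool)
    px[30:34, 30:34] = True
    exclusion = RegionMask(
        np.ones((64, 64), dtype=bool), GEOM.pitch_um, MaskLabel.VESSEL_EXCLUSION
    )
    with pytest.raises(UndefinedMetricError):
        fd_psv_metrics(_deficit(np.zeros((64, 64), bool)), exclusion, _roi(px), GEOM)


# ---- VFD ----


def test_three_four_five_triangle():
    g = ScanGeometry(scan_mm=10.0, raster_px=200)  # pitch 0.05 mm
    px = np.zeros((200, 200), dtype=bool)
    px[100, 100] = True  # center at (5.025, 5.025) mm
    res = vfd(_roi(px, g.pitch_um), (2.025, 1.025), g)
    assert res.vfd_mm == pytest.approx(5.0, abs=1e-12)
    assert res.x_off_mm == pytest.approx(3.0, abs=1e-12)
    assert res.y_off_mm == pytest.approx(4.0, abs=1e-12)
    assert res.single_cell is True


def test_symmetric_roi_has_zero_offsets_but_positive_vfd():
    g = ScanGeometry(scan_mm=10.0, raster_px=200)
    px = np.zeros((200, 200), dtype=bool)
    px[93:107, 93:107] = True  # square centered exactly on (5, 5) mm
    res = vfd(_roi(px, g.pitch_um), (5.0, 5.0), g)
    assert abs(res.x_off_mm) < 1e-12
    assert abs(res.y_off_mm) < 1e-12
    assert res.vfd_mm > 0


def test_pixel_fine_grid_equals_per_pixel_oracle():
    rng = np.random.default_rng(31)
    g = ScanGeometry(scan_mm=6.0, raster_px=256)
    px = np.zeros((256, 256), dtype=bool)
    rr, cc = draw_disk((100, 150), 9)
    px[rr, cc] = True
    fovea = g.center_mm
    res = vfd(_roi(px, g.pitch_um), fovea, g, unit_area_mm2=g.pitch_mm**2)
    want_d, want_x, want_y = vfd_pixel_oracle(px, fovea, g.pitch_mm)
    assert res.n_cells == px.sum()
    assert res.vfd_mm == pytest.approx(want_d, abs=1e-9)
    assert res.x_off_mm == pytest.approx(want_x, abs=1e-9)
    assert res.y_off_mm == pytest.approx(want_y, abs=1e-9)


def test_vfd_translation_equivariance():
    g = ScanGeometry(scan_mm=6.0, raster_px=256)
    px = np.zeros((256, 256), dtype=bool)
    rr, cc = draw_disk((80, 90), 7)
    px[rr, cc] = True
    fovea = (2.0, 2.5)
    res = vfd(_roi(px, g.pitch_um), fovea, g, unit_area_mm2=0.1)
    shift = 23  # pixels
    shifted = np.roll(np.roll(px, shift, axis=0), shift, axis=1)
    fovea2 = (fovea[0] + shift * g.pitch_mm, fovea[1] + shift * g.pitch_mm)
    res2 = vfd(_roi(shifted, g.pitch_um), fovea2, g, unit_area_mm2=0.1)
    assert res2.vfd_mm == pytest.approx(res.vfd_mm, abs=1e-12)
    assert res2.x_off_mm == pytest.approx(res.x_off_mm, abs=1e-12)
    assert res2.y_off_mm == pytest.approx(res.y_off_mm, abs=1e-12)
    assert res2.n_cells == res.n_cells


def test_magnification_scales_vfd_linearly_and_leaves_fd_alone():
    g1 = ScanGeometry(scan_mm=6.0, raster_px=256)
    axl = 30.0
    g2 = ScanGeometry(scan_mm=6.0, raster_px=256, axl_mm=axl)
    px = np.zeros((256, 256), dtype=bool)
    rr, cc = draw_disk((100, 150), 8)
    px[rr, cc] = True
    roi = _roi(px, g1.pitch_um)
    r1 = vfd(roi, g1.center_mm, g1)
    r2 = vfd(roi, g2.center_mm, g2)
    F = g2.F
    assert r2.vfd_mm == pytest.approx(r1.vfd_mm * F)
    assert r2.x_off_mm == pytest.approx(r1.x_off_mm * F)
    assert r2.y_off_mm == pytest.approx(r1.y_off_mm * F)
    rng = np.random.default_rng(2)
    deficit = _deficit(rng.random((256, 256)) < 0.2, g1.pitch_um)
    assert fd_psv_metrics(deficit, None, roi, g1) == fd_psv_metrics(
        deficit, None, roi, g2
    )


def test_fd250_indistinguishable_from_global_ccfd_under_uniform_deficits():
    """With spatially uniform (Bernoulli) deficits the ring metric estimates
    the same proportion as global CCFD%: a two-proportion z-test at α=0.01
    should almost never reject across 50 seeded scenes."""
    from scipy.stats import norm

    g = ScanGeometry(scan_mm=6.0, raster_px=256)
    px = np.zeros((256, 256), dtype=bool)
    rr, cc = draw_disk((128, 128), 10)
    px[rr, cc] = True
    roi = _roi(px, g.pitch_um)
    ring = ring_mask(roi, g, width_um=250.0)
    rejections = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        f = 0.18
        deficit = rng.random((256, 256)) < f
        n1 = ring.area_px
        x1 = (deficit & ring.pixels).sum()
        n2 = deficit.size
        x2 = deficit.sum()
        p_pool = (x1 + x2) / (n1 + n2)
        se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
        z = (x1 / n1 - x2 / n2) / se
        rejections += abs(z) > norm.ppf(1 - 0.01 / 2)
    assert rejections <= 3  # ≈ binomial(50, 0.01) upper tail


def test_vfd_input_contracts():
    g = ScanGeometry(scan_mm=6.0, raster_px=64)
    px = np.zeros((64, 64), dtype=bool)
    px[10, 10] = True
    with pytest.raises(ValueError, match="inside the frame"):
        vfd(_roi(px, g.pitch_um), (7.0, 3.0), g)
    with pytest.raises(ValueError):
        vfd(_roi(px, g.pitch_um), (3.0, 3.0), g, unit_area_mm2=0.0)
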