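"""Circle-Hough detector: accuracy, determinism, invariances, oracle match."""

import numpy as np
import pytest

from csfscan import (
    DetectorConfig,
    FieldImage,
    FieldSpec,
    detect_circles,
    filter_by_size,
    measure_intensities,
    render_field,
)
from csfscan.synthetic_field import _paint_disc

from conftest import brute_force_circles, match_detections


def make_disc_image(shape=(100, 100), discs=((40, 60, 6),), amp=1000.0,
                    background=100.0, soft=True):
    img = np.full(shape, background)
    for x, y, r in discs:
        if soft:
            _paint_disc(img, x, y, r, amp)
        else:
            yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
            img[(yy - y) ** 2 + (xx - x) ** 2 <= r**2] += amp
    return img


def test_blank_raster_yields_no_detections():
    assert detect_circles(np.full((60, 60), 500.0), DetectorConfig()) == []


def test_single_disc_found_within_one_pixel():
    img = make_disc_image(discs=((40, 60, 6),))
    dets = detect_circles(img, DetectorConfig())
    assert len(dets) == 1
    d = dets[0]
    assert abs(d.center_x_px - 40) <= 1
    assert abs(d.center_y_px - 60) <= 1
    assert abs(d.radius_px - 6) <= 1


def test_rendered_field_recall_and_precision():
    spec = FieldSpec(wbc_conc=650, rbc_conc=650, artifact_rate=0, seed=2)
    img, truth = render_field(spec)
    dets = detect_circles(img.gf + img.cf, DetectorConfig())
    hits, n_true, n_det = match_detections(dets, truth.cells)
    assert n_true >= 20
    assert hits / n_true >= 0.95
    assert hits == n_det  # no duplicates, no false positives


def test_detection_is_deterministic():
    img, _ = render_field(FieldSpec(wbc_conc=650, seed=8))
    a = detect_circles(img.gf, DetectorConfig())
    b = detect_circles(img.gf, DetectorConfig())
    assert [(d.center_x_px, d.center_y_px, d.radius_px, d.score) for d in a] \
        == [(d.center_x_px, d.center_y_px, d.radius_px, d.score) for d in b]


def test_translation_equivariance():
    img = make_disc_image(shape=(120, 120), discs=((40, 50, 5), (80, 90, 7)))
    dx, dy = 9, -6
    shifted = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
    a = detect_circles(img, DetectorConfig())
    b = detect_circles(shifted, DetectorConfig())
    got = sorted((d.center_x_px, d.center_y_px, d.radius_px) for d in b)
    want = sorted((d.center_x_px + dx, d.center_y_px + dy, d.radius_px)
                  for d in a)
    assert got == want


def test_matches_brute_force_search_on_small_image():
    """On a tiny image the detector agrees with an exhaustive correlation
    search over every (x, y, r) — centers within 1 px."""
    img = make_disc_image(shape=(64, 64), discs=((20, 20, 4), (45, 40, 6)))
    dets = detect_circles(img, DetectorConfig())
    oracle = brute_force_circles(img, 2, 8)
    assert len(dets) == len(oracle) == 2
    for ox, oy, _ in oracle:
        assert any(
            abs(d.center_x_px - ox) <= 1 and abs(d.center_y_px - oy) <= 1
            for d in dets
        )


def test_radius_range_too_large_raises():
    with pytest.raises(ValueError, match="radius_max"):
        detect_circles(np.zeros((20, 20)), DetectorConfig(radius_max_px=15))


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        DetectorConfig(radius_min_px=5, radius_max_px=3)


# --------------------------------------------------------------------------
# Size filter
# --------------------------------------------------------------------------

def test_filter_by_size_interval():
    from csfscan import CellDetection

    dets = [CellDetection(0, 0, r) for r in (1.0, 3.5, 6.0)]
    kept = filter_by_size(dets, (2.5, 7.0), pixel_size_um=1.0)
    assert [d.radius_px for d in kept] == [3.5, 6.0]
    assert filter_by_size([], (2.5, 7.0), 1.0) == []
    assert filter_by_size(dets, (0.0, np.inf), 1.0) == dets
    # pixel size converts px -> µm before the cut: radii become {2, 7, 12} µm
    assert [d.radius_px for d in filter_by_size(dets, (2.5, 7.0), 2.0)] == [3.5]
    with pytest.raises(ValueError):
        filter_by_size(dets, (7.0, 2.5), 1.0)
    with pytest.raises(ValueError):
        filter_by_size(dets, (2.5, 7.0), 0.0)


# --------------------------------------------------------------------------
# Intensity measurement
# --------------------------------------------------------------------------

def test_constant_disc_intensity_is_exact():
    from csfscan import CellDetection

    img = make_disc_image(shape=(50, 50), discs=((25, 25, 5),), amp=700.0,
                          background=120.0, soft=False)
    det = CellDetection(25, 25, 5)
    out = measure_intensities([det], img, np.full_like(img, 120.0))
    assert out[0].gf_intensity == pytest.approx(700.0, abs=1e-9)
    assert out[0].cf_intensity == pytest.approx(0.0, abs=1e-9)


def test_rendered_wbc_intensity_near_amplitude():
    spec = FieldSpec(wbc_conc=100, seed=4)
    img, truth = render_field(spec)
    dets = detect_circles(img.gf + img.cf, DetectorConfig())
    out = measure_intensities(dets, img.gf, img.cf)
    assert out
    for d in out:
        assert 400 < d.gf_intensity < 1600  # lognormal around 900
        assert abs(d.cf_intensity) < 50


def test_neighbor_exclusion_in_background_annulus():
    """A touching neighbour's disc is excluded from the annulus, so each
    cell's intensity stays within 5% of its isolated value."""
    from csfscan import CellDetection

    iso = make_disc_image(shape=(60, 60), discs=((25, 30, 5),), amp=900.0)
    pair = make_disc_image(shape=(60, 60),
                           discs=((25, 30, 5), (37, 30, 5)), amp=900.0)
    d1 = CellDetection(25, 30, 5)
    d2 = CellDetection(37, 30, 5)
    alone = measure_intensities([d1], iso, iso)[0].gf_intensity
    together = measure_intensities([d1, d2], pair, pair)[0].gf_intensity
    assert together == pytest.approx(alone, rel=0.05)


def test_edge_disc_is_flagged():
    from csfscan import CellDetection

    img = make_disc_image(shape=(40, 40), discs=((3, 20, 5),))
    out = measure_intensities([CellDetection(3, 20, 5)], img, img)
    assert "edge" in out[0].flags
    assert np.isfinite(out[0].gf_intensity)


# --------------------------------------------------------------------------
# FieldImage container
# --------------------------------------------------------------------------

def test_field_image_volume_consistency():
    z = np.zeros((100, 100))
    fi = FieldImage(z, z, z, pixel_size_um=1.0, depth_um=100.0)
    assert fi.volume_nl == pytest.approx(100 * 100 * 100 * 1e-6)
    with pytest.raises(ValueError, match="volume"):
        FieldImage(z, z, z, pixel_size_um=1.0, depth_um=100.0, volume_nl=2.0)
    with pytest.raises(ValueError, match="shape"):
        FieldImage(z, z, np.zeros((50, 50)), 1.0, 100.0)
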