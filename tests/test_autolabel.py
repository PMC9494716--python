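"""Classical label-generation pipeline: smoothing, thresholding,
morphology, contours, and the assembled auto-labeler."""

import dataclasses

import numpy as np
import pytest

from cellseg.autolabel import (AutolabelConfig, ConfigError, GeometryError,
                               adaptive_threshold, autolabel_image,
                               default_threshold_sigma, dilate, erode,
                               fill_contours, filter_small, find_contours,
                               gaussian_kernel, gaussian_smooth, open_morph,
                               preset_for_kind)
from cellseg.metrics import jaccard
from cellseg.synth import SynthConfig, generate_scene, scene_rng
from tests.conftest import (adaptive_threshold_oracle, flood_fill_area_oracle,
                            flood_fill_count_oracle, minmax_filter_oracle)


# ---------------------------------------------------------------------------
# Gaussian smoothing


def test_constant_image_is_invariant_under_smoothing():
    img = np.full((9, 9), 100, dtype=np.uint8)
    assert np.array_equal(gaussian_smooth(img, 3, 0.8), img)
    assert np.array_equal(gaussian_smooth(img, 7, 2.0), img)


def test_impulse_response_matches_dense_kernel():
    """A single 255 in zeros comes back as round(255*K) where K is the
    normalized outer-product Gaussian kernel."""
    img = np.zeros((7, 7), dtype=np.uint8)
    img[3, 3] = 255
    out = gaussian_smooth(img, 3, 0.8)
    d = np.array([math_exp(-(dd * dd) / (2 * 0.8**2)) for dd in (-1, 0, 1)])
    k = np.outer(d, d)
    k /= k.sum()
    expected = np.zeros((7, 7))
    expected[2:5, 2:5] = np.rint(255 * k)
    assert np.array_equal(out, expected.astype(np.uint8))


def math_exp(x):
    import math

    return math.exp(x)


def test_smoothing_is_linear_before_rounding(rng):
    a = rng.integers(0, 100, (12, 12)).astype(np.uint8)
    b = rng.integers(0, 100, (12, 12)).astype(np.uint8)
    fa = gaussian_smooth(a, 5, 1.0).astype(int)
    fb = gaussian_smooth(b, 5, 1.0).astype(int)
    fab = gaussian_smooth((a + b).astype(np.uint8), 5, 1.0).astype(int)
    assert np.abs(fab - (fa + fb)).max() <= 1  # rounding slack only


def test_even_kernel_size_is_rejected():
    with pytest.raises(ConfigError):
        gaussian_smooth(np.zeros((4, 4), dtype=np.uint8), size=4)
    with pytest.raises(ConfigError):
        gaussian_kernel(3, -1.0)


def test_default_threshold_sigma_matches_3x3_smoothing_sigma():
    # a 3x3 window uses sigma 0.8, tying the two Gaussian stages together
    assert default_threshold_sigma(3) == pytest.approx(0.8)


# ---------------------------------------------------------------------------
# adaptive threshold


def test_constant_image_thresholds_to_background():
    img = np.full((8, 8), 77, dtype=np.uint8)
    assert adaptive_threshold(img, 3, C=2.0, polarity="dark").sum() == 0
    # ties (C=0) are background too: strict inequality
    assert adaptive_threshold(img, 3, C=0.0, polarity="dark").sum() == 0
    assert adaptive_threshold(img, 3, C=0.0, polarity="light").sum() == 0


def test_bright_impulse_row_matches_bruteforce_oracle():
    img = np.array([[10, 10, 200, 10, 10]], dtype=np.uint8)
    got = adaptive_threshold(img, 3, C=0.0, polarity="dark")
    want = adaptive_threshold_oracle(img, 3, 0.0, "dark", default_threshold_sigma(3))
    assert np.array_equal(got, want)
    # the bright pixel pulls its neighbors' thresholds up: they become
    # foreground, while the bright pixel itself stays background
    assert got[0, 2] == 0
    assert got[0, 1] == 1 and got[0, 3] == 1


def test_inverting_image_and_polarity_gives_same_foreground(rng):
    img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
    dark = adaptive_threshold(img, 5, C=0.0, polarity="dark")
    light = adaptive_threshold((255 - img).astype(np.uint8), 5, C=0.0,
                               polarity="light")
    assert np.array_equal(dark, light)


def test_even_window_is_rejected():
    with pytest.raises(ConfigError):
        adaptive_threshold(np.zeros((4, 4), dtype=np.uint8), window=4)


# ---------------------------------------------------------------------------
# erosion / dilation / opening


def test_erode_square_to_center_pixel():
    img = np.zeros((7, 7), dtype=np.uint8)
    img[2:5, 2:5] = 1
    out = erode(img, 3)
    want = np.zeros((7, 7), dtype=np.uint8)
    want[3, 3] = 1
    assert np.array_equal(out, want)
    assert erode(np.zeros((5, 5), dtype=np.uint8), 3).sum() == 0


def test_dilate_pixel_to_square():
    img = np.zeros((7, 7), dtype=np.uint8)
    img[3, 3] = 1
    out = dilate(img, 3)
    assert out.sum() == 9
    assert out[2:5, 2:5].all()


def test_opening_closing_containment(random_binary_masks):
    for m in random_binary_masks[:20]:
        opened = dilate(erode(m, 3), 3)
        closed = erode(dilate(m, 3), 3)
        assert (opened <= m).all()
        assert (m <= closed).all()


def test_minmax_filters_match_bruteforce_oracle(rng):
    for _ in range(25):
        img = (rng.random((16, 16)) < 0.5).astype(np.uint8)
        assert np.array_equal(erode(img, 3), minmax_filter_oracle(img, 3, "min"))
        assert np.array_equal(dilate(img, 3), minmax_filter_oracle(img, 3, "max"))
    gray = rng.integers(0, 256, (16, 16), dtype=np.uint8)
    assert np.array_equal(erode(gray, 5), minmax_filter_oracle(gray, 5, "min"))
    assert np.array_equal(dilate(gray, 5), minmax_filter_oracle(gray, 5, "max"))


def test_opening_splits_thin_bridge_and_is_idempotent():
    img = np.zeros((9, 13), dtype=np.uint8)
    img[2:7, 1:6] = 1
    img[2:7, 7:12] = 1
    img[4, 6] = 1  # 1-px bridge between two 5x5 squares
    assert flood_fill_count_oracle(img) == 1
    opened = open_morph(img, 3)
    assert flood_fill_count_oracle(opened) == 2
    assert np.array_equal(open_morph(opened, 3), opened)
    # an isolated square at least as large as the kernel is unchanged
    sq = np.zeros((9, 9), dtype=np.uint8)
    sq[2:7, 2:7] = 1
    assert np.array_equal(open_morph(sq, 3), sq)


# ---------------------------------------------------------------------------
# contours


def test_empty_mask_has_no_contours():
    assert find_contours(np.zeros((8, 8), dtype=np.uint8)) == []


def test_filled_square_gives_one_closed_contour_with_area():
    img = np.zeros((8, 8), dtype=np.uint8)
    img[2:5, 3:6] = 1
    cons = find_contours(img)
    assert len(cons) == 1
    c = cons[0]
    assert c.closed
    assert c.filled_area == 9 == flood_fill_area_oracle(img)[0]
    # boundary is an 8-connected closed sequence
    pts = c.points
    diffs = np.abs(np.diff(np.vstack([pts, pts[:1]]), axis=0))
    assert (diffs.max(axis=1) == 1).all()


def test_contour_count_matches_flood_fill_on_random_masks(rng):
    for _ in range(100):
        m = (rng.random((32, 32)) < rng.uniform(0.05, 0.5)).astype(np.uint8)
        assert len(find_contours(m)) == flood_fill_count_oracle(m)


def test_contours_are_ordered_by_raster_start():
    m = np.zeros((10, 10), dtype=np.uint8)
    m[6:8, 1:3] = 1
    m[1:3, 6:8] = 1
    cons = find_contours(m)
    starts = [tuple(c.points[0]) for c in cons]
    assert starts == sorted(starts)


def test_filter_small_keeps_only_large_areas():
    m = np.zeros((12, 20), dtype=np.uint8)
    m[2:4, 2:5] = 1      # area 6
    m[6:11, 8:13] = 1    # area 25
    cons = find_contours(m)
    kept = filter_small(cons, 10)
    assert [c.filled_area for c in kept] == [25]
    assert filter_small(cons, 0) == cons
    assert filter_small(cons, 26) == []
    with pytest.raises(ConfigError):
        filter_small(cons, -1)


def test_fill_contours_inverts_find_contours_on_solid_shapes(rng):
    from scipy import ndimage as ndi

    assert fill_contours([], (6, 6)).sum() == 0
    for _ in range(30):
        raw = (rng.random((24, 24)) < 0.45).astype(np.uint8)
        # make every component hole-free
        labels, n = ndi.label(raw, structure=np.ones((3, 3)))
        m = np.zeros_like(raw)
        for lab in range(1, n + 1):
            m |= ndi.binary_fill_holes(labels == lab).astype(np.uint8)
        filled = fill_contours(find_contours(m), m.shape, 1)
        assert np.array_equal(filled, m)


def test_ring_fills_to_solid_disc():
    from skimage.draw import disk

    ring = np.zeros((20, 20), dtype=np.uint8)
    rr, cc = disk((10, 10), 7)
    ring[rr, cc] = 1
    rr, cc = disk((10, 10), 4)
    solid = ring.copy()
    ring[rr, cc] = 0  # punch the hole
    filled = fill_contours(find_contours(ring), ring.shape, 2)
    assert np.array_equal(filled, solid * 2)


def test_fill_contours_rejects_out_of_bounds():
    cons = find_contours(np.ones((4, 4), dtype=np.uint8))
    with pytest.raises(GeometryError):
        fill_contours(cons, (3, 3), 1)
    with pytest.raises(ConfigError):
        fill_contours(cons, (4, 4), 0)


# ---------------------------------------------------------------------------
# full pipeline


def test_blank_image_labels_as_background():
    img = np.full((32, 32), 180, dtype=np.uint8)
    out = autolabel_image(img, AutolabelConfig(), class_value=1)
    assert out.sum() == 0


def test_autolabel_recovers_clean_rbc_scene():
    cfg = SynthConfig(noise_std=0.0,
                      debris_prob={"rbc": 0.0, "macrophage": 0.0, "mixed": 0.0})
    sc = generate_scene(cfg, "rbc", scene_rng(4, "rbc", 0))
    label = autolabel_image(sc.image, preset_for_kind(cfg, "rbc"), class_value=1)
    assert set(np.unique(label)) <= {0, 1}
    assert jaccard(label == 1, sc.mask == 1) >= 0.95


def test_morphology_separates_adhesive_macrophages():
    """With opening, the detected component count equals the true cell
    count; without it, bridged adhesive pairs merge and the count drops."""
    cfg = SynthConfig(adhesion_prob=1.0,
                      debris_prob={"rbc": 0.0, "macrophage": 0.0, "mixed": 0.0})
    preset = preset_for_kind(cfg, "macrophage")
    checked_pairs = 0
    for i in range(4):
        sc = generate_scene(cfg, "macrophage", scene_rng(6, "macrophage", i))
        with_m = autolabel_image(sc.image, preset, class_value=2)
        without = autolabel_image(sc.image,
                                  dataclasses.replace(preset, morphology=False),
                                  class_value=2)
        assert flood_fill_count_oracle(with_m == 2) == sc.true_counts[2]
        if any(inst.adhesive for inst in sc.instances):
            checked_pairs += 1
            assert flood_fill_count_oracle(without == 2) < sc.true_counts[2]
    assert checked_pairs > 0
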