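"""Colour conversion, first-order, co-occurrence and run-length features."""

import numpy as np
import pytest
from helpers import (
    glcm_bruteforce,
    glcm_features_bruteforce,
    glrlm_bruteforce,
    glrlm_features_bruteforce,
    srgb_to_lab_reference,
)

from curemetrics.imaging import (
    FEATURE_NAMES,
    GLCMatrix,
    ROI,
    SliceImage,
    color_features,
    compute_glcm,
    compute_glrlm,
    first_order,
    glcm_features,
    glrlm_features,
    quantize,
    roi_feature_vector,
    select_rois,
    slice_feature_vector,
    srgb_to_lab,
    to_gray,
)


def const_image(rgb, size=16):
    px = np.zeros((size, size, 3), dtype=np.uint8)
    px[:] = rgb
    return SliceImage(px)


def full_roi(img):
    return ROI(0, 0, img.width, img.height)


# ---------------------------------------------------------------------------
# colour
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("rgb", [(255, 255, 255), (0, 0, 0), (255, 0, 0), (12, 200, 99)])
def test_srgb_to_lab_matches_reference_chain(rgb):
    lab = srgb_to_lab(np.array([[rgb]], dtype=np.uint8))[0, 0]
    ref = srgb_to_lab_reference(rgb)
    assert np.allclose(lab, ref, atol=0.01)


def test_white_and_black_points():
    white = srgb_to_lab(np.array([[(255, 255, 255)]], dtype=np.uint8))[0, 0]
    assert abs(white[0] - 100) < 0.01 and abs(white[1]) < 0.01 and abs(white[2]) < 0.01
    black = srgb_to_lab(np.array([[(0, 0, 0)]], dtype=np.uint8))[0, 0]
    assert abs(black[0]) < 1e-6


def test_color_features_constant_and_mixed():
    img = const_image((128, 64, 32))
    L, a, b = color_features(img, full_roi(img))
    ref = srgb_to_lab_reference((128, 64, 32))
    assert np.allclose((L, a, b), ref, atol=0.01)

    # half white, half black: L* is the mean of 100 and 0
    px = np.zeros((8, 8, 3), dtype=np.uint8)
    px[:4] = 255
    img = SliceImage(px)
    L, _, _ = color_features(img, full_roi(img))
    assert abs(L - 50.0) < 1e-6


def test_color_features_equal_bruteforce_mean():
    rng = np.random.default_rng(5)
    px = rng.integers(0, 256, (6, 7, 3), dtype=np.uint8)
    img = SliceImage(px)
    got = color_features(img, full_roi(img))
    ref = np.mean(
        [srgb_to_lab_reference(tuple(px[r, c])) for r in range(6) for c in range(7)], axis=0
    )
    assert np.allclose(got, ref, atol=0.01)


# ---------------------------------------------------------------------------
# grayscale and first-order statistics
# ---------------------------------------------------------------------------


def test_luma_weights_and_quantization():
    img = const_image((0, 0, 255))
    gray = to_gray(img, full_roi(img))
    assert np.all(gray.raw == 29)  # 0.114 * 255 rounded
    img = const_image((255, 255, 255))
    gray = to_gray(img, full_roi(img), n_levels=32)
    assert np.all(gray.raw == 255)
    assert np.all(gray.levels == 31)
    assert np.array_equal(quantize(np.array([0, 7, 8, 255]), 32), [0, 0, 1, 31])


def test_first_order_hand_case_and_degenerates():
    img = const_image((100, 100, 100))
    gray = to_gray(img, full_roi(img))
    mean, sd, skew = first_order(gray)
    assert sd == 0.0 and skew == 0.0

    class G:  # direct construction for a hand case
        raw = np.array([0, 0, 0, 255], dtype=np.int64)

    mean, sd, skew = first_order(G)
    assert mean == pytest.approx(63.75)
    m2 = np.mean((G.raw - 63.75) ** 2)
    m3 = np.mean((G.raw - 63.75) ** 3)
    assert sd == pytest.approx(np.sqrt(m2))
    assert skew == pytest.approx(m3 / m2**1.5)

    class Sym:
        raw = np.array([10, 20, 20, 30, 30, 30, 40, 40, 50], dtype=np.int64)

    _, _, skew = first_order(Sym)
    assert abs(skew) < 1e-9


# ---------------------------------------------------------------------------
# co-occurrence
# ---------------------------------------------------------------------------


def test_glcm_constant_image():
    lv = np.full((8, 8), 3)
    glcm = compute_glcm(lv, 8)
    for a in range(glcm.P.shape[2]):
        assert glcm.P[3, 3, a] == pytest.approx(1.0)
        assert glcm.P[:, :, a].sum() == pytest.approx(1.0)


def test_glcm_checkerboard_hand_case():
    lv = np.array([[0, 1], [1, 0]])
    glcm = compute_glcm(lv, 2, angles=(0,), symmetric=True)
    P = glcm.P[:, :, 0]
    assert P[0, 1] == pytest.approx(0.5) and P[1, 0] == pytest.approx(0.5)
    feats = glcm_features(glcm)
    assert feats["contrast"] == pytest.approx(1.0)
    assert feats["dissimilarity"] == pytest.approx(1.0)
    assert feats["angular_second_moment"] == pytest.approx(0.5)
    assert feats["energy"] == pytest.approx(np.sqrt(0.5))
    assert feats["homogeneity"] == pytest.approx(0.5)
    assert feats["entropy"] == pytest.approx(1.0)
    assert feats["correlation"] == pytest.approx(-1.0)


@pytest.mark.parametrize("size,levels", [(8, 8), (16, 8)])
def test_glcm_matches_bruteforce(size, levels):
    rng = np.random.default_rng(size)
    for _ in range(20):
        lv = rng.integers(0, levels, (size, size))
        glcm = compute_glcm(lv, levels)
        for ai, angle in enumerate(glcm.angles):
            ref = glcm_bruteforce(lv, levels, angle)
            assert np.allclose(glcm.P[:, :, ai], ref, atol=1e-12)


def test_glcm_features_match_double_loop_oracle():
    rng = np.random.default_rng(0)
    for _ in range(10):
        lv = rng.integers(0, 6, (10, 10))
        glcm = compute_glcm(lv, 6, angles=(0,))
        ref = glcm_features_bruteforce(glcm.P[:, :, 0])
        got = glcm_features(glcm)
        for k, v in ref.items():
            assert got[k] == pytest.approx(v, abs=1e-12)


def test_glcm_features_match_skimage_graycoprops():
    from skimage.feature import graycoprops

    rng = np.random.default_rng(3)
    lv = rng.integers(0, 8, (12, 12))
    glcm = compute_glcm(lv, 8, angles=(0, 90))
    P4 = glcm.P[:, :, None, :]  # (G, G, dist, angle) layout
    got = glcm_features(glcm)
    for name, key in [("contrast", "contrast"), ("dissimilarity", "dissimilarity"),
                      ("homogeneity", "homogeneity"), ("ASM", "angular_second_moment"),
                      ("correlation", "correlation")]:
        ref = graycoprops(P4, name)[0].mean()
        assert got[key] == pytest.approx(ref, abs=1e-10)
    # energy is the root of the angle-averaged ASM
    assert got["energy"] == pytest.approx(np.sqrt(graycoprops(P4, "ASM")[0].mean()), abs=1e-10)


def test_glcm_rejects_bad_input():
    with pytest.raises(ValueError, match="distance"):
        compute_glcm(np.zeros((4, 4), dtype=int), 8, distance=0)
    with pytest.raises(ValueError, match="smaller"):
        compute_glcm(np.zeros((1, 1), dtype=int), 8)


# ---------------------------------------------------------------------------
# run length
# ---------------------------------------------------------------------------


def test_glrlm_row_hand_case():
    lv = np.array([[0, 0, 1, 1, 1, 2]])
    (m,) = compute_glrlm(lv, 3, directions=(0,))
    assert m.n_runs == 3 and m.n_pixels == 6
    assert m.R[0, 1] == 1 and m.R[1, 2] == 1 and m.R[2, 0] == 1
    feats = glrlm_features([m])
    assert feats["short_run_emphasis"] == pytest.approx((1 / 4 + 1 / 9 + 1) / 3)
    assert feats["long_run_emphasis"] == pytest.approx((4 + 9 + 1) / 3)
    assert feats["run_percentage"] == pytest.approx(0.5)
    assert feats["gray_level_nonuniformity"] == pytest.approx(1.0)
    assert feats["run_length_nonuniformity"] == pytest.approx(1.0)


def test_glrlm_checkerboard_and_constant():
    cb = np.indices((6, 6)).sum(axis=0) % 2
    (m,) = compute_glrlm(cb, 2, directions=(0,))
    assert m.n_runs == m.n_pixels  # all runs have length 1
    feats = glrlm_features([m])
    assert feats["short_run_emphasis"] == pytest.approx(1.0)
    assert feats["long_run_emphasis"] == pytest.approx(1.0)
    assert feats["run_percentage"] == pytest.approx(1.0)

    const = np.zeros((4, 7), dtype=int)
    (m,) = compute_glrlm(const, 2, directions=(0,))
    assert m.n_runs == 4 and m.R[0, 6] == 4  # H runs of length W


@pytest.mark.parametrize("direction", [0, 45, 90, 135])
def test_glrlm_matches_bruteforce(direction):
    rng = np.random.default_rng(direction)
    for _ in range(15):
        lv = rng.integers(0, 4, (8, 8))
        (m,) = compute_glrlm(lv, 4, directions=(direction,))
        ref = glrlm_bruteforce(lv, 4, direction)
        assert np.array_equal(m.R, ref)
        # totals invariant: sum R = Nr, sum l*R = Np
        lengths = np.arange(1, m.R.shape[1] + 1)
        assert (m.R.sum(axis=0) * lengths).sum() == m.n_pixels


# ---------------------------------------------------------------------------
# ROI selection and aggregation
# ---------------------------------------------------------------------------


def test_grid_rois_disjoint_and_count():
    img = const_image((50, 50, 50), size=512)
    rois = select_rois(img, n=8, roi_size=(96, 96), strategy="grid")
    assert len(rois) == 8
    for i, a in enumerate(rois):
        for b in rois[i + 1 :]:
            assert a.x1 <= b.x0 or b.x1 <= a.x0 or a.y1 <= b.y0 or b.y1 <= a.y0


def test_full_frame_roi_and_errors():
    img = const_image((10, 10, 10), size=64)
    (roi,) = select_rois(img, n=1, roi_size=(64, 64))
    assert (roi.x0, roi.y0, roi.x1, roi.y1) == (0, 0, 64, 64)
    with pytest.raises(ValueError, match="width"):
        select_rois(img, n=1, roi_size=(100, 32))
    with pytest.raises(ValueError, match="height"):
        select_rois(img, n=1, roi_size=(32, 100))


def test_random_rois_seeded_and_nonoverlapping():
    img = const_image((10, 10, 10), size=128)
    first = select_rois(img, n=5, roi_size=(24, 24), strategy="random_nonoverlap", seed=9)
    for _ in range(20):
        again = select_rois(img, n=5, roi_size=(24, 24), strategy="random_nonoverlap", seed=9)
        assert again == first
    for i, a in enumerate(first):
        for b in first[i + 1 :]:
            assert a.x1 <= b.x0 or b.x1 <= a.x0 or a.y1 <= b.y0 or b.y1 <= a.y0


def test_slice_mean_is_featurewise_mean_of_rois():
    rng = np.random.default_rng(11)
    img = SliceImage(rng.integers(0, 256, (96, 96, 3), dtype=np.uint8))
    rois = select_rois(img, n=4, roi_size=(32, 32))
    per_roi = slice_feature_vector(img, rois, aggregation="per_roi")
    (mean,) = slice_feature_vector(img, rois, aggregation="slice_mean")
    for k in FEATURE_NAMES:
        assert mean[k] == pytest.approx(np.mean([v[k] for v in per_roi]))
    # identical ROIs: the mean equals any per-ROI vector
    const = const_image((90, 60, 40), size=64)
    rois = select_rois(const, n=2, roi_size=(16, 16))
    per_roi = slice_feature_vector(const, rois, aggregation="per_roi")
    (mean,) = slice_feature_vector(const, rois, aggregation="slice_mean")
    assert per_roi[0] == pytest.approx(per_roi[1])
    for k in FEATURE_NAMES:
        assert mean[k] == pytest.approx(per_roi[0][k])


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------


def test_gray_shift_invariance_of_texture_features():
    """Adding one quantisation step to every pixel leaves the co-occurrence
    differences and run structure unchanged."""
    rng = np.random.default_rng(21)
    lv = rng.integers(0, 30, (16, 16))  # leave headroom for the +1 shift
    shifted = lv + 1
    f0 = glcm_features(compute_glcm(lv, 32))
    f1 = glcm_features(compute_glcm(shifted, 32))
    for k in ("contrast", "dissimilarity", "homogeneity"):
        assert f0[k] == pytest.approx(f1[k], abs=1e-12)
    r0 = glrlm_features(compute_glrlm(lv, 32))
    r1 = glrlm_features(compute_glrlm(shifted, 32))
    for k in ("short_run_emphasis", "long_run_emphasis", "run_percentage",
              "run_length_nonuniformity"):
        assert r0[k] == pytest.approx(r1[k], abs=1e-12)


def test_energy_squared_equals_asm_everywhere():
    rng = np.random.default_rng(2)
    for _ in range(10):
        lv = rng.integers(0, 8, (12, 12))
        feats = glcm_features(compute_glcm(lv, 8))
        assert feats["energy"] ** 2 == pytest.approx(feats["angular_second_moment"], abs=1e-9)


def test_roi_feature_vector_is_complete_and_finite():
    rng = np.random.default_rng(4)
    img = SliceImage(rng.integers(0, 256, (80, 80, 3), dtype=np.uint8))
    vec = roi_feature_vector(img, full_roi(img))
    assert tuple(vec) == FEATURE_NAMES
    assert all(np.isfinite(v) for v in vec.values())
    assert 0 < vec["run_percentage"] <= 1


def test_fragmentation_raises_contrast_lowers_homogeneity(small_series_features):
    """With a positive speckle growth rate, co-occurrence contrast and
    dissimilarity rise with storage day while homogeneity and ASM fall."""
    means = small_series_features.groupby("day")[
        ["contrast", "dissimilarity", "homogeneity", "angular_second_moment"]
    ].mean()
    days = sorted(means.index)
    for up in ("contrast", "dissimilarity"):
        assert all(means.loc[a, up] < means.loc[b, up] for a, b in zip(days, days[1:]))
    for down in ("homogeneity", "angular_second_moment"):
        assert all(means.loc[a, down] > means.loc[b, down] for a, b in zip(days, days[1:]))
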