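"""Registration: disc/ROI selection, preprocessing, keypoints, MSAC, warping."""

import numpy as np
import pytest

from padar import (PhantomSpec, RoiRule, generate_fundus,
                   detect_optic_disc, estimate_affine, extract_control_points,
                   match_control_points, mosaic_qc,
                   preprocess_for_registration, select_reference,
                   warp_to_reference)
from padar.phantom import FundusImage, motion_matrix
from padar.registration import (ControlPointSet, DiscLocation,
                                corner_reprojection_error)


# -- optic disc --------------------------------------------------------------


def test_disc_detected_within_10px_of_ground_truth():
    spec = PhantomSpec(image_size=512, disease_class="HC",
                       disc_center=(300.0, 220.0), rng_seed=8)
    im, gt = generate_fundus(spec)
    d = detect_optic_disc(im)
    assert np.hypot(d.x - gt.disc_location[0], d.y - gt.disc_location[1]) < 10


def test_injected_detector_is_exact_passthrough():
    provided = DiscLocation(x=123.0, y=45.0, confidence=1.0)
    d = detect_optic_disc(np.zeros((64, 64, 3)), detector=lambda px: provided)
    assert d is provided


def test_all_black_image_has_no_fov():
    with pytest.raises(ValueError, match="no field of view"):
        detect_optic_disc(np.zeros((64, 64, 3), dtype=np.float32))


# -- reference selection (printed ROI formula) -------------------------------


def _img(image_id, date="2020-01-01", size=512):
    return FundusImage(pixels=np.zeros((size, size, 3), dtype=np.float32),
                       image_id=image_id, date=date)


def test_roi_rule_includes_and_excludes_by_printed_bounds():
    rule = RoiRule()
    # |dx| = 150 <= 0.3*512 = 153.6 and |dy| = 120 <= 0.25*512 = 128 -> inside
    assert rule.contains(DiscLocation(256 + 150, 256 + 120), 512, 512)
    # |dx| = 160 > 153.6 -> outside
    assert not rule.contains(DiscLocation(256 + 160, 256), 512, 512)


def test_reference_is_argmin_disc_to_center_distance():
    images = [_img("a"), _img("b"), _img("c")]
    locs = [DiscLocation(256 + 40, 256), DiscLocation(256 + 12, 256),
            DiscLocation(256, 256 + 90)]
    ref, kept = select_reference(images, locs)
    assert ref == 1
    assert kept == [0, 1, 2]


def test_no_qualifying_image_reports_distances():
    images = [_img("a")]
    with pytest.raises(ValueError, match="a: "):
        select_reference(images, [DiscLocation(256 + 200, 256)])


def test_reference_tie_breaks_by_date_then_id():
    images = [_img("b", "2021-01-01"), _img("a", "2020-01-01")]
    locs = [DiscLocation(256 + 10, 256), DiscLocation(256 - 10, 256)]
    ref, _ = select_reference(images, locs)
    assert ref == 1  # same distance, earlier date wins


# -- preprocessing -----------------------------------------------------------


def test_fov_mask_area_matches_eroded_analytic_circle():
    size, r = 512, 200
    yy, xx = np.mgrid[0:size, 0:size]
    circ = (np.hypot(xx - 256, yy - 256) <= r).astype(np.float32)
    img = np.stack([np.zeros_like(circ), 0.8 * circ, np.zeros_like(circ)],
                   axis=-1)
    enhanced, mask = preprocess_for_registration(img)
    expected = np.pi * (r - 5) ** 2
    assert abs(mask.sum() - expected) / expected < 0.02
    assert enhanced.min() == 0.0 and enhanced.max() == 1.0


def test_constant_image_rejected():
    with pytest.raises(ValueError, match="Otsu"):
        preprocess_for_registration(np.full((64, 64, 3), 0.5,
                                            dtype=np.float32))


def test_clahe_preserves_two_level_order_and_enhances_separation():
    from skimage.exposure import equalize_adapthist
    img = np.full((128, 128), 0.45)
    img[:, 64:] = 0.55
    out = equalize_adapthist(img, kernel_size=32, clip_limit=0.02)
    for ty in range(0, 128, 32):
        for tx in range(0, 128, 32):
            tile_in = img[ty:ty + 32, tx:tx + 32]
            tile_out = out[ty:ty + 32, tx:tx + 32]
            lo, hi = tile_in.min(), tile_in.max()
            if hi > lo:  # tile straddles the step: order must be preserved
                assert tile_out[tile_in == hi].min() >= \
                    tile_out[tile_in == lo].max()
    sep_in = 0.55 - 0.45
    sep_out = out[img == 0.55].mean() - out[img == 0.45].mean()
    assert sep_out > sep_in


# -- control points ----------------------------------------------------------


def test_blank_image_inside_mask_raises_insufficient_texture():
    blank = np.zeros((256, 256))
    mask = np.ones((256, 256), dtype=bool)
    with pytest.raises(ValueError, match="insufficient texture"):
        extract_control_points(blank, mask)


def test_phantom_vessel_texture_yields_many_keypoints(amd_phantom_512):
    im, _ = amd_phantom_512
    enhanced, mask = preprocess_for_registration(im.pixels)
    cps = extract_control_points(enhanced, mask)
    assert len(cps) >= 20
    assert len(cps.keypoints) == len(cps.descriptors)
    xs, ys = cps.xy[:, 0].astype(int), cps.xy[:, 1].astype(int)
    assert mask[ys, xs].all()


def test_descriptors_survive_90_degree_rotation(amd_phantom_512):
    im, _ = amd_phantom_512
    enhanced, mask = preprocess_for_registration(im.pixels)
    rot = np.rot90(enhanced)
    rot_mask = np.rot90(mask)
    a = extract_control_points(enhanced, mask)
    b = extract_control_points(rot, rot_mask)
    from sklearn.neighbors import NearestNeighbors
    fwd = NearestNeighbors(n_neighbors=1).fit(b.descriptors)
    _, fi = fwd.kneighbors(a.descriptors)
    back = NearestNeighbors(n_neighbors=1).fit(a.descriptors)
    _, bi = back.kneighbors(b.descriptors)
    mutual = sum(1 for i in range(len(a)) if bi[fi[i, 0], 0] == i)
    assert mutual / len(a) >= 0.5


# -- matching ----------------------------------------------------------------


def _cps(desc, image_id="x"):
    n = len(desc)
    kp = np.column_stack([np.arange(n, dtype=float),
                          np.arange(n, dtype=float),
                          np.ones(n), np.zeros(n)])
    return ControlPointSet(kp, np.asarray(desc, dtype=np.float64), image_id)


def test_self_matching_is_identity():
    rng = np.random.default_rng(0)
    s = _cps(rng.random((30, 8)))
    m = match_control_points(s, s)
    assert np.array_equal(m[:, 0], m[:, 1])
    assert len(m) == 30


def test_equidistant_neighbors_dropped_by_ratio_test():
    sx = _cps([[0.0, 0.0]])
    sy = _cps([[1.0, 0.0], [-1.0, 0.0]])  # both at distance 1 -> ratio 1
    with pytest.raises(ValueError, match="ratio"):
        match_control_points(sx, sy)


def test_nn_search_agrees_with_brute_force_oracle():
    rng = np.random.default_rng(1)
    sx = _cps(rng.random((500, 16)))
    sy = _cps(rng.random((500, 16)))
    m = match_control_points(sx, sy, ratio=1.1)  # keep every nearest match
    d2 = ((sx.descriptors[:, None, :] - sy.descriptors[None, :, :]) ** 2
          ).sum(axis=2)
    brute = d2.argmin(axis=1)
    agree = np.mean([brute[i] == j for i, j in m])
    assert agree >= 0.95


# -- robust affine -----------------------------------------------------------


def _correspondences(M, n=60, outlier_frac=0.0, seed=0, size=512):
    rng = np.random.default_rng(seed)
    src = rng.uniform(40, size - 40, (n, 2))
    dst = src @ M[:, :2].T + M[:, 2]
    n_out = int(outlier_frac * n)
    if n_out:
        dst[:n_out] = rng.uniform(0, size, (n_out, 2))
    # estimate maps SY (target=src) onto SX (reference=dst)
    sx = ControlPointSet(np.column_stack([dst, np.ones(n), np.zeros(n)]),
                         np.zeros((n, 4)))
    sy = ControlPointSet(np.column_stack([src, np.ones(n), np.zeros(n)]),
                         np.zeros((n, 4)))
    matches = np.column_stack([np.arange(n), np.arange(n)])
    return matches, sx, sy


def test_noiseless_affine_recovered_to_1e6():
    M = motion_matrix(10.0, (5.0, 5.0), 1.02, (256.0, 256.0))
    matches, sx, sy = _correspondences(M)
    est = estimate_affine(matches, sx, sy, seed=0)
    assert np.abs(est.matrix - M).max() < 1e-6


def test_30pct_outliers_still_subpixel_corner_error():
    M = motion_matrix(-12.0, (10.0, -8.0), 0.98, (256.0, 256.0))
    matches, sx, sy = _correspondences(M, n=100, outlier_frac=0.3, seed=3)
    est = estimate_affine(matches, sx, sy, seed=1)
    assert corner_reprojection_error(est.matrix, M) < 1.0


def test_identity_correspondences_give_identity_and_zero_rmse():
    I = np.column_stack([np.eye(2), np.zeros(2)])
    matches, sx, sy = _correspondences(I)
    est = estimate_affine(matches, sx, sy, seed=0)
    assert np.abs(est.matrix - I).max() < 1e-9
    assert est.inlier_rmse < 1e-9
    assert est.inlier_count == len(matches)


def test_msac_is_deterministic_for_fixed_seed():
    M = motion_matrix(8.0, (3.0, 4.0), 1.01, (256.0, 256.0))
    matches, sx, sy = _correspondences(M, n=80, outlier_frac=0.3, seed=5)
    e1 = estimate_affine(matches, sx, sy, seed=42)
    e2 = estimate_affine(matches, sx, sy, seed=42)
    assert np.array_equal(e1.matrix, e2.matrix)
    assert e1.inlier_count == e2.inlier_count


def test_too_few_matches_rejected():
    I = np.column_stack([np.eye(2), np.zeros(2)])
    matches, sx, sy = _correspondences(I, n=2)
    with pytest.raises(ValueError, match="3 matches"):
        estimate_affine(matches[:2], sx, sy)


# -- warping & mosaic --------------------------------------------------------


def test_identity_warp_is_exact():
    rng = np.random.default_rng(2)
    img = rng.random((64, 64))
    I = np.column_stack([np.eye(2), np.zeros(2)])
    assert np.allclose(warp_to_reference(img, I), img, atol=1e-12)


def test_warp_roundtrip_error_small_on_smooth_image():
    from scipy.ndimage import gaussian_filter
    rng = np.random.default_rng(3)
    img = gaussian_filter(rng.random((256, 256)), 5)
    M = motion_matrix(9.0, (6.0, -4.0), 1.03, (128.0, 128.0))
    M3 = np.vstack([M, [0, 0, 1]])
    back = warp_to_reference(warp_to_reference(img, M), np.linalg.inv(M3)[:2])
    interior = (slice(40, -40), slice(40, -40))
    assert np.abs(back[interior] - img[interior]).mean() < 2 / 255


def test_heatmap_and_image_displace_together():
    img = np.zeros((128, 128))
    img[60:68, 60:68] = 1.0
    heat = img.copy()
    M = motion_matrix(0.0, (15.0, -10.0), 1.0, (64.0, 64.0))
    wi = warp_to_reference(img, M)
    wh = warp_to_reference(heat, M)
    pi = np.unravel_index(np.argmax(wi), wi.shape)
    ph = np.unravel_index(np.argmax(wh), wh.shape)
    assert np.hypot(pi[0] - ph[0], pi[1] - ph[1]) <= 1.0


def test_singular_transform_rejected():
    S = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    with pytest.raises(ValueError, match="singular"):
        warp_to_reference(np.zeros((8, 8)), S)


def test_mosaic_identity_single_tile_and_parity():
    rng = np.random.default_rng(4)
    a = rng.random((128, 128))
    b = rng.random((128, 128))
    assert np.array_equal(mosaic_qc(a, a, tile=32), a)
    assert np.array_equal(mosaic_qc(a, b, tile=128), a)
    m = mosaic_qc(a, b, tile=32)
    for ty in range(4):
        for tx in range(4):
            block = m[ty * 32:(ty + 1) * 32, tx * 32:(tx + 1) * 32]
            src = a if (ty + tx) % 2 == 0 else b
            assert np.array_equal(
                block, src[ty * 32:(ty + 1) * 32, tx * 32:(tx + 1) * 32])
    with pytest.raises(ValueError, match="shapes differ"):
        mosaic_qc(a, b[:64])
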