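"""Background estimation, contour smoothing, interpolation and ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from ncfratio import (
    EdgeContour,
    SceneSpec,
    box_background,
    extract_edge_contour,
    halfway_background,
    interpolate_background,
    make_wedge_scene,
    mbs_ratio,
    nonuniform_ratio,
    sample_edge_intensity,
    smooth_contour_gaussian,
)
from ncfratio.background import estimate_nonuniform_background


def make_outer_contour(pixels, smoothed=None, raw=None, closed=True):
    return EdgeContour(
        pixels=np.asarray(pixels, int),
        side="outer",
        component_id=1,
        closed=closed,
        raw_intensity=None if raw is None else np.asarray(raw, float),
        smoothed_intensity=None if smoothed is None else np.asarray(smoothed, float),
    )


class TestBoxBackground:
    def test_constant_box(self):
        img = np.full((30, 30), 7.0)
        mean, std = box_background(img, (0, 0, 15, 15), min_area=100)
        assert mean == 7.0 and std == 0.0

    def test_two_value_box(self):
        img = np.ones((20, 20))
        img[:10] = 3.0
        mean, std = box_background(img, (0, 0, 20, 20), min_area=100)
        assert mean == pytest.approx(2.0)
        assert std == pytest.approx(np.std(img, ddof=1))

    def test_seeded_gaussian_recovers_moments(self):
        rng = np.random.default_rng(42)
        img = rng.normal(100.0, 5.0, (100, 100))
        mean, std = box_background(img, (0, 0, 100, 100))
        assert mean == pytest.approx(100.0, abs=0.2)
        assert std == pytest.approx(5.0, abs=0.2)

    def test_box_overlapping_mask_raises(self):
        mask = np.zeros((20, 20), bool)
        mask[5, 5] = True
        with pytest.raises(ValueError, match="overlaps"):
            box_background(np.zeros((20, 20)), (0, 0, 12, 12), mask=mask)

    def test_small_box_raises(self):
        with pytest.raises(ValueError, match="area"):
            box_background(np.zeros((20, 20)), (0, 0, 5, 5))


class TestMbsRatio:
    def test_scalar_arithmetic(self):
        res = mbs_ratio(np.full((3, 3), 10.0), np.full((3, 3), 6.0), 2.0, 2.0)
        assert np.allclose(res.ratio, 2.0)
        assert not res.invalid.any()

    def test_degenerate_denominator_all_invalid(self):
        res = mbs_ratio(np.ones((4, 4)), np.full((4, 4), 5.0), 0.0, 5.0)
        assert res.invalid.all()
        assert np.isnan(res.ratio).all()
        assert res.params["n_invalid"] == 16

    def test_noise_free_wedge_recovers_a0_exactly(self):
        scene = make_wedge_scene(SceneSpec(noise_sigma1=0, noise_sigma2=0))
        res = mbs_ratio(scene.img1, scene.img2, 120.0, 100.0)
        inside = scene.truth.S2_field > 0
        assert np.nanmax(np.abs(res.ratio[inside] - 0.7)) < 1e-12

    def test_matches_per_pixel_loop(self, rng):
        img1 = rng.normal(100, 20, (16, 16))
        img2 = rng.normal(100, 20, (16, 16))
        res = mbs_ratio(img1, img2, 10.0, 20.0)
        for r in range(16):
            for c in range(16):
                den = img2[r, c] - 20.0
                if den <= 0:
                    assert res.invalid[r, c]
                else:
                    assert abs(res.ratio[r, c] - (img1[r, c] - 10.0) / den) < 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            mbs_ratio(np.zeros((3, 3)), np.zeros((4, 4)), 0, 0)


class TestHalfwayBackground:
    @pytest.mark.parametrize(
        "distant,thresh,expected", [(100, 100, 100), (100, 140, 120), (0, 14, 7)]
    )
    def test_midpoint(self, distant, thresh, expected):
        assert halfway_background(distant, thresh) == expected

    def test_threshold_below_background_raises(self):
        with pytest.raises(ValueError, match="below"):
            halfway_background(100, 90)


class TestSampleEdgeIntensity:
    def test_constant_image(self):
        mask = np.zeros((7, 7), bool)
        mask[2:5, 2:5] = True
        (c,) = extract_edge_contour(mask, side="outer")
        filled = sample_edge_intensity(np.full((7, 7), 4.2), c)
        assert np.allclose(filled.raw_intensity, 4.2)

    def test_hot_pixel_appears_once(self):
        mask = np.zeros((7, 7), bool)
        mask[2:5, 2:5] = True
        (c,) = extract_edge_contour(mask, side="outer")
        img = np.zeros((7, 7))
        hot = tuple(c.pixels[3])
        img[hot] = 9.0
        filled = sample_edge_intensity(img, c)
        assert (filled.raw_intensity == 9.0).sum() == 1
        assert filled.raw_intensity[3] == 9.0

    def test_gradient_matches_direct_lookup(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        (c,) = extract_edge_contour(mask, side="outer")
        img = 50.0 + 2.0 * np.arange(20)[None, :] * np.ones((20, 1))
        filled = sample_edge_intensity(img, c)
        expected = img[c.pixels[:, 0], c.pixels[:, 1]]
        np.testing.assert_array_equal(filled.raw_intensity, expected)

    def test_inner_contour_rejected(self):
        mask = np.zeros((7, 7), bool)
        mask[2:5, 2:5] = True
        (c,) = extract_edge_contour(mask, side="inner")
        with pytest.raises(ValueError, match="outer"):
            sample_edge_intensity(np.zeros((7, 7)), c)


class TestSmoothContourGaussian:
    @given(
        sigma=hst.floats(0.3, 30.0),
        c=hst.floats(-50.0, 50.0),
        n=hst.integers(3, 200),
    )
    @settings(max_examples=40, deadline=None)
    def test_constant_preserved_exactly(self, sigma, c, n):
        out = smooth_contour_gaussian(np.full(n, c), sigma)
        np.testing.assert_allclose(out, c, rtol=0, atol=1e-9)

    def test_impulse_matches_kernel_formula(self):
        length, sigma = 101, 2.0
        impulse = np.zeros(length)
        impulse[0] = 1.0
        out = smooth_contour_gaussian(impulse, sigma)
        # direct evaluation of the truncated, renormalized kernel
        radius = int(3.0 * sigma + 0.5)
        k = np.arange(-radius, radius + 1)
        w = np.exp(-(k**2) / (2 * sigma**2))
        w /= w.sum()
        expected = np.zeros(length)
        for kk, ww in zip(k, w):
            expected[kk % length] += ww
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_huge_sigma_averages_periodic_signal(self):
        L = 101
        signal = np.sin(2 * np.pi * np.arange(L) / L)
        out = smooth_contour_gaussian(signal, 10.0 * L)
        assert np.max(np.abs(out)) < 1e-3

    def test_shift_equivariance(self, rng):
        signal = rng.normal(size=60)
        a = np.roll(smooth_contour_gaussian(signal, 3.0), 7)
        b = smooth_contour_gaussian(np.roll(signal, 7), 3.0)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_open_contour_uses_reflection(self):
        signal = np.arange(20.0)
        out = smooth_contour_gaussian(signal, 2.0, closed=False)
        # reflection keeps ends near their values instead of wrapping
        assert abs(out[0] - signal[0]) < abs(signal[-1] - signal[0]) / 4

    def test_nonpositive_sigma_raises(self):
        with pytest.raises(ValueError, match="sigma"):
            smooth_contour_gaussian(np.ones(10), 0.0)


class TestInterpolateBackground:
    def test_single_contour_pixel_constant_field(self):
        c = make_outer_contour([[3, 3]], smoothed=[11.0])
        field = interpolate_background(c, np.ones((8, 8), bool))
        np.testing.assert_allclose(field, 11.0)

    @pytest.mark.parametrize("m", [0.5, 1.0, 2.0, 4.0])
    def test_equidistant_point_averages(self, m):
        c = make_outer_contour([[0, 0], [0, 10]], smoothed=[10.0, 20.0])
        domain = np.zeros((11, 11), bool)
        domain[5, 5] = True  # equidistant from both contour pixels
        field = interpolate_background(c, domain, m=m)
        assert field[5, 5] == pytest.approx(15.0)

    def test_exact_at_contour_pixels(self):
        c = make_outer_contour([[2, 2], [6, 6]], smoothed=[1.0, 9.0])
        field = interpolate_background(c, np.ones((9, 9), bool))
        assert field[2, 2] == 1.0 and field[6, 6] == 9.0

    def test_matches_double_loop_oracle(self, rng):
        n_pts = 40
        angles = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
        pts = np.stack(
            [32 + 20 * np.sin(angles), 32 + 20 * np.cos(angles)], axis=1
        ).astype(int)
        vals = rng.normal(100, 10, n_pts)
        c = make_outer_contour(pts, smoothed=vals)
        domain = np.ones((64, 64), bool)
        field = interpolate_background(c, domain, m=2.0)
        # brute-force double loop over pixels and contour points
        expected = np.zeros((64, 64))
        for r in range(64):
            for col in range(64):
                d2 = (pts[:, 0] - r) ** 2 + (pts[:, 1] - col) ** 2
                if (d2 == 0).any():
                    expected[r, col] = vals[d2.argmin()]
                else:
                    w = 1.0 / d2  # d^m with m = 2
                    expected[r, col] = (w * vals).sum() / w.sum()
        assert np.max(np.abs(field - expected)) < 1e-9

    @given(seed=hst.integers(0, 50))
    @settings(max_examples=15, deadline=None)
    def test_bounded_by_contour_values(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        pts = rng.integers(0, 16, (n, 2))
        vals = rng.normal(0, 10, n)
        c = make_outer_contour(pts, smoothed=vals)
        field = interpolate_background(c, np.ones((16, 16), bool), m=2.0)
        assert field.min() >= vals.min() - 1e-9
        assert field.max() <= vals.max() + 1e-9

    def test_requires_smoothed_intensity(self):
        c = make_outer_contour([[1, 1]])
        with pytest.raises(ValueError, match="smooth"):
            interpolate_background(c, np.ones((4, 4), bool))


class TestNonuniformRatio:
    def test_constant_fields_reduce_to_mbs(self, rng):
        img1 = rng.normal(200, 10, (12, 12))
        img2 = rng.normal(300, 10, (12, 12))
        a = nonuniform_ratio(
            img1, img2, np.full((12, 12), 50.0), np.full((12, 12), 80.0)
        )
        b = mbs_ratio(img1, img2, 50.0, 80.0)
        np.testing.assert_array_equal(a.invalid, b.invalid)
        np.testing.assert_allclose(
            a.ratio[a.valid], b.ratio[b.valid], atol=1e-12
        )

    def test_noise_free_wedge_with_exact_fields(self):
        scene = make_wedge_scene(SceneSpec(noise_sigma1=0, noise_sigma2=0))
        shape = scene.img1.shape
        res = nonuniform_ratio(
            scene.img1, scene.img2, np.full(shape, 120.0), np.full(shape, 100.0)
        )
        inside = scene.truth.S2_field > 0
        assert np.nanmax(np.abs(res.ratio[inside] - 0.7)) < 1e-12

    def test_oversubtracted_edge_pixels_flagged(self):
        img1 = np.full((6, 6), 100.0)
        img2 = np.full((6, 6), 100.0)
        bg2 = np.full((6, 6), 50.0)
        bg2[:, 0] = 150.0  # over-subtraction strip
        res = nonuniform_ratio(img1, img2, np.zeros((6, 6)), bg2)
        assert res.invalid[:, 0].all()
        assert not res.invalid[:, 1:].any()
        assert res.params["n_invalid"] == 6

    def test_matches_per_pixel_loop(self, rng):
        img1 = rng.normal(100, 30, (16, 16))
        img2 = rng.normal(100, 30, (16, 16))
        f1 = rng.normal(20, 5, (16, 16))
        f2 = rng.normal(20, 5, (16, 16))
        res = nonuniform_ratio(img1, img2, f1, f2)
        for r in range(16):
            for c in range(16):
                den = img2[r, c] - f2[r, c]
                if den <= 0:
                    assert res.invalid[r, c]
                else:
                    expected = (img1[r, c] - f1[r, c]) / den
                    assert abs(res.ratio[r, c] - expected) < 1e-12


class TestEstimateNonuniformBackground:
    def test_flat_background_recovered_on_noise_free_scene(self):
        scene = make_wedge_scene(
            SceneSpec(shape=(96, 96), noise_sigma1=0, noise_sigma2=0,
                      cells=[__import__('ncfratio').CellGeometry((48.0, 48.0), 30.0)])
        )
        field = estimate_nonuniform_background(
            scene.img2, scene.truth.mask_true, sigma=5.0
        )
        # outer contour samples the exact constant background B2 = 100
        np.testing.assert_allclose(field, 100.0, atol=1e-9)
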