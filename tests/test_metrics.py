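import math

import numpy as np
import pytest

from echofuse import (
    Contour,
    UndefinedMetricError,
    correlation_coefficient,
    dice_similarity,
    entropy,
    evaluate,
    extract_contour,
    fusion_iqi,
    iqi,
    mean_surface_distance,
    overall_cross_entropy,
    rmse,
    spatial_frequency,
)


class TestRmseAndCorrelation:
    def test_rmse_identity_and_constant_offset(self, rng):
        a = rng.random((8, 8))
        assert rmse(a, a) == 0.0
        assert rmse(a, a + 0.07) == pytest.approx(0.07)

    def test_rmse_hand_arithmetic(self):
        a = np.array([[0.0, 0.0], [0.0, 0.0]])
        b = np.array([[0.3, 0.4], [0.3, 0.4]])
        assert rmse(a, b) == pytest.approx(math.sqrt((0.09 + 0.16) / 2))

    def test_rmse_symmetric(self, random_pair):
        assert rmse(*random_pair) == rmse(*random_pair[::-1])

    def test_cc_identity_and_anticorrelation(self, rng):
        a = rng.random((8, 8))
        assert correlation_coefficient(a, a) == pytest.approx(1.0)
        assert correlation_coefficient(a, 1.0 - a) == pytest.approx(-1.0)

    def test_cc_matches_direct_formula(self, random_pair):
        a, b = random_pair
        x, y = a.ravel() - a.mean(), b.ravel() - b.mean()
        expected = float((x @ y) / math.sqrt((x @ x) * (y @ y)))
        assert correlation_coefficient(a, b) == pytest.approx(expected, abs=1e-12)

    def test_cc_constant_input_undefined(self, rng):
        with pytest.raises(UndefinedMetricError):
            correlation_coefficient(rng.random((8, 8)), np.full((8, 8), 0.5))


def iqi_window_oracle(a, b, window):
    """Straightforward per-window loop implementation of the quality index."""
    h, w = a.shape
    scores = []
    for i in range(h - window + 1):
        for j in range(w - window + 1):
            x = a[i : i + window, j : j + window].ravel()
            y = b[i : i + window, j : j + window].ravel()
            mx, my = x.mean(), y.mean()
            vx, vy = x.var(), y.var()
            cov = ((x - mx) * (y - my)).mean()
            den = (vx + vy) * (mx * mx + my * my)
            if den > 1e-12:
                scores.append(4 * cov * mx * my / den)
            elif mx * mx + my * my > 1e-12:
                scores.append(2 * mx * my / (mx * mx + my * my))
            else:
                scores.append(1.0)
    return float(np.mean(scores))


class TestIqi:
    def test_identity_is_one(self, rng):
        a = rng.random((16, 16))
        assert iqi(a, a) == pytest.approx(1.0)

    def test_luminance_shift_lowers_index(self, rng):
        a = rng.random((16, 16)) * 0.5
        assert iqi(a, a + 0.5) < 1.0

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((20, 24)), rng.random((20, 24))
        assert iqi(a, b, window=7) == pytest.approx(
            iqi_window_oracle(a, b, 7), abs=1e-10
        )

    @pytest.mark.parametrize("window", [2, 8, 1, 33])
    def test_invalid_window_rejected(self, rng, window):
        a = rng.random((16, 16))
        with pytest.raises(ValueError):
            iqi(a, a, window=window)

    def test_fusion_iqi_identity_and_composition(self, rng):
        a, b, f = rng.random((16, 16)), rng.random((16, 16)), rng.random((16, 16))
        assert fusion_iqi(a, a, a) == pytest.approx(1.0)
        assert fusion_iqi(a, a, b) == pytest.approx((1.0 + iqi(a, b)) / 2)
        assert fusion_iqi(f, a, b) == pytest.approx((iqi(f, a) + iqi(f, b)) / 2)


class TestHistogramMetrics:
    def test_oce_identities(self, rng):
        a = rng.random((8, 8))
        assert overall_cross_entropy(a, a, a) == pytest.approx(0.0, abs=1e-9)

    def test_oce_hand_histogram_oracle(self):
        # 2x2 images, 2 bins: occupancies f=(3,1), i1=(2,2), i2=(1,3)
        fused = np.array([[0.1, 0.2], [0.3, 0.9]])
        in1 = np.array([[0.1, 0.2], [0.8, 0.9]])
        in2 = np.array([[0.1, 0.8], [0.7, 0.9]])
        eps = 1e-12

        def kl(p_counts, q_counts):
            p = np.array(p_counts, float) + eps
            q = np.array(q_counts, float) + eps
            p, q = p / p.sum(), q / q.sum()
            return float(np.sum(p * np.log2(p / q)))

        expected = (kl((2, 2), (3, 1)) + kl((1, 3), (3, 1))) / 2
        assert overall_cross_entropy(fused, in1, in2, bins=2) == pytest.approx(
            expected, abs=1e-12
        )

    def test_oce_symmetric_in_inputs(self, rng):
        f, a, b = rng.random((8, 8)), rng.random((8, 8)), rng.random((8, 8))
        assert overall_cross_entropy(f, a, b) == pytest.approx(
            overall_cross_entropy(f, b, a)
        )

    def test_entropy_limits(self):
        assert entropy(np.full((8, 8), 0.5)) == pytest.approx(0.0)
        half = np.zeros((8, 8))
        half[:4] = 1.0
        assert entropy(half, bins=256) == pytest.approx(1.0)
        uniform = (np.arange(256.0).reshape(16, 16) + 0.5) / 256.0
        assert entropy(uniform, bins=256) == pytest.approx(8.0)

    def test_bad_bins_rejected(self, rng):
        with pytest.raises(ValueError):
            entropy(rng.random((8, 8)), bins=1)


class TestSpatialFrequency:
    def test_constant_is_zero(self):
        assert spatial_frequency(np.full((8, 8), 0.3)) == 0.0

    def test_alternating_columns(self):
        stripes = np.tile([0.0, 1.0], (8, 4))
        assert spatial_frequency(stripes) == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        img = rng.random((10, 13))
        h, w = img.shape
        rf = math.sqrt(
            sum((img[i, j + 1] - img[i, j]) ** 2 for i in range(h) for j in range(w - 1))
            / (h * (w - 1))
        )
        cf = math.sqrt(
            sum((img[i + 1, j] - img[i, j]) ** 2 for i in range(h - 1) for j in range(w))
            / ((h - 1) * w)
        )
        assert spatial_frequency(img) == pytest.approx(
            math.sqrt(rf**2 + cf**2), abs=1e-12
        )


class TestDice:
    def test_identity_disjoint_and_half_overlap(self):
        a = np.zeros((20, 20), bool)
        a[:10, :10] = True  # |A| = 100
        b = np.zeros((20, 20), bool)
        b[5:15, :10] = True  # |B| = 100, overlap 50
        c = np.zeros((20, 20), bool)
        c[10:, 10:] = True
        assert dice_similarity(a, a) == 1.0
        assert dice_similarity(a, c) == 0.0
        assert dice_similarity(a, b) == pytest.approx(0.5)

    def test_symmetric(self, rng):
        a = rng.random((12, 12)) > 0.5
        b = rng.random((12, 12)) > 0.5
        assert dice_similarity(a, b) == dice_similarity(b, a)

    def test_both_empty_undefined(self):
        with pytest.raises(UndefinedMetricError):
            dice_similarity(np.zeros((4, 4), bool), np.zeros((4, 4), bool))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            dice_similarity(np.full((4, 4), 0.5), np.zeros((4, 4), bool))


def square_contour_points(top, left, size):
    pts = set()
    for k in range(size):
        pts |= {(top, left + k), (top + size - 1, left + k),
                (top + k, left), (top + k, left + size - 1)}
    return np.array(sorted(pts))


class TestSurfaceDistance:
    def test_extracted_boundary_touches_background(self):
        mask = np.zeros((16, 16), bool)
        mask[4:12, 5:11] = True
        contour = extract_contour(mask)
        for r, c in contour.boundary_pixels:
            assert mask[r, c]
            neighbors = [
                mask[r + dr, c + dc]
                if 0 <= r + dr < 16 and 0 <= c + dc < 16 else False
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
            ]
            assert not all(neighbors)

    def test_square_mask_boundary_matches_construction(self):
        mask = np.zeros((16, 16), bool)
        mask[4:10, 4:10] = True
        contour = extract_contour(mask)
        np.testing.assert_array_equal(
            np.array(sorted(map(tuple, contour.boundary_pixels))),
            square_contour_points(4, 4, 6),
        )

    def test_identical_contours_distance_zero(self):
        c = Contour(square_contour_points(2, 2, 5))
        assert mean_surface_distance(c, c) == 0.0

    def test_single_pixel_contours(self):
        a = Contour(np.array([[2, 2]]))
        b = Contour(np.array([[2, 5]]))
        assert mean_surface_distance(a, b) == pytest.approx(3.0)

    def test_shifted_square_matches_all_pairs_oracle(self):
        spacing = 0.5
        pts_a = square_contour_points(3, 3, 8)
        pts_b = square_contour_points(4, 3, 8)  # shifted one row down
        d_ab = np.array([
            min(math.dist(p, q) for q in pts_b) for p in pts_a
        ]).mean()
        d_ba = np.array([
            min(math.dist(p, q) for q in pts_a) for p in pts_b
        ]).mean()
        expected = 0.5 * (d_ab + d_ba) * spacing
        got = mean_surface_distance(
            Contour(pts_a, spacing), Contour(pts_b, spacing)
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_spacing_mismatch_rejected(self):
        a = Contour(np.array([[1, 1]]), pixel_spacing=1.0)
        b = Contour(np.array([[1, 2]]), pixel_spacing=0.5)
        with pytest.raises(ValueError):
            mean_surface_distance(a, b)

    def test_empty_mask_has_no_contour(self):
        with pytest.raises(UndefinedMetricError):
            extract_contour(np.zeros((8, 8), bool))


class TestMonotoneDegradation:
    def test_rmse_grows_and_cc_falls_with_noise(self):
        """Statistical check over seeds: heavier additive noise moves the
        metrics in the expected direction on average."""
        base = np.random.default_rng(0).random((32, 32)) * 0.5 + 0.25
        sigmas = [0.01, 0.05, 0.1, 0.2]
        mean_rmse, mean_cc = [], []
        for sigma in sigmas:
            rs, cs = [], []
            for seed in range(10):
                noisy = base + sigma * np.random.default_rng(seed).standard_normal(
                    base.shape
                )
                rs.append(rmse(base, noisy))
                cs.append(correlation_coefficient(base, noisy))
            mean_rmse.append(np.mean(rs))
            mean_cc.append(np.mean(cs))
        assert all(x < y for x, y in zip(mean_rmse, mean_rmse[1:]))
        assert all(x > y for x, y in zip(mean_cc, mean_cc[1:]))


class TestEvaluate:
    def test_identity_report(self, rng):
        a = rng.random((16, 16))
        report = evaluate(a, a, a, reference=a)
        assert report.reference_convention == "reference"
        assert report.values["iqi"] == pytest.approx(1.0)
        assert report.values["rmse"] == 0.0
        assert report.values["cc"] == pytest.approx(1.0)
        assert report.values["oce"] == pytest.approx(0.0, abs=1e-9)

    def test_report_schema(self, rng):
        a, b, f = rng.random((16, 16)), rng.random((16, 16)), rng.random((16, 16))
        report = evaluate(f, a, b)
        assert set(report.values) == {
            "iqi", "rmse", "cc", "oce", "entropy", "spatial_frequency"
        }
        assert report.reference_convention == "input_mean"

    def test_values_match_individual_metric_calls(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        f, t = rng.random((16, 16)), rng.random((16, 16))
        report = evaluate(f, a, b, reference=t, bins=64, window=5)
        assert report.values["iqi"] == fusion_iqi(f, a, b, 5)
        assert report.values["rmse"] == rmse(f, t)
        assert report.values["cc"] == correlation_coefficient(f, t)
        assert report.values["oce"] == overall_cross_entropy(f, a, b, 64)
        assert report.values["entropy"] == entropy(f, 64)
        assert report.values["spatial_frequency"] == spatial_frequency(f)
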