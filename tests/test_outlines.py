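import numpy as np
import pytest

from _oracles import procrustes_two_shape_distance
from scallopop import (
    EFACoefficients,
    LandmarkConfig,
    OutlineShape,
    efa_coefficients,
    gpa_align,
    harmonic_power_calibration,
    inverse_efa,
    normalize_start,
    rasterize_outline,
    resample_equal,
    smooth_outline,
    trace_outline,
)


def ellipse_points(a, b, n, phase=0.0):
    t = 2 * np.pi * np.arange(n) / n + phase
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


def make_config(points):
    c = points - points.mean(axis=0)
    return LandmarkConfig(points, float(np.sqrt((c**2).sum())))


class TestTraceOutline:
    def test_filled_square_boundary_pixel_count(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True  # 10x10 square: 36 boundary pixels
        out = trace_outline(mask)
        assert len(out.points) == 36
        assert out.orientation == "counterclockwise"
        # every chain pixel borders the background (flood comparison)
        interior = mask.copy()
        interior[3:11, 3:11] = False
        boundary = {(x, y) for y, x in zip(*np.nonzero(interior))}
        assert {tuple(p) for p in out.points.astype(int)} == boundary

    def test_too_small_component_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        with pytest.raises(ValueError):
            trace_outline(mask)

    def test_multiple_components_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        with pytest.raises(ValueError, match="2"):
            trace_outline(mask)

    def test_mirror_symmetry(self):
        mask = np.zeros((20, 24), dtype=bool)
        mask[4:16, 4:14] = True
        mask[6:10, 14:18] = True
        a = trace_outline(mask)
        b = trace_outline(mask[:, ::-1])
        mirrored = b.points.copy()
        mirrored[:, 0] = mask.shape[1] - 1 - mirrored[:, 0]
        sa = {tuple(p) for p in a.points.astype(int)}
        sb = {tuple(p) for p in mirrored.astype(int)}
        assert sa == sb


class TestSmoothOutline:
    def test_zero_iterations_is_identity(self):
        o = OutlineShape(ellipse_points(2, 1, 40))
        assert np.array_equal(smooth_outline(o, 0).points, o.points)

    def test_circle_shrinks_isotropically(self):
        o = OutlineShape(ellipse_points(1, 1, 100))
        s = smooth_outline(o, 1)
        radii = np.hypot(s.points[:, 0], s.points[:, 1])
        assert np.ptp(radii) < 1e-9
        # closed-form factor of the cyclic 3-point average on a circle
        expected = (1 + 2 * np.cos(2 * np.pi / 100)) / 3
        assert radii[0] == pytest.approx(expected, abs=1e-12)

    def test_zigzag_total_curvature_decreases(self):
        t = 2 * np.pi * np.arange(60) / 60
        r = 1.0 + 0.15 * (-1) ** np.arange(60)
        o = OutlineShape(np.column_stack([r * np.cos(t), r * np.sin(t)]))

        def total_curvature(pts):
            d = np.roll(pts, -1, axis=0) - pts
            ang = np.arctan2(d[:, 1], d[:, 0])
            turn = np.angle(np.exp(1j * (np.roll(ang, -1) - ang)))
            return np.abs(turn).sum()

        assert total_curvature(smooth_outline(o, 1).points) < total_curvature(o.points)


class TestResampleEqual:
    def test_unit_square_eight_points(self):
        sq = OutlineShape(np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]]))
        cfg = resample_equal(sq, 8)
        expected = np.array(
            [[0, 0], [0.5, 0], [1, 0], [1, 0.5], [1, 1], [0.5, 1], [0, 1], [0, 0.5]]
        )
        assert np.allclose(cfg.points, expected, atol=1e-12)

    def test_identity_on_equispaced_circle(self):
        pts = ellipse_points(1, 1, 64)
        cfg = resample_equal(OutlineShape(pts), 64)
        assert np.allclose(cfg.points, pts, atol=1e-9)

    def test_perimeter_preserved(self, rng):
        pts = ellipse_points(3, 1.5, 50) + rng.normal(0, 0.01, (50, 2))
        o = OutlineShape(pts)
        cfg = resample_equal(o, 500)
        per_in = o.perimeter()
        per_out = OutlineShape(cfg.points).perimeter()
        assert per_out <= per_in + 1e-6

    def test_equal_arc_gaps(self):
        o = OutlineShape(ellipse_points(2, 1, 37))
        cfg = resample_equal(o, 100)
        # verify by re-measuring arc positions on the source polyline
        closed = np.vstack([o.points, o.points[:1]])
        seg = np.diff(closed, axis=0)
        cum = np.concatenate([[0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
        target = np.arange(100) * cum[-1] / 100
        x = np.interp(target, cum, closed[:, 0])
        assert np.allclose(cfg.points[:, 0], x, atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            resample_equal(OutlineShape(ellipse_points(1, 1, 10)), 2)


class TestGPA:
    def test_similarity_invariance(self, rng):
        base = ellipse_points(2, 1, 60) + rng.normal(0, 0.05, (60, 2))
        th = np.deg2rad(37)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        variants = [base, base @ R.T, base + [4.0, -2.0], base * 3.0]
        aligned, mean = gpa_align([make_config(v) for v in variants])
        for cfg in aligned[1:]:
            assert np.allclose(cfg.points, aligned[0].points, atol=1e-7)
        assert np.allclose(mean, aligned[0].points, atol=1e-7)

    def test_idempotence(self, rng):
        shapes = [ellipse_points(2, 1, 40) + rng.normal(0, 0.1, (40, 2)) for _ in range(5)]
        once, _ = gpa_align([make_config(s) for s in shapes])
        twice, _ = gpa_align(once)
        for a, b in zip(once, twice):
            assert np.allclose(a.points, b.points, atol=1e-9)

    def test_unit_size_and_zero_centroid_after_alignment(self, rng):
        shapes = [ellipse_points(2, 1, 30) + rng.normal(0, 0.1, (30, 2)) for _ in range(4)]
        aligned, _ = gpa_align([make_config(s) for s in shapes])
        for cfg in aligned:
            assert np.allclose(cfg.points.mean(axis=0), 0.0, atol=1e-9)
            assert np.sqrt((cfg.points**2).sum()) == pytest.approx(1.0, abs=1e-9)

    def test_two_shape_residual_matches_closed_form(self, rng):
        A = ellipse_points(2, 1, 50) + rng.normal(0, 0.1, (50, 2))
        B = ellipse_points(2, 1, 50) + rng.normal(0, 0.1, (50, 2))
        aligned, _ = gpa_align([make_config(A), make_config(B)])
        resid = np.sqrt(((aligned[0].points - aligned[1].points) ** 2).sum())
        assert resid == pytest.approx(procrustes_two_shape_distance(A, B), abs=1e-8)

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ValueError):
            gpa_align([LandmarkConfig(np.ones((10, 2)) * 0 + 1e-300 + 1, 1.0)])


class TestEFA:
    def test_ellipse_harmonic_one(self):
        pts = ellipse_points(2, 1, 4000)
        c = efa_coefficients(pts, 5, parameterization="uniform")
        assert np.allclose(c.harmonics[0], [2, 0, 0, 1], atol=1e-6)
        assert np.all(c.power()[1:] < 1e-10)

    def test_circle_power(self):
        pts = ellipse_points(3, 3, 300_000)
        c = efa_coefficients(pts, 3, parameterization="uniform")
        assert c.power()[0] == pytest.approx(9.0, abs=1e-9)
        assert np.all(c.power()[1:] < 1e-9)

    def test_round_trip_recovers_coefficients(self, rng):
        h = rng.normal(0, 1, (10, 4)) * (0.6 ** np.arange(10))[:, None]
        h[0] = (2.0, 0.1, -0.1, 1.0)
        c0 = EFACoefficients(h, a0=0.5, c0=-0.3)
        o = inverse_efa(c0, 20_000)
        c1 = efa_coefficients(o, 10, parameterization="uniform")
        assert np.allclose(c1.harmonics, h, atol=1e-6)
        assert c1.a0 == pytest.approx(0.5, abs=1e-9)
        assert c1.c0 == pytest.approx(-0.3, abs=1e-9)

    def test_inverse_of_single_harmonic_is_exact_ellipse(self):
        c = EFACoefficients(np.array([[2.0, 0.0, 0.0, 1.0]]))
        o = inverse_efa(c, 500)
        resid = (o.points[:, 0] / 2) ** 2 + o.points[:, 1] ** 2 - 1.0
        assert np.all(np.abs(resid) < 1e-9)

    def test_linearity_under_scaling(self):
        c = EFACoefficients(np.array([[2.0, 0.0, 0.0, 1.0], [0.1, 0.05, 0.0, 0.02]]))
        c2 = EFACoefficients(2 * c.harmonics)
        a = inverse_efa(c, 100).points
        b = inverse_efa(c2, 100).points
        assert np.allclose(b, 2 * a, atol=1e-12)

    def test_start_point_invariance_of_total_power(self):
        pts = ellipse_points(2, 1, 600, phase=0.0)
        shifted = np.roll(pts, 123, axis=0)
        p1 = efa_coefficients(resample_equal(OutlineShape(pts), 500), 10).power().sum()
        p2 = efa_coefficients(resample_equal(normalize_start(OutlineShape(shifted)), 500), 10).power().sum()
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_invalid_inputs(self):
        pts = ellipse_points(1, 1, 20)
        with pytest.raises(ValueError):
            efa_coefficients(pts, 0)
        with pytest.raises(ValueError):
            efa_coefficients(pts, 10)  # >= k/2


class TestHarmonicCalibration:
    def test_pure_ellipse_needs_one_harmonic(self):
        sets = [efa_coefficients(ellipse_points(2, 1, 500), 5, parameterization="uniform")
                for _ in range(3)]
        n, _ = harmonic_power_calibration(sets, threshold=0.98, exclude_first=False)
        assert n == 1

    def test_residual_spectrum_hand_example(self):
        # powers (100, 49, 1): excluding harmonic 1, 49/50 = 0.98 at N=2
        h = np.zeros((3, 4))
        h[0, 0] = np.sqrt(200.0)
        h[1, 0] = np.sqrt(98.0)
        h[2, 0] = np.sqrt(2.0)
        n, curve = harmonic_power_calibration([EFACoefficients(h)], 0.98, exclude_first=True)
        assert n == 2
        assert curve[0] == pytest.approx(0.98)

    def test_threshold_one_needs_all_power(self):
        h = np.zeros((4, 4))
        h[0, 0] = 2.0
        h[1, 0] = 1.0
        h[2, 0] = 0.5
        n, _ = harmonic_power_calibration([EFACoefficients(h)], 1.0, exclude_first=False)
        assert n == 3

    def test_invalid_threshold(self):
        h = np.ones((2, 4))
        with pytest.raises(ValueError):
            harmonic_power_calibration([EFACoefficients(h)], 1.5)


class TestRasterRoundTrip:
    def test_trace_of_rasterized_outline_recovers_shape(self):
        c = EFACoefficients(np.array([[1.0, 0.0, 0.0, 0.8], [0.05, 0.0, 0.0, 0.04]]))
        outline = inverse_efa(c, 600)
        mask = rasterize_outline(outline, (512, 512))
        traced = trace_outline(mask)
        # compare in a scale-free way: nearest-distance from traced chain to
        # the scaled source outline, in pixels
        pts = outline.points
        lo = pts.min(axis=0)
        span = pts.max(axis=0) - lo
        scale = min((512 - 17) / span[0], (512 - 17) / span[1])
        ref = (pts - lo) * scale + 8
        d = np.sqrt(
            ((traced.points[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
        ).min(axis=1)
        assert d.mean() < 1.0
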