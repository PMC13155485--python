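"""Envelope, contour, angular-profile, autocorrelation and metric checks."""

import numpy as np
import pytest

from sparse_sizer.metrics import (
    AutocorrCurve,
    Envelope,
    FrameStack,
    annular_angular_profile,
    compute_envelope,
    compute_g2,
    contour_at_threshold,
    extract_metrics,
    metric_X1,
    metric_X2,
    metric_X3,
    metric_X4,
    peak_radial_fraction,
)


def gaussian_envelope(n=256, pitch=0.01, scale=0.5, c2=0.0, c4=0.0, axis_deg=0.0):
    xs = (np.arange(n) + 0.5 - n / 2) * pitch
    X, Y = np.meshgrid(xs, xs)
    R = np.hypot(X, Y)
    phi = (np.degrees(np.arctan2(Y, X)) - axis_deg + 90.0) % 360.0
    img = np.exp(-(R**2) / (2 * scale**2)) * (1 + c2 * np.cos(2 * np.radians(phi))
                                              + c4 * np.cos(4 * np.radians(phi)))
    return Envelope(image=img / img.max(), pixel_pitch=pitch, channel="co",
                    polarization_axis_deg=axis_deg)


class TestEnvelope:
    def test_constant_stack_gives_flat_envelope(self):
        frames = np.full((4, 32, 32), 3.0)
        st = FrameStack(frames=frames, frame_rate=100, exposure=1e-3,
                        pixel_pitch=0.01, channel="co")
        env = compute_envelope(st, smooth=0)
        assert np.allclose(env.image, 1.0)

    def test_envelope_recovers_generator_profile(self):
        rng = np.random.default_rng(0)
        xs = (np.arange(128) + 0.5 - 64) * 0.01
        X, Y = np.meshgrid(xs, xs)
        profile = np.exp(-(X**2 + Y**2) / (2 * 0.3**2))
        frames = rng.exponential(1.0, (200, 128, 128)) * profile
        st = FrameStack(frames=frames, frame_rate=100, exposure=1e-3,
                        pixel_pitch=0.01, channel="co")
        env = compute_envelope(st)
        core = profile > 0.1
        assert np.sqrt(np.mean((env.image - profile)[core] ** 2)) < 0.05

    def test_envelope_invariant_to_frame_order(self):
        rng = np.random.default_rng(1)
        frames = rng.exponential(1.0, (16, 16, 16))
        st1 = FrameStack(frames=frames, frame_rate=10, exposure=0.01,
                         pixel_pitch=0.01, channel="co")
        st2 = FrameStack(frames=frames[::-1].copy(), frame_rate=10, exposure=0.01,
                         pixel_pitch=0.01, channel="co")
        assert np.allclose(compute_envelope(st1, smooth=0).image,
                           compute_envelope(st2, smooth=0).image)

    def test_all_zero_stack_rejected(self):
        st = FrameStack(frames=np.zeros((4, 8, 8)), frame_rate=10, exposure=0.01,
                        pixel_pitch=0.01, channel="co")
        with pytest.raises(ValueError):
            compute_envelope(st)


class TestContour:
    def test_circular_contour_geometry(self):
        env = gaussian_envelope()
        geom = contour_at_threshold(env)
        r = 0.5 * np.sqrt(2 * np.log(1 / 0.3))
        assert geom.area_A == pytest.approx(np.pi * r**2, rel=5e-3)
        assert geom.perimeter_P == pytest.approx(2 * np.pi * r, rel=5e-3)
        assert geom.r_inner == pytest.approx(r, rel=5e-3)
        assert geom.r_outer == pytest.approx(r, rel=5e-3)

    def test_ellipse_area_and_perimeter_vs_polygon_oracle(self):
        n, pitch = 512, 0.01
        xs = (np.arange(n) + 0.5 - n / 2) * pitch
        X, Y = np.meshgrid(xs, xs)
        a_ax, b_ax = 1.4, 0.7
        img = np.exp(-(X**2 / a_ax**2 + Y**2 / b_ax**2))
        env = Envelope(image=img / img.max(), pixel_pitch=pitch, channel="cross")
        geom = contour_at_threshold(env)
        s = np.sqrt(np.log(1 / 0.3))
        sa, sb = a_ax * s, b_ax * s
        assert geom.area_A == pytest.approx(np.pi * sa * sb, rel=5e-3)
        t = np.linspace(0, 2 * np.pi, 100_000)
        oracle = np.hypot(np.diff(sa * np.cos(t)), np.diff(sb * np.sin(t))).sum()
        assert geom.perimeter_P == pytest.approx(oracle, rel=5e-3)

    def test_flat_envelope_has_no_contour(self):
        img = np.full((64, 64), 1.0)
        img[0, 0] = 0.999  # max must be 1 exactly after normalization
        env = Envelope(image=img / img.max(), pixel_pitch=0.01, channel="co")
        with pytest.raises(ValueError):
            contour_at_threshold(env)

    def test_four_lobed_contour_not_circular(self):
        env = gaussian_envelope(c4=0.25)
        geom = contour_at_threshold(env)
        assert metric_X2(geom) < 0.99


class TestAngularProfile:
    def test_isotropic_profile_constant(self):
        env = gaussian_envelope()
        geom = contour_at_threshold(env)
        _, prof = annular_angular_profile(env, geom)
        # thin annulus of a circular contour: pixelation noise only
        assert np.ptp(prof) / prof.mean() < 0.08

    def test_cos4_modulation_recovered(self):
        env = gaussian_envelope(c4=0.25)
        geom = contour_at_threshold(env)
        bins, prof = annular_angular_profile(env, geom)
        norm = prof / prof.mean()
        expected = 1 + 0.25 * np.cos(4 * np.radians(bins))
        expected = expected / expected.mean()
        assert np.max(np.abs(norm - expected)) < 0.06
        peaks = bins[np.nonzero(norm > norm.max() * 0.999)]
        for target in (0.0, 90.0, 180.0, 270.0):
            assert np.min(np.abs((peaks - target + 180) % 360 - 180)) < 6.0

    def test_rotating_envelope_swaps_axes(self):
        e0 = gaussian_envelope(c2=0.3, axis_deg=0.0)
        e90 = Envelope(image=np.rot90(e0.image).copy(), pixel_pitch=e0.pixel_pitch,
                       channel="co", polarization_axis_deg=0.0)
        g0 = contour_at_threshold(e0)
        g90 = contour_at_threshold(e90)
        b0, p0 = annular_angular_profile(e0, g0)
        b90, p90 = annular_angular_profile(e90, g90)
        x1_0 = metric_X1(b0, p0)
        x1_90 = metric_X1(b90, p90)
        assert x1_0 == pytest.approx(1 / x1_90, rel=0.02)


class TestMetrics:
    def test_x1_isotropic_is_unity(self):
        env = gaussian_envelope()
        geom = contour_at_threshold(env)
        bins, prof = annular_angular_profile(env, geom)
        assert metric_X1(bins, prof) == pytest.approx(1.0, abs=0.01)

    def test_x1_cos4_symmetric_is_unity(self):
        env = gaussian_envelope(c4=0.25)
        geom = contour_at_threshold(env)
        bins, prof = annular_angular_profile(env, geom)
        assert metric_X1(bins, prof) == pytest.approx(1.0, abs=0.02)

    def test_x1_dipole_below_unity(self):
        # elongated along the polarization axis (φ = 90°): X1 < 1
        env = gaussian_envelope(c2=-0.3)
        geom = contour_at_threshold(env)
        bins, prof = annular_angular_profile(env, geom)
        assert metric_X1(bins, prof) < 0.9

    def test_x2_circle_and_square(self):
        env = gaussian_envelope()
        assert metric_X2(contour_at_threshold(env)) == pytest.approx(1.0, abs=5e-3)
        from sparse_sizer.metrics import ContourGeometry
        s = 1.0
        square = np.array([[0, 0], [s, 0], [s, s], [0, s], [0, 0]], float)
        geom = ContourGeometry(polyline=square, centroid=np.array([0.5, 0.5]),
                               r_inner=0.5, r_outer=np.sqrt(0.5), area_A=1.0,
                               perimeter_P=4.0)
        assert metric_X2(geom) == pytest.approx(np.pi / 4)

    def test_x4_closed_forms(self):
        env = gaussian_envelope()
        geom = contour_at_threshold(env)
        r = 0.5 * np.sqrt(2 * np.log(1 / 0.3))
        assert metric_X4(geom) == pytest.approx(r, rel=5e-3)
        from sparse_sizer.metrics import ContourGeometry
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        geom = ContourGeometry(polyline=square, centroid=np.array([0.5, 0.5]),
                               r_inner=0.5, r_outer=np.sqrt(0.5), area_A=1.0,
                               perimeter_P=4.0)
        assert metric_X4(geom) == pytest.approx(1 / np.sqrt(np.pi))

    def test_x4_scales_with_pixel_pitch_x2_invariant(self):
        e1 = gaussian_envelope(pitch=0.01, c4=0.15)
        e2 = Envelope(image=e1.image, pixel_pitch=0.02, channel="co")
        g1, g2 = contour_at_threshold(e1), contour_at_threshold(e2)
        assert metric_X4(g2) == pytest.approx(2 * metric_X4(g1), rel=1e-9)
        assert metric_X2(g2) == pytest.approx(metric_X2(g1), rel=1e-9)

    def test_x3_identical_curves_degenerate(self):
        lags = np.geomspace(1e-4, 1.0, 64)
        c = AutocorrCurve(lags=lags, g2=np.exp(-2 * lags / 0.01))
        x3, _, degenerate = metric_X3(c, c)
        assert x3 == 1.0 and degenerate

    def test_x3_exponential_ratio(self):
        lags = np.geomspace(1e-4, 1.0, 200)
        tau = 0.02
        co = AutocorrCurve(lags=lags, g2=np.exp(-2 * lags / tau))
        cx = AutocorrCurve(lags=lags, g2=np.exp(-2 * lags / (tau / 2)))
        x3, t_max, degenerate = metric_X3(co, cx)
        assert not degenerate
        assert x3 == pytest.approx(2.0, rel=1e-3)  # up to lag-resampling interp
        band_co = np.exp(-2 * t_max / tau)
        assert 0.05 < band_co < 0.95

    def test_peak_radial_fraction_central_and_annular(self):
        env = gaussian_envelope()
        geom = contour_at_threshold(env)
        assert peak_radial_fraction(env, geom) < 0.1
        n, pitch = 256, 0.01
        xs = (np.arange(n) + 0.5 - n / 2) * pitch
        X, Y = np.meshgrid(xs, xs)
        R = np.hypot(X, Y)
        geom0 = contour_at_threshold(env)
        ring_r = 0.7 * metric_X4(geom0)
        img = np.exp(-((R - ring_r) ** 2) / (2 * 0.25**2))
        ring = Envelope(image=img / img.max(), pixel_pitch=pitch, channel="cross")
        geom_ring = contour_at_threshold(ring)
        frac = peak_radial_fraction(ring, geom_ring)
        assert frac == pytest.approx(ring_r / metric_X4(geom_ring), abs=0.03)

    def test_peak_radial_fraction_rotation_invariant(self):
        n, pitch = 256, 0.01
        xs = (np.arange(n) + 0.5 - n / 2) * pitch
        X, Y = np.meshgrid(xs, xs)
        img = np.exp(-((X - 0.3) ** 2 + Y**2) / (2 * 0.2**2)) + \
            0.5 * np.exp(-(X**2 + Y**2) / (2 * 0.6**2))
        env = Envelope(image=img / img.max(), pixel_pitch=pitch, channel="cross")
        rot = Envelope(image=np.rot90(img / img.max()).copy(), pixel_pitch=pitch,
                       channel="cross")
        f1 = peak_radial_fraction(env, contour_at_threshold(env))
        f2 = peak_radial_fraction(rot, contour_at_threshold(rot))
        assert f1 == pytest.approx(f2, rel=0.05)


class TestComputeG2:
    def test_identical_stacks_identical_curves(self, synthetic_pair):
        a = compute_g2(synthetic_pair["co"])
        b = compute_g2(synthetic_pair["co"])
        assert np.array_equal(a.g2, b.g2)

    def test_siegert_relation_on_generator_truth(self, synthetic_pair):
        """Contrast-normalized g2 equals |g1|²/|g1(t0)|² of the generator."""
        g2 = compute_g2(synthetic_pair["co"])
        tau = synthetic_pair["dyn_co"].tau_c
        t0 = g2.lags[0]
        pred = np.exp(-2 * (g2.lags - t0) / tau)
        sel = pred > 0.05
        assert np.max(np.abs(g2.g2[sel] - pred[sel])) < 0.05

    def test_frame_rate_metadata_scales_lags(self, synthetic_pair):
        st = synthetic_pair["co"]
        st2 = FrameStack(frames=st.frames, frame_rate=2 * st.frame_rate,
                         exposure=st.exposure, pixel_pitch=st.pixel_pitch,
                         channel=st.channel)
        a, b = compute_g2(st), compute_g2(st2)
        assert np.allclose(b.lags, a.lags / 2)
        assert np.allclose(a.g2, b.g2)

    def test_static_stack_rejected_for_contrast(self):
        frames = np.full((128, 32, 32), 2.0) + np.random.default_rng(0).normal(
            0, 1e-3, (128, 32, 32)
        )
        st = FrameStack(frames=np.abs(frames), frame_rate=100, exposure=1e-3,
                        pixel_pitch=0.01, channel="co")
        with pytest.raises(ValueError, match="contrast"):
            compute_g2(st)


class TestExtractMetrics:
    def test_simulated_extraction_deterministic(self, small_particle_grid):
        a = extract_metrics(small_particle_grid, small_particle_grid,
                            polarization_axis_deg=90.0)
        b = extract_metrics(small_particle_grid, small_particle_grid,
                            polarization_axis_deg=90.0)
        assert (a.X1, a.X2, a.X3, a.X4) == (b.X1, b.X2, b.X3, b.X4)

    def test_small_particle_x3_above_unity(self, small_particle_grid):
        mv = extract_metrics(small_particle_grid, small_particle_grid,
                             polarization_axis_deg=90.0)
        assert mv.X3 > 1.0

    def test_swapping_channels_inverts_x3(self, synthetic_pair):
        mv = extract_metrics(synthetic_pair["co"], synthetic_pair["cross"])
        co_sw = FrameStack(frames=synthetic_pair["cross"].frames,
                           frame_rate=1000.0, exposure=1e-3, pixel_pitch=0.006,
                           channel="co")
        cx_sw = FrameStack(frames=synthetic_pair["co"].frames,
                           frame_rate=1000.0, exposure=1e-3, pixel_pitch=0.006,
                           channel="cross")
        mv_sw = extract_metrics(co_sw, cx_sw)
        assert mv_sw.X3 == pytest.approx(1 / mv.X3, rel=0.05)
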