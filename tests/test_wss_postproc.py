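import numpy as np
import pytest

from pulmobif import morphometry as mm
from pulmobif import synthetic_data as sd
from pulmobif import wss_postproc as wp
from pulmobif.io_formats import RawCenterline, WallFieldSeries

def _series(surface, mags, period=0.8, direction=(1.0, 0.0, 0.0)):
    """Wall field with uniform per-step magnitudes along one direction."""
    t = np.linspace(0.0, period, len(mags))
    e = np.asarray(direction) / np.linalg.norm(direction)
    tau = np.asarray(mags)[:, None, None] * np.broadcast_to(
        e, (surface.n_vertices, 3)
    )
    return WallFieldSeries(surface=surface, t_s=t, tau=tau.copy(), period_T=period)


class TestTawss:
    def test_constant_magnitude(self, tube_surface):
        series = _series(tube_surface, np.full(16, 2.0))
        assert np.allclose(wp.tawss(series), 2.0)

    def test_rectified_sine_closed_form(self, tube_surface):
        t = np.linspace(0.0, 0.8, 65)
        series = _series(tube_surface, np.sin(2 * np.pi * t / 0.8))
        tw = wp.tawss(series)
        assert np.allclose(tw, 2.0 / np.pi, rtol=0.005)

    def test_poiseuille_synthetic_field(self, tube_surface):
        from pulmobif.flow_characterization import FlowWaveform

        wf = FlowWaveform(
            t=np.linspace(0, 0.8, 32, endpoint=False),
            Q=np.full(32, 10.0),
            period_T=0.8,
        )
        series, gt = sd.generate_wall_field(
            tube_surface, "poiseuille_scaled", waveform=wf, period_s=0.8,
            tube_radius_mm=10.0,
        )
        assert np.allclose(wp.tawss(series), 0.0509, atol=0.0002)
        assert gt.tawss_pa == pytest.approx(0.0509, abs=0.0002)

    def test_time_resolution_convergence(self, tube_surface):
        f = lambda t: 1.5 + np.sin(2 * np.pi * t / 0.8) + 0.3 * np.cos(
            4 * np.pi * t / 0.8
        )
        t64 = np.linspace(0, 0.8, 65)
        t128 = np.linspace(0, 0.8, 129)
        tw64 = wp.tawss(_series(tube_surface, f(t64)))[0]
        tw128 = wp.tawss(_series(tube_surface, f(t128)))[0]
        assert abs(tw128 - tw64) / tw64 < 0.002

    def test_cyclic_shift_invariance(self, tube_surface):
        t = np.linspace(0.0, 0.8, 33)
        mags = 1.0 + 0.5 * np.sin(2 * np.pi * t / 0.8)
        tw0 = wp.tawss(_series(tube_surface, mags))[0]
        shifted = np.concatenate([mags[8:-1], mags[:8], [mags[8]]])
        tw1 = wp.tawss(_series(tube_surface, shifted))[0]
        assert tw1 == pytest.approx(tw0, rel=1e-9)

    def test_non_periodic_grid_rejected(self, tube_surface):
        series = _series(tube_surface, np.full(8, 1.0))
        series.t_s = series.t_s * 0.5  # no longer spans [0, T]
        with pytest.raises(ValueError, match="span"):
            wp.tawss(series)


class TestOsi:
    def test_constant_direction_zero(self, tube_surface):
        series = _series(tube_surface, np.full(16, 2.0))
        assert np.allclose(wp.osi(series), 0.0)

    def test_zero_mean_oscillation_half(self, tube_surface):
        t = np.linspace(0.0, 0.8, 129)
        series = _series(tube_surface, np.sin(2 * np.pi * t / 0.8))
        assert np.allclose(wp.osi(series), 0.5, atol=1e-6)

    def test_randomized_fields_bounded(self, tube_surface):
        rng = np.random.default_rng(0)
        n = tube_surface.n_vertices
        for _ in range(5):
            t = np.linspace(0.0, 0.8, 17)
            tau = rng.normal(size=(17, n, 3))
            tau[-1] = tau[0]
            series = WallFieldSeries(
                surface=tube_surface, t_s=t, tau=tau, period_T=0.8
            )
            o = wp.osi(series)
            assert np.all(o >= 0.0) and np.all(o <= 0.5)


class TestNormalization:
    def test_uniform_field_ratio_one(self, tube_surface):
        field = np.full(tube_surface.n_vertices, 3.0)
        out = wp.tawss_normalize(tube_surface, field, [0, 0, 0], [0, 0, 1], 8.0)
        assert np.allclose(out.tawss_n, 1.0)
        assert out.reference_value == pytest.approx(3.0)

    def test_scale_invariance(self, tube_surface):
        rng = np.random.default_rng(1)
        field = 1.0 + rng.random(tube_surface.n_vertices)
        a = wp.tawss_normalize(tube_surface, field, [0, 0, 0], [0, 0, 1], 8.0)
        b = wp.tawss_normalize(tube_surface, 2 * field, [0, 0, 0], [0, 0, 1], 8.0)
        assert np.allclose(a.tawss_n, b.tawss_n)

    def test_constructed_peak_ratio(self, tube_surface):
        z = tube_surface.vertices[:, 2]
        field = np.where(z < 8.5, 2.0, np.where(z > 30.0, 8.0, 4.0))
        out = wp.tawss_normalize(tube_surface, field, [0, 0, 0], [0, 0, 1], 8.0)
        assert out.reference_value == pytest.approx(2.0)
        assert out.tawss_n.max() == pytest.approx(4.0)


@pytest.fixture(scope="module")
def tube_frame():
    pts = np.stack([np.zeros(40), np.zeros(40), np.linspace(0, 40, 40)], 1)
    curve = mm.smooth_centerline(RawCenterline("RPA", pts, np.full(40, 8.0)))
    frame = mm.BifurcationFrame(
        origin_O=np.array([0.0, 0.0, 4.0]),
        plane_point=np.zeros(3),
        plane_normal=np.array([0.0, 1.0, 0.0]),
        D_ref_mm=16.0,
    )
    return curve, frame


@pytest.fixture(scope="module")
def section(tube_surface, tube_frame):
    curve, frame = tube_frame
    return wp.cut_cross_section(tube_surface, curve, frame, 1.0)


class TestCrossSections:

    def test_circumference_of_tube_cut(self, tube_surface, tube_frame):
        curve, frame = tube_frame
        sec = wp.cut_cross_section(tube_surface, curve, frame, 1.0, label="a")
        assert sec.circumference_mm == pytest.approx(2 * np.pi * 8.0, rel=0.01)

    def test_fraction_zero_passes_through_origin(self, tube_surface, tube_frame):
        curve, frame = tube_frame
        sec = wp.cut_cross_section(tube_surface, curve, frame, 0.0)
        assert sec.plane_origin[2] == pytest.approx(frame.origin_O[2], abs=0.2)

    def test_nearest_loop_selected_on_bifurcation(self, curved_bifurcation):
        _, surface, cls, gt = curved_bifurcation
        res, frame, curves = mm.characterize_model(cls)
        sec = wp.cut_cross_section(surface, curves["RPA"], frame, 0.4, label="a")
        r_expect = gt.radius_mm["RPA"]
        assert sec.circumference_mm == pytest.approx(
            2 * np.pi * r_expect, rel=0.15
        )

    def test_too_short_branch_rejected(self, tube_surface, tube_frame):
        curve, frame = tube_frame
        with pytest.raises(ValueError):
            wp.cut_cross_section(tube_surface, curve, frame, 5.0)


class TestPerimeterSampling:
    def test_constant_field(self, tube_surface, section):
        field = np.full(tube_surface.n_vertices, 7.0)
        values, mean = wp.perimeter_sample(section, tube_surface, field)
        assert np.allclose(values, 7.0)
        assert mean == 7.0

    def test_linear_field_mean_near_centroid_value(self, tube_surface, section):
        field = 5.0 + 0.3 * tube_surface.vertices[:, 0]
        _, mean = wp.perimeter_sample(section, tube_surface, field, 8)
        centroid_val = 5.0 + 0.3 * section.centroid[0]
        assert mean == pytest.approx(centroid_val, rel=0.02)

    def test_n8_vs_n16_consistency(self, tube_surface, section):
        field = 5.0 + np.sin(tube_surface.vertices[:, 0] / 4.0)
        _, m8 = wp.perimeter_sample(section, tube_surface, field, 8)
        _, m16 = wp.perimeter_sample(section, tube_surface, field, 16)
        assert m16 == pytest.approx(m8, rel=0.03)

    def test_poiseuille_perimeter_mean(self, tube_surface):
        from pulmobif.flow_characterization import FlowWaveform

        wf = FlowWaveform(
            t=np.linspace(0, 0.8, 32, endpoint=False), Q=np.full(32, 10.0),
            period_T=0.8,
        )
        series, gt = sd.generate_wall_field(
            tube_surface, "poiseuille_scaled", waveform=wf, period_s=0.8,
            tube_radius_mm=8.0,
        )
        tw = wp.tawss(series)
        pts = np.stack([np.zeros(40), np.zeros(40), np.linspace(0, 40, 40)], 1)
        curve = mm.smooth_centerline(RawCenterline("RPA", pts, np.full(40, 8.0)))
        frame = mm.BifurcationFrame(
            origin_O=np.array([0.0, 0.0, 4.0]),
            plane_point=np.zeros(3),
            plane_normal=np.array([0.0, 1.0, 0.0]),
            D_ref_mm=16.0,
        )
        sec = wp.cut_cross_section(tube_surface, curve, frame, 1.0)
        _, mean = wp.perimeter_sample(sec, tube_surface, tw)
        analytic = 4 * 0.004 * 10e-6 / (np.pi * 0.008**3)
        assert mean == pytest.approx(analytic, rel=0.02)


class TestSecondaryFlow:
    def test_axial_flow_no_inplane(self):
        v = np.tile([0.0, 0.0, 1.2], (10, 1))
        vin, vn = wp.secondary_flow_decomposition(v, [0, 0, 1])
        assert np.allclose(vin, 0.0)
        assert np.allclose(vn, 1.2)

    def test_rigid_rotation_field(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-1, 1, (50, 2))
        omega = 2.0
        v = np.stack([-omega * pts[:, 1], omega * pts[:, 0], np.zeros(50)], 1)
        vin, vn = wp.secondary_flow_decomposition(v, [0, 0, 1])
        assert np.allclose(vn, 0.0)
        assert np.allclose(
            np.linalg.norm(vin, axis=1), omega * np.linalg.norm(pts, axis=1)
        )

    def test_normalized_bounded_by_one(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(30, 3))
        vmax = np.linalg.norm(v, axis=1).max()
        vin, vn = wp.secondary_flow_decomposition(v, [0, 0, 1], normalize_by=vmax)
        assert np.all(np.abs(vn) <= 1.0 + 1e-12)


class TestCohortSummary:
    def test_identical_models_zero_sd(self):
        import pandas as pd

        df = pd.DataFrame(
            [
                {"model": m, "section": "alpha", "condition": "avg",
                 "tawss_pa": 8.0, "tawss_n": 2.0}
                for m in range(1, 4)
            ]
        )
        out = wp.cohort_wss_summary(df)
        assert np.allclose(out["tawss_pa_sd"], 0.0)

    def test_hand_arithmetic(self):
        import pandas as pd

        df = pd.DataFrame(
            [
                {"model": 1, "section": "alpha", "condition": "avg",
                 "tawss_pa": 8.0, "tawss_n": 1.0},
                {"model": 2, "section": "alpha", "condition": "avg",
                 "tawss_pa": 12.0, "tawss_n": 1.0},
            ]
        )
        out = wp.cohort_wss_summary(df)
        assert out["tawss_pa_mean"].iloc[0] == pytest.approx(10.0)
        assert out["tawss_pa_sd"].iloc[0] == pytest.approx(2.8284, abs=1e-3)
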