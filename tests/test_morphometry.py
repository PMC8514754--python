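import numpy as np
import pytest

from pulmobif import morphometry as mm
from pulmobif import synthetic_data as sd
from pulmobif.io_formats import RawCenterline

from conftest import make_tube


def _curve_from_points(pts, radii=None, **kw):
    if radii is None:
        radii = np.ones(len(pts))
    return mm.smooth_centerline(RawCenterline("RPA", pts, radii), **kw)


class TestFrenet:
    def test_straight_line_flat(self):
        pts = np.stack([np.linspace(0, 50, 60), np.zeros(60), np.zeros(60)], 1)
        cur = _curve_from_points(pts)
        assert np.all(np.linalg.norm(cur.d2, axis=1) < 1e-6)
        kappa, tau, straight = mm.curvature_torsion(cur)
        assert np.all(kappa == 0.0)
        assert np.all(tau == 0.0)
        assert straight.all()

    def test_circle_curvature(self):
        th = np.linspace(0, np.pi, 80)
        pts = np.stack([20 * np.cos(th), 20 * np.sin(th), 0 * th], 1)
        kappa, tau, _ = mm.curvature_torsion(_curve_from_points(pts))
        inner = slice(len(kappa) // 10, -len(kappa) // 10)
        assert np.allclose(kappa[inner], 0.05, rtol=0.01)
        assert np.all(np.abs(tau[inner]) < 1e-4)

    def test_noisy_circle_within_two_percent(self):
        th = np.linspace(0, np.pi, 60)
        pts = np.stack([20 * np.cos(th), 20 * np.sin(th), 0 * th], 1)
        rng = np.random.default_rng(1)
        noisy = pts + rng.normal(0, 0.05, pts.shape)
        # smoothing budget ~ 3 sigma^2 per point for 3-D iid noise
        cur = _curve_from_points(noisy, smooth_factor=3 * 0.05**2)
        kappa, _, _ = mm.curvature_torsion(cur)
        inner = slice(len(kappa) // 10, -len(kappa) // 10)
        assert np.mean(kappa[inner]) == pytest.approx(0.05, rel=0.02)

    def test_helix_closed_forms(self):
        pts = sd.helix_path(10.0, 5.0, turns=1.5, n=150)
        kappa, tau, _ = mm.curvature_torsion(_curve_from_points(pts))
        inner = slice(len(kappa) // 10, -len(kappa) // 10)
        assert np.allclose(kappa[inner], 0.08, rtol=0.02)
        assert np.allclose(tau[inner], 0.04, rtol=0.02)

    def test_resample_convergence(self):
        th = np.linspace(0, np.pi, 80)
        pts = np.stack([20 * np.cos(th), 20 * np.sin(th), 0 * th], 1)
        k1, _, _ = mm.curvature_torsion(
            _curve_from_points(pts, resample_step_mm=0.25)
        )
        k2, _, _ = mm.curvature_torsion(
            _curve_from_points(pts, resample_step_mm=0.125)
        )
        inner1 = slice(len(k1) // 10, -len(k1) // 10)
        inner2 = slice(len(k2) // 10, -len(k2) // 10)
        assert abs(np.mean(k2[inner2]) - np.mean(k1[inner1])) < 0.005 * 0.05


class TestTortuosity:
    def test_straight_segment_zero(self):
        pts = np.stack([np.linspace(0, 30, 40), np.zeros(40), np.zeros(40)], 1)
        assert mm.tortuosity(_curve_from_points(pts)) == pytest.approx(0.0, abs=1e-6)

    def test_semicircle(self):
        th = np.linspace(0, np.pi, 100)
        pts = np.stack([20 * np.cos(th), 20 * np.sin(th), 0 * th], 1)
        x = mm.tortuosity(_curve_from_points(pts))
        assert x == pytest.approx(np.pi / 2 - 1, rel=0.005)

    def test_amplitude_sweep_monotone_to_zero(self):
        s = np.linspace(0, 60, 120)
        prev = np.inf
        for amp in (4.0, 2.0, 1.0, 0.5, 0.25):
            pts = np.stack([s, amp * np.sin(2 * np.pi * s / 30.0), 0 * s], 1)
            x = mm.tortuosity(_curve_from_points(pts))
            assert x < prev
            prev = x
        assert prev < 0.01


class TestInscribedRadius:
    def test_straight_tube_constant_radius(self, tube_surface):
        pts = np.stack([np.zeros(40), np.zeros(40), np.linspace(0, 40, 40)], 1)
        cur = _curve_from_points(pts, radii=np.full(40, 8.0))
        radii, r_min = mm.inscribed_radius_profile(tube_surface, cur, D_ref_mm=16.0)
        interior = (cur.s > 8) & (cur.s < 32)
        assert np.allclose(radii[interior], 8.0, rtol=0.01)

    def test_gaussian_waist_minimum(self):
        z = np.linspace(0, 40, 400)
        radii = 8.0 - 3.0 * np.exp(-((z - 20) ** 2) / 20.0)
        surf = make_tube(length=40.0, radii=radii, step_mm=0.5, n_circ=64)
        pts = np.stack([np.zeros(60), np.zeros(60), np.linspace(0, 40, 60)], 1)
        cur = _curve_from_points(pts, radii=np.full(60, 8.0))
        _, r_min = mm.inscribed_radius_profile(surf, cur, D_ref_mm=10.0)
        assert r_min == pytest.approx(5.0, rel=0.02)

    def test_tapered_tube_monotone(self):
        z = np.linspace(0, 40, 400)
        radii = 10.0 - 3.0 * z / 40.0
        surf = make_tube(length=40.0, radii=radii, step_mm=0.5, n_circ=64)
        pts = np.stack([np.zeros(60), np.zeros(60), np.linspace(0, 40, 60)], 1)
        cur = _curve_from_points(pts, radii=np.full(60, 7.0))
        prof, _ = mm.inscribed_radius_profile(surf, cur, D_ref_mm=10.0)
        # stay where the wall (not an end cap) is the nearest surface
        interior = (cur.s > 12) & (cur.s < 34)
        diffs = np.diff(prof[interior])
        assert np.all(diffs < 1e-3)

    def test_outside_point_rejected(self, tube_surface):
        pts = np.stack([np.full(40, 20.0), np.zeros(40), np.linspace(0, 40, 40)], 1)
        cur = _curve_from_points(pts)
        with pytest.raises(ValueError, match="outside"):
            mm.inscribed_radius_profile(tube_surface, cur, D_ref_mm=16.0)


class TestBifurcationFrame:
    def test_symmetric_origin_near_ground_truth(self):
        spec = sd.SyntheticBifurcationSpec(
            inplane_RPA=135.0, inplane_LPA=135.0, D_RPA=13.0, D_LPA=13.0
        )
        _, cls, gt = sd.generate_bifurcation(spec, n_circ=16)
        curves = [mm.smooth_centerline(c) for c in cls]
        O, sep = mm.detect_bifurcation_origin(curves)
        local_r = gt.radius_mm["MPA"]
        assert np.linalg.norm(O - gt.junction) <= local_r
        # symmetry plane: x = 0
        assert abs(O[0]) < 0.5

    def test_asymmetric_origin_within_local_radius(self, curved_bifurcation):
        _, _, cls, gt = curved_bifurcation
        curves = [mm.smooth_centerline(c) for c in cls]
        O, _ = mm.detect_bifurcation_origin(curves)
        assert np.linalg.norm(O - gt.junction) <= gt.radius_mm["MPA"]

    def test_parallel_curves_raise(self):
        line = lambda x0: np.stack(
            [np.full(50, x0), np.zeros(50), np.linspace(0, 49, 50)], 1
        )
        curves = [
            mm.smooth_centerline(RawCenterline(b, line(x0), np.full(50, 30.0)))
            for b, x0 in (("MPA", 0.0), ("RPA", 1.0), ("LPA", -1.0))
        ]
        with pytest.raises(ValueError, match="separate"):
            mm.detect_bifurcation_origin(curves)

    def test_planar_y_plane_exact_and_window_invariant(self):
        spec = sd.SyntheticBifurcationSpec(branch_curv_radius=40.0)
        _, cls, gt = sd.generate_bifurcation(spec, n_circ=16)
        curves = [mm.smooth_centerline(c) for c in cls]
        O, _ = mm.detect_bifurcation_origin(curves)
        p1, n1 = mm.bifurcation_plane(curves, origin_O=O, window_mm=33.0)
        p2, n2 = mm.bifurcation_plane(curves, origin_O=O, window_mm=66.0)
        # all samples on the nominal x-z plane
        assert abs(abs(np.dot(n1, [0, 1, 0])) - 1.0) < 1e-6
        assert np.allclose(np.abs(np.dot(n1, n2)), 1.0, atol=1e-6)

    def test_collinear_samples_degenerate(self):
        pts = np.stack([np.zeros(50), np.zeros(50), np.linspace(0, 49, 50)], 1)
        curves = [
            mm.smooth_centerline(RawCenterline(b, pts.copy(), np.full(50, 5.0)))
            for b in ("MPA", "RPA", "LPA")
        ]
        with pytest.raises(ValueError, match="ollinear|degenerate"):
            mm.bifurcation_plane(curves, origin_O=pts[25], window_mm=10.0)


class TestBranchAngles:
    def test_symmetric_planar_y(self):
        spec = sd.SyntheticBifurcationSpec(
            inplane_RPA=135.0, inplane_LPA=135.0, D_RPA=13.0, D_LPA=13.0
        )
        _, cls, _ = sd.generate_bifurcation(spec, n_circ=16)
        res, _, _ = mm.characterize_model(cls)
        assert res["RPA"].inplane_deg == pytest.approx(135.0, abs=1.0)
        assert res["LPA"].inplane_deg == pytest.approx(135.0, abs=1.0)
        assert res["RPA"].outplane_deg == pytest.approx(0.0, abs=1.0)
        assert res["LPA"].outplane_deg == pytest.approx(0.0, abs=1.0)

    def test_near_continuation_scores_near_180(self):
        spec = sd.SyntheticBifurcationSpec(
            inplane_RPA=179.0, inplane_LPA=120.0, D_RPA=13.0
        )
        _, cls, _ = sd.generate_bifurcation(spec, n_circ=16)
        res, _, _ = mm.characterize_model(cls)
        assert res["RPA"].inplane_deg == pytest.approx(179.0, abs=1.0)

    def test_out_of_plane_sign_convention_against_exact_paths(self):
        spec = sd.SyntheticBifurcationSpec(outplane_LPA=20.0)
        _, cls, gt = sd.generate_bifurcation(spec, n_circ=16)
        res, _, _ = mm.characterize_model(cls)
        oracle = sd.exact_branch_angles(gt)
        for b in ("RPA", "LPA"):
            assert res[b].outplane_deg == pytest.approx(oracle[b][1], abs=1.0)
            assert res[b].inplane_deg == pytest.approx(oracle[b][0], abs=1.0)
        # tilt direction is preserved: a positive spec tilt reads positive
        assert res["LPA"].outplane_deg > 0


class TestCohortRecovery:
    def test_angle_and_tortuosity_recovery(self):
        """Discrete pipeline vs the same conventions on exact paths."""
        cohort = sd.generate_cohort(
            sd.SyntheticCohortSpec(n_models=4, seed=5), n_circ=16, step_mm=1.0
        )
        for mdl in cohort:
            res, frame, _ = mm.characterize_model(mdl["centerlines"])
            gt = mdl["ground_truth"]
            oracle = sd.exact_branch_angles(gt)
            for b in ("RPA", "LPA"):
                assert res[b].inplane_deg == pytest.approx(oracle[b][0], abs=2.0)
                assert res[b].outplane_deg == pytest.approx(oracle[b][1], abs=2.0)
                assert res[b].tortuosity_x == pytest.approx(
                    gt.tortuosity[b], rel=0.05, abs=0.003
                )

    def test_rigid_motion_invariance(self, curved_bifurcation):
        _, _, cls, _ = curved_bifurcation
        res0, _, _ = mm.characterize_model(cls)
        # rotate + translate all centerlines rigidly
        ang = 0.7
        R = np.array(
            [
                [np.cos(ang), 0, np.sin(ang)],
                [0, 1, 0],
                [-np.sin(ang), 0, np.cos(ang)],
            ]
        )
        t = np.array([5.0, -3.0, 11.0])
        moved = [
            RawCenterline(c.branch_id, c.points @ R.T + t, c.radii) for c in cls
        ]
        res1, _, _ = mm.characterize_model(moved)
        for b in ("RPA", "LPA"):
            assert res1[b].inplane_deg == pytest.approx(
                res0[b].inplane_deg, abs=1e-6
            )
            assert res1[b].outplane_deg == pytest.approx(
                res0[b].outplane_deg, abs=1e-6
            )
            assert res1[b].tortuosity_x == pytest.approx(
                res0[b].tortuosity_x, abs=1e-9
            )
            assert res1[b].kappa_mean == pytest.approx(res0[b].kappa_mean, abs=1e-9)


class TestNormalizedAbscissa:
    def _kappa_curve(self, peaks_at, n=200, length=60.0):
        s = np.linspace(0, length, n)
        v = np.zeros(n)
        for p, a in peaks_at:
            v += a * np.exp(-((s - p) ** 2) / 8.0)
        pts = np.stack([s, np.zeros(n), np.zeros(n)], 1)
        cur = mm.CenterlineCurve("RPA", s, pts, None, None, None, np.ones(n))
        return s, v, cur

    def test_single_peak_maps_to_one(self):
        s, v, cur = self._kappa_curve([(25.0, 0.1)])
        nc = mm.normalized_abscissa(v, cur)
        i1 = np.argmin(np.abs(nc.grid - 1.0))
        assert nc.peak_s_mm == pytest.approx(25.0, abs=0.5)
        assert nc.values[i1] == pytest.approx(0.1, rel=0.01)

    def test_first_peak_used_for_normalization(self):
        s, v, cur = self._kappa_curve([(10.0, 0.08), (30.0, 0.12)])
        nc = mm.normalized_abscissa(v, cur)
        assert nc.peak_s_mm == pytest.approx(10.0, abs=0.5)

    def test_straight_branch_no_peak(self):
        s, v, cur = self._kappa_curve([])
        nc = mm.normalized_abscissa(v, cur)
        assert not nc.has_peak

    def test_cohort_average_hand_arithmetic(self):
        grid = np.linspace(0, 2, 81)
        mk = lambda v: mm.NormalizedCurve("LPA", grid, np.full(81, v), 10.0)
        df = mm.cohort_average_curves([mk(0.02), mk(0.04)])
        assert np.allclose(df["mean"], 0.03)
        assert np.allclose(df["sd"], 0.0141, atol=2e-4)

    def test_no_peak_model_excluded(self):
        grid = np.linspace(0, 2, 81)
        good = mm.NormalizedCurve("LPA", grid, np.full(81, 0.02), 10.0)
        bad = mm.NormalizedCurve("LPA", grid, np.full(81, np.nan), None)
        df = mm.cohort_average_curves([good, good, bad])
        assert np.all(df["n"] == 2)

    def test_identical_curves_zero_sd(self):
        grid = np.linspace(0, 2, 81)
        c = mm.NormalizedCurve("RPA", grid, np.linspace(0, 0.1, 81), 5.0)
        df = mm.cohort_average_curves([c, c, c])
        assert np.allclose(df["sd"].fillna(0.0), 0.0)
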