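"""Centerline morphometry: Frenet curvature and torsion, tortuosity,
inscribed-sphere radii, bifurcation origin and plane, branch angles, and
cohort averaging on a normalized curvilinear abscissa.

Conventions
-----------
* Curvature kappa(s) = |c' x c''| / |c'|^3 and torsion
  tau(s) = (c' x c'') . c''' / |c' x c''|^2, both in 1/mm, evaluated from an
  arc-length-parametrized smoothing spline.
* The bifurcation origin O is the first point moving downstream along the
  trunk centerline where the two daughter centerlines separate by more than
  the local inscribed radius.
* The bifurcation plane is the total-least-squares plane through
  centerline samples within a window of O on all three branches. When
  branches leave the plane the fit necessarily splits the deviation among
  them, so out-of-plane angles are relative to this documented convention.
* The oriented plane normal n satisfies n . (t_RPA x t_LPA) >= 0, with
  daughter tangents taken just downstream of O. In-plane angles use the
  upstream-pointing trunk direction, so a daughter continuing straight
  scores 180 deg. The out-of-plane angle is the signed angle between the
  branch direction and its in-plane projection, positive when the branch
  direction has a positive component along n (the clockwise sense when
  viewed along n).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import splev, splprep

from ._geometry import SurfaceDistance, angle_between_deg
from .io_formats import RawCenterline, TriSurface

log = logging.getLogger(__name__)


@dataclass
class CenterlineCurve:
    """Arc-length-parametrized smoothed centerline with derivatives."""

    branch_id: str
    s: np.ndarray  # (N,) mm, uniform
    c: np.ndarray  # (N, 3)
    d1: np.ndarray
    d2: np.ndarray
    d3: np.ndarray
    radii: np.ndarray  # (N,) mm inscribed-sphere radius

    @property
    def length(self) -> float:
        return float(self.s[-1] - self.s[0])

    def point_at(self, s_query):
        s_query = np.atleast_1d(s_query)
        return np.stack(
            [np.interp(s_query, self.s, self.c[:, k]) for k in range(3)], axis=1
        )

    def tangent_at(self, s_query):
        s_query = np.atleast_1d(s_query)
        t = np.stack(
            [np.interp(s_query, self.s, self.d1[:, k]) for k in range(3)], axis=1
        )
        return t / np.linalg.norm(t, axis=1, keepdims=True)


@dataclass
class MorphometryResult:
    branch_id: str
    kappa_mean: float
    kappa_max: float
    tau_min: float
    tau_mean: float
    tau_max: float
    tortuosity_x: float
    L_mm: float
    D_euclid_mm: float
    r_min_mm: float
    inplane_deg: float = np.nan
    outplane_deg: float = np.nan


@dataclass
class BifurcationFrame:
    origin_O: np.ndarray
    plane_point: np.ndarray
    plane_normal: np.ndarray
    D_ref_mm: float


# --------------------------------------------------------------------------
# smoothing and Frenet quantities


def smooth_centerline(
    raw: RawCenterline,
    smooth_factor: float = 1e-6,
    resample_step_mm: float = 0.25,
) -> CenterlineCurve:
    """Cubic smoothing-spline fit, reparametrized by arc length.

    ``smooth_factor`` is a per-point residual budget in mm^2 (scipy's ``s``
    equals ``smooth_factor * n_points``). The near-interpolating default
    keeps curvature error well under 1% on analytic fixtures; for noisy
    samples raise it to roughly ``3 * sigma**2`` of the coordinate noise.
    """
    pts = np.asarray(raw.points, float)
    keep = np.concatenate(
        [[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9]
    )
    pts = pts[keep]
    radii = np.asarray(raw.radii, float)[keep]
    if len(pts) < 4:
        raise ValueError(f"{raw.branch_id}: fewer than 4 distinct points")

    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    u = chord / chord[-1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tck, _ = splprep(pts.T, u=u, s=smooth_factor * len(pts), k=min(5, len(pts) - 1))

    # arc-length reparametrization on a fine grid
    uf = np.linspace(0.0, 1.0, max(20 * len(pts), 1000))
    cf = np.stack(splev(uf, tck), axis=1)
    sf = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(cf, axis=0), axis=1))]
    )
    total = sf[-1]
    n_out = max(int(np.round(total / resample_step_mm)) + 1, 8)
    sg = np.linspace(0.0, total, n_out)
    ug = np.interp(sg, sf, uf)

    c = np.stack(splev(ug, tck), axis=1)
    du1 = np.stack(splev(ug, tck, der=1), axis=1)
    du2 = np.stack(splev(ug, tck, der=2), axis=1)
    du3 = np.stack(splev(ug, tck, der=3), axis=1)
    # chain rule u -> s: ds/du = |c_u|
    speed = np.linalg.norm(du1, axis=1)
    dsdu = speed
    # ds2/du2 = (c_u . c_uu) / |c_u|
    d2sdu2 = np.einsum("ij,ij->i", du1, du2) / speed
    d1 = du1 / dsdu[:, None]
    d2 = (du2 - d1 * d2sdu2[:, None]) / dsdu[:, None] ** 2
    # third derivative via finite differences of d2 on the uniform s grid
    d3 = np.gradient(d2, sg, axis=0)

    rg = np.interp(sg, chord, radii)
    return CenterlineCurve(
        branch_id=raw.branch_id, s=sg, c=c, d1=d1, d2=d2, d3=d3, radii=rg
    )


def curvature_torsion(curve: CenterlineCurve, straight_tol: float = 1e-9):
    """Per-sample (kappa, tau, straight_mask); tau is 0 on straight spans."""
    cross = np.cross(curve.d1, curve.d2)
    n1 = np.linalg.norm(curve.d1, axis=1)
    ncross = np.linalg.norm(cross, axis=1)
    kappa = ncross / np.maximum(n1**3, 1e-30)
    straight = ncross < straight_tol
    tau = np.zeros_like(kappa)
    good = ~straight
    tau[good] = np.einsum("ij,ij->i", cross[good], curve.d3[good]) / ncross[good] ** 2
    return kappa, tau, straight


def tortuosity(curve: CenterlineCurve) -> float:
    """Relative excess length over the endpoint chord: x = L/D - 1."""
    D = np.linalg.norm(curve.c[-1] - curve.c[0])
    if D < 1e-9:
        raise ValueError("coincident endpoints: closed curves unsupported")
    return float(curve.length / D - 1.0)


def inscribed_radius_profile(
    surface: TriSurface, curve: CenterlineCurve, D_ref_mm: float | None = None
):
    """Distance from c(s) to the nearest surface point; r_min excludes
    0.5 D_ref at each extremity (end-cap artifacts)."""
    sd = SurfaceDistance(surface.vertices, surface.faces)
    _, d, _ = sd.query(curve.c)
    signed = sd.signed(curve.c)
    if np.any(signed > 1e-6):
        s_bad = curve.s[np.argmax(signed)]
        raise ValueError(f"centerline point outside surface at s = {s_bad:.2f} mm")
    if D_ref_mm is None:
        D_ref_mm = 2.0 * float(np.median(curve.radii))
    margin = 0.5 * D_ref_mm
    interior = (curve.s >= curve.s[0] + margin) & (curve.s <= curve.s[-1] - margin)
    if not interior.any():
        interior = slice(None)
    return d, float(np.min(d[interior]))


# --------------------------------------------------------------------------
# bifurcation frame


def _order_curves(curves):
    by_id = {c.branch_id: c for c in curves}
    if set(by_id) >= {"MPA", "RPA", "LPA"}:
        return by_id["MPA"], by_id["RPA"], by_id["LPA"]
    if len(curves) != 3:
        raise ValueError("need exactly three centerline curves")
    # fallback: shortest curve is the trunk
    order = np.argsort([c.length for c in curves])
    return curves[order[0]], curves[order[1]], curves[order[2]]


def detect_bifurcation_origin(curves):
    """Origin O: first trunk point, moving downstream, where the daughter
    centerlines separate by more than the local inscribed radius.

    Returns (O, separation_mm). Daughter curves must share the upstream
    trunk run (VMTK-style centerlines from a common inlet).
    """
    mpa, rpa, lpa = _order_curves(curves)
    sep = np.empty(len(mpa.s))
    for i, p in enumerate(mpa.c):
        pr = rpa.c[np.argmin(np.linalg.norm(rpa.c - p, axis=1))]
        pl = lpa.c[np.argmin(np.linalg.norm(lpa.c - p, axis=1))]
        sep[i] = np.linalg.norm(pr - pl)
    over = sep > mpa.radii
    if not over.any():
        # look past the trunk end along the daughters themselves
        tail = min(len(rpa.s), len(lpa.s))
        d_tail = np.linalg.norm(rpa.c[-tail:] - lpa.c[-tail:], axis=1)
        if not (d_tail > np.interp(np.linspace(0, 1, tail), [0, 1],
                                   [mpa.radii[-1], mpa.radii[-1]])).any():
            raise ValueError("daughter centerlines never separate: no bifurcation")
        return mpa.c[-1].copy(), float(sep[-1])
    i0 = int(np.argmax(over))
    return mpa.c[i0].copy(), float(sep[i0])


def _tls_plane_fit(points):
    """Total-least-squares plane; raises on collinear samples."""
    centroid = points.mean(axis=0)
    cov = (points - centroid).T @ (points - centroid)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-12 * max(evals[2], 1.0):
        raise ValueError("degenerate plane: samples are collinear")
    return centroid, evecs[:, 0]


def bifurcation_plane(curves, origin_O=None, window_mm=None, D_ref_mm=None):
    """TLS bifurcation plane through samples within ``window_mm``
    (default 1.5 D_ref) of O on all three branches; oriented normal.

    Note that when branches leave the plane, the fitted plane necessarily
    splits the deviation among them; out-of-plane angles are therefore a
    property of the (documented) fit convention, not of a branch alone.
    """
    mpa, rpa, lpa = _order_curves(curves)
    if origin_O is None:
        origin_O, _ = detect_bifurcation_origin(curves)
    if D_ref_mm is None:
        D_ref_mm = 2.0 * float(mpa.radii[0])
    if window_mm is None:
        window_mm = 1.5 * D_ref_mm

    samples = []
    for cur in (mpa, rpa, lpa):
        d = np.linalg.norm(cur.c - origin_O, axis=1)
        samples.append(cur.c[d <= window_mm])
    pts = np.vstack(samples)
    point, normal = _tls_plane_fit(pts)

    # orientation: n . (t_RPA x t_LPA) >= 0 with tangents just past O
    t_r = _branch_direction(rpa, origin_O, 0.5 * D_ref_mm, downstream=True)
    t_l = _branch_direction(lpa, origin_O, 0.5 * D_ref_mm, downstream=True)
    ref = np.cross(t_r, t_l)
    if np.dot(normal, ref) < 0:
        normal = -normal
    return point, normal


def _arc_position(curve, point):
    return float(curve.s[np.argmin(np.linalg.norm(curve.c - point, axis=1))])


def _branch_direction(curve, origin_O, arc_mm, downstream=True):
    """Mean unit tangent over an arc window starting at O."""
    s0 = _arc_position(curve, origin_O)
    if downstream:
        m = (curve.s >= s0) & (curve.s <= s0 + arc_mm)
    else:
        m = (curve.s >= s0 - arc_mm) & (curve.s <= s0)
    if not m.any():
        m = np.abs(curve.s - s0) == np.min(np.abs(curve.s - s0))
    t = curve.d1[m].mean(axis=0)
    n = np.linalg.norm(t)
    if n < 1e-12:
        raise ValueError("zero-length branch direction")
    return t / n


def branch_angles(curves, frame: BifurcationFrame, tangent_arc_mm: float | None = None):
    """In-plane (deg, (0,180)) and signed out-of-plane angles per daughter.

    Branch direction = mean tangent over ``tangent_arc_mm`` (default
    1.0 D_ref) downstream of O; trunk direction = mean tangent over the same
    arc upstream of O, reversed to point upstream.
    """
    mpa, rpa, lpa = _order_curves(curves)
    if tangent_arc_mm is None:
        tangent_arc_mm = frame.D_ref_mm
    n = frame.plane_normal / np.linalg.norm(frame.plane_normal)
    u_up = -_branch_direction(mpa, frame.origin_O, tangent_arc_mm, downstream=False)

    def project(v):
        vp = v - np.dot(v, n) * n
        nv = np.linalg.norm(vp)
        if nv < 1e-9:
            raise ValueError("branch direction parallel to plane normal")
        return vp / nv

    u_proj = project(u_up)
    out = {}
    for name, cur in (("RPA", rpa), ("LPA", lpa)):
        d = _branch_direction(cur, frame.origin_O, tangent_arc_mm, downstream=True)
        d_proj = project(d)
        inplane = angle_between_deg(u_proj, d_proj)
        outplane = float(np.degrees(np.arcsin(np.clip(np.dot(d, n), -1.0, 1.0))))
        out[name] = (inplane, outplane)
    return out


# --------------------------------------------------------------------------
# normalized abscissa and cohort curves


@dataclass
class NormalizedCurve:
    branch_id: str
    grid: np.ndarray  # normalized abscissa
    values: np.ndarray
    peak_s_mm: float | None  # None => no interior peak

    @property
    def has_peak(self) -> bool:
        return self.peak_s_mm is not None


def normalized_abscissa(
    values: np.ndarray,
    curve: CenterlineCurve,
    origin_O: np.ndarray | None = None,
    grid_max: float = 2.0,
    n_grid: int = 81,
    min_prominence: float = 1e-6,
) -> NormalizedCurve:
    """Resample values(s) on an abscissa normalized by the arc distance to
    the curvature peak nearest the bifurcation (value 1.0 = peak location).
    """
    from scipy.signal import find_peaks

    s0 = 0.0 if origin_O is None else _arc_position(curve, origin_O)
    s_rel = curve.s - s0
    sel = s_rel >= 0.0
    s_rel = s_rel[sel]
    v = np.asarray(values)[sel]
    grid = np.linspace(0.0, grid_max, n_grid)
    peaks, _ = find_peaks(v, prominence=min_prominence)
    if len(peaks) == 0:
        log.warning("%s: no interior curvature peak; excluded from averaging",
                    curve.branch_id)
        return NormalizedCurve(curve.branch_id, grid, np.full(n_grid, np.nan), None)
    s_peak = s_rel[peaks[0]]  # peak closest to the bifurcation
    if s_peak <= 0.0:
        s_peak = s_rel[peaks[np.argmax(s_rel[peaks] > 0)]]
    out = np.interp(grid, s_rel / s_peak, v, left=np.nan, right=np.nan)
    return NormalizedCurve(curve.branch_id, grid, out, float(s_peak))


def cohort_average_curves(curves: list[NormalizedCurve]):
    """Pointwise mean and sample SD over models on the common grid.

    Models lacking a value at a grid point (no-peak models, short branches)
    are excluded there; per-point counts are returned.
    """
    usable = [c for c in curves if c.has_peak]
    if not usable:
        raise ValueError("no curves with an interior peak to average")
    grid = usable[0].grid
    for c in usable[1:]:
        if not np.allclose(c.grid, grid):
            raise ValueError("curves are not on a common normalized grid")
    vals = np.stack([c.values for c in usable])
    n = np.sum(~np.isnan(vals), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0, ddof=1)
    return pd.DataFrame({"grid": grid, "mean": mean, "sd": sd, "n": n})


# --------------------------------------------------------------------------
# per-model driver


def characterize_branch(
    curve: CenterlineCurve,
    frame: BifurcationFrame | None = None,
    angles: tuple[float, float] | None = None,
) -> MorphometryResult:
    """Branch statistics from O to the branch end, excluding 0.5 D_ref at
    each extremity of the analysed span."""
    if frame is not None:
        s0 = _arc_position(curve, frame.origin_O)
        margin = 0.5 * frame.D_ref_mm
    else:
        s0, margin = 0.0, 0.0
    sel = (curve.s >= s0 + margin) & (curve.s <= curve.s[-1] - margin)
    if sel.sum() < 4:
        sel = curve.s >= s0
    sub = CenterlineCurve(
        curve.branch_id,
        curve.s[sel],
        curve.c[sel],
        curve.d1[sel],
        curve.d2[sel],
        curve.d3[sel],
        curve.radii[sel],
    )
    kappa, tau, straight = curvature_torsion(sub)
    tau_v = tau[~straight] if (~straight).any() else np.zeros(1)
    x = tortuosity(sub)
    inpl, outpl = (angles if angles is not None else (np.nan, np.nan))
    return MorphometryResult(
        branch_id=curve.branch_id,
        kappa_mean=float(np.mean(kappa)),
        kappa_max=float(np.max(kappa)),
        tau_min=float(np.min(tau_v)),
        tau_mean=float(np.mean(tau_v)),
        tau_max=float(np.max(tau_v)),
        tortuosity_x=x,
        L_mm=sub.length,
        D_euclid_mm=float(np.linalg.norm(sub.c[-1] - sub.c[0])),
        r_min_mm=float(np.min(sub.radii)),
        inplane_deg=inpl,
        outplane_deg=outpl,
    )


def characterize_model(
    centerlines: list[RawCenterline],
    surface: TriSurface | None = None,
    smooth_factor: float = 1e-4,
    resample_step_mm: float = 0.25,
):
    """Full morphometric characterization of one bifurcation model.

    Returns (dict branch -> MorphometryResult, BifurcationFrame,
    dict branch -> CenterlineCurve).
    """
    curves = [
        smooth_centerline(cl, smooth_factor, resample_step_mm) for cl in centerlines
    ]
    mpa, rpa, lpa = _order_curves(curves)
    O, _ = detect_bifurcation_origin(curves)
    D_ref = 2.0 * float(mpa.radii[0])
    point, normal = bifurcation_plane(curves, origin_O=O, D_ref_mm=D_ref)
    frame = BifurcationFrame(origin_O=O, plane_point=point, plane_normal=normal,
                             D_ref_mm=D_ref)
    ang = branch_angles(curves, frame)
    results = {}
    for name, cur in (("RPA", rpa), ("LPA", lpa)):
        res = characterize_branch(cur, frame, angles=ang[name])
        if surface is not None:
            s0 = _arc_position(cur, O)
            sel = cur.s >= s0
            sub = CenterlineCurve(name, cur.s[sel], cur.c[sel], cur.d1[sel],
                                  cur.d2[sel], cur.d3[sel], cur.radii[sel])
            _, r_min = inscribed_radius_profile(surface, sub, D_ref_mm=D_ref)
            res.r_min_mm = r_min
        results[name] = res
    return results, frame, {"MPA": mpa, "RPA": rpa, "LPA": lpa}


def results_to_frame(per_model: list[dict]) -> pd.DataFrame:
    """Rows of per-model branch metrics in cohort-table column order."""
    rows = []
    for i, res in enumerate(per_model, 1):
        r, l = res["RPA"], res["LPA"]
        rows.append(
            {
                "model": i,
                "kappa_mean_rpa": r.kappa_mean,
                "kappa_max_rpa": r.kappa_max,
                "kappa_mean_lpa": l.kappa_mean,
                "kappa_max_lpa": l.kappa_max,
                "tortuosity_rpa": r.tortuosity_x,
                "tortuosity_lpa": l.tortuosity_x,
                "r_min_rpa_mm": r.r_min_mm,
                "r_min_lpa_mm": l.r_min_mm,
                "inplane_rpa_deg": r.inplane_deg,
                "inplane_lpa_deg": l.inplane_deg,
                "outplane_rpa_deg": r.outplane_deg,
                "outplane_lpa_deg": l.outplane_deg,
            }
        )
    return pd.DataFrame(rows)
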