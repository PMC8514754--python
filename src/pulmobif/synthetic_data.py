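"""Synthetic pulmonary-bifurcation data with analytic ground truth.

Every generator here is a pure function of its spec (and seed) and returns
the generated artifact together with a ground-truth record, so that the
morphometry, flow, mapping, wall-shear, and template stages can be tested
end-to-end without any patient data.

Geometry model: a main pulmonary artery (MPA) trunk swept along +z ending
at the junction point O, plus two daughter branches (RPA toward +x, LPA
toward -x). Each daughter leaves O along a prescribed direction (set by its
in-plane and signed out-of-plane angle), runs straight for 0.8 D_MPA, then
follows a circular arc of prescribed radius, optionally perturbed by a
windowed sinusoid to add tortuosity. Tube surfaces are swept with a
parallel-transported frame and capped at the open ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import jv

from .io_formats import RawCenterline, TriSurface, VoxelFlowSeries, WallFieldSeries

DEFAULT_RHO = 1060.0  # kg/m^3
DEFAULT_MU = 0.004  # Pa s


class GenerationError(RuntimeError):
    """The requested geometry cannot be swept without self-intersection."""


# --------------------------------------------------------------------------
# specs


@dataclass
class SyntheticBifurcationSpec:
    """Parameters of one synthetic bifurcation (lengths mm, angles deg).

    Defaults sit mid-range of the repaired-TOF cohort this package targets:
    trunk diameter ~22 mm, in-plane angles ~143/132 deg, branch curvature
    radii of a few centimetres.
    """

    D_MPA: float = 22.0
    D_RPA: float = 13.0
    D_LPA: float = 15.0
    inplane_RPA: float = 143.0
    inplane_LPA: float = 132.0
    outplane_RPA: float = 0.0
    outplane_LPA: float = 0.0
    branch_curv_radius: float = np.inf  # mm; inf = straight daughters
    tort_amp: float = 0.0  # mm
    tort_wavelength: float = 25.0  # mm
    branch_length: float = 50.0  # mm arc length per daughter
    mpa_length: float | None = None  # default 1.5 * D_MPA
    taper: float = 0.0  # fractional diameter change over a branch
    seed: int = 0

    def __post_init__(self):
        for d in (self.D_MPA, self.D_RPA, self.D_LPA):
            if d <= 0:
                raise ValueError("diameters must be positive")
        if self.branch_length < 2.0 * self.D_MPA:
            raise ValueError("branch_length must be >= 2 * D_MPA")
        for a in (self.inplane_RPA, self.inplane_LPA):
            if not (0.0 < a < 180.0):
                raise ValueError("in-plane angles must lie in (0, 180) deg")
        if self.mpa_length is None:
            self.mpa_length = 1.5 * self.D_MPA


@dataclass
class SyntheticCohortSpec:
    """Uniform parameter ranges for a cohort of synthetic bifurcations.

    Default ranges follow the printed cohort: trunk diameters 17-30 mm,
    in-plane angles 124-164 (RPA) and 110-168 (LPA) deg, out-of-plane
    angles -35..10 and -21..59 deg, and moderate tortuosity perturbations.
    """

    n_models: int = 7
    seed: int = 0
    ranges: dict = field(default_factory=dict)
    waveform: dict = field(default_factory=dict)

    _DEFAULT_RANGES = {
        "D_MPA": (17.0, 30.0),
        "D_RPA": (9.0, 19.0),
        "D_LPA": (13.0, 22.0),
        "inplane_RPA": (124.0, 164.0),
        "inplane_LPA": (110.0, 168.0),
        "outplane_RPA": (-35.0, 10.0),
        "outplane_LPA": (-21.0, 59.0),
        "branch_curv_radius": (25.0, 80.0),
        "tort_amp": (0.0, 2.0),
        "tort_wavelength": (20.0, 40.0),
        "taper": (0.0, 0.15),
    }
    _DEFAULT_WAVEFORM = {
        "period_s": (0.6, 1.0),
        "q_mean_mls": (34.0, 114.0),
        "regurgitant_fraction": (0.30, 0.50),
    }

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        self.ranges = {**self._DEFAULT_RANGES, **self.ranges}
        self.waveform = {**self._DEFAULT_WAVEFORM, **self.waveform}


@dataclass
class BifurcationGroundTruth:
    """Analytic ground truth accompanying one generated bifurcation."""

    junction: np.ndarray  # point O, mm
    plane_normal: np.ndarray  # oriented nominal bifurcation plane normal
    D_ref_mm: float
    inplane_deg: dict  # branch -> nominal angle
    outplane_deg: dict
    tortuosity: dict  # daughter path O -> end
    kappa_mean: dict  # over daughter path, ends excluded by 0.5 D_ref
    kappa_max: dict
    radius_mm: dict  # tube radius at branch start
    paths: dict  # branch -> exact fine polyline (N, 3), trunk included
    path_radii: dict  # branch -> tube radius per fine sample


# --------------------------------------------------------------------------
# exact parametric paths (oracles)


def straight_path(p0, direction, length, n=400):
    p0 = np.asarray(p0, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    t = np.linspace(0.0, length, n)
    return p0 + t[:, None] * d


def arc_path(center, radius, e1, e2, angle_span, n=800):
    """Circular arc center + R(cos a e1 + sin a e2), a in [0, angle_span]."""
    a = np.linspace(0.0, angle_span, n)
    return (
        np.asarray(center, float)
        + radius * np.cos(a)[:, None] * np.asarray(e1, float)
        + radius * np.sin(a)[:, None] * np.asarray(e2, float)
    )


def helix_path(radius, pitch_param, turns=2.0, n=2000):
    """Helix (r cos t, r sin t, c t): kappa = r/(r^2+c^2), tau = c/(r^2+c^2)."""
    t = np.linspace(0.0, 2 * np.pi * turns, n)
    return np.stack(
        [radius * np.cos(t), radius * np.sin(t), pitch_param * t], axis=1
    )


def polyline_arclength(points):
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def polyline_curvature(points):
    """Discrete curvature of a fine polyline via central differences."""
    s = polyline_arclength(points)
    d1 = np.gradient(points, s, axis=0)
    d2 = np.gradient(d1, s, axis=0)
    cross = np.cross(d1, d2)
    n1 = np.linalg.norm(d1, axis=1)
    return np.linalg.norm(cross, axis=1) / np.maximum(n1**3, 1e-30)


# --------------------------------------------------------------------------
# bifurcation generator


def _daughter_direction(inplane_deg, outplane_deg, side):
    """Initial daughter direction for the nominal x-z bifurcation plane.

    ``side`` is +1 for the RPA (+x) and -1 for the LPA (-x). The oriented
    plane normal is -y (see morphometry's orientation rule), so a positive
    out-of-plane angle tilts toward -y.
    """
    theta = np.radians(180.0 - inplane_deg)
    beta = np.radians(outplane_deg)
    d_ip = np.array([side * np.sin(theta), 0.0, np.cos(theta)])
    d = np.cos(beta) * d_ip + np.sin(beta) * np.array([0.0, -1.0, 0.0])
    return d / np.linalg.norm(d)


def _daughter_path(spec, d0, side, n_fine=2000):
    """Exact daughter path from O: straight run, then arc, plus optional
    windowed sinusoidal perturbation normal to the branch plane."""
    L = spec.branch_length
    Ls = min(0.8 * spec.D_MPA, 0.5 * L)
    s = np.linspace(0.0, L, n_fine)

    u = np.array([0.0, 0.0, 1.0])  # MPA flow direction
    # branch plane: spanned by u and d0 (falls back to x-z for collinear)
    b = np.cross(d0, u)
    nb = np.linalg.norm(b)
    b = b / nb if nb > 1e-9 else np.array([0.0, -1.0, 0.0])
    m = np.cross(b, d0)  # in-branch-plane normal to d0, points away from u
    m /= np.linalg.norm(m)

    pts = np.empty((n_fine, 3))
    straight = s <= Ls
    pts[straight] = s[straight, None] * d0
    R = spec.branch_curv_radius
    sa = s[~straight] - Ls
    p_anchor = Ls * d0
    if np.isinf(R):
        pts[~straight] = p_anchor + sa[:, None] * d0
    else:
        ang = sa / R
        center = p_anchor + R * m
        pts[~straight] = (
            center
            - R * np.cos(ang)[:, None] * m
            + R * np.sin(ang)[:, None] * d0
        )
    if spec.tort_amp > 0.0:
        w = np.zeros(n_fine)
        post = s > Ls
        sp = (s[post] - Ls) / (L - Ls)
        w[post] = np.sin(np.pi * sp) ** 2
        pts += (
            spec.tort_amp
            * w[:, None]
            * np.sin(2 * np.pi * (s - Ls) / spec.tort_wavelength)[:, None]
            * b
        )
    return pts


def _parallel_transport_frames(points):
    """Rotation-minimizing normals along a polyline (double-reflection-free
    simple transport; adequate at the fine sampling used here)."""
    tangents = np.gradient(points, polyline_arclength(points), axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.empty_like(tangents)
    t0 = tangents[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n = ref - np.dot(ref, t0) * t0
    normals[0] = n / np.linalg.norm(n)
    for i in range(1, len(points)):
        n = normals[i - 1] - np.dot(normals[i - 1], tangents[i]) * tangents[i]
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            n = np.cross(tangents[i], np.cross(normals[i - 1], tangents[i]))
            nn = np.linalg.norm(n)
        normals[i] = n / nn
    return tangents, normals


def _sweep_tube(path, radii, n_circ=64, step_mm=0.5, cap=True):
    """Sweep a circular tube of per-sample radius along a fine path."""
    s = polyline_arclength(path)
    n_rings = max(int(np.ceil(s[-1] / step_mm)) + 1, 4)
    sg = np.linspace(0.0, s[-1], n_rings)
    ctr = np.stack([np.interp(sg, s, path[:, k]) for k in range(3)], axis=1)
    rad = np.interp(sg, s, radii)
    tangents, normals = _parallel_transport_frames(ctr)
    binormals = np.cross(tangents, normals)
    phi = np.linspace(0.0, 2 * np.pi, n_circ, endpoint=False)
    ring = np.cos(phi)[:, None, None] * normals + np.sin(phi)[:, None, None] * binormals
    verts = (ctr[None] + rad[None, :, None] * ring).transpose(1, 0, 2).reshape(-1, 3)

    faces = []
    for i in range(n_rings - 1):
        a = i * n_circ + np.arange(n_circ)
        b = (a + 1) % n_circ + i * n_circ
        c = a + n_circ
        d = (a + 1) % n_circ + (i + 1) * n_circ
        faces.append(np.stack([a, b, d], axis=1))
        faces.append(np.stack([a, d, c], axis=1))
    faces = np.concatenate(faces)
    verts = list(verts)
    faces = list(faces)
    if cap:
        for ring_i, flip in ((0, True), (n_rings - 1, False)):
            ci = len(verts)
            verts.append(ctr[ring_i])
            base = ring_i * n_circ
            for j in range(n_circ):
                tri = [base + j, base + (j + 1) % n_circ, ci]
                if flip:
                    tri = tri[::-1]
                faces.append(np.array(tri))
    return np.asarray(verts), np.asarray(faces, dtype=np.int64)


def _junction_fillet(vertices, faces, center, radius, n_iter=2):
    """Light Laplacian vertex averaging within one diameter of the junction."""
    from scipy.sparse import coo_matrix

    n = len(vertices)
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    adj.data[:] = 1.0
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    inside = np.linalg.norm(vertices - center, axis=1) < radius
    v = vertices.copy()
    for _ in range(n_iter):
        avg = adj.dot(v) / deg[:, None]
        v[inside] = 0.5 * v[inside] + 0.5 * avg[inside]
    return v


def generate_bifurcation(
    spec: SyntheticBifurcationSpec,
    n_circ: int = 64,
    step_mm: float = 0.5,
    centerline_step_mm: float = 1.0,
    fillet: bool = True,
):
    """Generate (TriSurface, [RawCenterline x3], BifurcationGroundTruth).

    Daughter centerlines are emitted VMTK-style: they include the trunk run
    from the MPA inlet through O, so origin detection has the upstream
    overlap it needs.
    """
    O = np.zeros(3)
    u = np.array([0.0, 0.0, 1.0])
    trunk = straight_path(O - spec.mpa_length * u, u, spec.mpa_length, n=800)

    r_mpa = 0.5 * spec.D_MPA
    sides = {"RPA": +1, "LPA": -1}
    diam = {"RPA": spec.D_RPA, "LPA": spec.D_LPA}
    inpl = {"RPA": spec.inplane_RPA, "LPA": spec.inplane_LPA}
    outpl = {"RPA": spec.outplane_RPA, "LPA": spec.outplane_LPA}

    paths = {"MPA": trunk}
    path_radii = {"MPA": np.full(len(trunk), r_mpa)}
    tort, kmean, kmax = {}, {}, {}
    for b in ("RPA", "LPA"):
        d0 = _daughter_direction(inpl[b], outpl[b], sides[b])
        pts = _daughter_path(spec, d0, sides[b])
        s = polyline_arclength(pts)
        r0 = 0.5 * diam[b]
        radii = r0 * (1.0 - spec.taper * s / s[-1])
        kap = polyline_curvature(pts)
        if np.max(kap * radii) >= 0.95:
            raise GenerationError(
                f"{b}: sweep would self-intersect (max kappa*r = "
                f"{np.max(kap * radii):.2f}); reduce tort_amp or curvature"
            )
        paths[b] = pts
        path_radii[b] = radii
        # stats over the same trimmed span the pipeline analyses:
        # O to branch end, excluding 0.5 D_ref at each extremity
        core = (s > 0.5 * spec.D_MPA) & (s < s[-1] - 0.5 * spec.D_MPA)
        pc = pts[core]
        sc = s[core]
        chord = np.linalg.norm(pc[-1] - pc[0])
        tort[b] = float((sc[-1] - sc[0]) / chord - 1.0)
        kmean[b] = float(np.mean(kap[core]))
        kmax[b] = float(np.max(kap[core]))

    # swept union
    all_v, all_f = [], []
    offset = 0
    for b in ("MPA", "RPA", "LPA"):
        v, f = _sweep_tube(paths[b], path_radii[b], n_circ=n_circ, step_mm=step_mm)
        all_v.append(v)
        all_f.append(f + offset)
        offset += len(v)
    vertices = np.vstack(all_v)
    faces = np.vstack(all_f)
    if fillet:
        vertices = _junction_fillet(vertices, faces, O, spec.D_MPA)
    surface = TriSurface(vertices=vertices, faces=faces)

    # centerlines: MPA trunk alone; daughters prefixed with the trunk run
    def _resample(pts, radii, step):
        s = polyline_arclength(pts)
        sg = np.linspace(0.0, s[-1], max(int(np.round(s[-1] / step)) + 1, 4))
        p = np.stack([np.interp(sg, s, pts[:, k]) for k in range(3)], axis=1)
        return p, np.interp(sg, s, radii)

    centerlines = []
    p, r = _resample(trunk, path_radii["MPA"], centerline_step_mm)
    centerlines.append(RawCenterline("MPA", p, r))
    for b in ("RPA", "LPA"):
        joint = np.vstack([trunk[:-1], paths[b]])
        jr = np.concatenate([path_radii["MPA"][:-1], path_radii[b]])
        p, r = _resample(joint, jr, centerline_step_mm)
        centerlines.append(RawCenterline(b, p, r))

    gt = BifurcationGroundTruth(
        junction=O,
        plane_normal=np.array([0.0, -1.0, 0.0]),
        D_ref_mm=spec.D_MPA,
        inplane_deg=dict(inpl),
        outplane_deg=dict(outpl),
        tortuosity=tort,
        kappa_mean=kmean,
        kappa_max=kmax,
        radius_mm={"MPA": r_mpa, "RPA": 0.5 * spec.D_RPA, "LPA": 0.5 * spec.D_LPA},
        paths=paths,
        path_radii=path_radii,
    )
    return surface, centerlines, gt


def exact_branch_angles(gt: BifurcationGroundTruth, window_factor: float = 1.5,
                        tangent_factor: float = 1.0):
    """Evaluate the pipeline's angle/plane conventions on the exact
    analytic paths (known O, no smoothing): the convention-consistent
    oracle for angle-recovery tests.
    """
    from .morphometry import BifurcationFrame, CenterlineCurve, branch_angles, \
        bifurcation_plane

    curves = []
    for b in ("MPA", "RPA", "LPA"):
        pts = gt.paths[b] if b == "MPA" else np.vstack(
            [gt.paths["MPA"][:-1], gt.paths[b]]
        )
        radii = gt.path_radii[b] if b == "MPA" else np.concatenate(
            [gt.path_radii["MPA"][:-1], gt.path_radii[b]]
        )
        s = polyline_arclength(pts)
        d1 = np.gradient(pts, s, axis=0)
        d1 /= np.linalg.norm(d1, axis=1, keepdims=True)
        zeros = np.zeros_like(pts)
        curves.append(CenterlineCurve(b, s, pts, d1, zeros, zeros, radii))
    point, normal = bifurcation_plane(
        curves, origin_O=gt.junction, D_ref_mm=gt.D_ref_mm,
        window_mm=window_factor * gt.D_ref_mm,
    )
    frame = BifurcationFrame(origin_O=np.asarray(gt.junction, float),
                             plane_point=point, plane_normal=normal,
                             D_ref_mm=gt.D_ref_mm)
    return branch_angles(curves, frame,
                         tangent_arc_mm=tangent_factor * gt.D_ref_mm)


# --------------------------------------------------------------------------
# waveforms


def generate_waveform(
    family: str = "systolic_sine",
    params: dict | None = None,
    period_s: float = 0.8,
    regurgitant_fraction: float = 0.0,
    n_samples: int = 100,
):
    """One-cycle pulsatile flow-rate waveform Q(t) in ml/s.

    ``systolic_sine``: a sin^2 systolic lobe over the first ``systole_frac``
    of the cycle, followed (if ``regurgitant_fraction > 0``) by a negative
    diastolic sin^2 lobe scaled so that backward volume equals
    ``regurgitant_fraction`` times forward volume.
    """
    from .flow_characterization import FlowWaveform

    if period_s <= 0:
        raise ValueError("period_s must be positive")
    if not (0.0 <= regurgitant_fraction < 1.0):
        raise ValueError("regurgitant_fraction must lie in [0, 1)")
    if family != "systolic_sine":
        raise ValueError(f"unknown waveform family {family!r}")
    params = params or {}
    peak = float(params.get("peak_mls", 400.0))
    sf = float(params.get("systole_frac", 0.35))
    t = np.linspace(0.0, period_s, n_samples, endpoint=False)
    ts = sf * period_s
    Q = np.zeros_like(t)
    sys = t < ts
    Q[sys] = peak * np.sin(np.pi * t[sys] / ts) ** 2
    if regurgitant_fraction > 0.0:
        # forward volume = peak*ts/2; backward lobe integral = B*(T-ts)/2
        B = regurgitant_fraction * peak * ts / (period_s - ts)
        dia = ~sys
        Q[dia] = -B * np.sin(np.pi * (t[dia] - ts) / (period_s - ts)) ** 2
    return FlowWaveform(t=t, Q=Q, period_T=period_s)


# --------------------------------------------------------------------------
# voxel flow grids


def womersley_alpha(radius_m, period_s, nu=DEFAULT_MU / DEFAULT_RHO):
    return radius_m * np.sqrt(2 * np.pi / (nu * period_s))


def _womersley_shape(r_norm, alpha):
    """Complex oscillatory profile shape, unit cross-sectional average."""
    i32 = 1j ** 1.5
    j0a = jv(0, i32 * alpha)
    j1a = jv(1, i32 * alpha)
    denom = 1.0 - 2.0 * j1a / (i32 * alpha * j0a)
    return (1.0 - jv(0, i32 * alpha * r_norm) / j0a) / denom


def generate_voxel_flow(
    waveform,
    profile: str = "parabolic",
    lumen_radius_mm: float = 11.0,
    pixel_mm: float = 1.25,
    n_frames: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
    nu_m2s: float = DEFAULT_MU / DEFAULT_RHO,
) -> VoxelFlowSeries:
    """Voxel velocity series carrying a plug / parabolic / womersley_like
    profile whose per-frame discrete flux equals the waveform exactly
    before noise (each frame is flux-normalized over the discrete mask).
    """
    if pixel_mm >= lumen_radius_mm / 3.0:
        raise ValueError("grid too coarse: pixel_mm must be < lumen_radius_mm / 3")
    if profile not in ("plug", "parabolic", "womersley_like"):
        raise ValueError(f"unknown profile {profile!r}")
    R = lumen_radius_mm
    half = int(np.ceil(R / pixel_mm)) + 1
    ax = (np.arange(-half, half + 1) + 0.0) * pixel_mm
    X, Y = np.meshgrid(ax, ax)
    pos = np.stack([X.ravel(), Y.ravel(), np.zeros(X.size)], axis=1)
    r = np.hypot(pos[:, 0], pos[:, 1])
    mask = r <= R
    area_mm2 = mask.sum() * pixel_mm**2

    tf = np.linspace(0.0, waveform.period_T, n_frames, endpoint=False)
    Qf = waveform.resample(tf)  # ml/s

    rn = np.clip(r / R, 0.0, 1.0)
    if profile == "plug":
        shape_t = np.ones((n_frames, mask.sum()))
    elif profile == "parabolic":
        shp = 1.0 - rn[mask] ** 2
        shape_t = np.tile(shp, (n_frames, 1))
    else:  # womersley_like: steady part + first two harmonics
        alpha = womersley_alpha(R * 1e-3, waveform.period_T, nu_m2s)
        tq = np.linspace(0.0, waveform.period_T, 256, endpoint=False)
        q = waveform.resample(tq)
        coeffs = np.fft.rfft(q) / len(tq)
        omega_t = 2 * np.pi * tf / waveform.period_T
        shape_t = np.tile(
            (2.0 * (1.0 - rn[mask] ** 2)) * coeffs[0].real, (n_frames, 1)
        )
        for h in (1, 2):
            sh = _womersley_shape(rn[mask], alpha * np.sqrt(h))
            phase = np.exp(1j * h * omega_t)
            shape_t += 2.0 * np.real(coeffs[h] * phase[:, None] * sh[None, :])
    v = np.zeros((n_frames, len(pos)))
    for f in range(n_frames):
        s = shape_t[f]
        mean_s = s.mean()
        if abs(mean_s) < 1e-12:
            scaled = np.zeros_like(s) if abs(Qf[f]) < 1e-12 else None
            if scaled is None:
                # degenerate frame: fall back to plug at the required flux
                scaled = np.full_like(s, (Qf[f] * 1e3) / area_mm2)
        else:
            # Q [ml/s] = 1e3 mm^3/s; v [m/s] * area [mm^2] * 1e-3 = ml/s
            v_mean_mps = Qf[f] / area_mm2  # ml/s / mm^2 == m/s
            scaled = v_mean_mps * s / mean_s
        v[f, mask] = scaled
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        v[:, mask] += rng.normal(0.0, noise_sd, size=(n_frames, int(mask.sum())))
    return VoxelFlowSeries(
        t_s=tf, positions=pos, v_mps=v, in_mask=mask, pixel_area_mm2=pixel_mm**2
    )


# --------------------------------------------------------------------------
# wall-shear series


@dataclass
class WallFieldGroundTruth:
    tawss_pa: float
    osi: float


def generate_wall_field(
    surface: TriSurface,
    pattern: str = "constant_vector",
    waveform=None,
    period_s: float = 0.8,
    n_steps: int = 64,
    amplitude_pa: float = 2.0,
    tube_radius_mm: float = 10.0,
    mu_pa_s: float = DEFAULT_MU,
    direction=(1.0, 0.0, 0.0),
):
    """Wall-shear vector series with closed-form TAWSS/OSI ground truth.

    Patterns: ``constant_vector`` (TAWSS = amplitude, OSI = 0),
    ``zero_mean_oscillatory`` A sin(2 pi t / T) e (TAWSS = 2A/pi, OSI = 0.5),
    ``poiseuille_scaled`` tau(t) = 4 mu Q(t) / (pi R^3) along a fixed
    direction.
    """
    if pattern not in ("constant_vector", "poiseuille_scaled", "zero_mean_oscillatory"):
        raise ValueError(f"unknown pattern {pattern!r}")
    e = np.asarray(direction, float)
    e = e / np.linalg.norm(e)
    t = np.linspace(0.0, period_s, n_steps + 1)  # first/last identified
    n = surface.n_vertices
    if pattern == "constant_vector":
        mag = np.full(len(t), amplitude_pa)
        gt = WallFieldGroundTruth(tawss_pa=amplitude_pa, osi=0.0)
    elif pattern == "zero_mean_oscillatory":
        mag = amplitude_pa * np.sin(2 * np.pi * t / period_s)
        gt = WallFieldGroundTruth(tawss_pa=2.0 * amplitude_pa / np.pi, osi=0.5)
    else:
        if waveform is None:
            raise ValueError("poiseuille_scaled requires a waveform")
        Q = waveform.resample(np.mod(t, waveform.period_T)) * 1e-6  # m^3/s
        R = tube_radius_mm * 1e-3
        mag = 4.0 * mu_pa_s * Q / (np.pi * R**3)
        # fine-quadrature ground truth of the analytic magnitude integral
        tq = np.linspace(0.0, period_s, 4096, endpoint=False)
        Qq = waveform.resample(np.mod(tq, waveform.period_T)) * 1e-6
        mq = 4.0 * mu_pa_s * Qq / (np.pi * R**3)
        denom = np.mean(np.abs(mq))
        gt = WallFieldGroundTruth(
            tawss_pa=float(denom),
            osi=float(0.5 * (1.0 - abs(np.mean(mq)) / denom)) if denom > 0 else 0.0,
        )
    tau = mag[:, None, None] * np.broadcast_to(e, (n, 3))[None]
    series = WallFieldSeries(surface=surface, t_s=t, tau=tau.copy(), period_T=period_s)
    return series, gt


# --------------------------------------------------------------------------
# cohorts


def generate_cohort(spec: SyntheticCohortSpec, n_circ: int = 64, step_mm: float = 0.5):
    """Draw ``n_models`` bifurcation specs + waveforms from uniform ranges.

    Returns a list of dicts with keys ``spec``, ``surface``, ``centerlines``,
    ``ground_truth``, ``waveform``. Deterministic given the cohort seed.
    """
    rng = np.random.default_rng(spec.seed)
    models = []
    for i in range(spec.n_models):
        # rejection-sample geometrically feasible draws: range corners can
        # combine into self-intersecting sweeps (tight arc + wide branch)
        for _ in range(50):
            draws = {k: float(rng.uniform(*v)) for k, v in spec.ranges.items()}
            d_mpa = draws["D_MPA"]
            bspec = SyntheticBifurcationSpec(
                D_MPA=d_mpa,
                D_RPA=min(draws["D_RPA"], 0.95 * d_mpa),
                D_LPA=min(draws["D_LPA"], 0.95 * d_mpa),
                inplane_RPA=draws["inplane_RPA"],
                inplane_LPA=draws["inplane_LPA"],
                outplane_RPA=draws["outplane_RPA"],
                outplane_LPA=draws["outplane_LPA"],
                branch_curv_radius=draws["branch_curv_radius"],
                tort_amp=draws["tort_amp"],
                tort_wavelength=draws["tort_wavelength"],
                branch_length=2.3 * d_mpa,
                taper=draws["taper"],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            try:
                surface, centerlines, gt = generate_bifurcation(
                    bspec, n_circ=n_circ, step_mm=step_mm
                )
                break
            except GenerationError:
                continue
        else:
            raise GenerationError("no feasible draw in 50 attempts; narrow ranges")
        period = float(rng.uniform(*spec.waveform["period_s"]))
        q_mean = float(rng.uniform(*spec.waveform["q_mean_mls"]))
        rf = float(rng.uniform(*spec.waveform["regurgitant_fraction"]))
        sf = 0.35
        # net mean of the lobe model = peak*sf/2*(1-rf)/1
        peak = q_mean / (0.5 * sf * (1.0 - rf))
        wf = generate_waveform(
            params={"peak_mls": peak, "systole_frac": sf},
            period_s=period,
            regurgitant_fraction=rf,
        )
        models.append(
            {
                "spec": bspec,
                "surface": surface,
                "centerlines": centerlines,
                "ground_truth": gt,
                "waveform": wf,
            }
        )
    return models
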