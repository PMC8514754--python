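"""Wall-shear post-processing: TAWSS, inlet-normalized TAWSS, OSI,
cross-section cutting and eight-point perimeter sampling, secondary-flow
decomposition, and cohort wall-shear summaries.

TAWSS = (1/T) integral_0^T |tau_w(t)| dt per vertex by periodic trapezoid;
OSI = 0.5 (1 - |integral tau dt| / integral |tau| dt) (0 where the
denominator vanishes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree

from ._geometry import vertex_lumped_areas
from .io_formats import TriSurface, WallFieldSeries
from .morphometry import BifurcationFrame, CenterlineCurve, _arc_position

log = logging.getLogger(__name__)


@dataclass
class TawssField:
    tawss: np.ndarray  # (N,) Pa
    tawss_n: np.ndarray  # dimensionless
    reference_value: float  # Pa


@dataclass
class CrossSection:
    label: str
    plane_origin: np.ndarray
    plane_normal: np.ndarray  # local centerline tangent
    boundary: np.ndarray  # (K, 3) ordered closed loop (last != first)
    arc_from_O_mm: float

    @property
    def circumference_mm(self) -> float:
        loop = np.vstack([self.boundary, self.boundary[:1]])
        return float(np.linalg.norm(np.diff(loop, axis=0), axis=1).sum())

    @property
    def centroid(self) -> np.ndarray:
        return self.boundary.mean(axis=0)


# --------------------------------------------------------------------------
# time integrals


def _check_periodic(series: WallFieldSeries, rtol=1e-6):
    t = series.t_s
    if abs(t[0]) > rtol * series.period_T or abs(t[-1] - series.period_T) > rtol * series.period_T:
        raise ValueError(
            "wall field series must span [0, T] with first/last steps identified"
        )


def tawss(series: WallFieldSeries) -> np.ndarray:
    """Per-vertex time-averaged wall-shear magnitude (Pa)."""
    if len(series.t_s) < 3:
        raise ValueError("need at least 3 steps")
    _check_periodic(series)
    mag = np.linalg.norm(series.tau, axis=2)  # (S, N)
    return np.trapezoid(mag, series.t_s, axis=0) / series.period_T


def osi(series: WallFieldSeries) -> np.ndarray:
    """Per-vertex oscillatory shear index in [0, 0.5]."""
    if len(series.t_s) < 3:
        raise ValueError("need at least 3 steps")
    _check_periodic(series)
    mean_vec = np.trapezoid(series.tau, series.t_s, axis=0)
    mean_mag = np.trapezoid(np.linalg.norm(series.tau, axis=2), series.t_s, axis=0)
    out = np.zeros(series.surface.n_vertices)
    ok = mean_mag > 0.0
    out[ok] = 0.5 * (1.0 - np.linalg.norm(mean_vec[ok], axis=1) / mean_mag[ok])
    return np.clip(out, 0.0, 0.5)


def tawss_normalize(
    surface: TriSurface,
    tawss_field: np.ndarray,
    inlet_center,
    inlet_normal,
    local_radius_mm: float,
) -> TawssField:
    """Normalize by the area-weighted mean TAWSS over the wall band one
    local radius wide adjacent to the inlet."""
    c = np.asarray(inlet_center, float)
    n = np.asarray(inlet_normal, float)
    n = n / np.linalg.norm(n)
    rel = surface.vertices - c
    axial = rel @ n
    radial = np.linalg.norm(rel - axial[:, None] * n, axis=1)
    band = (axial >= 0.0) & (axial <= local_radius_mm) & (radial <= 2.0 * local_radius_mm)
    if not band.any():
        raise ValueError("empty inlet band: check inlet center/normal")
    w = vertex_lumped_areas(surface.vertices, surface.faces)[band]
    ref = float(np.average(tawss_field[band], weights=w))
    if ref == 0.0:
        raise ValueError("zero inlet reference TAWSS")
    return TawssField(tawss=tawss_field, tawss_n=tawss_field / ref, reference_value=ref)


# --------------------------------------------------------------------------
# cross-sections


def cut_cross_section(
    surface: TriSurface,
    curve: CenterlineCurve,
    frame: BifurcationFrame,
    fraction_of_D: float,
    label: str = "",
) -> CrossSection:
    """Cut the surface with the plane at arc distance ``fraction_of_D *
    D_ref`` from O along the branch centerline (normal = local tangent);
    keep the intersection loop nearest the centerline point."""
    s0 = _arc_position(curve, frame.origin_O)
    s_cut = s0 + fraction_of_D * frame.D_ref_mm
    if s_cut > curve.s[-1]:
        raise ValueError("branch too short for the requested cut distance")
    origin = curve.point_at(s_cut)[0]
    normal = curve.tangent_at(s_cut)[0]

    mesh = trimesh.Trimesh(surface.vertices, surface.faces, process=False)
    sec = mesh.section(plane_origin=origin, plane_normal=normal)
    if sec is None or len(sec.entities) == 0:
        raise ValueError("plane does not intersect the surface")
    loops = [np.asarray(d) for d in sec.discrete]
    dists = [np.linalg.norm(lp.mean(axis=0) - origin) for lp in loops]
    if len(loops) > 1:
        log.info("cross-section %s: %d loops found, keeping nearest, "
                 "discarding %d", label, len(loops), len(loops) - 1)
    loop = loops[int(np.argmin(dists))]
    if np.allclose(loop[0], loop[-1]):
        loop = loop[:-1]
    return CrossSection(
        label=label,
        plane_origin=origin,
        plane_normal=normal,
        boundary=loop,
        arc_from_O_mm=float(s_cut - s0),
    )


def perimeter_sample(
    section: CrossSection,
    surface: TriSurface,
    field: np.ndarray,
    n_points: int = 8,
    anchor_direction=None,
):
    """Sample a per-vertex field at ``n_points`` equally spaced (by arc
    length) boundary points, starting at the loop point most aligned with
    ``anchor_direction`` (default: radial direction of the first loop
    point — fixed so results are reproducible). Returns (values, mean)."""
    loop = np.vstack([section.boundary, section.boundary[:1]])
    seg = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    centroid = section.centroid
    if anchor_direction is not None:
        a = np.asarray(anchor_direction, float)
        proj = (section.boundary - centroid) @ a
        start = int(np.argmax(proj))
    else:
        start = 0
    s_start = s[start]
    targets = np.mod(s_start + np.arange(n_points) * total / n_points, total)
    pts = np.stack(
        [np.interp(targets, s, loop[:, k]) for k in range(3)], axis=1
    )
    tree = cKDTree(surface.vertices)
    _, vid = tree.query(pts)
    values = field[vid]
    return values, float(values.mean())


# --------------------------------------------------------------------------
# secondary flow


def secondary_flow_decomposition(velocities, plane_normal, normalize_by=None):
    """Split slice velocities into through-plane and in-plane parts.

    Returns (in_plane_vectors, normal_component); optionally divides both
    by ``normalize_by`` (e.g. the cycle-maximum velocity magnitude).
    """
    v = np.asarray(velocities, float)
    n = np.asarray(plane_normal, float)
    n = n / np.linalg.norm(n)
    vn = v @ n
    vin = v - vn[:, None] * n
    if normalize_by is not None:
        if normalize_by <= 0:
            raise ValueError("normalization constant must be positive")
        vn = vn / normalize_by
        vin = vin / normalize_by
    return vin, vn


# --------------------------------------------------------------------------
# cohort summary


def cohort_wss_summary(per_model: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sample SD of eight-point section means across models.

    ``per_model`` columns: model, section, condition, tawss_pa, tawss_n.
    Output mirrors a section-by-condition summary table; empty condition
    groups are omitted with a warning.
    """
    if len(per_model) == 0:
        raise ValueError("no models to summarize")
    rows = []
    for (section, condition), grp in per_model.groupby(["section", "condition"]):
        if len(grp) == 0:
            log.warning("empty condition column %s/%s omitted", section, condition)
            continue
        row = {"section": section, "condition": condition, "n": len(grp)}
        for col in ("tawss_pa", "tawss_n"):
            if col in grp:
                row[f"{col}_mean"] = grp[col].mean()
                row[f"{col}_sd"] = grp[col].std(ddof=1) if len(grp) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
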