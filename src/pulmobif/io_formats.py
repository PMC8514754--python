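"""External representations of the pipeline: STL surfaces, centerline CSVs,
voxel-velocity series, wall-shear series, and ascii inlet triangulations.

Unit conventions (fixed across the package): geometry in millimetres,
velocities in m/s, wall shear in Pa, time in seconds. Conversion to SI
lengths happens only inside the dimensionless-number computations.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

log = logging.getLogger(__name__)

BRANCH_IDS = ("MPA", "RPA", "LPA")


class FormatError(ValueError):
    """A file failed to parse as its declared format."""


class SchemaError(ValueError):
    """A file parsed, but violates the declared column/row schema."""


# --------------------------------------------------------------------------
# containers


@dataclass
class TriSurface:
    """Triangulated vessel wall (mm) with optional per-vertex fields."""

    vertices: np.ndarray  # (N, 3) mm
    faces: np.ndarray  # (M, 3) int
    vertex_fields: dict[str, np.ndarray] = field(default_factory=dict)
    patch_labels: np.ndarray | None = None  # (M,) face labels

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index exceeds vertex count")
        for name, arr in self.vertex_fields.items():
            if len(arr) != len(self.vertices):
                raise ValueError(f"vertex field {name!r} length mismatch")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclass
class RawCenterline:
    """Ordered centerline points of one branch with inscribed-sphere radii."""

    branch_id: str
    points: np.ndarray  # (N, 3) mm
    radii: np.ndarray  # (N,) mm

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if len(self.points) < 4:
            raise ValueError(f"{self.branch_id}: need >= 4 centerline points")
        if np.any(self.radii <= 0):
            raise ValueError(f"{self.branch_id}: radii must be positive")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps == 0.0):
            raise ValueError(f"{self.branch_id}: consecutive duplicate points")


@dataclass
class InletPatch:
    """Disk-topology inlet triangulation of the fluid domain."""

    nodes: np.ndarray  # (N, 3) mm
    triangles: np.ndarray  # (M, 3) int
    centroid: np.ndarray = None
    unit_normal: np.ndarray = None  # points into the fluid domain

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.centroid is None:
            self.centroid = self.nodes.mean(axis=0)
        if self.unit_normal is None:
            from ._geometry import face_normals, face_areas

            n = face_normals(self.nodes, self.triangles)
            a = face_areas(self.nodes, self.triangles)
            mean_n = (n * a[:, None]).sum(axis=0)
            self.unit_normal = mean_n / np.linalg.norm(mean_n)
        self.unit_normal = np.asarray(self.unit_normal, dtype=float)
        nn = np.linalg.norm(self.unit_normal)
        if not np.isclose(nn, 1.0, atol=1e-6):
            self.unit_normal = self.unit_normal / nn


@dataclass
class VoxelFlowSeries:
    """Time-resolved through-plane voxel velocities inside a lumen mask.

    Emulates a PC-MRI export: one velocity sample per voxel per cardiac
    frame, with a binary lumen mask. Positions mm, velocity m/s.
    """

    t_s: np.ndarray  # (F,)
    positions: np.ndarray  # (V, 3) mm, constant across frames
    v_mps: np.ndarray  # (F, V)
    in_mask: np.ndarray  # (V,) bool
    pixel_area_mm2: float

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.v_mps = np.asarray(self.v_mps, dtype=float)
        self.in_mask = np.asarray(self.in_mask, dtype=bool)
        if self.v_mps.shape != (len(self.t_s), len(self.positions)):
            raise ValueError("v_mps shape must be (n_frames, n_voxels)")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("t_s must be strictly increasing")
        if self.pixel_area_mm2 <= 0:
            raise ValueError("pixel_area_mm2 must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.t_s)

    @property
    def n_voxels(self) -> int:
        return len(self.positions)


@dataclass
class WallFieldSeries:
    """Per-vertex wall-shear vectors tau(t) (Pa) over one cardiac cycle."""

    surface: TriSurface
    t_s: np.ndarray  # (S,)
    tau: np.ndarray  # (S, N, 3) Pa
    period_T: float

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.shape[0] != len(self.t_s):
            raise ValueError("tau step count must match t_s")
        if self.tau.shape[1] != self.surface.n_vertices:
            raise ValueError("tau vertex count must match surface")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("t_s must be strictly increasing")
        if self.period_T <= 0:
            raise ValueError("period must be positive")


# --------------------------------------------------------------------------
# STL surfaces


def read_surface(path, format: str = "auto", merge_tol_mm: float = 1e-6) -> TriSurface:
    """Read an STL surface (ascii or binary), merging duplicate vertices and
    dropping zero-area facets (logged with a count).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        mesh = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # corrupt header / truncated facet block
        size = path.stat().st_size
        raise FormatError(
            f"{path}: failed to parse STL (file size {size} bytes): {exc}"
        ) from exc
    if isinstance(mesh, trimesh.Scene):
        raise FormatError(f"{path}: expected a single STL solid")
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    vertices, faces = _merge_vertices(vertices, faces, merge_tol_mm)
    from ._geometry import face_areas

    keep = face_areas(vertices, faces) > 1e-14
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("%s: dropped %d zero-area facet(s), %d retained",
                    path.name, n_dropped, int(keep.sum()))
    return TriSurface(vertices=vertices, faces=faces[keep])


def write_surface(surface: TriSurface, path, format: str = "stl_ascii") -> None:
    mesh = surface.as_trimesh()
    path = Path(path)
    if format == "stl_ascii":
        Path(path).write_text(mesh.export(file_type="stl_ascii"))
    elif format == "stl_binary":
        Path(path).write_bytes(mesh.export(file_type="stl"))
    else:
        raise ValueError(f"unknown STL format {format!r}")


def _merge_vertices(vertices, faces, tol):
    """Merge vertices closer than ``tol`` by coordinate rounding."""
    if len(vertices) == 0:
        return vertices, faces
    key = np.round(vertices / max(tol, 1e-12)).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    merged = vertices[first]
    new_faces = inverse[faces]
    # drop collapsed faces
    ok = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    return merged, new_faces[ok]


# --------------------------------------------------------------------------
# centerlines

_CENTERLINE_COLS = ["branch_id", "point_index", "x_mm", "y_mm", "z_mm", "radius_mm"]


def read_centerlines(path) -> list[RawCenterline]:
    df = pd.read_csv(path)
    missing = [c for c in _CENTERLINE_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    bad = df.index[df["radius_mm"] <= 0]
    if len(bad):
        # +2: header line plus 1-based file rows
        raise SchemaError(f"{path}: radius_mm <= 0 at row {bad[0] + 2}")
    out = []
    for bid, grp in df.groupby("branch_id", sort=False):
        idx = grp["point_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            row = grp.index[np.argmax(np.diff(idx) <= 0) + 1] + 2
            raise SchemaError(f"{path}: non-monotone point_index at row {row}")
        out.append(
            RawCenterline(
                branch_id=str(bid),
                points=grp[["x_mm", "y_mm", "z_mm"]].to_numpy(),
                radii=grp["radius_mm"].to_numpy(),
            )
        )
    return out


def write_centerlines(centerlines: list[RawCenterline], path) -> None:
    frames = []
    for cl in centerlines:
        frames.append(
            pd.DataFrame(
                {
                    "branch_id": cl.branch_id,
                    "point_index": np.arange(len(cl.points)),
                    "x_mm": cl.points[:, 0],
                    "y_mm": cl.points[:, 1],
                    "z_mm": cl.points[:, 2],
                    "radius_mm": cl.radii,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format="%.6f")


# --------------------------------------------------------------------------
# voxel flow series

_VOXEL_COLS = ["frame", "t_s", "x_mm", "y_mm", "z_mm", "v_mps", "in_mask"]


def read_voxel_flow(path, pixel_area_mm2: float | None = None) -> VoxelFlowSeries:
    df = pd.read_csv(path)
    missing = [c for c in _VOXEL_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    frames = np.sort(df["frame"].unique())
    expected = np.arange(len(frames))
    if not np.array_equal(frames, expected):
        gaps = sorted(set(expected) - set(frames)) or list(frames)
        raise SchemaError(f"{path}: frames not contiguous from 0 (problem near {gaps})")
    counts = df.groupby("frame").size()
    if counts.nunique() != 1:
        offenders = counts[counts != counts.iloc[0]].index.tolist()
        raise SchemaError(f"{path}: inconsistent voxel counts in frames {offenders}")
    df = df.sort_values(["frame", "y_mm", "x_mm"], kind="stable")
    nv = int(counts.iloc[0])
    t_s = df.groupby("frame")["t_s"].first().to_numpy()
    if np.any(np.diff(t_s) <= 0):
        raise SchemaError(f"{path}: t_s not strictly increasing with frame")
    f0 = df[df["frame"] == 0]
    positions = f0[["x_mm", "y_mm", "z_mm"]].to_numpy()
    v = df["v_mps"].to_numpy().reshape(len(frames), nv)
    mask = f0["in_mask"].to_numpy().astype(bool)
    if pixel_area_mm2 is None:
        pixel_area_mm2 = _infer_pixel_area(positions)
    return VoxelFlowSeries(t_s=t_s, positions=positions, v_mps=v,
                           in_mask=mask, pixel_area_mm2=pixel_area_mm2)


def _infer_pixel_area(positions: np.ndarray) -> float:
    """Infer pixel area from the smallest nonzero x/y spacings."""
    dx = np.diff(np.unique(np.round(positions[:, 0], 9)))
    dy = np.diff(np.unique(np.round(positions[:, 1], 9)))
    if len(dx) == 0 or len(dy) == 0:
        raise SchemaError("cannot infer pixel area from a degenerate grid")
    return float(dx.min() * dy.min())


def write_voxel_flow(series: VoxelFlowSeries, path) -> None:
    rows = []
    for f in range(series.n_frames):
        rows.append(
            pd.DataFrame(
                {
                    "frame": f,
                    "t_s": series.t_s[f],
                    "x_mm": series.positions[:, 0],
                    "y_mm": series.positions[:, 1],
                    "z_mm": series.positions[:, 2],
                    "v_mps": series.v_mps[f],
                    "in_mask": series.in_mask.astype(int),
                }
            )
        )
    pd.concat(rows).to_csv(path, index=False, float_format="%.9g")


# --------------------------------------------------------------------------
# wall-shear series (one CSV per step + manifest)


def write_wall_field(series: WallFieldSeries, out_dir, stem: str = "tau") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for s in range(len(series.t_s)):
        fname = f"{stem}_{s:04d}.csv"
        pd.DataFrame(series.tau[s], columns=["taux_pa", "tauy_pa", "tauz_pa"]).to_csv(
            out_dir / fname, index=False, float_format="%.12g"
        )
        manifest.append({"step": s, "t_s": series.t_s[s], "file": fname})
    pd.DataFrame(manifest).to_csv(out_dir / f"{stem}_manifest.csv", index=False)


def read_wall_field(out_dir, surface: TriSurface, stem: str = "tau",
                    period_T: float | None = None) -> WallFieldSeries:
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / f"{stem}_manifest.csv")
    t = manifest["t_s"].to_numpy()
    dup = manifest["t_s"][manifest["t_s"].duplicated()]
    if len(dup):
        raise SchemaError(f"manifest has duplicate t_s = {dup.iloc[0]}")
    taus = []
    n_ref = None
    for _, row in manifest.sort_values("step").iterrows():
        arr = pd.read_csv(out_dir / row["file"]).to_numpy()
        if n_ref is None:
            n_ref = len(arr)
        elif len(arr) != n_ref:
            raise SchemaError(
                f"vertex-count drift: step {int(row['step'])} has {len(arr)} "
                f"vertices, expected {n_ref}"
            )
        taus.append(arr)
    if period_T is None:
        period_T = float(t[-1])
    return WallFieldSeries(surface=surface, t_s=t, tau=np.stack(taus), period_T=period_T)


# --------------------------------------------------------------------------
# ascii inlet triangulation (Gmsh-style minimal node/element listing)


def read_inlet_patch(path) -> InletPatch:
    """Parse a minimal ascii listing: ``nodes`` block of ``id x y z`` rows
    then an ``elements`` block of ``id n1 n2 n3`` rows (1-based ids).
    """
    nodes, tris = [], []
    section = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        low = s.lower()
        if low.startswith("nodes"):
            section = "nodes"
            continue
        if low.startswith("elements"):
            section = "elements"
            continue
        parts = s.split()
        if section == "nodes":
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 'id x y z'")
            nodes.append([float(parts[1]), float(parts[2]), float(parts[3])])
        elif section == "elements":
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 'id n1 n2 n3'")
            tris.append([int(parts[1]) - 1, int(parts[2]) - 1, int(parts[3]) - 1])
        else:
            raise FormatError(f"{path}:{lineno}: data before a section header")
    if not nodes or not tris:
        raise FormatError(f"{path}: missing nodes or elements block")
    return InletPatch(nodes=np.array(nodes), triangles=np.array(tris))


def write_inlet_patch(patch: InletPatch, path) -> None:
    lines = ["nodes"]
    for i, p in enumerate(patch.nodes, 1):
        lines.append(f"{i} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    lines.append("elements")
    for i, t in enumerate(patch.triangles, 1):
        lines.append(f"{i} {t[0] + 1} {t[1] + 1} {t[2] + 1}")
    Path(path).write_text("\n".join(lines) + "\n")
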