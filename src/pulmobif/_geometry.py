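"""Low-level geometric primitives shared across modules.

Point-to-triangle distance uses a cKDTree candidate search over face
centroids followed by an exact barycentric-clamp projection, so it needs no
spatial-index extension beyond scipy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "closest_point_on_surface",
    "signed_distance",
    "fit_plane_tls",
    "vertex_lumped_areas",
    "face_areas",
    "face_normals",
    "angle_between_deg",
    "perpendicular_basis",
]


def face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def face_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0.0] = 1.0
    return n / norm


def vertex_lumped_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """One third of every incident triangle's area, accumulated per vertex."""
    areas = face_areas(vertices, faces)
    out = np.zeros(len(vertices))
    for i in range(3):
        np.add.at(out, faces[:, i], areas / 3.0)
    return out


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest points to ``p[i]`` on matched triangles ``tri[i]`` (N,3,3).

    Ericson's barycentric-region algorithm, fully vectorized.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex A
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    # vertex B
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m
    # vertex C
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m
    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m
    # interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class SurfaceDistance:
    """Reusable nearest-point query object for one triangulated surface."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 24):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.centroids = self.vertices[self.faces].mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self.k = min(k, len(self.faces))
        self.normals = face_normals(self.vertices, self.faces)

    def query(self, points: np.ndarray, chunk: int = 20000):
        """Return (closest_points, distances, face_ids)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        cps = np.empty_like(points)
        ds = np.empty(len(points))
        fids = np.empty(len(points), dtype=np.int64)
        for lo in range(0, len(points), chunk):
            p = points[lo : lo + chunk]
            _, idx = self.tree.query(p, k=self.k)
            idx = np.atleast_2d(idx)
            n, k = idx.shape
            tri = self.vertices[self.faces[idx.ravel()]]
            pc = np.repeat(p, k, axis=0)
            cp = _closest_on_triangles(pc, tri).reshape(n, k, 3)
            d2 = np.sum((cp - p[:, None, :]) ** 2, axis=2)
            best = np.argmin(d2, axis=1)
            rows = np.arange(n)
            cps[lo : lo + chunk] = cp[rows, best]
            ds[lo : lo + chunk] = np.sqrt(d2[rows, best])
            fids[lo : lo + chunk] = idx[rows, best]
        return cps, ds, fids

    def signed(self, points: np.ndarray, chunk: int = 20000) -> np.ndarray:
        """Signed distance, negative inside.

        Sign is taken from the outward normal of the nearest face; exact for
        smooth closed meshes away from sharp creases, which is adequate for
        the vessel sweeps and isosurfaces handled here.
        """
        cp, d, fid = self.query(points, chunk=chunk)
        side = np.einsum("ij,ij->i", np.atleast_2d(points) - cp, self.normals[fid])
        return np.where(side >= 0.0, d, -d)


def closest_point_on_surface(vertices, faces, points):
    return SurfaceDistance(vertices, faces).query(points)


def signed_distance(vertices, faces, points):
    return SurfaceDistance(vertices, faces).signed(points)


def fit_plane_tls(points: np.ndarray):
    """Total-least-squares plane fit; returns (point_on_plane, unit_normal).

    Normal = singular vector of the smallest singular value of the centered
    point cloud. Raises on degenerate (collinear) input.
    """
    points = np.asarray(points, dtype=float)
    centroid = points.mean(axis=0)
    u, s, vt = np.linalg.svd(points - centroid, full_matrices=False)
    if len(s) < 3 or (s[1] < 1e-12 * max(s[0], 1.0)):
        raise ValueError("plane fit degenerate: points are collinear")
    return centroid, vt[2]


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero-length vector in angle computation")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def perpendicular_basis(normal: np.ndarray):
    """Deterministic orthonormal in-plane basis (e1, e2) for a unit normal."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, n)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2
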