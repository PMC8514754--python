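"""Map voxel-wise through-plane velocities (a PC-MRI surrogate) onto a CFD
inlet triangulation and emit solver-ready per-timestep boundary files.

Both point sets are centered on their own centroid, projected into a shared
in-plane basis built from the inlet normal, and radius-normalized by their
own maximum radius. Each inlet node then takes the velocity of the closest
masked voxel in the normalized disc (Euclidean metric in
(r cos theta, r sin theta); ties resolved to the lowest voxel index). The
scalar velocity is applied along the inlet normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._geometry import perpendicular_basis, vertex_lumped_areas
from .io_formats import InletPatch, VoxelFlowSeries

log = logging.getLogger(__name__)


@dataclass
class MappedInletSeries:
    nodes: np.ndarray  # (N, 3) mm
    normal: np.ndarray  # unit, into the fluid domain
    t_s: np.ndarray  # (F,)
    v_node: np.ndarray  # (F, N) scalar velocity along the normal, m/s
    node_area_mm2: np.ndarray  # (N,) lumped nodal areas

    @property
    def velocity_vectors(self):
        """(F, N, 3) velocity vectors along the inlet normal."""
        return self.v_node[:, :, None] * self.normal[None, None, :]

    def flux_mls(self):
        """Nodal-integrated flux per timestep (ml/s)."""
        return self.v_node @ self.node_area_mm2


def _normalized_polar(points_2d):
    r = np.linalg.norm(points_2d, axis=1)
    rmax = r.max()
    if rmax == 0.0:
        return points_2d
    return points_2d / rmax


def map_voxels_to_inlet(
    series: VoxelFlowSeries,
    inlet: InletPatch,
    planarity_tol_mm: float = 1e-3,
) -> MappedInletSeries:
    """Transfer per-frame voxel velocities to the inlet nodes.

    The voxel plane is assumed aligned with the inlet plane; the shared
    2D basis comes from the inlet normal, which keeps nearest-neighbour
    matching invariant under a common rigid rotation of both grids.
    """
    mask = series.in_mask
    if not mask.any():
        raise ValueError("voxel mask is empty")
    e1, e2 = perpendicular_basis(inlet.unit_normal)

    vox = series.positions[mask]
    vox2 = np.stack([(vox - vox.mean(0)) @ e1, (vox - vox.mean(0)) @ e2], axis=1)
    nod = inlet.nodes
    nod2 = np.stack([(nod - nod.mean(0)) @ e1, (nod - nod.mean(0)) @ e2], axis=1)

    off_plane = np.abs((nod - nod.mean(0)) @ inlet.unit_normal)
    if off_plane.max() > max(planarity_tol_mm, 1e-9):
        log.warning("inlet patch non-planar: max deviation %.3g mm", off_plane.max())

    voxn = _normalized_polar(vox2)
    nodn = _normalized_polar(nod2)

    tree = cKDTree(voxn)
    k = min(4, len(voxn))
    d, idx = tree.query(nodn, k=k)
    d = np.atleast_2d(d)
    idx = np.atleast_2d(idx)
    # deterministic tie-break: among equidistant candidates, lowest index
    best = np.empty(len(nodn), dtype=np.int64)
    for i in range(len(nodn)):
        ties = idx[i][d[i] <= d[i, 0] + 1e-12]
        best[i] = ties.min()

    v_node = series.v_mps[:, mask][:, best]
    areas = vertex_lumped_areas(inlet.nodes, inlet.triangles)
    return MappedInletSeries(
        nodes=inlet.nodes.copy(),
        normal=inlet.unit_normal.copy(),
        t_s=series.t_s.copy(),
        v_node=v_node,
        node_area_mm2=areas,
    )


def rescale_flux(mapped: MappedInletSeries, target_Q_mls) -> MappedInletSeries:
    """Uniformly rescale nodal velocities per timestep so the nodal-
    integrated flux equals the target exactly (flux conservation repair)."""
    target = np.asarray(target_Q_mls, float)
    if target.shape == ():
        target = np.full(len(mapped.t_s), float(target))
    if len(target) != len(mapped.t_s):
        raise ValueError("target flux length must match timestep count")
    flux = mapped.flux_mls()
    scale = np.ones_like(flux)
    nonzero_target = np.abs(target) > 0.0
    bad = nonzero_target & (np.abs(flux) < 1e-300)
    if bad.any():
        raise ValueError(f"zero mapped flux with nonzero target at step {np.argmax(bad)}")
    scale[nonzero_target] = target[nonzero_target] / flux[nonzero_target]
    zero_target = ~nonzero_target
    scale[zero_target & (np.abs(flux) > 0)] = 0.0
    return MappedInletSeries(
        nodes=mapped.nodes,
        normal=mapped.normal,
        t_s=mapped.t_s,
        v_node=mapped.v_node * scale[:, None],
        node_area_mm2=mapped.node_area_mm2,
    )


def resample_timesteps(mapped: MappedInletSeries, t_new, period_T: float):
    """Periodic linear interpolation of nodal velocities onto solver
    timesteps (the mapping itself never interpolates in time)."""
    t_new = np.asarray(t_new, float)
    tq = np.mod(t_new, period_T)
    tp = np.concatenate([mapped.t_s, [mapped.t_s[0] + period_T]])
    vp = np.concatenate([mapped.v_node, mapped.v_node[:1]], axis=0)
    v_new = np.empty((len(tq), mapped.v_node.shape[1]))
    for j in range(mapped.v_node.shape[1]):
        v_new[:, j] = np.interp(tq, tp, vp[:, j])
    return MappedInletSeries(
        nodes=mapped.nodes,
        normal=mapped.normal,
        t_s=t_new,
        v_node=v_new,
        node_area_mm2=mapped.node_area_mm2,
    )


# --------------------------------------------------------------------------
# solver boundary files

_BC_PATTERN = "inlet_bc_{step:04d}.txt"


def write_bc_series(mapped: MappedInletSeries, out_dir) -> list:
    """One ascii file per timestep: three header lines (time, node count,
    normal) then rows ``x_mm y_mm z_mm vx vy vz``; plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if mapped.v_node.shape[1] != len(mapped.nodes):
        raise ValueError("node count mismatch between velocities and nodes")
    vecs = mapped.velocity_vectors
    manifest = []
    written = []
    for s, t in enumerate(mapped.t_s):
        fname = _BC_PATTERN.format(step=s)
        lines = [
            f"# time_s {t:.9g}",
            f"# n_nodes {len(mapped.nodes)}",
            f"# normal {mapped.normal[0]:.12g} {mapped.normal[1]:.12g} "
            f"{mapped.normal[2]:.12g}",
        ]
        for p, v in zip(mapped.nodes, vecs[s]):
            lines.append(
                f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g} "
                f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}"
            )
        (out_dir / fname).write_text("\n".join(lines) + "\n")
        manifest.append({"step": s, "t_s": t, "file": fname})
        written.append(out_dir / fname)
    pd.DataFrame(manifest).to_csv(out_dir / "bc_manifest.csv", index=False)
    return written


def read_bc_series(out_dir) -> MappedInletSeries:
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "bc_manifest.csv")
    t_s, vmats, nodes, normal = [], [], None, None
    for _, row in manifest.sort_values("step").iterrows():
        txt = (out_dir / row["file"]).read_text().splitlines()
        t_s.append(float(txt[0].split()[-1]))
        normal = np.array([float(x) for x in txt[2].split()[-3:]])
        data = np.array([[float(x) for x in ln.split()] for ln in txt[3:] if ln.strip()])
        if nodes is None:
            nodes = data[:, :3]
        vmats.append(data[:, 3:6] @ normal)
    # areas cannot be recovered from the files alone; store zeros
    return MappedInletSeries(
        nodes=nodes,
        normal=normal,
        t_s=np.array(t_s),
        v_node=np.stack(vmats),
        node_area_mm2=np.zeros(len(nodes)),
    )
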