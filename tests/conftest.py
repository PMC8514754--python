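import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from pulmobif.io_formats import InletPatch, TriSurface
from pulmobif.synthetic_data import (
    SyntheticBifurcationSpec,
    _sweep_tube,
    generate_bifurcation,
    straight_path,
)


def make_tube(radius=8.0, length=40.0, n_circ=48, step_mm=1.0, radii=None):
    path = straight_path([0.0, 0.0, 0.0], [0.0, 0.0, 1.0], length, n=400)
    if radii is None:
        radii = np.full(len(path), radius)
    v, f = _sweep_tube(path, radii, n_circ=n_circ, step_mm=step_mm)
    return TriSurface(v, f)


def make_disk_inlet(radius=11.0, n_rings=8, n_theta=24, z=0.0):
    """Polar-grid triangulated disk in the z-plane."""
    pts = [[0.0, 0.0, z]]
    for i in range(1, n_rings + 1):
        r = radius * i / n_rings
        for j in range(n_theta):
            a = 2 * np.pi * j / n_theta
            pts.append([r * np.cos(a), r * np.sin(a), z])
    pts = np.asarray(pts)
    tris = [[0, 1 + j, 1 + (j + 1) % n_theta] for j in range(n_theta)]
    for i in range(n_rings - 1):
        base = 1 + i * n_theta
        nxt = base + n_theta
        for j in range(n_theta):
            a, b = base + j, base + (j + 1) % n_theta
            c, d = nxt + j, nxt + (j + 1) % n_theta
            tris += [[a, b, d], [a, d, c]]
    return InletPatch(nodes=pts, triangles=np.asarray(tris))


@pytest.fixture(scope="session")
def tube_surface():
    return make_tube()


@pytest.fixture(scope="session")
def disk_inlet():
    return make_disk_inlet()


@pytest.fixture(scope="session")
def curved_bifurcation():
    """One representative curved, tilted, mildly tortuous bifurcation."""
    spec = SyntheticBifurcationSpec(
        branch_curv_radius=30.0, outplane_RPA=-10.0, outplane_LPA=20.0,
        tort_amp=1.0,
    )
    surface, centerlines, gt = generate_bifurcation(spec)
    return spec, surface, centerlines, gt


@pytest.fixture(scope="session")
def small_template_cohort():
    """Five small perturbed bifurcations (<= ~2 mm shape differences)."""
    rng = np.random.default_rng(7)
    out = []
    for _ in range(5):
        spec = SyntheticBifurcationSpec(
            D_MPA=12 + rng.uniform(-1, 1),
            D_RPA=8 + rng.uniform(-1, 1),
            D_LPA=9 + rng.uniform(-1, 1),
            inplane_RPA=140 + rng.uniform(-5, 5),
            inplane_LPA=130 + rng.uniform(-5, 5),
            outplane_RPA=rng.uniform(-5, 5),
            outplane_LPA=rng.uniform(-5, 5),
            branch_curv_radius=40.0,
            branch_length=26.0,
            mpa_length=16.0,
        )
        surface, _, gt = generate_bifurcation(spec, n_circ=32, step_mm=1.0)
        out.append((surface, gt))
    return out
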