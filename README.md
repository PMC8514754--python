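# pulmobif

Morphometric and hemodynamic characterization of pulmonary-artery
bifurcations, aimed at the repaired tetralogy-of-Fallot (rTOF) population,
where residual pulmonary regurgitation and left-pulmonary-artery kinking
make the trunk–RPA–LPA junction a clinically important flow environment.

The package turns the standard patient-specific workflow — centerline
morphometry, PC-MRI flow extraction, dimensionless characterization, inlet
boundary-condition mapping, wall-shear post-processing, and statistical
mean-shape construction — into a tested, reusable library, and pairs it
with a synthetic-data generator whose outputs carry closed-form ground
truth, so every stage is verifiable without patient data.

## What it computes

**Centerline morphometry.** For an arc-length-parametrized centerline
c(s), curvature and torsion follow the Frenet formulas

    kappa(s) = |c' x c''| / |c'|^3,
    tau(s)   = (c' x c'') . c''' / |c' x c''|^2,

in mm⁻¹, from a smoothing-spline fit. Tortuosity is x = L/D − 1 (centerline
length over endpoint chord), vessel caliber is the maximal inscribed-sphere
radius, and each daughter branch gets an in-plane angle (relative to the
main pulmonary artery, 180° = straight continuation) and a signed
out-of-plane angle relative to the total-least-squares bifurcation plane.
Curvature profiles are averaged across a cohort on a normalized abscissa
(1.0 = location of the curvature peak nearest the bifurcation).

**Flow characterization.** Flow rate Q(t) and lumen area A(t) from
voxel-wise through-plane velocities (a PC-MRI surrogate), cohort waveform
averaging on normalized cycle time, flow splits from net (forward −
backward) branch volumes, and a radius-squared estimator for a patient
without branch flow data. Dimensionless groups:

    Re = U D / nu,   Wo = (D/2) sqrt(2 pi / (nu T)),
    De_max = Re_max(MPA) * split * sqrt(D / (2 R)),  R = 1/kappa,

with blood as a Newtonian fluid (rho = 1060 kg/m³, mu = 0.004 Pa·s), plus
k–ω SST inflow values (I, k, L, ω).

**Inlet mapping.** Voxel velocities are transferred to a CFD inlet
triangulation by centering both point sets, normalizing their radii, and
matching nearest neighbours in the shared polar disc; per-timestep
solver-ready boundary files are emitted, optionally rescaled so nodal flux
matches a target waveform exactly.

**Wall shear.** TAWSS = (1/T)∫|τ_w|dt and OSI = 0.5(1 − |∫τdt|/∫|τ|dt) per
vertex, inlet-normalized TAWSS, cross-sections at 0.4D/0.6D from the
bifurcation origin with eight-point perimeter sampling, and cohort
summaries.

**Mean shape.** An iterative template: surfaces registered at their
bifurcation origins, signed-distance fields averaged on a 1 mm grid, zero
isosurface extracted, repeated with the template as reference until
successive surfaces differ by under 1 mm (a documented surrogate for
diffeomorphic atlas construction).

## Worked example

```python
import numpy as np
from pulmobif import synthetic_data as sd, morphometry as mm
from pulmobif import flow_characterization as fc, reference_cohort as ref

spec = sd.SyntheticBifurcationSpec(
    D_MPA=22.0, D_RPA=13.0, D_LPA=15.0,
    inplane_RPA=143.0, inplane_LPA=132.0,
    branch_curv_radius=30.0, tort_amp=1.0,
)
surface, centerlines, truth = sd.generate_bifurcation(spec)
results, frame, curves = mm.characterize_model(centerlines)
print(f"origin O = {np.round(frame.origin_O, 2)} mm, D_ref = {frame.D_ref_mm} mm")
for b in ("RPA", "LPA"):
    r = results[b]
    print(f"{b}: kappa_mean={r.kappa_mean:.3f} /mm  kappa_max={r.kappa_max:.3f} /mm  "
          f"tortuosity={r.tortuosity_x:.3f}  in-plane={r.inplane_deg:.1f} deg")
props = fc.FluidProperties()
print(f"Wo (D=22 mm, T=0.8 s) = {fc.womersley(0.022, 0.8, props):.1f}")
agg = fc.aggregate_cohort_table(ref.dimensionless_table())
print(f"cohort mean Re_mean(MPA) = {agg.iloc[-1]['re_mean_mpa']:.0f}")
```

prints

```
origin O = [ 0.  0. -0.] mm, D_ref = 22.0 mm
RPA: kappa_mean=0.042 /mm  kappa_max=0.091 /mm  tortuosity=0.034  in-plane=144.2 deg
LPA: kappa_mean=0.042 /mm  kappa_max=0.091 /mm  tortuosity=0.034  in-plane=133.2 deg
Wo (D=22 mm, T=0.8 s) = 15.9
cohort mean Re_mean(MPA) = 737
```

The detected origin sits at the analytic junction, the recovered maximum
curvature is the prescribed arc curvature 1/30 mm plus the sinusoidal
perturbation, and the in-plane angles match the generator's 143°/132°
within about a degree. The last line re-aggregates the embedded
seven-patient cohort table and reproduces its printed mean Reynolds number.

A `pulmobif` command-line tool exposes the same stages (`synth`,
`morphometry`, `map-inlet`, `wss`, `mean-shape`, `run`); `pulmobif run
--config cfg.yaml` executes the configured pipeline end to end and writes
cohort-table CSVs with provenance headers.

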