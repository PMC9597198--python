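# atflap

Computer-aided preoperative evaluation of A-T advancement skin flaps:
closed-form incision geometry plus a 2-D nonlinear finite-element
simulation of the wound closure.

An A-T (O-T / T-plasty) repair excises a circular skin lesion inside a
triangle and closes the defect by advancing two flaps along lateral
base-extension incisions, leaving a T-shaped suture line.  `atflap`
answers the two planning questions quantitatively:

* **Geometry** — for a defect of radius *r* and apex angle *2θ*, the
  closed forms for the flap length-width ratio *h/d*, the maximum suture
  distance *d* and the excised (suture) area *S*, and the apex angle that
  minimises *S* subject to a clinical length-width bound.
* **Mechanics** — a plane-stress, incompressible two-term Ogden model of
  facial skin on a structured quadrilateral mesh, solved through a
  *suture* stage (wound margins ramped onto the closed-T position) and a
  *release* stage (prescriptions replaced by stitch ties, the wound
  settling into equilibrium).

## Quick start

```sh
$ atflap design --radius 10
apex angle 2*theta = 60.00 deg
flap length  h = 30.00 mm
flap width   d = 34.64 mm
ratio      h/d = 0.87
suture area  S = 519.62 mm^2

$ atflap sweep --radius 10
  40.0 deg  h/d= 1.37  d= 28.56 mm  S=  560.38 mm^2
  50.0 deg  h/d= 1.07  d= 31.39 mm  S=  528.39 mm^2
  60.0 deg  h/d= 0.87  d= 34.64 mm  S=  519.62 mm^2
  70.0 deg  h/d= 0.71  d= 38.42 mm  S=  527.01 mm^2
  80.0 deg  h/d= 0.60  d= 42.89 mm  S=  548.08 mm^2
```

The 60° apex minimises the suture area — the analytic optimum of
*S(θ) ∝ (1+sin θ)² / (sin θ cos θ)* is exactly *θ = 30°*.

Run the reference simulation (10 mm defect, 60° apex, 90 × 100 mm skin
domain, 3 mm quadrilaterals, facial-skin Ogden parameters):

```sh
$ atflap simulate --out results
suture   max von Mises 562.305 MPa, max displacement 10.000 mm
release  max von Mises 168.886 MPa, max displacement 11.631 mm
artifacts in results/
```

Artifacts include the mesh and per-stage displacement / von Mises fields
as legacy-VTK files (ParaView-readable), nodal CSV tables and a JSON
report.  Note that the stress *maxima* are corner concentrations at the
T-joint and defect apex and grow under mesh refinement; see
[docs/methods.md](docs/methods.md) for the interpretation and for the
closure-kinematics assumptions behind these numbers.

Python API:

```python
from atflap import (FACIAL_SKIN, SimulationConfig, design_flap,
                    run_pipeline, sweep)

design = design_flap(10.0, 60.0)          # h = 30 mm, d = 34.64 mm
report = run_pipeline(SimulationConfig()) # full two-stage simulation
print(report.release["max_von_mises_mpa"])
```

## Package layout

| Path | Contents |
| --- | --- |
| `src/atflap/geometry.py` | closed-form flap design and apex optimisation |
| `src/atflap/material.py` | Ogden model, uniaxial forms, plane-stress response, fitting |
| `src/atflap/mesh.py` | block-structured quad mesher, quality metrics, closure plan |
| `src/atflap/solver.py` | total-Lagrangian FEM, Newton solver, suture/release stages |
| `src/atflap/pipeline.py` | end-to-end orchestration, reports, sensitivity study |
| `src/atflap/cli.py` | `atflap` command-line interface |
| `src/atflap/fixtures.py` | synthetic curves and brute-force oracles for testing |
| `docs/methods.md` | model description, numerical methods, limitations |
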