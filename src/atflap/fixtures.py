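"""Synthetic data and independent oracles for testing without lab data.

The uniaxial facial-skin experiment behind the default material constants is
not tabulated anywhere public, so fitting is exercised on synthetic curves
generated from known Ogden parameters.  The oracles here deliberately avoid
the closed-form code paths they are used to check:

* :func:`brute_force_uniaxial` obtains the uniaxial stress by numerically
  minimising the strain energy over the lateral stretch (traction-free
  lateral condition as an energy minimum) and differentiating the resulting
  one-variable energy, instead of using the eliminated-pressure formula.
* :func:`patch_meshes` supplies tiny meshes with known analytic behaviour
  for solver patch tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .material import OgdenParameters, StressStretchCurve, strain_energy

__all__ = [
    "SyntheticCurveSpec",
    "make_curve",
    "brute_force_uniaxial",
    "patch_meshes",
]


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Recipe for a synthetic uniaxial stress-stretch curve."""

    params: OgdenParameters
    stretch_min: float = 1.0
    stretch_max: float = 1.5
    n_points: int = 50
    noise_sd: float = 0.0  # MPa, additive Gaussian on stress
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.stretch_min < self.stretch_max):
            raise ValueError("need 0 < stretch_min < stretch_max")
        if self.n_points < 4:
            raise ValueError("need at least 4 sample points")


def make_curve(spec: SyntheticCurveSpec) -> StressStretchCurve:
    """Synthesize a nominal stress-stretch curve from Ogden parameters.

    Stress is the closed-form uniaxial nominal response plus optional
    Gaussian noise; deterministic for a fixed seed.
    """
    from .material import uniaxial_nominal_stress

    lam = np.linspace(spec.stretch_min, spec.stretch_max, spec.n_points)
    stress = uniaxial_nominal_stress(lam, spec.params)
    stress = np.asarray(stress, dtype=float)
    if spec.noise_sd > 0.0:
        rng = np.random.default_rng(spec.seed)
        stress = stress + rng.normal(0.0, spec.noise_sd, lam.shape)
    return StressStretchCurve(stretch=lam, nominal_stress=stress)


def _constrained_energy(lam: float, params: OgdenParameters) -> float:
    """min over lateral stretch of W(lam, l2, 1/(lam*l2))."""

    def w(log_l2: float) -> float:
        l2 = float(np.exp(log_l2))
        return float(strain_energy(lam, l2, 1.0 / (lam * l2), params))

    res = minimize_scalar(
        w, bounds=(np.log(0.05), np.log(20.0)), method="bounded",
        options={"xatol": 1e-13},
    )
    return float(res.fun)


def brute_force_uniaxial(lam: float, params: OgdenParameters, h: float = 1e-5) -> float:
    """Uniaxial Cauchy stress by energy minimisation + differentiation.

    sigma = lam * dW_hat/dlam where W_hat(lam) is the energy minimised over
    the lateral stretch under the incompressibility substitution.  The
    envelope theorem makes the inner-minimiser inaccuracy second order, so a
    central difference of W_hat gives ~1e-9 MPa absolute accuracy.
    """
    if lam <= 0:
        raise ValueError("stretch must be positive")
    wp = _constrained_energy(lam + h, params)
    wm = _constrained_energy(lam - h, params)
    return lam * (wp - wm) / (2.0 * h)


def patch_meshes():
    """Library of tiny meshes with known properties for solver tests.

    Returns a dict with:

    * ``"single"`` — one 3 mm square element;
    * ``"two_by_two"`` — a 2x2-element, 6 mm square patch;
    * ``"mini_at"`` — a coarse A-T mesh (~tens of elements) on a small
      domain, mirror-symmetric, with the full suture machinery attached.
    """
    from .geometry import design_flap
    from .mesh import SkinMesh, build_domain, generate_mesh

    def square(n: int, size: float) -> SkinMesh:
        xs = np.linspace(0.0, n * size, n + 1)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        nodes = np.column_stack([X.ravel(), Y.ravel()])
        quads = []
        for i in range(n):
            for j in range(n):
                a = i * (n + 1) + j
                quads.append([a, a + (n + 1), a + (n + 2), a + 1])
        return SkinMesh(
            nodes=nodes,
            quads=np.asarray(quads, dtype=int),
            element_size=size,
        )

    design = design_flap(5.0, 60.0)
    domain = build_domain(design, width=45.0, height=50.0)
    mini = generate_mesh(domain, element_size=6.0)
    return {"single": square(1, 3.0), "two_by_two": square(2, 3.0), "mini_at": mini}
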