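"""Ogden hyperelastic model for skin: energy, stress responses, fitting.

Skin under flap advancement is modelled as an isotropic, incompressible
Ogden solid.  The strain energy in principal stretches is

    W = sum_n  mu_n/alpha_n * (l1^a_n + l2^a_n + l3^a_n - 3)            (J = 1)

with the optional compressible extension

    W = sum_n  mu_n/alpha_n * (J^(-a_n/3)(l1^a_n + l2^a_n + l3^a_n) - 3)
        + 4.5 K (J^(1/3) - 1)^2,        J = l1 l2 l3.

The default two-term parameter set for facial skin is
mu = (7.5809e-7, 0.1683) MPa, alpha = (2.1065, 12.006).

The solver works in plane stress: for an in-plane deformation gradient F the
thickness stretch follows from incompressibility, l3 = 1/det(F), and the
hydrostatic pressure is eliminated by sigma_33 = 0, giving principal Cauchy
stresses sigma_i = sum_n mu_n (l_i^a_n - l3^a_n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "OgdenParameters",
    "FACIAL_SKIN",
    "StressStretchCurve",
    "strain_energy",
    "uniaxial_cauchy_stress",
    "uniaxial_nominal_stress",
    "fit_ogden",
    "OgdenFit",
    "FitError",
    "plane_stress_response",
    "plane_stress_principal",
]


@dataclass(frozen=True)
class OgdenParameters:
    """Ogden parameter set: shear parameters mu_n (MPa), exponents alpha_n.

    ``bulk_modulus`` (MPa) switches on the compressible energy form; when
    ``None`` the material is treated as fully incompressible (J = 1).
    """

    mu: tuple
    alpha: tuple
    bulk_modulus: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "mu", tuple(float(m) for m in self.mu))
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
        if len(self.mu) != len(self.alpha) or len(self.mu) < 1:
            raise ValueError("mu and alpha must have equal length N >= 1")

    @property
    def n_terms(self) -> int:
        return len(self.mu)

    @property
    def ground_state_shear_modulus(self) -> float:
        """mu_0 = 0.5 * sum mu_n alpha_n (small-strain shear modulus, MPa)."""
        return 0.5 * sum(m * a for m, a in zip(self.mu, self.alpha))

    def validate(self) -> None:
        if not self.ground_state_shear_modulus > 0.0:
            raise ValueError("sum(mu_n * alpha_n) must be positive")


#: Two-term facial-skin parameter set used as the simulation default.
FACIAL_SKIN = OgdenParameters(mu=(7.5809e-7, 0.1683), alpha=(2.1065, 12.006))


@dataclass
class StressStretchCurve:
    """Uniaxial test data: stretch samples and nominal stress (MPa)."""

    stretch: np.ndarray
    nominal_stress: np.ndarray
    convention: str = "nominal"

    def __post_init__(self):
        self.stretch = np.asarray(self.stretch, dtype=float)
        self.nominal_stress = np.asarray(self.nominal_stress, dtype=float)
        if self.stretch.shape != self.nominal_stress.shape:
            raise ValueError("stretch and stress arrays must have equal length")
        if np.any(self.stretch <= 0.0):
            raise ValueError("stretches must be positive")
        if np.any(np.diff(self.stretch) <= 0.0):
            raise ValueError("stretches must be strictly increasing")


def strain_energy(l1, l2, l3, params: OgdenParameters, j_tol: float = 1e-8):
    """Strain-energy density (MPa) at principal stretches (vectorised).

    In incompressible mode (no bulk modulus) the caller must supply stretches
    with J = l1 l2 l3 = 1 to within ``j_tol``.
    """
    l1, l2, l3 = (np.asarray(v, dtype=float) for v in (l1, l2, l3))
    if np.any(l1 <= 0) or np.any(l2 <= 0) or np.any(l3 <= 0):
        raise ValueError("principal stretches must be positive")
    J = l1 * l2 * l3
    W = np.zeros(np.broadcast(l1, l2, l3).shape)
    if params.bulk_modulus is None:
        if np.any(np.abs(J - 1.0) > j_tol):
            raise ValueError(
                "incompressible mode requires l1*l2*l3 = 1; "
                f"max |J-1| = {float(np.max(np.abs(J - 1.0))):.3e}"
            )
        for m, a in zip(params.mu, params.alpha):
            W = W + m / a * (l1**a + l2**a + l3**a - 3.0)
    else:
        for m, a in zip(params.mu, params.alpha):
            W = W + m / a * (J ** (-a / 3.0) * (l1**a + l2**a + l3**a) - 3.0)
        W = W + 4.5 * params.bulk_modulus * (J ** (1.0 / 3.0) - 1.0) ** 2
    return W if W.shape else float(W)


def uniaxial_cauchy_stress(lam, params: OgdenParameters):
    """Uniaxial Cauchy stress sigma(lambda) (MPa), incompressible.

    Lateral directions traction-free (l2 = l3 = lambda^(-1/2)); the pressure
    is eliminated, leaving sigma = sum_n mu_n (lam^a_n - lam^(-a_n/2)).
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch must be positive")
    s = np.zeros(lam.shape)
    for m, a in zip(params.mu, params.alpha):
        s = s + m * (lam**a - lam ** (-a / 2.0))
    return s if s.shape else float(s)


def uniaxial_nominal_stress(lam, params: OgdenParameters):
    """First Piola-Kirchhoff uniaxial stress P = sigma/lambda (MPa)."""
    lam = np.asarray(lam, dtype=float)
    return uniaxial_cauchy_stress(lam, params) / lam


class FitError(RuntimeError):
    """Raised when Ogden fitting fails to converge; carries best-so-far."""

    def __init__(self, message, best=None, residual=None):
        super().__init__(message)
        self.best = best
        self.residual = residual


@dataclass(frozen=True)
class OgdenFit:
    params: OgdenParameters
    rms_residual: float


def fit_ogden(
    curve: StressStretchCurve,
    n_terms: int = 2,
    convention: str | None = None,
    n_starts: int = 20,
    seed: int = 0,
    rms_tol: float = np.inf,
) -> OgdenFit:
    """Fit Ogden parameters to a uniaxial stress-stretch curve.

    Multi-start bounded nonlinear least squares on the stress residuals
    (nominal by default, Cauchy if the curve says so).  Two-term Ogden
    parameters are notoriously non-identifiable from a single uniaxial
    curve, so the quantity that matters is the predicted stress curve (the
    returned ``rms_residual``), not the parameter values themselves.

    Bounds: alpha in [0.1, 30], mu >= 0; fits with non-positive ground-state
    shear modulus are rejected.
    """
    if n_terms not in (1, 2, 3):
        raise ValueError("n_terms must be 1, 2 or 3")
    lam = curve.stretch
    target = curve.nominal_stress
    if lam.size < 2 * n_terms:
        raise ValueError("need at least 2*N data points")
    conv = convention or curve.convention

    def predict(mu, alpha):
        p = OgdenParameters(mu=tuple(mu), alpha=tuple(alpha))
        if conv == "cauchy":
            return uniaxial_cauchy_stress(lam, p)
        return uniaxial_nominal_stress(lam, p)

    def residuals(x):
        mu, alpha = x[:n_terms], x[n_terms:]
        return predict(mu, alpha) - target

    scale = max(1e-12, float(np.max(np.abs(target))))
    if scale <= 1e-12:  # all-zero data: the zero-stress model fits exactly
        params = OgdenParameters(mu=(0.0,) * n_terms, alpha=(2.0,) * n_terms)
        return OgdenFit(params=params, rms_residual=0.0)

    rng = np.random.default_rng(seed)
    lb = np.r_[np.zeros(n_terms), np.full(n_terms, 0.1)]
    ub = np.r_[np.full(n_terms, 100.0 * scale), np.full(n_terms, 30.0)]
    best_x, best_cost = None, np.inf
    # one deterministic start (near-linear guess) plus random restarts
    starts = [np.r_[np.full(n_terms, scale / n_terms), np.linspace(2.0, 12.0, n_terms)]]
    for _ in range(n_starts - 1):
        mu0 = scale * rng.uniform(0.01, 2.0, n_terms)
        a0 = rng.uniform(0.5, 25.0, n_terms)
        starts.append(np.r_[mu0, a0])
    for x0 in starts:
        try:
            res = least_squares(residuals, x0, bounds=(lb, ub), method="trf")
        except Exception:
            continue
        mu, alpha = res.x[:n_terms], res.x[n_terms:]
        if not sum(m * a for m, a in zip(mu, alpha)) > 0.0:
            continue
        if res.cost < best_cost:
            best_cost, best_x = res.cost, res.x
    if best_x is None:
        raise FitError("Ogden fit failed from every start point")
    mu, alpha = best_x[:n_terms], best_x[n_terms:]
    params = OgdenParameters(mu=tuple(mu), alpha=tuple(alpha))
    rms = float(np.sqrt(np.mean(residuals(best_x) ** 2)))
    if rms > rms_tol:
        raise FitError(
            f"fit residual {rms:.3e} exceeds tolerance {rms_tol:.3e}",
            best=params,
            residual=rms,
        )
    return OgdenFit(params=params, rms_residual=rms)


# ---------------------------------------------------------------------------
# plane-stress incompressible response
# ---------------------------------------------------------------------------


def _principal_stretches_2d(F: np.ndarray):
    """Principal in-plane stretches and spatial directions from 2x2 F.

    Works on stacked input (..., 2, 2).  Uses the left Cauchy-Green tensor
    b = F F^T, whose eigenvalues are the squared stretches and whose
    eigenvectors are the spatial principal directions; eigenvalues are
    clamped at 1e-12 to guard the square root against round-off.
    """
    F = np.asarray(F, dtype=float)
    b11 = F[..., 0, 0] ** 2 + F[..., 0, 1] ** 2
    b22 = F[..., 1, 0] ** 2 + F[..., 1, 1] ** 2
    b12 = F[..., 0, 0] * F[..., 1, 0] + F[..., 0, 1] * F[..., 1, 1]
    mean = 0.5 * (b11 + b22)
    rad = np.sqrt(np.maximum(0.25 * (b11 - b22) ** 2 + b12**2, 0.0))
    x1 = np.maximum(mean + rad, 1e-12)  # eigenvalues of b (squared stretches)
    x2 = np.maximum(mean - rad, 1e-12)
    return (b11, b22, b12), (x1, x2)


def plane_stress_principal(F: np.ndarray, params: OgdenParameters):
    """In-plane Cauchy stress (2x2, MPa) and thickness stretch, vectorised.

    ``F`` has shape (..., 2, 2) with det F > 0.  Incompressibility gives
    l3 = 1/det F; sigma_33 = 0 eliminates the pressure.  The stress is
    reassembled from the spectral form as sigma = phi0 I + phi1 b, which is
    stable through coincident principal stretches.
    """
    F = np.asarray(F, dtype=float)
    detF = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    if np.any(detF <= 0.0):
        raise FloatingPointError("element inversion: det F <= 0")
    (b11, b22, b12), (x1, x2) = _principal_stretches_2d(F)
    l1, l2 = np.sqrt(x1), np.sqrt(x2)
    l3 = 1.0 / detF

    def sig(l):  # principal Cauchy stress with pressure from sigma_33 = 0
        s = np.zeros(np.shape(l))
        for m, a in zip(params.mu, params.alpha):
            s = s + m * (l**a - l3**a)
        return s

    s1, s2 = sig(l1), sig(l2)
    dx = x1 - x2
    near = dx <= 1e-9 * (x1 + x2)
    safe_dx = np.where(near, 1.0, dx)
    phi1 = np.where(near, 0.0, (s1 - s2) / safe_dx)
    phi0 = s1 - phi1 * x1
    # isotropic limit when l1 == l2: sigma = s1 * I exactly
    sigma = np.empty(F.shape)
    sigma[..., 0, 0] = phi0 + phi1 * b11
    sigma[..., 1, 1] = phi0 + phi1 * b22
    sigma[..., 0, 1] = phi1 * b12
    sigma[..., 1, 0] = sigma[..., 0, 1]
    return sigma, l3


def plane_stress_response(F: np.ndarray, params: OgdenParameters):
    """Single-point convenience wrapper: (2x2 Cauchy stress, lambda_3)."""
    F = np.asarray(F, dtype=float)
    if F.shape != (2, 2):
        raise ValueError("F must be a 2x2 matrix")
    sigma, l3 = plane_stress_principal(F, params)
    return sigma, float(l3)
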