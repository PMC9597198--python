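"""2-D total-Lagrangian hyperelastic finite-element solver.

Four-node quadrilaterals with 2x2 Gauss quadrature, plane stress with
incompressibility enforced analytically through the thickness stretch
(``l3 = 1/det F``), unit reference thickness.  The flap simulation runs two
stages:

* **suture** — every wound-margin node is driven to its target on the
  closed "T" by ramped prescribed displacements (no contact mechanics: a
  stitch is modelled as node-to-node gluing);
* **release** — the prescribed displacements are removed and replaced by
  tie constraints (slave bound to its master's *current position*,
  enforced by dof condensation), starting from the converged suture state;
  the residual wound-margin reactions are unloaded gradually over the load
  steps (force continuation), letting tissue elasticity redistribute the
  stress while the stitches keep the margins coincident.

The element tangent is a central finite difference of the (analytic)
internal force, which keeps the constitutive code in one place; Newton
convergence is judged on the exact residual, so the attainable tolerance is
not limited by the differencing.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .material import OgdenParameters, plane_stress_principal
from .mesh import GAUSS_POINTS, SkinMesh, closure_plan

log = logging.getLogger("atflap")

__all__ = [
    "StageDefinition",
    "SolverConfig",
    "FieldSolution",
    "SolverError",
    "RankDeficiencyError",
    "von_mises",
    "element_internal_force",
    "internal_forces",
    "tangent_stiffness",
    "solve_stage",
    "run_suture_then_release",
    "make_suture_stage",
    "make_release_stage",
    "count_zero_energy_modes",
]


class SolverError(RuntimeError):
    """Non-convergence; carries the last converged state and residuals."""

    def __init__(self, message, last_u=None, residual_history=None):
        super().__init__(message)
        self.last_u = last_u
        self.residual_history = residual_history or []


class RankDeficiencyError(RuntimeError):
    """The constrained system still has zero-energy (rigid) modes."""


# shape-function derivatives wrt (xi, eta) at each Gauss point: (4 gp, 4 a, 2)
def _dN_at(xi: float, eta: float) -> np.ndarray:
    return 0.25 * np.array([
        [-(1 - eta), -(1 - xi)],
        [(1 - eta), -(1 + xi)],
        [(1 + eta), (1 + xi)],
        [-(1 + eta), (1 - xi)],
    ])


_DN = np.stack([_dN_at(xi, eta) for xi, eta in GAUSS_POINTS])
_GAUSS_W = np.ones(4)

# Gauss -> corner extrapolation for bilinear elements: treat the Gauss points
# as nodes of a sqrt(3)-scaled bilinear patch and evaluate at the corners.
_CORNERS = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])
_EXTRAP = np.empty((4, 4))
for _c, (_x, _y) in enumerate(_CORNERS):
    for _g, (_xg, _yg) in enumerate(GAUSS_POINTS):
        _EXTRAP[_c, _g] = 0.25 * (1.0 + 3.0 * _x * _xg) * (1.0 + 3.0 * _y * _yg)


def von_mises(sigma: np.ndarray, tol: float = 1e-9) -> float | np.ndarray:
    """Plane-stress equivalent (von Mises) stress of 2x2 Cauchy tensors.

    sqrt(s11^2 - s11 s22 + s22^2 + 3 s12^2); the through-thickness stress is
    zero by the plane-stress condition.  Input must be symmetric.
    """
    s = np.asarray(sigma, dtype=float)
    asym = np.abs(s[..., 0, 1] - s[..., 1, 0])
    scale = 1.0 + np.abs(s).max(axis=(-1, -2))
    if np.any(asym > tol * scale):
        raise ValueError("von Mises input must be a symmetric tensor")
    s11, s22, s12 = s[..., 0, 0], s[..., 1, 1], s[..., 0, 1]
    out = np.sqrt(np.maximum(s11**2 - s11 * s22 + s22**2 + 3.0 * s12**2, 0.0))
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# element and global internal force
# ---------------------------------------------------------------------------


def _element_force_stress(Xe: np.ndarray, ue: np.ndarray,
                          params: OgdenParameters, want_stress: bool = False):
    """Internal nodal forces (E, 4, 2) for stacked elements; optionally the
    Gauss-point Cauchy stresses (E, 4gp, 2, 2)."""
    E = Xe.shape[0]
    f = np.zeros((E, 4, 2))
    sig_out = np.empty((E, 4, 2, 2)) if want_stress else None
    for g in range(4):
        dN = _DN[g]  # (4, 2)
        J0 = np.einsum("eai,aj->eij", Xe, dN)
        detJ0 = J0[:, 0, 0] * J0[:, 1, 1] - J0[:, 0, 1] * J0[:, 1, 0]
        if np.any(detJ0 <= 0.0):
            raise FloatingPointError("non-positive reference Jacobian")
        invJ0 = np.empty_like(J0)
        invJ0[:, 0, 0] = J0[:, 1, 1]
        invJ0[:, 1, 1] = J0[:, 0, 0]
        invJ0[:, 0, 1] = -J0[:, 0, 1]
        invJ0[:, 1, 0] = -J0[:, 1, 0]
        invJ0 /= detJ0[:, None, None]
        gradN = np.einsum("aj,ejk->eak", dN, invJ0)  # dN/dX
        F = np.einsum("eai,eak->eik", ue, gradN)
        F[:, 0, 0] += 1.0
        F[:, 1, 1] += 1.0
        sigma, _l3 = plane_stress_principal(F, params)
        if want_stress:
            sig_out[:, g] = sigma
        # first Piola-Kirchhoff (unit thickness, J3 = 1): P = sigma F^{-T}
        detF = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
        invFT = np.empty_like(F)
        invFT[:, 0, 0] = F[:, 1, 1]
        invFT[:, 1, 1] = F[:, 0, 0]
        invFT[:, 0, 1] = -F[:, 1, 0]
        invFT[:, 1, 0] = -F[:, 0, 1]
        invFT /= detF[:, None, None]
        P = np.einsum("eij,ejk->eik", sigma, invFT)
        f += _GAUSS_W[g] * detJ0[:, None, None] * np.einsum(
            "eak,eik->eai", gradN, P)
    return (f, sig_out) if want_stress else f


def element_internal_force(coords: np.ndarray, u_element: np.ndarray,
                           material: OgdenParameters):
    """Internal force (4, 2) and Gauss stresses (4, 2, 2) of one element."""
    Xe = np.asarray(coords, dtype=float)[None]
    ue = np.asarray(u_element, dtype=float)[None]
    f, sig = _element_force_stress(Xe, ue, material, want_stress=True)
    return f[0], sig[0]


def internal_forces(mesh: SkinMesh, u: np.ndarray, material: OgdenParameters,
                    want_stress: bool = False):
    """Assembled internal force vector (N, 2); optionally Gauss stresses."""
    Xe = mesh.nodes[mesh.quads]
    ue = u[mesh.quads]
    out = _element_force_stress(Xe, ue, material, want_stress=want_stress)
    fe, sig = out if want_stress else (out, None)
    f = np.zeros_like(u)
    np.add.at(f, mesh.quads.ravel(), fe.reshape(-1, 2))
    return (f, sig) if want_stress else f


def _element_tangents(Xe: np.ndarray, ue: np.ndarray,
                      params: OgdenParameters, h: float = 1e-6) -> np.ndarray:
    """Consistent element tangents (E, 8, 8) by central differencing of the
    analytic internal force."""
    E = Xe.shape[0]
    K = np.empty((E, 8, 8))
    for k in range(8):
        a, i = divmod(k, 2)
        up = ue.copy()
        up[:, a, i] += h
        um = ue.copy()
        um[:, a, i] -= h
        fp = _element_force_stress(Xe, up, params)
        fm = _element_force_stress(Xe, um, params)
        K[:, :, k] = (fp - fm).reshape(E, 8) / (2.0 * h)
    return 0.5 * (K + K.transpose(0, 2, 1))  # symmetrise round-off


def tangent_stiffness(mesh: SkinMesh, u: np.ndarray,
                      material: OgdenParameters) -> sp.csr_matrix:
    """Assembled tangent stiffness (2N x 2N, CSR)."""
    Xe = mesh.nodes[mesh.quads]
    ue = u[mesh.quads]
    Ke = _element_tangents(Xe, ue, material)
    dofs = (2 * mesh.quads[:, :, None] + np.arange(2)).reshape(-1, 8)
    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    n = 2 * mesh.n_nodes
    return sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def count_zero_energy_modes(K, scale_tol: float = 1e-8) -> int:
    """Number of (numerically) zero eigenvalues of a small stiffness matrix.

    Detects unconstrained rigid modes: 3 in 2-D (two translations and a
    rotation).  Dense eigendecomposition — small systems only.
    """
    Kd = K.toarray() if sp.issparse(K) else np.asarray(K)
    w = np.linalg.eigvalsh(0.5 * (Kd + Kd.T))
    return int(np.sum(np.abs(w) < scale_tol * max(1e-30, np.max(np.abs(w)))))


# ---------------------------------------------------------------------------
# stages and constraint handling
# ---------------------------------------------------------------------------


@dataclass
class StageDefinition:
    """Boundary conditions for one analysis stage.

    ``prescribed`` maps (node, dof) -> final displacement value (mm), ramped
    over the load steps.  ``ties`` lists (master, slave) node pairs bound to
    equal displacement.  ``fixed_nodes`` have both dofs zero.
    """

    tag: str
    prescribed: dict = field(default_factory=dict)
    ties: list = field(default_factory=list)
    fixed_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def validate(self) -> None:
        if self.tag == "suture" and self.ties:
            raise ValueError("suture stage must not carry tie constraints")
        if self.tag == "release" and self.prescribed:
            raise ValueError("release stage has no prescribed displacements")


@dataclass
class SolverConfig:
    load_steps: int = 10
    newton_tol: float = 1e-8
    max_newton_iter: int = 30
    line_search: bool = True
    max_bisections: int = 4

    def validate(self) -> None:
        if self.load_steps < 1 or self.newton_tol <= 0.0:
            raise ValueError("invalid solver configuration")


@dataclass
class FieldSolution:
    """Converged displacement and stress fields for one stage."""

    stage: str
    u: np.ndarray  # (N, 2) mm
    gauss_stress: np.ndarray  # (E, 4, 2, 2) MPa
    element_stress: np.ndarray  # (E, 2, 2) centroid-average MPa
    nodal_stress: np.ndarray  # (N, 2, 2) extrapolated + averaged MPa
    nodal_von_mises: np.ndarray  # (N,)
    element_von_mises: np.ndarray  # (E,)
    max_von_mises: float
    max_von_mises_node: int
    max_von_mises_location: np.ndarray
    max_displacement: float
    max_displacement_node: int
    max_displacement_location: np.ndarray
    converged: bool
    residual_history: list
    newton_iterations: int


def _build_transform(mesh: SkinMesh, stage: StageDefinition):
    """Sparse maps for the constrained system.

    Returns ``(T, S, u_tie, pres_dofs, pres_vals)`` such that the full
    displacement vector is ``u = T q + u_tie + u_pres(tau)`` and ``q = S u``
    recovers the reduced coordinates from a constraint-consistent state.
    A tie binds the slave node to the *current position* of its master,
    ``u_s = u_m + (X_m - X_s)``: the constant offset vanishes for the
    reference-coincident duplicated cut pairs and otherwise encodes the
    closed-wound geometry of the stitched margins.
    """
    n = 2 * mesh.n_nodes
    master_of = {}
    for m, s in stage.ties:
        s, m = int(s), int(m)
        if s in master_of:
            raise ValueError(f"node {s} appears as slave twice")
        master_of[s] = m
    for s, m in master_of.items():
        if m in master_of:
            raise ValueError("tie chains (slave used as master) not supported")
    fixed = set(int(v) for v in np.asarray(stage.fixed_nodes).ravel())
    pres_dofs = np.asarray(
        [2 * nd + d for (nd, d) in stage.prescribed], dtype=int)
    pres_vals = np.asarray(
        [stage.prescribed[k] for k in stage.prescribed], dtype=float)
    constrained = set(pres_dofs.tolist())
    for nd in fixed:
        constrained.update((2 * nd, 2 * nd + 1))

    col_of = {}
    rows, cols = [], []
    for nd in range(mesh.n_nodes):
        if nd in master_of or nd in fixed:
            continue
        for d in range(2):
            dof = 2 * nd + d
            if dof in constrained:
                continue
            col_of[dof] = len(col_of)
            rows.append(dof)
            cols.append(col_of[dof])
    s_rows = list(range(len(col_of)))
    s_cols = rows.copy()
    u_tie = np.zeros(n)
    for s, m in master_of.items():
        offset = mesh.nodes[m] - mesh.nodes[s]
        for d in range(2):
            sdof, mdof = 2 * s + d, 2 * m + d
            if mdof not in col_of:
                raise ValueError(
                    f"tie master dof of node {m} is itself constrained")
            rows.append(sdof)
            cols.append(col_of[mdof])
            u_tie[sdof] = offset[d]
    T = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, len(col_of))
    ).tocsr()
    S = sp.coo_matrix(
        (np.ones(len(s_rows)), (s_rows, s_cols)), shape=(len(col_of), n)
    ).tocsr()
    return T, S, u_tie, pres_dofs, pres_vals


def _newton(mesh, material, config, T, S, u_start, u_p_fun, f_ext_fun):
    """Incremental-iterative solve of T^t f_int(u) = f_ext(tau).

    ``u_p_fun(tau)`` gives the full-length constrained-displacement vector
    (prescribed values and tie offsets); ``f_ext_fun(tau)`` the reduced
    external force.  Step bisection on divergence, optional backtracking
    line search.  Returns (u, history, total Newton iterations).
    """
    u = u_start.ravel().copy()
    Tt = T.T.tocsr()
    # u_start must be consistent with the tau = 0 constraints
    q = S @ u
    history, total_iters = [], 0
    tau, dtau, bisections = 0.0, 1.0 / config.load_steps, 0

    def residual(qv, tauv):
        uf = (T @ qv) + u_p_fun(tauv)
        f = internal_forces(mesh, uf.reshape(-1, 2), material)
        r = Tt @ f.ravel() - f_ext_fun(tauv)
        return r, f, uf

    while tau < 1.0 - 1e-12:
        tau_try = min(1.0, tau + dtau)
        q_trial = q.copy()
        ok = False
        try:
            r, f, uf = residual(q_trial, tau_try)
            for it in range(config.max_newton_iter):
                total_iters += 1
                fscale = max(float(np.linalg.norm(f)), 1e-12)
                rnorm = float(np.linalg.norm(r))
                history.append((tau_try, it, rnorm))
                log.debug("tau=%.4f newton=%d |r|=%.3e", tau_try, it, rnorm)
                if rnorm <= config.newton_tol * fscale or rnorm < 1e-14:
                    ok = True
                    break
                K = tangent_stiffness(mesh, uf.reshape(-1, 2), material)
                Kr = (Tt @ K @ T).tocsc()
                try:
                    dq = spla.splu(Kr).solve(-r)
                except RuntimeError as exc:
                    raise RankDeficiencyError(
                        "singular tangent: unconstrained rigid modes remain"
                    ) from exc
                step = 1.0
                for _ in range(6):
                    r_new, f_new, uf_new = residual(q_trial + step * dq,
                                                    tau_try)
                    if (not config.line_search
                            or np.linalg.norm(r_new) < rnorm
                            or step < 0.05):
                        break
                    step *= 0.5
                q_trial = q_trial + step * dq
                r, f, uf = r_new, f_new, uf_new
        except FloatingPointError:
            ok = False
        if ok:
            q, tau = q_trial, tau_try
        else:
            bisections += 1
            dtau *= 0.5
            if bisections > config.max_bisections:
                raise SolverError(
                    f"Newton failed to converge at load factor {tau_try:.4f} "
                    f"after {config.max_bisections} step bisections",
                    last_u=((T @ q) + u_p_fun(tau)).reshape(-1, 2),
                    residual_history=history,
                )
    u_final = (T @ q) + u_p_fun(1.0)
    return u_final.reshape(-1, 2), history, total_iters


def _field_solution(mesh, material, stage_tag, u, history, iters):
    f, sig = internal_forces(mesh, u, material, want_stress=True)
    elem_stress = sig.mean(axis=1)
    # extrapolate Gauss stresses to element corners, average per node
    corner = np.einsum("cg,egij->ecij", _EXTRAP, sig)
    nodal = np.zeros((mesh.n_nodes, 2, 2))
    counts = np.zeros(mesh.n_nodes)
    np.add.at(nodal, mesh.quads.ravel(), corner.reshape(-1, 2, 2))
    np.add.at(counts, mesh.quads.ravel(), 1.0)
    nodal /= np.maximum(counts, 1.0)[:, None, None]
    nvm = von_mises(nodal)
    evm = von_mises(elem_stress)
    imax = int(np.argmax(nvm))
    disp = np.linalg.norm(u, axis=1)
    idmax = int(np.argmax(disp))
    return FieldSolution(
        stage=stage_tag,
        u=u,
        gauss_stress=sig,
        element_stress=elem_stress,
        nodal_stress=nodal,
        nodal_von_mises=nvm,
        element_von_mises=evm,
        max_von_mises=float(nvm[imax]),
        max_von_mises_node=imax,
        max_von_mises_location=mesh.nodes[imax].copy(),
        max_displacement=float(disp[idmax]),
        max_displacement_node=idmax,
        max_displacement_location=mesh.nodes[idmax].copy(),
        converged=True,
        residual_history=history,
        newton_iterations=iters,
    )


def make_suture_stage(mesh: SkinMesh, plan=None) -> StageDefinition:
    """Suture stage: every wound-margin node ramped to its closure target."""
    plan = plan or closure_plan(mesh)
    prescribed = {}
    for node, target in plan.targets.items():
        dx = target - mesh.nodes[node]
        prescribed[(int(node), 0)] = float(dx[0])
        prescribed[(int(node), 1)] = float(dx[1])
    return StageDefinition(
        tag="suture", prescribed=prescribed, ties=[],
        fixed_nodes=mesh.corner_nodes.copy(),
    )


def make_release_stage(mesh: SkinMesh, plan=None) -> StageDefinition:
    """Release stage: margins tied pairwise, only the outer corners fixed."""
    plan = plan or closure_plan(mesh)
    return StageDefinition(
        tag="release", prescribed={}, ties=list(plan.ties),
        fixed_nodes=mesh.corner_nodes.copy(),
    )


def solve_stage(mesh: SkinMesh, material: OgdenParameters,
                stage: StageDefinition, config: SolverConfig | None = None,
                u_init: np.ndarray | None = None) -> FieldSolution:
    """Solve one analysis stage.

    The suture stage ramps the prescribed displacements from zero; the
    release stage starts from ``u_init`` (the converged suture state) and
    unloads the wound-margin reactions by force continuation while the tie
    constraints hold the stitched pairs together.
    """
    config = config or SolverConfig()
    config.validate()
    stage.validate()
    T, S, u_tie, pres_dofs, pres_vals = _build_transform(mesh, stage)
    if T.shape[1] == 0:
        raise RankDeficiencyError("no free degrees of freedom")
    if pres_dofs.size == 0 and stage.fixed_nodes.size == 0:
        # ties alone never remove the rigid translations/rotation
        raise RankDeficiencyError(
            "stage constrains no degrees of freedom; rigid-body modes "
            "would make the tangent singular"
        )
    n = 2 * mesh.n_nodes
    if stage.tag == "suture":
        u0 = np.zeros((mesh.n_nodes, 2)) if u_init is None else u_init

        def u_p_fun(tau):
            up = np.zeros(n)
            if pres_dofs.size:
                up[pres_dofs] = tau * pres_vals
            return up

        def f_ext_fun(tau):
            return np.zeros(T.shape[1])

    else:  # release: unload the reactions carried over from the start state
        if u_init is None:
            raise ValueError("release stage needs the suture state as u_init")
        u0 = u_init
        g0 = T.T @ internal_forces(mesh, u0, material).ravel()

        def u_p_fun(tau):
            return u_tie

        def f_ext_fun(tau):
            return (1.0 - tau) * g0

    t0 = time.perf_counter()
    u, history, iters = _newton(mesh, material, config, T, S, u0, u_p_fun,
                                f_ext_fun)
    log.info("%s stage: %d Newton iterations in %.2f s",
             stage.tag, iters, time.perf_counter() - t0)
    sol = _field_solution(mesh, material, stage.tag, u, history, iters)
    return sol


def run_suture_then_release(mesh: SkinMesh, material: OgdenParameters,
                            config: SolverConfig | None = None):
    """Full two-stage analysis; returns (suture, release) field solutions."""
    plan = closure_plan(mesh)
    suture = solve_stage(mesh, material, make_suture_stage(mesh, plan), config)
    release = solve_stage(mesh, material, make_release_stage(mesh, plan),
                          config, u_init=suture.u)
    return suture, release
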