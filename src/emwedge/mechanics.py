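"""Quasistatic finite elasticity of the wedge with active stress.

Passive myocardium follows the reduced transversely isotropic
Holzapfel-Ogden law

    Psi(I1, I4f) = a/(2b) [exp(b(I1-3)) - 1]
                 + a_f/(2 b_f) [exp(b_f (I4f-1)^2) - 1] . [I4f >= 1]

(the fiber term is switched off under fiber compression).  Contraction
enters as an additive fiber-aligned second Piola-Kirchhoff stress
S_a = Ta_max Ta (f0 x f0)/|F f0|^2.  Near-incompressibility is
enforced by a three-field (displacement / pressure / dilatation)
formulation on trilinear hexahedra with element-wise constant pressure
and dilatation (Q1/P0/P0 mean-dilatation); both element fields are
condensed out, leaving a displacement system solved by an incremental
Newton method with convergence measured in the energy norm.

Units: lengths mm, stresses kPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .tissue_ep import _SHAPE
from .wedge_setup import WedgeMesh

__all__ = [
    "HOParams",
    "KinematicsPoint",
    "MechanicsState",
    "strain_energy",
    "passive_second_pk",
    "active_second_pk",
    "solve_equilibrium",
    "wall_thickening",
    "default_bcs",
]

_EXP_CLAMP = 50.0  # exponent guard for the exponential energy terms
_I4_SMOOTH = 1e-4  # C-infinity regularization width of the I4f >= 1 switch


def _fiber_excess(I4):
    """Smooth positive part of I4f - 1 and its derivative.

    The compression switch [I4f >= 1] has a tangent-stiffness jump of
    2 a_f at I4f = 1, which makes Newton chatter when quadrature
    points sit exactly at the reference state; the softplus-like
    blend (x + sqrt(x^2 + delta^2))/2 removes the kink while staying
    numerically indistinguishable from max(x, 0) outside a 1e-4 band.
    """
    x = np.asarray(I4, float) - 1.0
    s = np.sqrt(x * x + _I4_SMOOTH * _I4_SMOOTH)
    return 0.5 * (x + s), 0.5 * (1.0 + x / s)


@dataclass
class HOParams:
    """Reduced Holzapfel-Ogden material constants.

    ``stiffness_scale`` multiplies all four constants (1 normal,
    5 heart failure); ``bulk_modulus`` (kPa) is the penalty modulus of
    the volumetric energy U(theta) = kappa/2 (theta-1)^2 in the mixed
    formulation.
    """

    a: float = 0.496       # kPa
    b: float = 7.209
    a_f: float = 15.193    # kPa
    b_f: float = 20.417
    stiffness_scale: float = 1.0
    bulk_modulus: float = 10000.0  # kPa

    def __post_init__(self):
        if min(self.a, self.b, self.a_f, self.b_f) <= 0:
            raise ValueError("HO constants must be positive")
        if self.stiffness_scale <= 0 or self.bulk_modulus <= 0:
            raise ValueError("scales must be positive")

    def effective(self):
        s = self.stiffness_scale
        return self.a * s, self.b * s, self.a_f * s, self.b_f * s


@dataclass
class KinematicsPoint:
    """Deformation measures at one quadrature point."""

    F: np.ndarray
    f0: np.ndarray
    J: float = field(init=False)
    C: np.ndarray = field(init=False)
    I1: float = field(init=False)
    I4f: float = field(init=False)

    def __post_init__(self):
        self.F = np.asarray(self.F, float)
        self.f0 = np.asarray(self.f0, float)
        n = np.linalg.norm(self.f0)
        if abs(n - 1.0) > 1e-8:
            self.f0 = self.f0 / n
        self.J = float(np.linalg.det(self.F))
        if self.J <= 0:
            raise ValueError("non-positive Jacobian determinant")
        self.C = self.F.T @ self.F
        if np.linalg.norm(self.C - self.C.T) > 1e-10 * np.linalg.norm(self.C):
            raise ValueError("C must be symmetric")
        try:
            np.linalg.cholesky(self.C)
        except np.linalg.LinAlgError as exc:
            raise ValueError("C must be positive definite") from exc
        self.I1 = float(np.trace(self.C))
        self.I4f = float(self.f0 @ self.C @ self.f0)


def _safe_exp(x):
    return np.exp(np.clip(x, -_EXP_CLAMP, _EXP_CLAMP))


def strain_energy(I1, I4f, params: HOParams):
    """Passive strain-energy density (kPa).

    The fiber term contributes only in extension (I4f >= 1); exponents
    are clamped against overflow.
    """
    a, b, af, bf = params.effective()
    I1 = np.asarray(I1, float)
    I4f = np.asarray(I4f, float)
    iso = a / (2.0 * b) * (_safe_exp(b * (I1 - 3.0)) - 1.0)
    ex, _ = _fiber_excess(I4f)
    fib = af / (2.0 * bf) * (_safe_exp(bf * ex ** 2) - 1.0)
    out = iso + fib
    return float(out) if out.ndim == 0 else out


def passive_second_pk(point: KinematicsPoint, params: HOParams,
                      pressure: float = 0.0):
    """Passive second Piola-Kirchhoff stress 2 dPsi/dC (kPa).

    ``pressure`` adds the volumetric term p J C^-1 of the mixed
    formulation (zero for the purely isochoric passive response).
    """
    a, b, af, bf = params.effective()
    S = a * _safe_exp(b * (point.I1 - 3.0)) * np.eye(3)
    ex, dex = _fiber_excess(point.I4f)
    S = S + 2.0 * af * ex * dex * _safe_exp(bf * ex ** 2) \
        * np.outer(point.f0, point.f0)
    if pressure != 0.0:
        S = S + pressure * point.J * np.linalg.inv(point.C)
    return S


def active_second_pk(Ta, Ta_max, F, f0):
    """Active stress S_a = Ta_max Ta (f0 x f0)/|F f0|^2 (kPa)."""
    if Ta < 0:
        raise ValueError("active force must be non-negative")
    F = np.asarray(F, float)
    f0 = np.asarray(f0, float)
    lam2 = float(np.sum((F @ f0) ** 2))
    if lam2 <= 0:
        raise ValueError("degenerate fiber stretch |F f0| = 0")
    return Ta_max * Ta / lam2 * np.outer(f0, f0)


@dataclass
class MechanicsState:
    """Converged displacement solution with the condensed mixed fields."""

    u: np.ndarray               # (n_nodes, 3) displacements, mm
    theta: np.ndarray           # (n_elems,) element dilatation
    pressure: np.ndarray        # (n_elems,) element pressure, kPa
    residual_norm: float
    energy_history: list

    def deformation_gradients(self, mesh: WedgeMesh):
        """F at the 2x2x2 Gauss points of every element, (ne, 8, 3, 3)."""
        return _deformation_gradients(mesh, self.u)


def default_bcs(mesh: WedgeMesh):
    """Zero normal displacement on x=0, y=0, z=0 and z=z_max faces."""
    return {"x0": 0, "y0": 1, "z0": 2, "zmax": 2}


def _solve_uniaxial(params: HOParams, T_active):
    """Fiber stretch ly of the homogeneous uniaxial active balance
    a (1/ly^2 - ly^2) exp(b(I1-3)) = T (z held, x free, incompressible)."""
    from scipy.optimize import brentq

    a, b, _, _ = params.effective()
    if T_active <= 1e-12:
        return 1.0

    def balance(ly):
        lx2 = 1.0 / ly ** 2
        return a * (lx2 - ly ** 2) * np.exp(
            np.clip(b * (lx2 + ly ** 2 - 2.0), -_EXP_CLAMP, _EXP_CLAMP)) \
            - T_active

    try:
        return brentq(balance, 0.2, 1.0 - 1e-12)
    except ValueError:
        return 1.0


def _layered_predictor(mesh: WedgeMesh, params: HOParams, ta_nodes):
    """Newton initial guess from per-slab uniaxial solutions.

    The wedge contracts along y with an x-dependent active tension
    (cell-type layers activate at different times), so each transmural
    element slab is given its own homogeneous uniaxial solution; the
    transmural displacement accumulates the slab stretches 1/ly and
    the fiber-direction displacement uses the slab-averaged ly at the
    node's transmural position.  ``ta_nodes`` is Ta_max*Ta per node in
    kPa.  Exact for a uniform field; for layered fields Newton only
    has to resolve the interface shear corrections.
    """
    if not np.allclose(mesh.fibers, [0.0, 1.0, 0.0]):
        return np.zeros((mesh.n_nodes, 3))
    nx = mesh.shape[0]
    dx = mesh.dx
    ix_elem = np.arange(mesh.n_elems) % nx
    ta_elem = np.asarray(ta_nodes, float)[mesh.elems].mean(axis=1)
    ly_slab = np.ones(nx)
    for i in range(nx):
        sel = ix_elem == i
        ly_slab[i] = _solve_uniaxial(params, float(ta_elem[sel].mean()))
    # node transmural index and deformed x positions
    ix_node = np.rint(mesh.nodes[:, 0] / dx).astype(int)
    xdef = np.concatenate([[0.0], np.cumsum(dx / ly_slab)])
    ly_node = np.empty(nx + 1)
    ly_node[0] = ly_slab[0]
    ly_node[-1] = ly_slab[-1]
    ly_node[1:-1] = 0.5 * (ly_slab[:-1] + ly_slab[1:])
    u = np.zeros((mesh.n_nodes, 3))
    u[:, 0] = xdef[ix_node] - mesh.nodes[:, 0]
    u[:, 1] = (ly_node[ix_node] - 1.0) * mesh.nodes[:, 1]
    return u


def _homogeneous_predictor(mesh: WedgeMesh, params: HOParams, T_active):
    """Analytic homogeneous solution used as a Newton initial guess.

    For uniform fibers along y, the wedge boundary conditions admit a
    homogeneous incompressible deformation diag(1/ly, ly, 1) whose
    fiber stretch solves the uniaxial balance
    a (lx^2 - ly^2) exp(b (I1 - 3)) = T_active (active Cauchy stress).
    This predictor lets Newton skip the soft low-strain regime where
    the exponential passive law provides almost no stiffness.
    """
    from scipy.optimize import brentq

    a, b, _, _ = params.effective()
    if T_active <= 1e-12:
        return np.zeros((mesh.n_nodes, 3))
    if not np.allclose(mesh.fibers, [0.0, 1.0, 0.0]):
        return np.zeros((mesh.n_nodes, 3))

    def balance(ly):
        lx2 = 1.0 / ly ** 2
        return a * (lx2 - ly ** 2) * np.exp(
            np.clip(b * (lx2 + ly ** 2 - 2.0), -_EXP_CLAMP, _EXP_CLAMP)) \
            - T_active

    try:
        ly = brentq(balance, 0.2, 1.0 - 1e-12)
    except ValueError:
        return np.zeros((mesh.n_nodes, 3))
    u = np.zeros((mesh.n_nodes, 3))
    u[:, 0] = (1.0 / ly - 1.0) * mesh.nodes[:, 0]
    u[:, 1] = (ly - 1.0) * mesh.nodes[:, 1]
    return u


def _grad_ops(mesh: WedgeMesh):
    """Physical shape gradients (8,3) per Gauss point and detJ (mm^3)."""
    e0 = mesh.elems[0]
    h = mesh.nodes[e0].max(axis=0) - mesh.nodes[e0].min(axis=0)
    detj = h.prod() / 8.0
    B = np.array([dN * (2.0 / h) for (_, dN) in _SHAPE])  # (8 gauss, 8, 3)
    return B, detj


def _deformation_gradients(mesh, u):
    B, _ = _grad_ops(mesh)
    ue = u[mesh.elems]                      # (ne, 8, 3)
    # F[e,g,i,j] = delta_ij + sum_a ue[e,a,i] B[g,a,j]
    F = np.einsum("eai,gaj->egij", ue, B, optimize=True)
    F += np.eye(3)
    return F


def _element_residual(mesh, u, params: HOParams, active_gauss, fibers,
                      B, detj, w_g=1.0):
    """Internal force per element (ne, 8, 3) and mean dilatation.

    Stresses: passive HO + volumetric (mean-dilatation pressure) +
    active.  ``active_gauss`` is Ta_max*Ta (kPa) per (ne, 8).
    """
    a, b, af, bf = params.effective()
    kappa = params.bulk_modulus
    F = _deformation_gradients(mesh, u)     # (ne, 8, 3, 3)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise FloatingPointError("element inversion (J <= 0)")
    C = np.einsum("egki,egkj->egij", F, F, optimize=True)
    Cinv = np.linalg.inv(C)
    I1 = np.trace(C, axis1=2, axis2=3)
    f0 = fibers                             # (ne, 3)
    Cf = np.einsum("egij,ej->egi", C, f0, optimize=True)
    I4 = np.einsum("egi,ei->eg", Cf, f0, optimize=True)

    theta = J.mean(axis=1)                  # mean dilatation (equal weights)
    p = kappa * (theta - 1.0)               # (ne,)

    # passive + volumetric S
    S = a * _safe_exp(b * (I1 - 3.0))[..., None, None] * np.eye(3)
    ex, dex = _fiber_excess(I4)
    coef = 2.0 * af * ex * dex * _safe_exp(bf * ex ** 2)
    ff = np.einsum("ei,ej->eij", f0, f0, optimize=True)
    S = S + coef[..., None, None] * ff[:, None]
    S = S + (p[:, None] * J)[..., None, None] * Cinv
    # active stress along f0/|F f0|^2
    lam2 = np.einsum("egij,ej,egik,ek->eg", F, f0, F, f0, optimize=True)
    S = S + (active_gauss / lam2)[..., None, None] * ff[:, None]

    P = np.einsum("egik,egkj->egij", F, S, optimize=True)  # first Piola-Kirchhoff
    fint = detj * np.einsum("egij,gaj->eai", P, B, optimize=True)
    return fint, theta, p


def total_potential_energy(mesh, u, params: HOParams, active_gauss,
                           B=None, detj=None):
    """Total potential (kPa mm^3) whose gradient is the residual.

    Pi(u) = int Psi(I1, I4f) + kappa/2 (theta_e - 1)^2
          + (Ta_max Ta / 2) ln I4f,
    with theta_e the element-mean Jacobian: the active fiber stress
    Ta_max Ta (f0 x f0)/I4f is conservative with potential
    (Ta_max Ta/2) ln I4f, so quasistatic equilibria are stationary
    points (minima) of Pi.
    """
    if B is None:
        B, detj = _grad_ops(mesh)
    F = _deformation_gradients(mesh, u)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise FloatingPointError("element inversion (J <= 0)")
    C = np.einsum("egki,egkj->egij", F, F, optimize=True)
    I1 = np.trace(C, axis1=2, axis2=3)
    I4 = np.einsum("ei,egij,ej->eg", mesh.fibers, C, mesh.fibers, optimize=True)
    a, b, af, bf = params.effective()
    psi = a / (2 * b) * (_safe_exp(b * (I1 - 3.0)) - 1.0)
    ex, _ = _fiber_excess(I4)
    psi = psi + af / (2 * bf) * (_safe_exp(bf * ex ** 2) - 1.0)
    psi = psi + 0.5 * active_gauss * np.log(I4)
    theta = J.mean(axis=1)
    vol = 8.0 * detj * 0.5 * params.bulk_modulus * (theta - 1.0) ** 2
    return float(detj * psi.sum() + vol.sum())


def _assemble_residual(mesh, u, params, active_gauss, B, detj):
    fint, theta, p = _element_residual(mesh, u, params, active_gauss,
                                       mesh.fibers, B, detj)
    R = np.zeros((mesh.n_nodes, 3))
    np.add.at(R, mesh.elems, fint)
    return R, theta, p


def _assemble_tangent(mesh, u, params, active_gauss, B, detj,
                      h_fd=1e-7):
    """Consistent tangent by central differencing of the element
    residual over the 24 element dofs; all 48 perturbed configurations
    are evaluated in a single vectorized pass."""
    ne = mesh.n_elems
    ue = u[mesh.elems]                      # (ne, 8, 3)

    pert = np.zeros((48, ne, 8, 3))
    pert[:] = ue
    for dof in range(24):
        a, i = divmod(dof, 3)
        pert[2 * dof, :, a, i] += h_fd
        pert[2 * dof + 1, :, a, i] -= h_fd
    big_ue = pert.reshape(48 * ne, 8, 3)
    fibers = np.tile(mesh.fibers, (48, 1))
    ta = np.tile(active_gauss, (48, 1))

    a_, b_, af_, bf_ = params.effective()
    F = np.einsum("eai,gaj->egij", big_ue, B, optimize=True)
    F += np.eye(3)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise FloatingPointError("element inversion (J <= 0)")
    C = np.einsum("egki,egkj->egij", F, F, optimize=True)
    Cinv = np.linalg.inv(C)
    I1 = np.trace(C, axis1=2, axis2=3)
    I4 = np.einsum("ei,egij,ej->eg", fibers, C, fibers, optimize=True)
    theta = J.mean(axis=1)
    p = params.bulk_modulus * (theta - 1.0)
    S = a_ * _safe_exp(b_ * (I1 - 3.0))[..., None, None] * np.eye(3)
    ex, dex = _fiber_excess(I4)
    coef = 2.0 * af_ * ex * dex * _safe_exp(bf_ * ex ** 2)
    ff = np.einsum("ei,ej->eij", fibers, fibers, optimize=True)
    S = S + coef[..., None, None] * ff[:, None]
    S = S + (p[:, None] * J)[..., None, None] * Cinv
    lam2 = np.einsum("egij,ej,egik,ek->eg", F, fibers, F, fibers, optimize=True)
    S = S + (ta / lam2)[..., None, None] * ff[:, None]
    P = np.einsum("egik,egkj->egij", F, S, optimize=True)
    fint = detj * np.einsum("egij,gaj->eai", P, B, optimize=True)  # (48 ne, 8, 3)

    fint = fint.reshape(48, ne, 24)
    K = np.empty((ne, 24, 24))
    for dof in range(24):
        K[:, :, dof] = (fint[2 * dof] - fint[2 * dof + 1]) / (2.0 * h_fd)
    return K


def _scatter_tangent(mesh, K):
    ne = mesh.n_elems
    edof = (3 * mesh.elems[:, :, None] + np.arange(3)).reshape(ne, 24)
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    n = 3 * mesh.n_nodes
    return sp.coo_matrix((K.ravel(), (rows, cols)), shape=(n, n)).tocsc()


def _fixed_dofs(mesh: WedgeMesh, bcs: dict):
    fixed = []
    for tag, comp in bcs.items():
        fixed.append(3 * mesh.face_nodes[tag] + comp)
    return np.unique(np.concatenate(fixed)) if fixed else np.array([], int)


def _minimize_equilibrium(mesh, u, params, ta_gauss, free, B, detj,
                          maxiter=800):
    """L-BFGS descent on the total potential from ``u``; used when
    Newton leaves its basin of attraction (limit points of the
    load-controlled active-stress response)."""
    from scipy.optimize import minimize

    n = mesh.n_nodes

    def fun(x):
        uu = np.zeros(3 * n)
        uu[free] = x
        uu = uu.reshape(n, 3)
        try:
            e = total_potential_energy(mesh, uu, params, ta_gauss, B, detj)
            R, _, _ = _assemble_residual(mesh, uu, params, ta_gauss, B,
                                         detj)
        except FloatingPointError:
            return 1e30, np.zeros_like(x)
        return e, R.reshape(-1)[free]

    res = minimize(fun, u.reshape(-1)[free], jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": 1e-12,
                            "ftol": 1e-13})
    out = np.zeros(3 * n)
    out[free] = res.x
    return out.reshape(n, 3)


def solve_equilibrium(mesh: WedgeMesh, params: HOParams, active_field,
                      bcs: dict | None = None, n_inc: int = 10,
                      energy_tol: float = 1e-6, max_iter: int = 120,
                      u0: np.ndarray | None = None,
                      Ta_max: float = 50.0) -> MechanicsState:
    """Incremental Newton solve of div(FS) = 0.

    ``active_field``: normalized active force Ta per node (or scalar),
    scaled by ``Ta_max`` (kPa) and ramped linearly over ``n_inc`` load
    increments; trilinearly interpolated to Gauss points.  Convergence
    per increment in the energy norm: |du.R| at iteration k must fall
    below ``energy_tol`` times its first-iteration value.  Each
    increment is warm-started by a per-slab homogeneous predictor; a
    backtracking line search rejects steps that invert elements or
    grow the residual, the factorized tangent is reused until it
    stalls, and an energy-minimization rescue handles increments whose
    Newton path crosses a limit point.
    """
    bcs = default_bcs(mesh) if bcs is None else bcs
    B, detj = _grad_ops(mesh)
    n = mesh.n_nodes
    Ta = np.broadcast_to(np.asarray(active_field, float), (n,))
    N_shapes = np.array([N for (N, _) in _SHAPE])  # (8 gauss, 8 nodes)
    ta_gauss_full = Ta_max * np.einsum("ga,ea->eg", N_shapes,
                                       Ta[mesh.elems], optimize=True)

    fixed = _fixed_dofs(mesh, bcs)
    free = np.setdiff1d(np.arange(3 * n), fixed)
    use_predictor = u0 is None and bcs == default_bcs(mesh)
    u = np.zeros((n, 3)) if u0 is None else u0.copy()
    energy_hist = []
    h_prev = np.zeros((n, 3))
    lu = None

    def residual(uu, tg):
        R, th, p = _assemble_residual(mesh, uu, params, tg, B, detj)
        return R.reshape(-1)[free], th, p

    for inc in range(1, n_inc + 1):
        load = inc / n_inc
        ta_gauss = load * ta_gauss_full
        if use_predictor:
            h_now = _layered_predictor(mesh, params,
                                       load * Ta_max * Ta)
            u_try = u + (h_now - h_prev)
            try:
                residual(u_try, ta_gauss)
                u = u_try
                h_prev = h_now
            except FloatingPointError:
                pass
        e0 = None
        refreshed = False
        n_rescues = 0
        converged = False
        prev_energy = None
        r, theta, p = residual(u, ta_gauss)
        for it in range(max_iter):
            rn = np.linalg.norm(r)
            if lu is None:
                K = _assemble_tangent(mesh, u, params, ta_gauss, B, detj)
                A = _scatter_tangent(mesh, K)[np.ix_(free, free)]
                try:
                    lu = spla.splu(A.tocsc())
                except RuntimeError as exc:
                    raise RuntimeError(
                        "singular tangent; check boundary conditions "
                        "suppress all rigid-body modes") from exc
                refreshed = True
            du = lu.solve(-r)
            if not np.all(np.isfinite(du)):
                raise RuntimeError(
                    "singular tangent; check boundary conditions "
                    "suppress all rigid-body modes")
            energy = abs(float(du @ r))
            energy_hist.append((inc, it, energy, rn))
            # absolute floor (kPa mm^3): unloaded/near-unloaded
            # increments start converged
            if e0 is None:
                e0 = max(energy, 1e-300)
                if energy < 1e-12:
                    converged = True
                    break
            elif energy <= max(energy_tol * e0, 1e-12):
                converged = True
                break
            # a stale tangent that only creeps (slow energy decay)
            # is rebuilt before taking further steps
            if not refreshed and prev_energy is not None \
                    and energy > 0.5 * prev_energy:
                lu = None
                prev_energy = energy
                continue
            prev_energy = energy
            accepted = False
            alpha = 1.0
            for _ in range(8):
                unew = u.reshape(-1).copy()
                unew[free] += alpha * du
                unew = unew.reshape(n, 3)
                try:
                    r_t, th_t, p_t = residual(unew, ta_gauss)
                except FloatingPointError:
                    alpha *= 0.5
                    continue
                if np.linalg.norm(r_t) <= (1.0 + 1e-8) * rn:
                    u, r, theta, p = unew, r_t, th_t, p_t
                    accepted = True
                    break
                alpha *= 0.5
            if accepted:
                refreshed = False
                continue
            if not refreshed:
                lu = None  # stale tangent: rebuild and retry
            elif n_rescues < 2:
                u = _minimize_equilibrium(mesh, u, params, ta_gauss,
                                          free, B, detj)
                r, theta, p = residual(u, ta_gauss)
                lu = None
                n_rescues += 1
                e0 = None
                prev_energy = None
            else:
                break
        if not converged:
            hist = [f"inc {i} it {k}: dE={e:.3e} |R|={rr:.3e}"
                    for i, k, e, rr in energy_hist[-max_iter:]]
            raise RuntimeError("Newton did not converge:\n"
                               + "\n".join(hist))

    r, theta, p = residual(u, ta_gauss_full)
    return MechanicsState(u=u, theta=theta, pressure=p,
                          residual_norm=float(np.linalg.norm(r)),
                          energy_history=energy_hist)


def wall_thickening(state: MechanicsState, mesh: WedgeMesh) -> float:
    """Percent change of the transmural (x) extent of the wedge."""
    x = mesh.nodes[:, 0] + state.u[:, 0]
    ref = mesh.nodes[:, 0].max() - mesh.nodes[:, 0].min()
    return 100.0 * ((x.max() - x.min()) - ref) / ref
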