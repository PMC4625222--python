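"""Deformation-modified bidomain electrophysiology on hexahedral meshes.

The bidomain equations in the reference configuration read

    chi Cm d(J v)/dt + J I_ion - Div(J F^-1 D_i F^-T Grad(v + u_e)) = 0
    Div(J F^-1 (D_i + D_e) F^-T Grad u_e) = -Div(J F^-1 D_i F^-T Grad v)

with transversely isotropic conductivity tensors about the local fiber
direction.  Spatial discretization uses trilinear hexahedra (linear
elements for the 1-D cable), time discretization Crank-Nicolson with
Godunov splitting of the ionic reaction (Rush-Larsen cell update,
then the parabolic solve for v, then the elliptic solve for u_e).
The extracellular potential is gauge-fixed to zero mean through a
Lagrange multiplier.

Unit convention: conductivities in mS/cm, chi in 1/cm, Cm in uF/cm^2,
lengths converted from mm to cm at assembly, v and u_e in mV, time in
ms; the membrane reaction then enters as chi*Cm*I_ion in uA/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import cell_models as cm
from .wedge_setup import WedgeMesh, layer_element_counts

__all__ = [
    "ConductivitySet",
    "StimulusProtocol",
    "effective_conductivity",
    "assemble_bidomain",
    "BidomainOperators",
    "TissueState",
    "step_bidomain",
    "run_wedge_ep",
    "run_cable_1d",
]

MM_TO_CM = 0.1


@dataclass
class ConductivitySet:
    """Fiber / cross-fiber conductivities (mS/cm) with an HF scale."""

    sigma_i_f: float = 3.0
    sigma_i_s: float = 1.0
    sigma_e_f: float = 2.0
    sigma_e_s: float = 1.65
    scale: float = 1.0  # 1.0 normal, 0.7 heart failure

    def __post_init__(self):
        for v in (self.sigma_i_f, self.sigma_i_s, self.sigma_e_f,
                  self.sigma_e_s, self.scale):
            if v <= 0:
                raise ValueError("conductivities must be positive")

    def _tensor(self, s_f, s_s, f0):
        f0 = np.asarray(f0, float)
        return self.scale * (s_s * np.eye(3)
                             + (s_f - s_s) * np.outer(f0, f0))

    def intra(self, f0):
        return self._tensor(self.sigma_i_f, self.sigma_i_s, f0)

    def extra(self, f0):
        return self._tensor(self.sigma_e_f, self.sigma_e_s, f0)


@dataclass
class StimulusProtocol:
    """Transmembrane current injection on a node set."""

    nodes: np.ndarray
    amplitude: float = -80.0  # pA/pF
    duration: float = 2.0     # ms
    start: float = 0.0        # ms

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, int)
        if self.nodes.size == 0:
            raise ValueError("stimulus region is empty")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")

    def current(self, t, n_nodes):
        istim = np.zeros(n_nodes)
        if self.start <= t < self.start + self.duration:
            istim[self.nodes] = self.amplitude
        return istim


def effective_conductivity(D, F):
    """Pull-back J F^-1 D F^-T of a conductivity tensor; SPD-preserving."""
    D = np.asarray(D, float)
    F = np.asarray(F, float)
    J = np.linalg.det(F)
    if J <= 0:
        raise ValueError("deformation gradient must have positive determinant")
    Finv = np.linalg.inv(F)
    return J * Finv @ D @ Finv.T


# ---------------------------------------------------------------------------
# trilinear hexahedral FEM assembly (structured box elements)
# ---------------------------------------------------------------------------

_G = 1.0 / np.sqrt(3.0)
GAUSS_PTS = np.array([[sx, sy, sz] for sz in (-_G, _G) for sy in (-_G, _G)
                      for sx in (-_G, _G)])
# reference hexahedron node coordinates, VTK ordering
_XI = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], float)


def hex_shape(gp):
    """Values and reference gradients of the 8 trilinear functions."""
    x, y, z = gp
    N = (1 + _XI[:, 0] * x) * (1 + _XI[:, 1] * y) * (1 + _XI[:, 2] * z) / 8.0
    dN = np.empty((8, 3))
    dN[:, 0] = _XI[:, 0] * (1 + _XI[:, 1] * y) * (1 + _XI[:, 2] * z) / 8.0
    dN[:, 1] = _XI[:, 1] * (1 + _XI[:, 0] * x) * (1 + _XI[:, 2] * z) / 8.0
    dN[:, 2] = _XI[:, 2] * (1 + _XI[:, 0] * x) * (1 + _XI[:, 1] * y) / 8.0
    return N, dN


_SHAPE = [hex_shape(gp) for gp in GAUSS_PTS]


def _element_size_cm(mesh: WedgeMesh):
    e0 = mesh.elems[0]
    h = (mesh.nodes[e0].max(axis=0) - mesh.nodes[e0].min(axis=0)) * MM_TO_CM
    return h


def _scatter(mesh, ke):
    """Assemble per-element (ne, 8, 8) blocks into a CSR matrix."""
    ne = mesh.n_elems
    rows = np.repeat(mesh.elems, 8, axis=1).ravel()
    cols = np.tile(mesh.elems, (1, 8)).ravel()
    A = sp.coo_matrix((ke.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    return A.tocsr()


def assemble_stiffness(mesh: WedgeMesh, tensors):
    """Stiffness matrix for Div(D Grad .) with per-element/Gauss tensors.

    ``tensors`` may be a single (3,3), per-element (ne,3,3) or
    per-element-per-Gauss (ne,8,3,3) array, in mS/cm.
    """
    ne = mesh.n_elems
    D = np.asarray(tensors, float)
    if D.shape == (3, 3):
        D = np.broadcast_to(D, (ne, 8, 3, 3))
    elif D.shape == (ne, 3, 3):
        D = np.broadcast_to(D[:, None], (ne, 8, 3, 3))
    elif D.shape != (ne, 8, 3, 3):
        raise ValueError("bad tensor field shape")

    h = _element_size_cm(mesh)
    detj = h.prod() / 8.0
    ke = np.zeros((ne, 8, 8))
    for g, (_, dN) in enumerate(_SHAPE):
        B = dN * (2.0 / h)  # physical gradients, (8,3)
        ke += detj * np.einsum("ai,nij,bj->nab", B, D[:, g], B,
                               optimize=True)
    return _scatter(mesh, ke)


def assemble_mass(mesh: WedgeMesh, weight=None, lumped: bool = False):
    """Consistent (default) or lumped mass matrix, optionally weighted
    by a per-element/Gauss scalar field (e.g. J)."""
    ne = mesh.n_elems
    if weight is None:
        w = np.ones((ne, 8))
    else:
        w = np.asarray(weight, float)
        if w.shape == (ne,):
            w = np.broadcast_to(w[:, None], (ne, 8))
    h = _element_size_cm(mesh)
    detj = h.prod() / 8.0
    me = np.zeros((ne, 8, 8))
    for g, (N, _) in enumerate(_SHAPE):
        me += detj * w[:, g, None, None] * np.outer(N, N)
    M = _scatter(mesh, me)
    if lumped:
        M = sp.diags(np.asarray(M.sum(axis=1)).ravel()).tocsr()
    return M


# ---------------------------------------------------------------------------
# operators and time stepping
# ---------------------------------------------------------------------------

class _LinearSolve:
    """Prefactorized direct solve or ILU-preconditioned Krylov solve."""

    def __init__(self, A, method="direct", symmetric_indefinite=False,
                 rtol=1e-8):
        self.method = method
        self.rtol = rtol
        A = A.tocsc()
        self.A = A
        self.indefinite = symmetric_indefinite
        if method == "direct":
            self.lu = spla.splu(A)
        elif method == "pcg":
            ilu = spla.spilu(A, drop_tol=1e-5, fill_factor=20)
            self.prec = spla.LinearOperator(A.shape, ilu.solve)
        else:
            raise ValueError(f"unknown solver {method!r}")

    def __call__(self, b, x0=None):
        if self.method == "direct":
            return self.lu.solve(b)
        if self.indefinite:
            # the gauge-augmented elliptic block is symmetric
            # indefinite and the ILU preconditioner is not symmetric,
            # so GMRES stands in for a symmetric Krylov method here
            x, info = spla.gmres(self.A, b, x0=x0, rtol=self.rtol,
                                 maxiter=2000, M=self.prec)
        else:
            x, info = spla.cg(self.A, b, x0=x0, rtol=self.rtol,
                              maxiter=2000, M=self.prec)
        if info != 0:
            res = np.linalg.norm(self.A @ x - b) / max(np.linalg.norm(b),
                                                       1e-300)
            raise RuntimeError(
                f"Krylov solver did not converge (info={info}, "
                f"relative residual {res:.2e})")
        return x


@dataclass
class BidomainOperators:
    """Assembled FEM operators + factorized solvers for one F-field."""

    M: sp.csr_matrix            # (J-weighted) mass
    Ki: sp.csr_matrix           # intracellular stiffness
    Kie: sp.csr_matrix          # intra + extracellular stiffness
    chi: float
    cm_: float
    dt: float
    monodomain: bool = False
    solver: str = "direct"
    _par: _LinearSolve = field(init=False, repr=False)
    _ell: _LinearSolve | None = field(init=False, repr=False, default=None)
    _rhs_op: sp.csr_matrix = field(init=False, repr=False)
    _gauge_w: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self):
        n = self.M.shape[0]
        a = self.chi * self.cm_ / self.dt
        A_par = (a * self.M + 0.5 * self.Ki).tocsc()
        self._rhs_op = (a * self.M - 0.5 * self.Ki).tocsr()
        self._par = _LinearSolve(A_par, self.solver)
        if not self.monodomain:
            w = np.asarray(self.M.sum(axis=1)).ravel()
            self._gauge_w = w
            A_ell = sp.bmat([[self.Kie, w[:, None]],
                             [w[None, :], None]], format="csc")
            self._ell = _LinearSolve(A_ell, self.solver,
                                     symmetric_indefinite=True)

    def parabolic_solve(self, v_star, ue):
        rhs = self._rhs_op @ v_star
        if not self.monodomain:
            rhs = rhs - self.Ki @ ue
        return self._par(rhs, x0=v_star)

    def elliptic_solve(self, v, ue_prev=None):
        rhs = np.append(-(self.Ki @ v), 0.0)
        x0 = None if ue_prev is None else np.append(ue_prev, 0.0)
        return self._ell(rhs, x0=x0)[:-1]


def _tensor_fields(mesh: WedgeMesh, cond: ConductivitySet, F_field=None):
    ne = mesh.n_elems
    Di = np.empty((ne, 3, 3))
    De = np.empty((ne, 3, 3))
    for e in range(ne):
        Di[e] = cond.intra(mesh.fibers[e])
        De[e] = cond.extra(mesh.fibers[e])
    Jw = None
    if F_field is not None:
        F = np.asarray(F_field, float)
        if F.shape == (ne, 3, 3):
            F = np.broadcast_to(F[:, None], (ne, 8, 3, 3)).copy()
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise ValueError("deformation gradient with non-positive J")
        Finv = np.linalg.inv(F)
        Di = np.einsum("ng,ngij,njk,nglk->ngil", J, Finv, Di, Finv,
                       optimize=True)
        De = np.einsum("ng,ngij,njk,nglk->ngil", J, Finv, De, Finv,
                       optimize=True)
        Jw = J
    return Di, De, Jw


def assemble_bidomain(mesh: WedgeMesh, cond: ConductivitySet,
                      F_field=None, chi: float = 2000.0, cm_: float = 1.0,
                      dt: float = 0.05, solver: str = "direct",
                      lumped_mass: bool = False,
                      monodomain: bool = False) -> BidomainOperators:
    """Assemble the parabolic/elliptic bidomain operators.

    ``F_field`` (per element or per Gauss point) activates the
    deformation pull-back J F^-1 D F^-T of both conductivity tensors
    and the J-weighting of the mass matrix; ``None`` means the
    undeformed (identity) configuration.  ``monodomain=True`` builds a
    single parabolic operator with the harmonic-mean tensor
    D_i (D_i + D_e)^-1 D_e.
    """
    Di, De, Jw = _tensor_fields(mesh, cond, F_field)
    M = assemble_mass(mesh, weight=Jw, lumped=lumped_mass)
    if monodomain:
        if Di.ndim == 3:
            Dm = np.array([cond.intra(f) @ np.linalg.inv(
                cond.intra(f) + cond.extra(f)) @ cond.extra(f)
                for f in mesh.fibers])
        else:
            Dm = np.einsum("ngij,ngjk,ngkl->ngil", Di,
                           np.linalg.inv(Di + De), De, optimize=True)
        Km = assemble_stiffness(mesh, Dm)
        return BidomainOperators(M=M, Ki=Km, Kie=Km, chi=chi, cm_=cm_,
                                 dt=dt, monodomain=True, solver=solver)
    Ki = assemble_stiffness(mesh, Di)
    Ke = assemble_stiffness(mesh, De)
    return BidomainOperators(M=M, Ki=Ki, Kie=(Ki + Ke).tocsr(), chi=chi,
                             cm_=cm_, dt=dt, solver=solver)


@dataclass
class TissueState:
    """Nodal cell states plus the extracellular potential."""

    cells: np.ndarray   # (n_nodes, NSTATE)
    ue: np.ndarray      # (n_nodes,)

    @property
    def v(self):
        return self.cells[:, cm.IV]

    @classmethod
    def resting(cls, cell_params_rows, initial_rows=None):
        n = cell_params_rows.shape[0]
        if initial_rows is None:
            cells = np.tile(cm.initial_state(), (n, 1))
        else:
            cells = np.array(initial_rows, float, copy=True)
        return cls(cells=cells, ue=np.zeros(n))


def step_bidomain(state: TissueState, params_rows, ops: BidomainOperators,
                  dt: float, istim):
    """One Godunov-split step: cell ODEs, parabolic CN solve for v,
    elliptic solve for u_e (skipped for monodomain operators)."""
    cm.step_cells(state.cells, params_rows, dt, istim)
    v_star = state.cells[:, cm.IV].copy()
    v_new = ops.parabolic_solve(v_star, state.ue)
    state.cells[:, cm.IV] = v_new
    if not ops.monodomain:
        state.ue = ops.elliptic_solve(v_new, ue_prev=state.ue)
    if not np.all(np.isfinite(v_new)):
        raise FloatingPointError("non-finite transmembrane voltage")
    return state


def run_wedge_ep(mesh: WedgeMesh, params_rows, cond: ConductivitySet,
                 protocol: StimulusProtocol, T: float, dt: float = 0.05,
                 initial_rows=None, record_dt: float | None = None,
                 chi: float = 2000.0, cm_: float = 1.0,
                 solver: str = "direct", monodomain: bool = False,
                 step_hook=None):
    """Pure electrophysiology time loop on a wedge mesh.

    ``step_hook(t, state, ops) -> ops or None`` is called after every
    step; returning new operators swaps them in (used by the
    electromechanical driver to feed back deformation).  Returns a
    dict with sampled times, v and u_e histories and final state.
    """
    n = mesh.n_nodes
    if params_rows.shape[0] != n:
        raise ValueError("one parameter row per node required")
    state = TissueState.resting(params_rows, initial_rows)
    ops = assemble_bidomain(mesh, cond, chi=chi, cm_=cm_, dt=dt,
                            solver=solver, monodomain=monodomain)
    n_steps = int(round(T / dt))
    stride = 1 if record_dt is None else max(1, int(round(record_dt / dt)))
    n_rec = n_steps // stride + 1
    t_rec = np.empty(n_rec)
    v_rec = np.empty((n_rec, n))
    ue_rec = np.empty((n_rec, n))
    t_rec[0], v_rec[0], ue_rec[0] = 0.0, state.v, state.ue
    k_rec = 1
    t = 0.0
    for k in range(n_steps):
        istim = protocol.current(t, n)
        step_bidomain(state, params_rows, ops, dt, istim)
        t = (k + 1) * dt
        if step_hook is not None:
            new_ops = step_hook(t, state, ops)
            if new_ops is not None:
                ops = new_ops
        if (k + 1) % stride == 0:
            t_rec[k_rec] = t
            v_rec[k_rec] = state.v
            ue_rec[k_rec] = state.ue
            k_rec += 1
    return {"t": t_rec[:k_rec], "v": v_rec[:k_rec], "ue": ue_rec[:k_rec],
            "state": state, "ops": ops}


# ---------------------------------------------------------------------------
# 1-D transmural cable (planar-wave surrogate of the wedge)
# ---------------------------------------------------------------------------

def wedge_cell_setup(mesh: WedgeMesh, hf: bool = False,
                     pace_kwargs: dict | None = None,
                     steady_states: dict | None = None):
    """Per-node parameter rows and 1-Hz steady-state initial rows.

    Each node is initialized from its cell type's single-cell steady
    state (NF or HF as requested).  ``steady_states`` may supply
    precomputed {cell_type: state-vector} entries to skip pacing.
    """
    pace_kwargs = pace_kwargs or {}
    types = mesh.node_types_named()
    rows = np.empty((mesh.n_nodes, cm.NPARAM))
    states = {}
    for ct in ("endo", "M", "epi"):
        p = cm.baseline_params(ct)
        if hf:
            p = cm.apply_hf_remodeling(p)
        arr = p.as_array()
        if steady_states is not None and ct in steady_states:
            y = np.asarray(steady_states[ct], float)
        else:
            st, _, _ = cm.pace_to_steady_state(p, **pace_kwargs)
            y = st.y
        states[ct] = (arr, y)
    init = np.empty((mesh.n_nodes, cm.NSTATE))
    for i, ct in enumerate(types):
        rows[i] = states[ct][0]
        init[i] = states[ct][1]
    return rows, init


def cable_params(n_nodes, n_elems, hf: bool = False,
                 fractions=(0.12, 0.60, 0.28), g_NaL=None):
    """Per-node parameter rows with transmural endo/M/epi layering."""
    n_endo, n_m, n_epi = layer_element_counts(n_elems, fractions)
    rows = np.empty((n_nodes, cm.NPARAM))
    types = []
    for i in range(n_nodes):
        if i <= n_endo:
            ct = "endo"
        elif i <= n_endo + n_m:
            ct = "M"
        else:
            ct = "epi"
        p = cm.baseline_params(ct) if g_NaL is None else \
            cm.baseline_params(ct, g_NaL=g_NaL)
        if hf:
            p = cm.apply_hf_remodeling(p)
        rows[i] = p.as_array()
        types.append(ct)
    return rows, types


def run_cable_1d(length: float, dx: float = 0.5,
                 cond: ConductivitySet | None = None,
                 protocol: StimulusProtocol | None = None,
                 T: float = 1000.0, dt: float = 0.05, hf: bool = False,
                 params_rows=None, initial_rows=None,
                 fractions=(0.12, 0.60, 0.28), chi: float = 2000.0,
                 cm_: float = 1.0, monodomain: bool = False,
                 solver: str = "direct", record_dt: float | None = None):
    """Bidomain cable along the transmural axis (fibers transverse, so
    propagation uses the cross-fiber conductivities).

    ``length`` and ``dx`` in mm; stimulus defaults to the endocardial
    end node.  Returns sampled t, v, u_e plus node positions/types.
    """
    ne = int(round(length / dx))
    if abs(ne * dx - length) > 1e-9:
        raise ValueError("length must be a multiple of dx")
    n = ne + 1
    cond = cond or ConductivitySet()
    if params_rows is None:
        params_rows, types = cable_params(n, ne, hf=hf, fractions=fractions)
    else:
        types = None
    if protocol is None:
        protocol = StimulusProtocol(nodes=np.array([0]))

    h = dx * MM_TO_CM
    si, se = cond.scale * cond.sigma_i_s, cond.scale * cond.sigma_e_s
    main = np.full(n, 2.0)
    main[0] = main[-1] = 1.0
    K1 = sp.diags([main, -np.ones(n - 1), -np.ones(n - 1)],
                  [0, -1, 1]) / h
    Mmain = np.full(n, 4.0)
    Mmain[0] = Mmain[-1] = 2.0
    M = sp.diags([Mmain, np.ones(n - 1), np.ones(n - 1)], [0, -1, 1]) * h / 6.0
    if monodomain:
        sm = si * se / (si + se)
        ops = BidomainOperators(M=M.tocsr(), Ki=(sm * K1).tocsr(),
                                Kie=(sm * K1).tocsr(), chi=chi, cm_=cm_,
                                dt=dt, monodomain=True, solver=solver)
    else:
        ops = BidomainOperators(M=M.tocsr(), Ki=(si * K1).tocsr(),
                                Kie=((si + se) * K1).tocsr(), chi=chi,
                                cm_=cm_, dt=dt, solver=solver)

    state = TissueState.resting(params_rows, initial_rows)
    n_steps = int(round(T / dt))
    stride = 1 if record_dt is None else max(1, int(round(record_dt / dt)))
    n_rec = n_steps // stride + 1
    t_rec = np.empty(n_rec)
    v_rec = np.empty((n_rec, n))
    ue_rec = np.empty((n_rec, n))
    t_rec[0], v_rec[0], ue_rec[0] = 0.0, state.v, state.ue
    k_rec = 1
    for k in range(n_steps):
        istim = protocol.current(k * dt, n)
        step_bidomain(state, params_rows, ops, dt, istim)
        if (k + 1) % stride == 0:
            t_rec[k_rec] = (k + 1) * dt
            v_rec[k_rec] = state.v
            ue_rec[k_rec] = state.ue
            k_rec += 1
    return {"t": t_rec[:k_rec], "v": v_rec[:k_rec], "ue": ue_rec[:k_rec],
            "x_mm": np.arange(n) * dx, "types": types, "state": state}
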