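"""Staggered electromechanical driver.

Electrophysiology advances with dt_ep; every dt_mech (1 ms) the nodal
normalized active force is interpolated to the Gauss points, the
quasistatic mechanics problem is re-solved from the previous
displacement, and the resulting deformation gradient is fed back into
the bidomain operators (conductivity pull-back and J-weighted mass),
which are then held until the next mechanics step.  With
``deformation_on=False`` mechanics is skipped entirely and F = I
throughout, giving the pure-electrophysiology arm of every
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from . import cell_models as cm
from . import mechanics as mech
from . import tissue_ep as te
from .wedge_setup import WedgeMesh, center_probe_nodes

__all__ = ["CouplingSchedule", "project_active_tension", "run_coupled"]


@dataclass
class CouplingSchedule:
    """Time-stepping layout of the coupled problem (ms)."""

    dt_ep: float = 0.05
    dt_mech: float = 1.0
    total_T: float = 1000.0

    def __post_init__(self):
        ratio = self.dt_mech / self.dt_ep
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("dt_mech must be an integer multiple of dt_ep")
        ratio2 = self.total_T / self.dt_mech
        if abs(ratio2 - round(ratio2)) > 1e-9:
            raise ValueError("total_T must be a multiple of dt_mech")

    @property
    def steps_per_mech(self):
        return int(round(self.dt_mech / self.dt_ep))


def project_active_tension(node_Ta, mesh: WedgeMesh, Ta_max: float = 1.0):
    """Trilinear interpolation of Ta_max*Ta to the 2x2x2 Gauss points.

    Returns an (n_elems, 8) array; linear nodal fields are reproduced
    exactly and every Gauss value is a convex combination of the
    element's nodal values.
    """
    node_Ta = np.asarray(node_Ta, float)
    N = np.array([Ns for (Ns, _) in te._SHAPE])  # (8 gauss, 8 nodes)
    return Ta_max * np.einsum("ga,ea->eg", N, node_Ta[mesh.elems])


class _QuasiStaticStepper:
    """Warm-started quasistatic solves by energy minimization.

    The active stress is conservative (potential (Ta_max Ta/2) ln I4f)
    so each mechanics step minimizes the total potential energy with
    L-BFGS, warm-started from the previous step.  Minimization remains
    robust where Newton stalls: the soft low-strain response of the
    exponential passive law puts the tissue near limit points of the
    load-controlled active-stress problem during twitch onset.
    """

    def __init__(self, mesh, params, Ta_max, bcs=None, tol=1e-5,
                 max_iter=60):
        self.mesh = mesh
        self.params = params
        self.Ta_max = Ta_max
        self.bcs = mech.default_bcs(mesh) if bcs is None else bcs
        self.B, self.detj = mech._grad_ops(mesh)
        fixed = mech._fixed_dofs(mesh, self.bcs)
        self.free = np.setdiff1d(np.arange(3 * mesh.n_nodes), fixed)
        self.u = np.zeros((mesh.n_nodes, 3))
        self.tol = tol
        self.max_iter = max_iter
        self._lu = None
        self._h_prev = np.zeros((mesh.n_nodes, 3))
        self._r_scale = max(Ta_max, 1.0) * self.detj

    def _residual(self, u, ta_gauss):
        R, _, _ = mech._assemble_residual(self.mesh, u, self.params,
                                          ta_gauss, self.B, self.detj)
        r = R.reshape(-1)[self.free]
        return r, np.linalg.norm(r) / self._r_scale

    def _refresh_tangent(self, ta_gauss):
        K = mech._assemble_tangent(self.mesh, self.u, self.params,
                                   ta_gauss, self.B, self.detj)
        A = mech._scatter_tangent(self.mesh, K)[
            np.ix_(self.free, self.free)]
        self._lu = spla.splu(A.tocsc())

    def _newton_phase(self, ta_gauss, max_iter=30, max_refresh=5):
        """Damped Newton with a frozen tangent that is refreshed on
        stall; returns the final relative residual norm."""
        fresh = False
        n_refresh = 0
        r, rn = self._residual(self.u, ta_gauss)
        for _ in range(max_iter):
            if rn < self.tol:
                return rn
            if self._lu is None:
                self._refresh_tangent(ta_gauss)
                fresh = True
                n_refresh += 1
            du = self._lu.solve(-r)
            improved = False
            alpha = 1.0
            for _ in range(10):
                unew = self.u.reshape(-1).copy()
                unew[self.free] += alpha * du
                unew = unew.reshape(-1, 3)
                try:
                    r_t, rn_t = self._residual(unew, ta_gauss)
                except FloatingPointError:
                    alpha *= 0.5
                    continue
                if rn_t < rn:
                    self.u, r, rn = unew, r_t, rn_t
                    improved = True
                    break
                alpha *= 0.5
            if improved:
                fresh = False
                continue
            if fresh or n_refresh >= max_refresh:
                return rn
            self._lu = None
        return rn

    def _minimize_phase(self, ta_gauss, maxiter=600):
        """L-BFGS on the total potential; globalizes across the limit
        points where Newton's basin of attraction vanishes."""
        from scipy.optimize import minimize

        n = self.mesh.n_nodes

        def fun(x):
            u = np.zeros(3 * n)
            u[self.free] = x
            u = u.reshape(n, 3)
            try:
                e = mech.total_potential_energy(
                    self.mesh, u, self.params, ta_gauss, self.B,
                    self.detj)
                r, _ = self._residual(u, ta_gauss)
            except FloatingPointError:
                return 1e30, np.zeros_like(x)
            return e, r

        res = minimize(fun, self.u.reshape(-1)[self.free], jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": maxiter, "gtol": 1e-12,
                                "ftol": 1e-13})
        u = np.zeros(3 * n)
        u[self.free] = res.x
        self.u = u.reshape(n, 3)
        self._lu = None

    def solve(self, node_Ta):
        node_Ta = np.asarray(node_Ta, float)
        ta_gauss = project_active_tension(node_Ta, self.mesh, self.Ta_max)
        rn = self._newton_phase(ta_gauss)
        if rn < self.tol:
            self._ta_prev = node_Ta
            return self.u
        # rescue 1: continuation in the active-tension change
        ta_old = getattr(self, "_ta_prev", np.zeros_like(node_Ta))
        for k in range(1, 5):
            frac = k / 4.0
            tg = project_active_tension(
                ta_old + frac * (node_Ta - ta_old), self.mesh,
                self.Ta_max)
            rn = self._newton_phase(tg)
        if rn >= self.tol:
            # rescue 2: energy minimization across the limit point
            self._minimize_phase(ta_gauss)
            rn = self._newton_phase(ta_gauss)
        self._ta_prev = node_Ta
        self.max_residual = max(getattr(self, "max_residual", 0.0), rn)
        if rn > 5e-2:
            raise RuntimeError(
                f"mechanics did not converge (residual {rn:.2e})")
        return self.u


def run_coupled(mesh: WedgeMesh, params_rows, cond: te.ConductivitySet,
                ho_params: mech.HOParams, schedule: CouplingSchedule,
                deformation_on: bool = True,
                protocol: te.StimulusProtocol | None = None,
                initial_rows=None, Ta_max: float = 50.0,
                chi: float = 2000.0, cm_: float = 1.0,
                record_dt: float = 0.5, solver: str = "direct"):
    """Run the wedge electromechanics for ``schedule.total_T`` ms.

    Returns a dict with sampled t / v / u_e histories, the probe node
    indices (endocardial and epicardial face centers), the wall
    thickening trace and the final states.  With
    ``deformation_on=False`` the call reduces exactly to the pure
    electrophysiology loop.
    """
    if protocol is None:
        protocol = te.StimulusProtocol(nodes=mesh.face_nodes["x0"])
    endo_probe, epi_probe = center_probe_nodes(mesh)

    thickening = []
    state_box = {}

    if deformation_on:
        stepper = _QuasiStaticStepper(mesh, ho_params, Ta_max)
        steps = schedule.steps_per_mech

        def hook(t, state, ops):
            k = int(round(t / schedule.dt_ep))
            if k % steps != 0:
                return None
            node_ta = np.array([cm._rice_force(
                params_rows[i][cm.PSL],
                state.cells[i, cm.IXXBPRER], state.cells[i, cm.IXXBPOSTR],
                state.cells[i, cm.IXBPRER], state.cells[i, cm.IXBPOSTR])
                for i in range(mesh.n_nodes)])
            u = stepper.solve(node_ta)
            x = mesh.nodes[:, 0] + u[:, 0]
            ref = mesh.nodes[:, 0].max()
            thickening.append((t, 100.0 * (x.max() - x.min() - ref) / ref))
            F = mech._deformation_gradients(mesh, u)
            ops_new = te.assemble_bidomain(
                mesh, cond, F_field=F, chi=chi, cm_=cm_,
                dt=schedule.dt_ep, solver=solver)
            state_box["u"] = u
            return ops_new
    else:
        hook = None

    out = te.run_wedge_ep(mesh, params_rows, cond, protocol,
                          T=schedule.total_T, dt=schedule.dt_ep,
                          initial_rows=initial_rows, record_dt=record_dt,
                          chi=chi, cm_=cm_, solver=solver, step_hook=hook)
    out["endo_probe"] = endo_probe
    out["epi_probe"] = epi_probe
    out["thickening"] = np.array(thickening) if thickening else \
        np.zeros((0, 2))
    out["u"] = state_box.get("u")
    return out
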