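"""Tests of the deformation-modified bidomain machinery."""

import numpy as np
import pytest
import scipy.sparse as sp

from emwedge import cell_models as cm
from emwedge import postprocess as pp
from emwedge import tissue_ep as te
from emwedge import wedge_setup as ws


def _assert_bi_mono_equivalent(bi, mono):
    """Same wavefront (ACT within the u_e staggering lag) and same
    final voltages once the upstroke has passed everywhere."""
    n = bi["v"].shape[1]
    act_b = [pp.activation_time(bi["t"], bi["v"][:, i]) for i in range(n)]
    act_m = [pp.activation_time(mono["t"], mono["v"][:, i])
             for i in range(n)]
    assert np.nanmax(np.abs(np.array(act_b) - np.array(act_m))) < 0.5
    assert np.max(np.abs(bi["v"][-1] - mono["v"][-1])) < 2.0


def small_mesh(n=2, dx=1.0):
    spec = ws.WedgeSpec(condition="nf", dx=dx, depth=n * dx,
                        width=n * dx, height=n * dx)
    return ws.build_wedge(spec)


class TestEffectiveConductivity:
    def test_identity_pullback(self):
        D = te.ConductivitySet().intra([0, 1, 0])
        assert np.allclose(te.effective_conductivity(D, np.eye(3)), D)

    def test_diagonal_stretch_algebra(self):
        lam = 1.3
        F = np.diag([lam, 1 / lam, 1.0])
        d = 2.0
        out = te.effective_conductivity(d * np.eye(3), F)
        # J = 1, so the pullback is diag(d/lam^2, d lam^2, d)
        assert np.allclose(out, np.diag([d / lam ** 2, d * lam ** 2, d]))

    def test_spd_preserved(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            F = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.1:
                continue
            A = rng.standard_normal((3, 3))
            D = A @ A.T + 0.5 * np.eye(3)
            out = te.effective_conductivity(D, F)
            assert np.all(np.linalg.eigvalsh((out + out.T) / 2) > 0)

    def test_singular_F_rejected(self):
        F = np.diag([1.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            te.effective_conductivity(np.eye(3), F)


class TestAssembly:
    def test_stiffness_annihilates_constants(self):
        mesh = small_mesh(3)
        K = te.assemble_stiffness(mesh, np.eye(3))
        v = np.full(mesh.n_nodes, 3.7)
        assert np.allclose(K @ v, 0.0, atol=1e-12)

    def test_mass_integrates_volume(self):
        mesh = small_mesh(3)
        M = te.assemble_mass(mesh)
        vol = float(np.ones(mesh.n_nodes) @ (M @ np.ones(mesh.n_nodes)))
        assert vol == pytest.approx((3 * te.MM_TO_CM) ** 3)

    def test_stiffness_scales_linearly_with_h(self):
        """3-D trilinear stiffness entries scale as the element size."""
        k1 = te.assemble_stiffness(small_mesh(2, dx=1.0), np.eye(3))
        k2 = te.assemble_stiffness(small_mesh(2, dx=0.5), np.eye(3))
        assert k1[0, 0] == pytest.approx(2 * k2[0, 0])

    def test_identity_F_matches_undeformed(self):
        mesh = small_mesh(2)
        cond = te.ConductivitySet()
        a = te.assemble_bidomain(mesh, cond)
        F = np.broadcast_to(np.eye(3), (mesh.n_elems, 8, 3, 3)).copy()
        b = te.assemble_bidomain(mesh, cond, F_field=F)
        assert np.allclose(a.Ki.toarray(), b.Ki.toarray())
        assert np.allclose(a.M.toarray(), b.M.toarray())

    def test_elliptic_compatibility(self):
        """No-flux stiffness has zero row sums, so the elliptic
        right-hand side -Ki v is orthogonal to constants."""
        mesh = small_mesh(3)
        cond = te.ConductivitySet()
        ops = te.assemble_bidomain(mesh, cond)
        rng = np.random.default_rng(0)
        v = rng.standard_normal(mesh.n_nodes)
        assert abs(np.sum(ops.Ki @ v)) < 1e-10


class TestStepping:
    def test_rest_is_preserved(self):
        mesh = small_mesh(2)
        rows, init = te.wedge_cell_setup(
            mesh, steady_states={c: cm.initial_state()
                                 for c in ("endo", "M", "epi")})
        ops = te.assemble_bidomain(mesh, te.ConductivitySet(), dt=0.05)
        state = te.TissueState.resting(rows, init)
        v0 = state.v.copy()
        for _ in range(20):
            te.step_bidomain(state, rows, ops, 0.05,
                             np.zeros(mesh.n_nodes))
        # the generic initial condition is not an exact equilibrium;
        # 1 ms of drift stays below a fraction of a millivolt
        assert np.allclose(state.v, v0, atol=0.3)

    def test_gauge_invariance(self):
        """Shifting u_e by a constant does not change the v update."""
        mesh = small_mesh(2)
        rows, init = te.wedge_cell_setup(
            mesh, steady_states={c: cm.initial_state()
                                 for c in ("endo", "M", "epi")})
        ops = te.assemble_bidomain(mesh, te.ConductivitySet(), dt=0.05)
        istim = np.zeros(mesh.n_nodes)
        istim[mesh.face_nodes["x0"]] = -80.0
        s1 = te.TissueState.resting(rows, init)
        s2 = te.TissueState.resting(rows, init.copy())
        s2.ue = s2.ue + 5.0
        te.step_bidomain(s1, rows, ops, 0.05, istim)
        te.step_bidomain(s2, rows, ops, 0.05, istim)
        assert np.allclose(s1.v, s2.v, atol=1e-9)

    def test_planar_stimulus_stays_planar(self):
        """Full-face stimulation of a cube keeps v a function of the
        transmural coordinate only."""
        mesh = small_mesh(4, dx=0.5)
        rows, init = te.wedge_cell_setup(
            mesh, steady_states={c: cm.initial_state()
                                 for c in ("endo", "M", "epi")})
        # uniform cells to isolate the geometry symmetry
        rows[:] = cm.baseline_params("M").as_array()
        protocol = te.StimulusProtocol(nodes=mesh.face_nodes["x0"])
        out = te.run_wedge_ep(mesh, rows, te.ConductivitySet(), protocol,
                              T=5.0, initial_rows=init)
        v = out["v"][-1]
        vr = v.max() - v.min()
        for xi in np.unique(mesh.nodes[:, 0]):
            sel = np.abs(mesh.nodes[:, 0] - xi) < 1e-9
            assert np.ptp(v[sel]) < 1e-6 * max(vr, 1.0)


class TestCable:
    def test_bidomain_matches_monodomain_for_proportional_tensors(self):
        """With D_e proportional to D_i the bidomain reduces to the
        monodomain with the harmonic-mean conductivity."""
        lam = 1.65
        cond = te.ConductivitySet(sigma_i_s=1.0, sigma_e_s=lam,
                                  sigma_i_f=3.0, sigma_e_f=3.0 * lam)
        rows, types = te.cable_params(13, 12)
        kw = dict(T=40.0, params_rows=rows,
                  protocol=te.StimulusProtocol(nodes=np.array([0, 1])))
        bi = te.run_cable_1d(6.0, 0.5, cond=cond, **kw)
        mono = te.run_cable_1d(6.0, 0.5, cond=cond, monodomain=True, **kw)
        _assert_bi_mono_equivalent(bi, mono)

    def test_conduction_scales_with_sqrt_conductivity(self, steady_states):
        """Scaling both conductivity tensors by 0.7 slows conduction
        by about sqrt(0.7) (same cells in both runs).  Measured over an
        interior interval on a fine grid (dx = 0.125 mm) where the
        discrete-wavefront slowdown of the coarse working grid does
        not distort the continuum scaling law."""
        dx = 0.125
        ne = int(round(9.0 / dx))
        rows = np.tile(steady_states[("M", False)]["params"].as_array(),
                       (ne + 1, 1))
        init = np.tile(steady_states[("M", False)]["state"].y,
                       (ne + 1, 1))
        span = {}
        for scale in (1.0, 0.7):
            res = te.run_cable_1d(9.0, dx,
                                  cond=te.ConductivitySet(scale=scale),
                                  T=60.0, params_rows=rows,
                                  initial_rows=init)
            a_lo = pp.activation_time(res["t"],
                                      res["v"][:, int(2.5 / dx)])
            a_hi = pp.activation_time(res["t"],
                                      res["v"][:, int(8.5 / dx)])
            assert np.isfinite(a_lo) and np.isfinite(a_hi)
            span[scale] = a_hi - a_lo
        ratio = span[1.0] / span[0.7]  # CV(0.7) / CV(1.0)
        assert np.sqrt(0.7) - 0.05 < ratio < np.sqrt(0.7) + 0.05

    def test_cable_agrees_with_3d_planar_wedge(self, steady_states):
        """A wedge with full-face stimulus is a planar problem: the
        3-D FEM solution along x matches the 1-D cable at every node
        (narrow cross-section used for speed; the lateral extent is
        irrelevant under no-flux conditions)."""
        length, T = 9.0, 450.0
        spec = ws.WedgeSpec(condition="nf", dx=0.5, depth=length,
                            width=1.0, height=1.0)
        mesh = ws.build_wedge(spec)
        rows3, init3 = te.wedge_cell_setup(
            mesh, steady_states={c: steady_states[(c, False)]["state"].y
                                 for c in ("endo", "M", "epi")})
        out3 = te.run_wedge_ep(
            mesh, rows3, te.ConductivitySet(),
            te.StimulusProtocol(nodes=mesh.face_nodes["x0"]), T=T,
            initial_rows=init3)
        ne = int(round(length / 0.5))
        rows1, types = te.cable_params(ne + 1, ne)
        init1 = np.array([steady_states[(t, False)]["state"].y
                          for t in types])
        out1 = te.run_cable_1d(length, 0.5, T=T, params_rows=rows1,
                               initial_rows=init1)
        # compare along the x axis at y=z=0
        sel = np.flatnonzero((mesh.nodes[:, 1] < 1e-9)
                             & (mesh.nodes[:, 2] < 1e-9))
        order = np.argsort(mesh.nodes[sel, 0])
        sel = sel[order]
        act3, rep3, _ = pp.per_node_metrics(out3["t"], out3["v"][:, sel])
        act1, rep1, _ = pp.per_node_metrics(out1["t"], out1["v"])
        assert np.max(np.abs(act3 - act1)) < 1.0
        assert np.max(np.abs(rep3 - rep1)) < 1.0

    def test_dt_convergence_of_apd(self, steady_states):
        """Halving dt changes the center-node APD by under 1 ms."""
        rows, types = te.cable_params(19, 18)
        init = np.array([steady_states[(t, False)]["state"].y
                         for t in types])
        apds = {}
        for dt in (0.05, 0.025):
            res = te.run_cable_1d(9.0, 0.5, T=500.0, dt=dt,
                                  params_rows=rows, initial_rows=init)
            apds[dt] = pp.apd(res["t"], res["v"][:, 9])
        assert abs(apds[0.05] - apds[0.025]) < 1.0

    def test_pcg_solver_agrees_with_direct(self):
        rows, types = te.cable_params(13, 12)
        kw = dict(T=20.0, params_rows=rows,
                  protocol=te.StimulusProtocol(nodes=np.array([0])))
        d = te.run_cable_1d(6.0, 0.5, solver="direct", **kw)
        k = te.run_cable_1d(6.0, 0.5, solver="pcg", **kw)
        assert np.max(np.abs(d["v"] - k["v"])) < 1e-3
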