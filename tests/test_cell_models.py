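"""Unit and property tests of the coupled myocyte model."""

import math
from dataclasses import replace

import numpy as np
import pytest

from emwedge import cell_models as cm

from conftest import CELL_TYPES


class TestLateSodium:
    def test_rates_at_singularity(self):
        rs = cm.late_sodium_rates(-47.13)
        assert rs.alpha_mL == pytest.approx(3.2, rel=1e-6)
        # continuity across the removable singularity
        lo = cm.late_sodium_rates(-47.13 - 1e-5).alpha_mL
        hi = cm.late_sodium_rates(-47.13 + 1e-5).alpha_mL
        assert lo == pytest.approx(3.2, rel=1e-4)
        assert hi == pytest.approx(3.2, rel=1e-4)

    def test_rate_values(self):
        assert cm.late_sodium_rates(0.0).beta_mL == pytest.approx(0.08)
        assert cm.late_sodium_rates(-91.0).hL_inf == pytest.approx(0.5)
        assert cm.late_sodium_rates(10.0).tau_hL == 233.0

    @pytest.mark.parametrize("v", np.linspace(-120, 60, 19))
    def test_rates_well_formed(self, v):
        rs = cm.late_sodium_rates(float(v))
        assert rs.alpha_mL >= 0 and rs.beta_mL >= 0
        assert 0 < rs.hL_inf < 1

    def test_current_zero_conductance(self):
        state = cm.CellState()
        p = cm.baseline_params("epi", g_NaL=0.0)
        assert cm.late_sodium_current(state, p) == 0.0

    def test_current_at_reversal(self):
        state = cm.CellState()
        p = cm.baseline_params("epi", g_NaL=0.01)
        state.m_L, state.h_L = 0.7, 0.5
        state.v = p.e_na(state.Na_i)
        assert cm.late_sodium_current(state, p) == pytest.approx(0.0)

    def test_current_unit_gate_algebra(self):
        state = cm.CellState()
        p = cm.baseline_params("epi", g_NaL=0.01)
        state.m_L, state.h_L = 1.0, 1.0
        state.v = p.e_na(state.Na_i) + 100.0
        assert cm.late_sodium_current(state, p) == pytest.approx(1.0)


class TestTotalCurrent:
    def test_sum_of_thirteen(self):
        state = cm.CellState()
        p = cm.baseline_params("M")
        cur = cm.ionic_currents(state, p)
        assert cur.shape == (13,)
        assert cm.total_ionic_current(state, p) == pytest.approx(cur.sum())

    def test_reduces_to_baseline_without_late_na(self):
        state = cm.CellState()
        with_nal = cm.apply_hf_remodeling(cm.baseline_params("epi"))
        without = replace(with_nal, g_NaL=0.0)
        diff = cm.total_ionic_current(state, with_nal) \
            - cm.total_ionic_current(state, without)
        assert diff == pytest.approx(
            cm.late_sodium_current(state, with_nal))

    def test_resting_net_current_small(self, steady_states):
        """At end-diastole of the paced steady state the membrane
        currents nearly balance."""
        for ct in CELL_TYPES:
            entry = steady_states[(ct, False)]
            i_ion = cm.total_ionic_current(entry["state"], entry["params"])
            assert abs(i_ion) < 0.05  # pA/pF


class TestHFRemodeling:
    def test_homogeneous_scalings(self):
        p = cm.baseline_params("epi")
        hf = cm.apply_hf_remodeling(p)
        assert hf.g_K1 == pytest.approx(5.405 * 0.67)
        assert hf.g_K1 == pytest.approx(3.621, abs=5e-4)
        assert hf.P_NaK == pytest.approx(p.P_NaK * 0.90)
        assert hf.g_bCa == pytest.approx(p.g_bCa * 2.53)
        assert hf.V_leak == pytest.approx(p.V_leak * 6.0)

    def test_late_na_activated(self):
        hf = cm.apply_hf_remodeling(cm.baseline_params("M"))
        assert hf.g_NaL == pytest.approx(3.0 * cm.G_NAL_REF)

    @pytest.mark.parametrize("ct,vmax_f,gcal_f,gto_f,knaca_f", [
        ("epi", 0.70, 1.00, 0.30, 3.00),
        ("M", 0.60, 0.80, 0.30, 2.65),
        ("endo", 0.55, 0.65, 1.00, 2.65),
    ])
    def test_heterogeneous_scalings(self, ct, vmax_f, gcal_f, gto_f,
                                    knaca_f):
        p = cm.baseline_params(ct)
        hf = cm.apply_hf_remodeling(p)
        assert hf.V_maxup == pytest.approx(p.V_maxup * vmax_f)
        assert hf.g_CaL == pytest.approx(p.g_CaL * gcal_f)
        assert hf.g_to == pytest.approx(p.g_to * gto_f)
        assert hf.K_NaCa == pytest.approx(p.K_NaCa * knaca_f)

    def test_double_application_rejected(self):
        hf = cm.apply_hf_remodeling(cm.baseline_params("epi"))
        with pytest.raises(ValueError):
            cm.apply_hf_remodeling(hf)

    def test_conductances_stay_nonnegative(self):
        for ct in CELL_TYPES:
            hf = cm.apply_hf_remodeling(cm.baseline_params(ct))
            for name in ("g_K1", "g_to", "g_CaL", "K_NaCa", "V_maxup",
                         "V_leak", "g_NaL"):
                assert getattr(hf, name) >= 0


class TestRushLarsen:
    def test_gate_exponential_relaxation(self):
        """With frozen rates the gate update is the exact exponential
        g_inf + (g0 - g_inf) exp(-dt/tau), so composing two half steps
        equals one full step to machine precision."""
        g0, ginf, tau = 0.2, 0.9, 12.0
        for dt in (0.05, 1.0, 50.0):
            one = cm._rl_gate(g0, ginf, tau, dt)
            two = cm._rl_gate(cm._rl_gate(g0, ginf, tau, dt / 2),
                              ginf, tau, dt / 2)
            exact = ginf + (g0 - ginf) * math.exp(-dt / tau)
            assert one == pytest.approx(exact, rel=1e-14)
            assert two == pytest.approx(exact, rel=1e-14)

    def test_small_dt_limit(self):
        state = cm.CellState()
        p = cm.baseline_params("epi")
        out = cm.step_rush_larsen(state, p, dt=1e-6)
        assert np.allclose(out.y, state.y, atol=1e-5)

    def test_step_halving_consistency(self):
        p = cm.baseline_params("M")
        y1 = cm.initial_state()
        y2 = cm.initial_state()
        for _ in range(200):
            y1 = cm.step_rush_larsen(y1, p, 0.05, I_stim=-52.0)
        for _ in range(400):
            y2 = cm.step_rush_larsen(y2, p, 0.025, I_stim=-52.0)
        # first-order splitting: voltages agree to the step-size error
        assert abs(y1[cm.IV] - y2[cm.IV]) < 2.0

    def test_nonfinite_state_named(self):
        y = cm.initial_state()
        y[cm.ICA_I] = np.nan
        with pytest.raises(FloatingPointError, match="Ca_i"):
            cm.step_rush_larsen(y, cm.baseline_params("epi"), 0.05)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            cm.step_rush_larsen(cm.CellState(), cm.baseline_params("epi"),
                                0.0)


class TestPacedPhenotypes:
    def test_gates_bounded(self, steady_states):
        hh_gates = [cm.IM, cm.IH, cm.IJ, cm.IXR1, cm.IXR2, cm.IXS,
                    cm.IR, cm.IS, cm.ID, cm.IF, cm.IML, cm.IHL]
        for key, entry in steady_states.items():
            y = entry["state"].y
            assert np.all(y[hh_gates] >= 0.0) and np.all(y[hh_gates] <= 1.0)
            # the calcium-dependent fCa / g gates may slightly exceed
            # one at diastolic calcium (their steady-state curves are
            # defined that way in the cited formulation)
            assert 0.0 <= y[cm.IFCA] <= 1.05 and 0.0 <= y[cm.IGREL] <= 1.05
            # concentrations positive
            for idx in (cm.INA_I, cm.IK_I, cm.ICA_I, cm.ICA_SR):
                assert y[idx] > 0

    def test_nf_matches_cited_baseline(self, steady_states):
        """Without late sodium current, the nonfailing cells reproduce
        the published single-cell values of the cited human
        ventricular model (resting potential, Na+, APD ordering)."""
        published_apd = {"epi": 276.0, "endo": 282.0, "M": 336.0}
        for ct in CELL_TYPES:
            info = steady_states[(ct, False)]["info"]
            y = steady_states[(ct, False)]["state"].y
            assert info["v_rest"] == pytest.approx(-86.2, abs=1.5)
            assert abs(info["apd"] - published_apd[ct]) \
                / published_apd[ct] < 0.08
            assert y[cm.INA_I] == pytest.approx(11.6, abs=2.0)
            assert 0.5e-3 < info["ca_peak"] < 1.5e-3   # ~1 uM systolic

    def test_nf_apd_ordering(self, steady_states):
        apd = {ct: steady_states[(ct, False)]["info"]["apd"]
               for ct in CELL_TYPES}
        assert apd["epi"] < apd["endo"] < apd["M"]

    def test_hf_apd_ordering_flips(self, steady_states):
        apd = {ct: steady_states[(ct, True)]["info"]["apd"]
               for ct in CELL_TYPES}
        assert apd["endo"] < apd["epi"]

    def test_hf_calcium_phenotype(self, steady_states):
        """HF reduces the calcium peak and slows the transient decay
        in every cell type, and raises diastolic calcium on average
        (the endocardial diastolic level lags the rise at the working
        steady-state tolerance)."""
        dia_nf, dia_hf = [], []
        for ct in CELL_TYPES:
            nf = steady_states[(ct, False)]
            hf = steady_states[(ct, True)]
            assert hf["info"]["ca_peak"] < nf["info"]["ca_peak"]
            assert _decay_time(nf) < _decay_time(hf)
            dia_nf.append(nf["info"]["ca_diastolic"])
            dia_hf.append(hf["info"]["ca_diastolic"])
        assert np.mean(dia_hf) > np.mean(dia_nf)

    def test_hf_force_phenotype(self, steady_states):
        """HF reduces the active-force peak and prolongs its duration."""
        for ct in CELL_TYPES:
            nf = steady_states[(ct, False)]
            hf = steady_states[(ct, True)]
            assert hf["info"]["ta_peak"] < nf["info"]["ta_peak"]
            assert _duration50(hf) > _duration50(nf)


def _decay_time(entry):
    """Time for Ca_i to fall from peak to halfway toward diastole."""
    ca = entry["traces"]["Ca_i_mM"]
    k = int(np.argmax(ca))
    half = 0.5 * (ca[k] + ca.min())
    below = np.flatnonzero(ca[k:] <= half)
    return below[0] * 0.05 if below.size else np.inf


def _duration50(entry):
    ta = entry["traces"]["Ta_norm"]
    return float((ta > 0.5 * ta.max()).sum()) * 0.05
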