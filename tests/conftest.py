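"""Shared fixtures: expensive simulations are session-scoped so the
pacing runs, cable runs and quasistatic solves are computed once."""

import warnings

import numpy as np
import pytest

from emwedge import cell_models as cm
from emwedge import mechanics as mech
from emwedge import postprocess as pp
from emwedge import tissue_ep as te
from emwedge import wedge_setup as ws

CELL_TYPES = ("endo", "M", "epi")


@pytest.fixture(scope="session")
def steady_states():
    """1-Hz steady states for all cell types, NF and HF."""
    out = {}
    for hf in (False, True):
        for ct in CELL_TYPES:
            p = cm.baseline_params(ct)
            if hf:
                p = cm.apply_hf_remodeling(p)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                state, traces, info = cm.pace_to_steady_state(p)
            out[(ct, hf)] = {"params": p, "state": state,
                             "traces": traces, "info": info}
    return out


def _cable_run(steady_states, hf, length, T):
    ne = int(round(length / 0.5))
    rows, types = te.cable_params(ne + 1, ne, hf=hf)
    init = np.array([steady_states[(t, hf)]["state"].y for t in types])
    cond = te.ConductivitySet(scale=0.7 if hf else 1.0)
    res = te.run_cable_1d(length, 0.5, cond=cond, T=T,
                          params_rows=rows, initial_rows=init)
    act, rep, apd = pp.per_node_metrics(res["t"], res["v"])
    res.update(act=act, rep=rep, apd=apd)
    return res


@pytest.fixture(scope="session")
def nf_cable(steady_states):
    """Normal 9 mm transmural cable, Table-3 parameters."""
    return _cable_run(steady_states, hf=False, length=9.0, T=600.0)


@pytest.fixture(scope="session")
def hf_cable(steady_states):
    """Failing 13 mm cable, conductivities x0.7."""
    return _cable_run(steady_states, hf=True, length=13.0, T=700.0)


@pytest.fixture(scope="session")
def coupled_morphology(steady_states):
    """Coupled runs (deformation on/off) for all three conditions on
    thin-cross-section wedges.

    With full-face stimulus, no-flux lateral boundaries and x-only
    mechanics modes, the planar solution does not depend on the
    lateral extent, so a 1 mm cross-section reproduces the full
    wedge's transmural electrophysiology and thickening at dx = 0.5.
    """
    from emwedge import coupling as cp

    out = {}
    for cond_name, depth, scale, hf, T in (
            ("nf", 9.0, 1.0, False, 500.0),
            ("hf", 13.0, 5.0, True, 650.0),
            ("hf_case2", 13.0, 1.0, True, 650.0)):
        spec = ws.WedgeSpec(condition="nf" if cond_name == "nf" else "hf",
                            dx=0.5, depth=depth, width=1.0, height=1.0)
        mesh = ws.build_wedge(spec)
        rows, init = te.wedge_cell_setup(
            mesh, steady_states={c: steady_states[(c, hf)]["state"].y
                                 for c in CELL_TYPES})
        cond = te.ConductivitySet(scale=0.7 if hf else 1.0)
        ho = mech.HOParams(stiffness_scale=scale)
        sched = __import__("emwedge").coupling.CouplingSchedule(total_T=T)
        for defo in (False, True):
            res = cp.run_coupled(mesh, rows, cond, ho, sched,
                                 deformation_on=defo, initial_rows=init,
                                 record_dt=0.5)
            act, rep, apd = pp.per_node_metrics(res["t"], res["v"])
            eg = pp.transmural_electrogram(res["ue"], res["epi_probe"],
                                           res["endo_probe"])
            twave = pp.twave_peak(res["t"], eg,
                                  t_start=float(np.nanmax(act)) + 50.0)
            out[(cond_name, defo)] = {
                "act": act, "rep": rep, "apd": apd, "twave": twave,
                "thickening": res["thickening"]}
    return out


@pytest.fixture(scope="session")
def thickening(steady_states):
    """Quasistatic peak-tension wall-thickening solves, all conditions."""
    out = {}
    for cond_name, depth, scale, hf in (("nf", 9.0, 1.0, False),
                                        ("hf", 13.0, 5.0, True),
                                        ("hf_case2", 13.0, 1.0, True)):
        spec = ws.WedgeSpec(condition="nf" if cond_name == "nf" else "hf",
                            dx=1.0, depth=depth)
        mesh = ws.build_wedge(spec)
        Ta = np.array([steady_states[(t, hf)]["info"]["ta_peak"]
                       for t in mesh.node_types_named()])
        params = mech.HOParams(stiffness_scale=scale)
        state = mech.solve_equilibrium(mesh, params, active_field=Ta)
        out[cond_name] = {"mesh": mesh, "state": state,
                          "percent": mech.wall_thickening(state, mesh)}
    return out
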