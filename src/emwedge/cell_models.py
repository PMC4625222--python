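"""Coupled electromechanical human ventricular myocyte model.

Electrophysiology follows the ten Tusscher, Noble, Noble & Panfilov
(2004) human ventricular model (endo / M / epi variants), extended
with a Hodgkin-Huxley late sodium current I_NaL.  Active force is
produced by the Rice et al. (2008) myofilament model driven one-way
by the intracellular calcium transient (isosarcometric by default).
Heart failure is modelled by multiplicative remodeling of
conductances and fluxes, applied homogeneously (all cell types) and
heterogeneously (per cell type).

Units follow the single-cell convention throughout: mV, ms, mM,
pA/pF.  The Rice rate constants are expressed in ms^-1 at 37 degC and
calcium is passed to the myofilament model in uM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "CellParams",
    "CellState",
    "RateSet",
    "baseline_params",
    "apply_hf_remodeling",
    "late_sodium_rates",
    "late_sodium_current",
    "total_ionic_current",
    "ionic_currents",
    "active_force",
    "step_rush_larsen",
    "pace_to_steady_state",
    "initial_state",
    "NSTATE",
    "STATE_NAMES",
]

# ---------------------------------------------------------------------------
# physical constants and fixed model parameters (TNNP convention)
# ---------------------------------------------------------------------------

R_GAS = 8314.472       # mJ/(mol K)
FARADAY = 96485.3415   # C/mol
TEMP = 310.0           # K
RTONF = R_GAS * TEMP / FARADAY  # ~26.71 mV

KO = 5.4     # mM
NAO = 140.0  # mM
CAO = 2.0    # mM

VC = 0.016404
VSR = 0.001094
CAPACITANCE = 0.185

BUFC, KBUFC = 0.15, 0.001
BUFSR, KBUFSR = 10.0, 0.3

KUP = 0.00025
A_REL, B_REL, C_REL = 0.016464, 0.25, 0.008232  # mM/ms, mM, mM/ms
TAU_G = 2.0    # ms
TAU_FCA = 2.0  # ms

PKNA = 0.03
KMK, KMNA = 1.0, 40.0
KMNAI, KMCA, KSAT, GAMMA, ALPHA_NACA = 87.5, 1.38, 0.1, 0.35, 2.5
KPCA = 0.0005

INV_VC_F = 1.0 / (VC * FARADAY)
INV_VC_F2 = 1.0 / (2.0 * VC * FARADAY)

# Rice (2008) myofilament constants, ms^-1 / uM at 37 degC
SL_DEFAULT = 2.2       # um, isosarcometric sarcomere length
LEN_THICK = 1.65       # um
LEN_HBARE = 0.1        # um
LEN_THIN = 1.2         # um
X0 = 0.007             # um, mean post-rotation strain
KON = 0.05             # 1/(uM ms)
KOFF_L = 0.25          # 1/ms
KOFF_H = 0.025         # 1/ms
PERM50 = 0.5
NPERM = 15.0
KNP = 0.5              # 1/ms (nonpermissive -> permissive)
KPN = 0.05             # 1/ms
XBMOD = 0.2            # species modifier slowing crossbridge cycling
FAPP = 0.5 * XBMOD     # 1/ms
GAPP = 0.07 * XBMOD    # 1/ms
HF_XB = 2.0 * XBMOD    # 1/ms
HB_XB = 0.4 * XBMOD    # 1/ms
GXB = 0.07 * XBMOD     # 1/ms
GSLMOD = 6.0
HFMDC = 5.0
SIGMAP = 8.0
SIGMAN = 1.0
XPSI = 2.0

TAU_HL = 233.0  # ms, late-Na inactivation time constant


def _rice_duty_fractions():
    den = (FAPP * HF_XB + GXB * HF_XB + GXB * GAPP
           + HB_XB * FAPP + HB_XB * GAPP + GXB * FAPP)
    ss_prer = (HB_XB * FAPP + GXB * FAPP) / den
    ss_postr = FAPP * HF_XB / den
    return ss_prer, ss_postr


SS_XBPRER, SS_XBPOSTR = _rice_duty_fractions()

# ---------------------------------------------------------------------------
# state vector layout
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "v", "Na_i", "K_i", "Ca_i", "Ca_sr",
    "m", "h", "j", "xr1", "xr2", "xs", "r", "s",
    "d", "f", "fCa", "g_rel", "m_L", "h_L",
    "N", "XBprer", "XBpostr", "xXBprer", "xXBpostr", "TRPNCaL", "TRPNCaH",
)
NSTATE = len(STATE_NAMES)
_IDX = {n: i for i, n in enumerate(STATE_NAMES)}

IV, INA_I, IK_I, ICA_I, ICA_SR = range(5)
IM, IH, IJ, IXR1, IXR2, IXS, IR, IS = range(5, 13)
ID, IF, IFCA, IGREL, IML, IHL = range(13, 19)
IN_RICE, IXBPRER, IXBPOSTR, IXXBPRER, IXXBPOSTR, ITRPNL, ITRPNH = range(19, 26)

# parameter vector layout
NPARAM = 17
(PG_NA, PG_K1, PG_TO, PG_KR, PG_KS, PG_CAL, PK_NACA, PP_NAK, PG_PCA,
 PG_PK, PG_BCA, PG_BNA, PV_MAXUP, PV_LEAK, PG_NAL, PIS_ENDO, PSL) = range(NPARAM)

# Reference late-Na conductance (nS/pF) of the I_NaL formulation; the
# nonfailing cell carries no late sodium current (the current is added
# as part of the heart-failure remodeling) and the HF cell uses
# 3 x G_NAL_REF.  See docs/methods.md for the calibration rationale.
G_NAL_REF = 0.03

_BASE = {
    "g_Na": 14.838,
    "g_K1": 5.405,
    "g_Kr": 0.096,
    "g_CaL": 0.000175,
    "K_NaCa": 1000.0,
    "P_NaK": 1.362,
    "g_pCa": 0.825,
    "g_pK": 0.0146,
    "g_bCa": 0.000592,
    "g_bNa": 0.00029,
    "V_maxup": 0.000425,
    "V_leak": 0.00008,
}
_G_TO = {"epi": 0.294, "M": 0.294, "endo": 0.073}
_G_KS = {"epi": 0.245, "M": 0.062, "endo": 0.245}

# heart-failure remodeling factors (down x% -> 1-x/100, up x% -> 1+x/100)
_HF_HOMOGENEOUS = {
    "g_K1": 0.67,
    "P_NaK": 0.90,
    "g_bCa": 2.53,
    "V_leak": 6.00,
    "g_NaL": 3.00,
}
_HF_HETEROGENEOUS = {
    "V_maxup": {"epi": 0.70, "M": 0.60, "endo": 0.55},
    "K_NaCa": {"epi": 3.00, "M": 2.65, "endo": 2.65},
    "g_CaL": {"epi": 1.00, "M": 0.80, "endo": 0.65},
    "g_to": {"epi": 0.30, "M": 0.30, "endo": 1.00},
}


# ---------------------------------------------------------------------------
# parameter / state containers
# ---------------------------------------------------------------------------

@dataclass
class CellParams:
    """Conductance set for one myocyte.

    All conductances in the TNNP unit convention (nS/pF or the
    original flux units); ``Ta_max`` is the tissue-level active stress
    scale in kPa and is carried here for convenience.
    """

    cell_type: str
    g_Na: float
    g_K1: float
    g_to: float
    g_Kr: float
    g_Ks: float
    g_CaL: float
    K_NaCa: float
    P_NaK: float
    g_pCa: float
    g_pK: float
    g_bCa: float
    g_bNa: float
    V_maxup: float
    V_leak: float
    g_NaL: float
    Ta_max: float = 50.0
    sarcomere_length: float = SL_DEFAULT
    hf_flag: bool = False

    def __post_init__(self):
        if self.cell_type not in ("endo", "M", "epi"):
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        for name in ("g_Na", "g_K1", "g_to", "g_Kr", "g_Ks", "g_CaL",
                     "K_NaCa", "P_NaK", "g_pCa", "g_pK", "g_bCa", "g_bNa",
                     "V_maxup", "V_leak", "g_NaL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        p = np.empty(NPARAM)
        p[PG_NA] = self.g_Na
        p[PG_K1] = self.g_K1
        p[PG_TO] = self.g_to
        p[PG_KR] = self.g_Kr
        p[PG_KS] = self.g_Ks
        p[PG_CAL] = self.g_CaL
        p[PK_NACA] = self.K_NaCa
        p[PP_NAK] = self.P_NaK
        p[PG_PCA] = self.g_pCa
        p[PG_PK] = self.g_pK
        p[PG_BCA] = self.g_bCa
        p[PG_BNA] = self.g_bNa
        p[PV_MAXUP] = self.V_maxup
        p[PV_LEAK] = self.V_leak
        p[PG_NAL] = self.g_NaL
        p[PIS_ENDO] = 1.0 if self.cell_type == "endo" else 0.0
        p[PSL] = self.sarcomere_length
        return p

    def e_na(self, Na_i: float) -> float:
        """Sodium reversal potential (mV) from the Nernst relation."""
        return RTONF * math.log(NAO / Na_i)


def baseline_params(cell_type: str, *, g_NaL: float | None = None,
                    Ta_max: float = 50.0) -> CellParams:
    """Nonfailing parameter set for ``cell_type`` in {endo, M, epi}."""
    if cell_type not in ("endo", "M", "epi"):
        raise ValueError(f"unknown cell type {cell_type!r}")
    return CellParams(
        cell_type=cell_type,
        g_to=_G_TO[cell_type],
        g_Ks=_G_KS[cell_type],
        g_NaL=0.0 if g_NaL is None else g_NaL,
        Ta_max=Ta_max,
        **_BASE,
    )


def apply_hf_remodeling(params: CellParams) -> CellParams:
    """Return a heart-failure remodelled copy of ``params``.

    Homogeneous scalings (same for every cell type) and heterogeneous
    scalings (selected by cell type) are multiplicative.  Double
    application is refused so remodeling stays idempotent.
    """
    if params.hf_flag:
        raise ValueError("heart-failure remodeling already applied")
    changes = {k: getattr(params, k) * f for k, f in _HF_HOMOGENEOUS.items()}
    # the late-Na scaling acts on the formulation's reference
    # conductance when the nonfailing cell carries no I_NaL
    if params.g_NaL == 0.0:
        changes["g_NaL"] = _HF_HOMOGENEOUS["g_NaL"] * G_NAL_REF
    for name, per_type in _HF_HETEROGENEOUS.items():
        base = changes.get(name, getattr(params, name))
        changes[name] = base * per_type[params.cell_type]
    return replace(params, hf_flag=True, **changes)


@dataclass
class RateSet:
    """Late-sodium gate kinetics at a fixed voltage."""
    alpha_mL: float
    beta_mL: float
    hL_inf: float
    tau_hL: float = TAU_HL


@dataclass
class CellState:
    """Named view over the raw state vector of one myocyte."""

    y: np.ndarray = field(default_factory=lambda: initial_state())

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (NSTATE,):
            raise ValueError(f"state vector must have length {NSTATE}")

    def __getattr__(self, name):
        idx = _IDX.get(name)
        if idx is None:
            raise AttributeError(name)
        return self.y[idx]

    def __setattr__(self, name, value):
        if name == "y":
            object.__setattr__(self, name, value)
        else:
            idx = _IDX.get(name)
            if idx is None:
                object.__setattr__(self, name, value)
            else:
                self.y[idx] = value

    @property
    def T_a(self) -> float:
        return active_force(self)


def initial_state(sarcomere_length: float = SL_DEFAULT) -> np.ndarray:
    """Resting-state initial conditions (washed out by pacing)."""
    y = np.zeros(NSTATE)
    y[IV] = -86.2
    y[INA_I] = 11.6
    y[IK_I] = 138.3
    y[ICA_I] = 0.0002
    y[ICA_SR] = 0.2
    y[IM] = 0.0
    y[IH] = 0.75
    y[IJ] = 0.75
    y[IXR1] = 0.0
    y[IXR2] = 1.0
    y[IXS] = 0.0
    y[IR] = 0.0
    y[IS] = 1.0
    y[ID] = 0.0
    y[IF] = 1.0
    y[IFCA] = 1.0
    y[IGREL] = 1.0
    y[IML] = 0.0
    y[IHL] = 0.3
    y[IN_RICE] = 0.97
    y[IXBPRER] = 1e-6
    y[IXBPOSTR] = 1e-6
    y[IXXBPRER] = 0.0
    y[IXXBPOSTR] = X0
    y[ITRPNL] = 0.015
    y[ITRPNH] = 0.13
    return y


# ---------------------------------------------------------------------------
# late sodium current (python-level API; the kernel repeats the algebra)
# ---------------------------------------------------------------------------

def late_sodium_rates(v: float) -> RateSet:
    """m_L/h_L kinetics of the late sodium current.

    The activation alpha rate has a removable singularity at
    v = -47.13 mV, handled by its analytic limit 3.2 ms^-1.
    """
    x = v + 47.13
    if abs(x) < 1e-6:
        alpha = 3.2
    else:
        alpha = 0.32 * x / (1.0 - math.exp(-0.1 * x))
    beta = 0.08 * math.exp(-v / 11.0)
    hl_inf = 1.0 / (1.0 + math.exp((v + 91.0) / 6.1))
    return RateSet(alpha_mL=alpha, beta_mL=beta, hL_inf=hl_inf)


def _state_array(state) -> np.ndarray:
    return state.y if isinstance(state, CellState) else np.asarray(state, float)


def late_sodium_current(state, params: CellParams) -> float:
    """I_NaL = g_NaL m_L^3 h_L (v - E_Na), in pA/pF."""
    y = _state_array(state)
    e_na = RTONF * math.log(NAO / y[INA_I])
    return params.g_NaL * y[IML] ** 3 * y[IHL] * (y[IV] - e_na)


def total_ionic_current(state, params: CellParams) -> float:
    """Sum of the 13 membrane currents (pA/pF, outward positive)."""
    return float(np.sum(ionic_currents(state, params)))


def ionic_currents(state, params: CellParams) -> np.ndarray:
    """The 13 individual membrane currents, ordered as
    [INa, INaL, IK1, Ito, IKr, IKs, ICaL, INaCa, INaK, IpCa, IpK, IbCa, IbNa].
    """
    y = _state_array(state)
    out = np.empty(13)
    _currents_kernel(y, params.as_array(), out)
    return out


def active_force(state) -> float:
    """Normalized active force T_a (dimensionless, >= 0)."""
    y = _state_array(state)
    return _rice_force(SL_DEFAULT, y[IXXBPRER], y[IXXBPOSTR],
                       y[IXBPRER], y[IXBPOSTR])


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rice_force(sl, xprer, xpostr, prer, postr):
    sovr_ze = min(LEN_THICK / 2.0, sl / 2.0)
    sovr_cle = max(sl / 2.0 - (sl - LEN_THIN), LEN_HBARE / 2.0)
    len_sovr = sovr_ze - sovr_cle
    sovf_thick = len_sovr * 2.0 / (LEN_THICK - LEN_HBARE)
    force = sovf_thick * (xpostr * postr + xprer * prer)
    ta = force / (X0 * SS_XBPOSTR)
    return ta if ta > 0.0 else 0.0


@njit(cache=True)
def _currents_kernel(y, p, out):
    v = y[IV]
    nai = y[INA_I]
    ki = y[IK_I]
    cai = y[ICA_I]

    ek = RTONF * math.log(KO / ki)
    ena = RTONF * math.log(NAO / nai)
    eks = RTONF * math.log((KO + PKNA * NAO) / (ki + PKNA * nai))
    eca = 0.5 * RTONF * math.log(CAO / cai)

    ina = p[PG_NA] * y[IM] ** 3 * y[IH] * y[IJ] * (v - ena)
    inal = p[PG_NAL] * y[IML] ** 3 * y[IHL] * (v - ena)

    ak1 = 0.1 / (1.0 + math.exp(0.06 * (v - ek - 200.0)))
    bk1 = (3.0 * math.exp(0.0002 * (v - ek + 100.0))
           + math.exp(0.1 * (v - ek - 10.0))) / (1.0 + math.exp(-0.5 * (v - ek)))
    ik1 = p[PG_K1] * ak1 / (ak1 + bk1) * (v - ek)

    ito = p[PG_TO] * y[IR] * y[IS] * (v - ek)
    ikr = p[PG_KR] * math.sqrt(KO / 5.4) * y[IXR1] * y[IXR2] * (v - ek)
    iks = p[PG_KS] * y[IXS] * y[IXS] * (v - eks)

    vv = v
    if abs(vv) < 1e-6:
        vv = 1e-6
    ex = math.exp(2.0 * vv / RTONF)
    ical = (p[PG_CAL] * y[ID] * y[IF] * y[IFCA]
            * 4.0 * vv * (FARADAY / RTONF)
            * (cai * ex - 0.341 * CAO) / (ex - 1.0))

    expg = math.exp(GAMMA * v / RTONF)
    expg1 = math.exp((GAMMA - 1.0) * v / RTONF)
    inaca = (p[PK_NACA]
             * (expg * nai ** 3 * CAO - expg1 * NAO ** 3 * cai * ALPHA_NACA)
             / ((KMNAI ** 3 + NAO ** 3) * (KMCA + CAO)
                * (1.0 + KSAT * expg1)))

    inak = (p[PP_NAK] * KO / (KO + KMK) * nai / (nai + KMNA)
            / (1.0 + 0.1245 * math.exp(-0.1 * v / RTONF)
               + 0.0353 * math.exp(-v / RTONF)))

    ipca = p[PG_PCA] * cai / (KPCA + cai)
    ipk = p[PG_PK] * (v - ek) / (1.0 + math.exp((25.0 - v) / 5.98))
    ibca = p[PG_BCA] * (v - eca)
    ibna = p[PG_BNA] * (v - ena)

    out[0] = ina
    out[1] = inal
    out[2] = ik1
    out[3] = ito
    out[4] = ikr
    out[5] = iks
    out[6] = ical
    out[7] = inaca
    out[8] = inak
    out[9] = ipca
    out[10] = ipk
    out[11] = ibca
    out[12] = ibna


@njit(cache=True)
def _rl_gate(g, ginf, tau, dt):
    return ginf - (ginf - g) * math.exp(-dt / tau)


@njit(cache=True)
def _step_one(y, p, dt, istim):
    """Advance one myocyte by dt (ms): Rush-Larsen gates, explicit
    Euler for concentrations/crossbridge states, reaction update of v."""
    cur = np.empty(13)
    _currents_kernel(y, p, cur)
    iion = 0.0
    for k in range(13):
        iion += cur[k]
    ina, inal, ik1, ito, ikr, iks, ical = cur[0], cur[1], cur[2], cur[3], \
        cur[4], cur[5], cur[6]
    inaca, inak, ipca, ipk, ibca, ibna = cur[7], cur[8], cur[9], cur[10], \
        cur[11], cur[12]

    v = y[IV]
    cai = y[ICA_I]
    casr = y[ICA_SR]

    # --- calcium subsystem (analytic rapid-buffering updates) ---
    irel = (A_REL * casr * casr / (B_REL * B_REL + casr * casr) + C_REL) \
        * y[ID] * y[IGREL]
    ileak = p[PV_LEAK] * (casr - cai)
    iup = p[PV_MAXUP] / (1.0 + (KUP * KUP) / (cai * cai))

    cacsqn = BUFSR * casr / (casr + KBUFSR)
    dcasr = dt * (VC / VSR) * (iup - irel - ileak)
    bjsr = BUFSR - cacsqn - dcasr - casr + KBUFSR
    cjsr = KBUFSR * (cacsqn + dcasr + casr)
    y[ICA_SR] = (math.sqrt(bjsr * bjsr + 4.0 * cjsr) - bjsr) / 2.0

    cabuf = BUFC * cai / (cai + KBUFC)
    dcai = dt * (-(ical + ibca + ipca - 2.0 * inaca) * INV_VC_F2
                 * CAPACITANCE - iup + irel + ileak)
    bc = BUFC - cabuf - dcai - cai + KBUFC
    cc = KBUFC * (cabuf + dcai + cai)
    y[ICA_I] = (math.sqrt(bc * bc + 4.0 * cc) - bc) / 2.0

    # I_NaL enters the voltage equation (total ionic current) only;
    # the Na+ bookkeeping keeps the original TNNP flux list
    y[INA_I] += dt * (-(ina + ibna + 3.0 * inak + 3.0 * inaca)
                      * INV_VC_F * CAPACITANCE)
    y[IK_I] += dt * (-(istim + ik1 + ito + ikr + iks - 2.0 * inak + ipk)
                     * INV_VC_F * CAPACITANCE)

    # --- Hodgkin-Huxley gates (Rush-Larsen) ---
    m_inf = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) \
        + 0.1 / (1.0 + math.exp((v - 50.0) / 200.0))
    y[IM] = _rl_gate(y[IM], m_inf, am * bm, dt)

    h_inf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    y[IH] = _rl_gate(y[IH], h_inf, 1.0 / (ah + bh), dt)

    if v >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * v)
               - 6.948e-6 * math.exp(-0.04391 * v)) * (v + 37.78)
              / (1.0 + math.exp(0.311 * (v + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * v) \
            / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    y[IJ] = _rl_gate(y[IJ], h_inf, 1.0 / (aj + bj), dt)

    xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
    a1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    b1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    y[IXR1] = _rl_gate(y[IXR1], xr1_inf, a1 * b1, dt)

    xr2_inf = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
    a2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    b2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    y[IXR2] = _rl_gate(y[IXR2], xr2_inf, a2 * b2, dt)

    xs_inf = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
    axs = 1100.0 / math.sqrt(1.0 + math.exp((-10.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((v - 60.0) / 20.0))
    y[IXS] = _rl_gate(y[IXS], xs_inf, axs * bxs, dt)

    r_inf = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
    tau_r = 9.5 * math.exp(-(v + 40.0) ** 2 / 1800.0) + 0.8
    y[IR] = _rl_gate(y[IR], r_inf, tau_r, dt)

    if p[PIS_ENDO] > 0.5:
        s_inf = 1.0 / (1.0 + math.exp((v + 28.0) / 5.0))
        tau_s = 1000.0 * math.exp(-(v + 67.0) ** 2 / 1000.0) + 8.0
    else:
        s_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
        tau_s = 85.0 * math.exp(-(v + 45.0) ** 2 / 320.0) \
            + 5.0 / (1.0 + math.exp((v - 20.0) / 5.0)) + 3.0
    y[IS] = _rl_gate(y[IS], s_inf, tau_s, dt)

    d_inf = 1.0 / (1.0 + math.exp((-5.0 - v) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    y[ID] = _rl_gate(y[ID], d_inf, ad * bd + gd, dt)

    f_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    tau_f = 1125.0 * math.exp(-(v + 27.0) ** 2 / 240.0) + 80.0 \
        + 165.0 / (1.0 + math.exp((25.0 - v) / 10.0))
    y[IF] = _rl_gate(y[IF], f_inf, tau_f, dt)

    # calcium-dependent gates with one-way (downward) voltage clamp
    cai_new = y[ICA_I]
    afca = 1.0 / (1.0 + (cai_new / 0.000325) ** 8)
    bfca = 0.1 / (1.0 + math.exp((cai_new - 0.0005) / 0.0001))
    gfca = 0.2 / (1.0 + math.exp((cai_new - 0.00075) / 0.0008))
    fca_inf = (afca + bfca + gfca + 0.23) / 1.46
    fca_new = _rl_gate(y[IFCA], fca_inf, TAU_FCA, dt)
    if not (fca_new > y[IFCA] and v > -60.0):
        y[IFCA] = fca_new

    if cai_new < 0.00035:
        g_inf = 1.0 / (1.0 + (cai_new / 0.00035) ** 6)
    else:
        g_inf = 1.0 / (1.0 + (cai_new / 0.00035) ** 16)
    g_new = _rl_gate(y[IGREL], g_inf, TAU_G, dt)
    if not (g_new > y[IGREL] and v > -60.0):
        y[IGREL] = g_new

    # late sodium gates
    x = v + 47.13
    if abs(x) < 1e-6:
        aml = 3.2
    else:
        aml = 0.32 * x / (1.0 - math.exp(-0.1 * x))
    bml = 0.08 * math.exp(-v / 11.0)
    y[IML] = _rl_gate(y[IML], aml / (aml + bml), 1.0 / (aml + bml), dt)
    hl_inf = 1.0 / (1.0 + math.exp((v + 91.0) / 6.1))
    y[IHL] = _rl_gate(y[IHL], hl_inf, TAU_HL, dt)

    # --- Rice myofilament model (Ca_i in uM drives troponin) ---
    sl = p[PSL]
    sovr_ze = min(LEN_THICK / 2.0, sl / 2.0)
    sovr_cle = max(sl / 2.0 - (sl - LEN_THIN), LEN_HBARE / 2.0)
    len_sovr = sovr_ze - sovr_cle
    sovf_thick = len_sovr * 2.0 / (LEN_THICK - LEN_HBARE)
    sovf_thin = len_sovr / LEN_THIN

    ca_um = cai_new * 1000.0
    trl = y[ITRPNL]
    trh = y[ITRPNH]
    y[ITRPNL] = _rl_gate(trl, KON * ca_um / (KON * ca_um + KOFF_L),
                         1.0 / (KON * ca_um + KOFF_L), dt)
    y[ITRPNH] = _rl_gate(trh, KON * ca_um / (KON * ca_um + KOFF_H),
                         1.0 / (KON * ca_um + KOFF_H), dt)

    trop_reg = (1.0 - sovf_thin) * trl + sovf_thin * trh
    if trop_reg < 1e-8:
        trop_reg = 1e-8
    permtot = math.sqrt(1.0 / (1.0 + (PERM50 / trop_reg) ** NPERM))
    inprmt = 1.0 / permtot
    if inprmt > 100.0:
        inprmt = 100.0

    n_xb = y[IN_RICE]
    prer = y[IXBPRER]
    postr = y[IXBPOSTR]
    p_xb = 1.0 - n_xb - prer - postr
    xprer = y[IXXBPRER]
    xpostr = y[IXXBPOSTR]

    gapslmd = 1.0 + (1.0 - sovf_thick) * GSLMOD
    gapp_t = GAPP * gapslmd
    hfmd = math.exp(-math.copysign(1.0, xprer) * HFMDC * (xprer / X0) ** 2)
    hf_t = HF_XB * hfmd
    hb_t = HB_XB
    if xpostr < X0:
        gxbmd = math.exp(SIGMAP * ((X0 - xpostr) / X0) ** 2)
    else:
        gxbmd = math.exp(SIGMAN * ((xpostr - X0) / X0) ** 2)
    gxb_t = GXB * gxbmd

    y[IN_RICE] = n_xb + dt * (-KNP * permtot * n_xb + KPN * inprmt * p_xb)
    y[IXBPRER] = prer + dt * (FAPP * p_xb - (gapp_t + hf_t) * prer
                              + hb_t * postr)
    y[IXBPOSTR] = postr + dt * (hf_t * prer - (hb_t + gxb_t) * postr)
    y[IXXBPRER] = xprer + dt * (XPSI / SS_XBPRER) * (
        -xprer * FAPP + hb_t * (xpostr - X0 - xprer))
    y[IXXBPOSTR] = xpostr + dt * (XPSI / SS_XBPOSTR) * (
        hf_t * (xprer + X0 - xpostr))

    # --- membrane voltage (reaction part) ---
    y[IV] = v + dt * (-(iion + istim))


@njit(cache=True)
def step_cells(states, params, dt, istim):
    """Advance every cell in ``states`` (n, NSTATE) by one dt."""
    for i in range(states.shape[0]):
        _step_one(states[i], params[i], dt, istim[i])


@njit(cache=True)
def _run_beat(y, p, dt, n_steps, stim_amp, stim_steps,
              v_out, ca_out, ta_out):
    for k in range(n_steps):
        istim = stim_amp if k < stim_steps else 0.0
        _step_one(y, p, dt, istim)
        v_out[k] = y[IV]
        ca_out[k] = y[ICA_I]
        ta_out[k] = _rice_force(p[PSL], y[IXXBPRER], y[IXXBPOSTR],
                                y[IXBPRER], y[IXBPOSTR])


# ---------------------------------------------------------------------------
# high-level single-cell drivers
# ---------------------------------------------------------------------------

def step_rush_larsen(state, params: CellParams, dt: float,
                     I_stim: float = 0.0):
    """One Rush-Larsen / explicit-Euler step of the coupled myocyte.

    Gates (including m_L, h_L and the troponin sites) use the
    exponential closed-form update; concentrations, crossbridge states
    and v use explicit Euler.  Raises on non-finite state entries,
    naming the offending variable.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    y = _state_array(state)
    bad = np.flatnonzero(~np.isfinite(y))
    if bad.size:
        raise FloatingPointError(
            f"non-finite state variable {STATE_NAMES[bad[0]]!r}")
    ynew = y.copy()
    _step_one(ynew, params.as_array(), dt, I_stim)
    bad = np.flatnonzero(~np.isfinite(ynew))
    if bad.size:
        raise FloatingPointError(
            f"non-finite state variable {STATE_NAMES[bad[0]]!r} after step")
    return CellState(ynew) if isinstance(state, CellState) else ynew


STIM_AMPLITUDE = -52.0  # pA/pF, single-cell pacing pulse
STIM_DURATION = 1.0     # ms


def pace_to_steady_state(params: CellParams, freq: float = 1.0,
                         n_beats: int = 200, dt: float = 0.05,
                         tol: float = 1e-3, apd_fraction: float = 0.9):
    """Pace a single myocyte at ``freq`` Hz until steady state.

    Steady state is declared when the beat-to-beat relative change of
    both APD and the Ca_i peak falls below ``tol`` (the TNNP model
    keeps drifting very slowly in Na+/K+ for hundreds of beats; the
    default tolerance accepts the plateau the published single-cell
    values correspond to).  Returns ``(state, traces, info)`` where ``traces`` holds the last
    beat (time_ms, v_mV, Ca_i_mM, Ta_norm) and ``info`` carries
    per-beat APD / calcium-peak histories and the convergence flag.
    """
    if freq <= 0:
        raise ValueError("pacing frequency must be positive")
    from . import postprocess  # local import to avoid a cycle

    bcl = 1000.0 / freq
    n_steps = int(round(bcl / dt))
    stim_steps = max(1, int(round(STIM_DURATION / dt)))
    y = initial_state(params.sarcomere_length)
    p = params.as_array()
    v = np.empty(n_steps)
    ca = np.empty(n_steps)
    ta = np.empty(n_steps)
    t = (np.arange(n_steps) + 1) * dt

    apds, ca_peaks, ta_peaks = [], [], []
    converged = False
    beats_run = 0
    for b in range(n_beats):
        _run_beat(y, p, dt, n_steps, STIM_AMPLITUDE, stim_steps, v, ca, ta)
        beats_run = b + 1
        apd = postprocess.apd(t, v, fraction=apd_fraction)
        apds.append(apd)
        ca_peaks.append(float(ca.max()))
        ta_peaks.append(float(ta.max()))
        if b > 0 and np.isfinite(apds[-1]) and np.isfinite(apds[-2]):
            dapd = abs(apds[-1] - apds[-2]) / max(abs(apds[-2]), 1e-12)
            dca = abs(ca_peaks[-1] - ca_peaks[-2]) / max(ca_peaks[-2], 1e-12)
            if dapd < tol and dca < tol:
                converged = True
                break
    if not converged:
        last = abs(apds[-1] - apds[-2]) / max(abs(apds[-2]), 1e-12) \
            if len(apds) > 1 else float("nan")
        warnings.warn(
            f"pacing did not reach steady state in {n_beats} beats "
            f"(last APD residual {last:.2e})", RuntimeWarning)

    traces = {"time_ms": t.copy(), "v_mV": v.copy(),
              "Ca_i_mM": ca.copy(), "Ta_norm": ta.copy()}
    info = {"apd_history": np.array(apds),
            "ca_peak_history": np.array(ca_peaks),
            "ta_peak_history": np.array(ta_peaks),
            "converged": converged, "beats": beats_run,
            "apd": apds[-1], "ca_peak": ca_peaks[-1],
            "ta_peak": ta_peaks[-1],
            "ca_diastolic": float(ca.min()),
            "v_rest": float(v[-1])}
    return CellState(y), traces, info
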