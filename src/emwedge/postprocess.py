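"""Repolarization metrics, dispersions and transmural electrograms.

Activation time (ACT) is the first upward crossing of a voltage
threshold (default -20 mV), repolarization time (REP) the first
downward crossing of the 90%-return level toward the pre-stimulus
baseline after the peak; both are linearly interpolated between
samples.  APD = REP - ACT per node, and dispersion of any metric is
max - min over the activated nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NOT_ACTIVATED",
    "activation_time",
    "repolarization_time",
    "apd",
    "dispersion",
    "per_node_metrics",
    "transmural_electrogram",
    "twave_peak",
    "RepolarizationReport",
]

#: Sentinel returned when a trace never activates / repolarizes.
NOT_ACTIVATED = float("nan")


def activation_time(t, v, threshold: float = -20.0,
                    rule: str = "threshold") -> float:
    """Activation time of a voltage trace (ms).

    ``rule='threshold'`` (default): first upward crossing of
    ``threshold``; ``rule='dvdt'``: time of maximum upstroke velocity.
    Returns NaN when the trace never crosses the threshold.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    if rule == "dvdt":
        dv = np.diff(v) / np.diff(t)
        return float(t[int(np.argmax(dv))])
    if rule != "threshold":
        raise ValueError(f"unknown activation rule {rule!r}")
    above = v >= threshold
    if not above.any() or above[0]:
        if above.all() or above[0]:
            return float(t[0]) if above[0] else NOT_ACTIVATED
        return NOT_ACTIVATED
    k = int(np.argmax(above))  # first sample at/above threshold
    v0, v1 = v[k - 1], v[k]
    if v1 == v0:
        return float(t[k])
    return float(t[k - 1] + (threshold - v0) / (v1 - v0) * (t[k] - t[k - 1]))


def repolarization_time(t, v, fraction: float = 0.9,
                        baseline: float | None = None) -> float:
    """Time of ``fraction`` repolarization from peak toward baseline.

    The baseline defaults to the first sample (pre-stimulus resting
    potential).  Returns NaN when the trace has not repolarized by the
    end of the record.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    if baseline is None:
        baseline = float(v[0])
    kpk = int(np.argmax(v))
    peak = float(v[kpk])
    level = peak - fraction * (peak - baseline)
    tail = v[kpk:]
    below = tail <= level
    if not below.any():
        warnings.warn("trace not repolarized by end of record",
                      RuntimeWarning)
        return NOT_ACTIVATED
    k = kpk + int(np.argmax(below))
    if k == kpk:
        return float(t[k])
    v0, v1 = v[k - 1], v[k]
    if v1 == v0:
        return float(t[k])
    return float(t[k - 1] + (level - v0) / (v1 - v0) * (t[k] - t[k - 1]))


def apd(t, v, fraction: float = 0.9, threshold: float = -20.0) -> float:
    """Action potential duration: REP minus ACT (ms)."""
    act = activation_time(t, v, threshold=threshold)
    if np.isnan(act):
        return NOT_ACTIVATED
    rep = repolarization_time(t, v, fraction=fraction)
    if np.isnan(rep):
        return NOT_ACTIVATED
    return rep - act


def dispersion(values) -> float:
    """max - min over activated nodes; NaN entries are excluded."""
    values = np.asarray(values, float)
    ok = np.isfinite(values)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} node(s) excluded from "
                      "dispersion (not activated/repolarized)",
                      RuntimeWarning)
    if not ok.any():
        return NOT_ACTIVATED
    return float(values[ok].max() - values[ok].min())


def per_node_metrics(t, v_history, fraction: float = 0.9,
                     threshold: float = -20.0):
    """ACT, REP, APD arrays for a (n_times, n_nodes) voltage history."""
    v_history = np.asarray(v_history, float)
    n = v_history.shape[1]
    act = np.empty(n)
    rep = np.empty(n)
    for i in range(n):
        act[i] = activation_time(t, v_history[:, i], threshold=threshold)
        rep[i] = repolarization_time(t, v_history[:, i], fraction=fraction)
    return act, rep, rep - act


def transmural_electrogram(ue_history, epi_node: int, endo_node: int):
    """u_e(epi) - u_e(endo) per sample (mV)."""
    ue = np.asarray(ue_history, float)
    n = ue.shape[1]
    for node in (epi_node, endo_node):
        if not 0 <= node < n:
            raise IndexError(f"probe node {node} outside 0..{n - 1}")
    return ue[:, epi_node] - ue[:, endo_node]


def twave_peak(t, electrogram, t_start: float, t_end: float | None = None):
    """Signed extremum of the electrogram inside the T-wave window."""
    t = np.asarray(t, float)
    eg = np.asarray(electrogram, float)
    mask = t >= t_start
    if t_end is not None:
        mask &= t <= t_end
    if not mask.any():
        raise ValueError("empty T-wave window")
    seg = eg[mask]
    k = int(np.argmax(np.abs(seg)))
    return float(seg[k])


@dataclass
class RepolarizationReport:
    """Per-node repolarization metrics plus derived summaries."""

    act: np.ndarray
    rep: np.ndarray
    apd: np.ndarray
    disp_act: float = field(init=False)
    disp_rep: float = field(init=False)
    disp_apd: float = field(init=False)
    electrogram_t: np.ndarray | None = None
    electrogram: np.ndarray | None = None
    twave_peak: float | None = None
    max_wall_thickening: float | None = None

    def __post_init__(self):
        self.act = np.asarray(self.act, float)
        self.rep = np.asarray(self.rep, float)
        self.apd = np.asarray(self.apd, float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.disp_act = dispersion(self.act)
            self.disp_rep = dispersion(self.rep)
            self.disp_apd = dispersion(self.apd)

    def summary(self) -> dict:
        out = {
            "ACT_min": float(np.nanmin(self.act)),
            "ACT_max": float(np.nanmax(self.act)),
            "disp_ACT": self.disp_act,
            "REP_min": float(np.nanmin(self.rep)),
            "REP_max": float(np.nanmax(self.rep)),
            "disp_REP": self.disp_rep,
            "APD_min": float(np.nanmin(self.apd)),
            "APD_max": float(np.nanmax(self.apd)),
            "disp_APD": self.disp_apd,
        }
        if self.twave_peak is not None:
            out["Twave_peak_mV"] = self.twave_peak
        if self.max_wall_thickening is not None:
            out["max_wall_thickening_pct"] = self.max_wall_thickening
        return out
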