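"""Sarcolemmal ion currents: structured wrappers over the compiled kernels.

Sign convention: outward positive, dV/dt = -sum(I)/C_m.  Each function
returns the instantaneous current(s) in pA and, where applicable, the gate
steady states / time constants so callers can form dx/dt = (x_inf - x)/tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import rhs as R
from .geometry import build_geometry
from .params import Parameters


@dataclass(frozen=True)
class GateRates:
    """Steady-state values and time constants (ms) keyed by gate name."""

    x_inf: dict
    tau: dict


def _pack(params: Parameters | None) -> np.ndarray:
    params = params or Parameters()
    return params.pack(build_geometry())


def reversal_potentials(Na_i: float, K_i: float, Ca_ss: float,
                        params: Parameters | None = None) -> dict:
    """Nernst potentials (mV) for the intra/extracellular concentration pairs."""
    c = (params or Parameters()).constants
    return {
        "E_Na": c.nernst(1, c.Na_o, Na_i),
        "E_K": c.nernst(1, c.K_o, K_i),
        "E_Ca": c.nernst(2, c.Ca_o, Ca_ss),
    }


def fast_na_current(V: float, m: float, h1: float, h2: float, Na_in: float,
                    params: Parameters | None = None):
    """Fast Na+ current (GHK form) and its gate kinetics."""
    p = _pack(params)
    I = R.i_na(V, m, h1, h2, Na_in, p)
    m_inf, tau_m, h1_inf, tau_h1, h2_inf, tau_h2 = R.na_gates(V)
    rates = GateRates(
        x_inf={"m": m_inf, "h1": h1_inf, "h2": h2_inf},
        tau={"m": tau_m, "h1": tau_h1, "h2": tau_h2})
    return I, rates


def l_type_ca_current(V: float, d: float, f1: float, f2: float, fca: float,
                      Ca_ss: float, params: Parameters | None = None):
    """L-type Ca2+ current with voltage- and Ca2+-dependent inactivation."""
    if Ca_ss <= 0:
        raise ValueError("Ca_ss must be positive")
    pr = params or Parameters()
    p = _pack(pr)
    I = R.i_cal(V, d, f1, f2, fca, p)
    d_inf, tau_d, f1_inf, tau_f1, f2_inf, tau_f2 = R.cal_gates(V)
    fca_inf = R.fca_gate(Ca_ss, pr.k_fca, pr.n_fca)
    rates = GateRates(
        x_inf={"d": d_inf, "f1": f1_inf, "f2": f2_inf, "fca": fca_inf},
        tau={"d": tau_d, "f1": tau_f1, "f2": tau_f2,
             "fca": pr.tau_fca * 1e3})
    return I, rates


def potassium_currents(V: float, gates: dict, K_i: float, Na_in: float,
                       params: Parameters | None = None):
    """All K+-carrying currents {I_to, I_sus, I_Kr, I_Ks, I_K1, I_f} and
    the associated gate kinetics.

    ``gates`` must contain r_to, s_to, r_sus, s_sus, n_ks, pa_kr, y_f.
    """
    p = _pack(params)
    I_to, I_sus, I_Ks, I_Kr, I_K1, I_fNa, I_fK = R.i_k(
        V, gates["r_to"], gates["s_to"], gates["r_sus"], gates["s_sus"],
        gates["n_ks"], gates["pa_kr"], gates["y_f"], K_i, Na_in, p)
    r_inf, tau_r, s_inf, tau_s, rs_inf, tau_rs, ss_inf, tau_ss = R.to_sus_gates(V)
    n_inf, tau_n, pa_inf, tau_pa = R.ks_kr_gates(V)
    y_inf, tau_y = R.f_gate(V)
    rates = GateRates(
        x_inf={"r_to": r_inf, "s_to": s_inf, "r_sus": rs_inf,
               "s_sus": ss_inf, "n_ks": n_inf, "pa_kr": pa_inf, "y_f": y_inf},
        tau={"r_to": tau_r, "s_to": tau_s, "r_sus": tau_rs, "s_sus": tau_ss,
             "n_ks": tau_n, "pa_kr": tau_pa, "y_f": tau_y})
    currents = {"I_to": I_to, "I_sus": I_sus, "I_Kr": I_Kr, "I_Ks": I_Ks,
                "I_K1": I_K1, "I_f": I_fNa + I_fK}
    return currents, rates


def pumps_exchangers(V: float, Na_in: float, K_i: float, Ca_ss: float,
                     params: Parameters | None = None,
                     ncx_reverse_block: bool = False) -> dict:
    """{I_NKA, I_NCX, I_PMCA, I_Nab, I_Cab} in pA.

    NCX carries +1 net charge per extruded Ca2+ (3Na:1Ca); outward current
    corresponds to Ca2+ influx (reverse mode), which ``ncx_reverse_block``
    clamps to zero.
    """
    if min(Na_in, K_i, Ca_ss) <= 0:
        raise ValueError("concentrations must be positive")
    p = _pack(params)
    I_NKA = R.i_nak(V, Na_in, p)
    I_NCX = R.i_ncx(V, Na_in, Ca_ss, p, 1.0, 1.0 if ncx_reverse_block else 0.0)
    I_PMCA = R.i_pmca(Ca_ss, p, 1.0)
    I_Nab, I_Cab = R.i_background(V, Na_in, Ca_ss, p)
    return {"I_NKA": I_NKA, "I_NCX": I_NCX, "I_PMCA": I_PMCA,
            "I_Nab": I_Nab, "I_Cab": I_Cab}
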