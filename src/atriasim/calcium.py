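"""Intracellular / SR Ca2+ subsystem: RyR units, SERCA, leak, buffering and
the radial diffusion operators.

These are the structured (and grid-generic) counterparts of the kernels the
engine integrates; the diffusion operators here accept any number of shells
and are used for grid-refinement and fine-grid PDE cross-checks.  Fluxes are
in nL*mM/ms with explicit source and sink compartments; inter-shell fluxes
are antisymmetric so mass is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import rhs as R
from .geometry import CellGeometry, build_geometry
from .params import Parameters


def _pack(params: Parameters | None, geom: CellGeometry | None = None):
    return (params or Parameters()).pack(geom or build_geometry())


# ---------------------------------------------------------------------------
# RyR
# ---------------------------------------------------------------------------
@dataclass
class RyRUnit:
    """One phenomenological release unit (open/closed/adaptation gates)."""

    o: float
    c: float
    a: float
    junctional: bool = False

    @property
    def p_open(self) -> float:
        return self.o * self.c


def ryr_gate_rates(Ca_local: float, Ca_sr_local: float, unit: RyRUnit,
                   params: Parameters | None = None) -> dict:
    """Gate derivatives (1/ms) and targets for frozen local concentrations.

    The open and closed gates relax toward sigmoids of local cytosolic
    [Ca2+] whose midpoints are shifted by the slow adaptation variable; the
    junctional unit uses faster time constants than bulk units.
    """
    if Ca_local <= 0 or Ca_sr_local <= 0:
        raise ValueError("concentrations must be positive")
    pr = params or Parameters()
    p = _pack(pr)
    o_inf, c_inf, a_inf, srca = R.ryr_steady_states(
        Ca_local, Ca_sr_local, unit.a, p)
    if unit.junctional:
        tau_o, tau_c = pr.ryr_tau_act_ss * 1e3, pr.ryr_tau_inact_ss * 1e3
    else:
        tau_o, tau_c = pr.ryr_tau_act_bulk * 1e3, pr.ryr_tau_inact_bulk * 1e3
    tau_a = pr.ryr_tau_adapt * 1e3
    return {
        "do_dt": (o_inf - unit.o) / tau_o,
        "dc_dt": (c_inf - unit.c) / tau_c,
        "da_dt": (a_inf - unit.a) / tau_a,
        "o_inf": o_inf, "c_inf": c_inf, "a_inf": a_inf,
        "sr_factor": srca,
        "tau_o": tau_o, "tau_c": tau_c, "tau_a": tau_a,
    }


def ryr_release_flux(unit: RyRUnit, Ca_sr: float, Ca_cyto: float,
                     volume_nl: float, scale: float = 1.0,
                     params: Parameters | None = None) -> float:
    """Release flux (nL*mM/ms) through one unit; zero when ``scale`` is 0."""
    if scale < 0:
        raise ValueError("release scale must be >= 0")
    pr = params or Parameters()
    p = _pack(pr)
    nu = (pr.ryr_nu_ss if unit.junctional else pr.ryr_nu_bulk) * 1e-3
    _, _, _, srca = R.ryr_steady_states(max(Ca_cyto, 1e-12), Ca_sr, unit.a, p)
    return scale * nu * volume_nl * unit.p_open * srca * (Ca_sr - Ca_cyto)


# ---------------------------------------------------------------------------
# SERCA
# ---------------------------------------------------------------------------
def serca_flux(Ca_cyto: float, Ca_serca: float, Ca_sr: float,
               volume_nl: float, params: Parameters | None = None,
               scale: float = 1.0) -> dict:
    """Two-step SERCA fluxes for one unit.

    Returns cytosol->pump and pump->SR fluxes (nL*mM/ms; each cycle moves
    two Ca2+) and the pump-bound intermediate derivative (mM/ms).  Mass is
    conserved: d(Ca_serca)/dt = (J_in - J_out) / (2 * volume).
    """
    p = _pack(params)
    r_in, r_out = R.serca_rates(Ca_cyto, Ca_sr, Ca_serca, p, scale)
    J_in = r_in * volume_nl * 2.0
    J_out = r_out * volume_nl * 2.0
    return {"J_cyto_to_pump": J_in, "J_pump_to_sr": J_out,
            "dCa_serca_dt": 0.5 * (r_in - r_out) * 2.0}


def sr_leak(Ca_sr: float, Ca_cyto: float, volume_nl: float,
            params: Parameters | None = None) -> float:
    """Passive SR->cytosol leak (nL*mM/ms), linear in the gradient."""
    pr = params or Parameters()
    return pr.k_SRleak * 1e-3 * (Ca_sr - Ca_cyto) * volume_nl


# ---------------------------------------------------------------------------
# Buffering
# ---------------------------------------------------------------------------
def buffer_equilibrium(Ca_free: float, B_tot: float, K_d: float) -> tuple:
    """Single-site rapid equilibrium: (bound concentration, gamma term).

    bound = B_tot*Ca/(K_d+Ca); gamma = B_tot*K_d/(K_d+Ca)^2 is the species'
    contribution to 1/beta - 1.
    """
    if Ca_free < 0:
        raise ValueError("Ca_free must be >= 0")
    bound = B_tot * Ca_free / (K_d + Ca_free)
    gamma = B_tot * K_d / (K_d + Ca_free) ** 2
    return bound, gamma


def rapid_buffer_beta(Ca_free: float, buffers: list[tuple]) -> float:
    """beta = (1 + sum_i B_i*K_i/(K_i+Ca)^2)^-1 for [(B_tot, K_d), ...]."""
    g = sum(buffer_equilibrium(Ca_free, b, k)[1] for b, k in buffers)
    return 1.0 / (1.0 + g)


def bulk_beta(Ca_free, params: Parameters | None = None):
    pr = params or Parameters()
    return rapid_buffer_beta(Ca_free, [(pr.BCa, pr.K_dBCa)])


def subspace_beta(Ca_free, params: Parameters | None = None):
    pr = params or Parameters()
    return rapid_buffer_beta(Ca_free, [(pr.SLlow, pr.K_dSLlow),
                                       (pr.SLhigh, pr.K_dSLhigh),
                                       (pr.BCa, pr.K_dBCa)])


def sr_beta(Ca_free, params: Parameters | None = None):
    pr = params or Parameters()
    return rapid_buffer_beta(Ca_free, [(pr.CSQN, pr.K_dCSQN)])


# ---------------------------------------------------------------------------
# Radial diffusion (grid-generic finite volume)
# ---------------------------------------------------------------------------
def cytosolic_diffusion(Ca: np.ndarray, geom: CellGeometry,
                        params: Parameters | None = None) -> np.ndarray:
    """dCa/dt (mM/ms) from radial diffusion in the bulk cytosol.

    Finite-volume discretization of cylindrical radial diffusion carrying
    free Ca2+ (D_Ca) plus the mobile-buffer complex (D_CaBm), scaled by the
    rapid-buffering factor.  Zero-flux boundaries at the axis and at the
    subspace interface (junctional exchange is a separate flux).
    """
    pr = params or Parameters()
    Ca = np.asarray(Ca, float)
    if Ca.shape != (geom.n_bulk,):
        raise ValueError("Ca must have one entry per bulk shell")
    dca = pr.D_Ca * 1e-3
    dcab = pr.D_CaBm * 1e-3
    cab = pr.BCa * Ca / (pr.K_dBCa + Ca)
    net = np.zeros_like(Ca)
    for j in range(geom.n_bulk - 1):
        flux = geom.A_faces[j] * (
            dca * (Ca[j + 1] - Ca[j]) + dcab * (cab[j + 1] - cab[j])
        ) / geom.dr * 1e-6
        net[j] += flux
        net[j + 1] -= flux
    beta = np.array([bulk_beta(c, pr) for c in Ca])
    return beta * net / geom.V_bulk


def sr_diffusion(Ca_sr: np.ndarray, geom: CellGeometry,
                 params: Parameters | None = None,
                 csqn: float | None = None) -> np.ndarray:
    """dCa_SR/dt (mM/ms) from radial diffusion inside the SR network.

    Same operator with D_CaSR and calsequestrin buffering; ``csqn``
    overrides the calsequestrin concentration (0 recovers free diffusion).
    """
    pr = params or Parameters()
    if csqn is not None:
        pr = pr.replace(CSQN=csqn)
    Ca_sr = np.asarray(Ca_sr, float)
    dcasr = pr.D_CaSR * 1e-3
    net = np.zeros_like(Ca_sr)
    srf = geom.sr_fraction
    for j in range(geom.n_bulk - 1):
        flux = (geom.A_faces[j] * srf * dcasr
                * (Ca_sr[j + 1] - Ca_sr[j]) / geom.dr * 1e-6)
        net[j] += flux
        net[j + 1] -= flux
    beta = np.array([sr_beta(c, pr) for c in Ca_sr])
    return beta * net / geom.V_sr


def junctional_bulk_exchange(Ca_ss: float, Ca_bulk_outer: float,
                             geom: CellGeometry,
                             params: Parameters | None = None) -> float:
    """Diffusive flux (nL*mM/ms) from the junctional subspace into the
    outermost bulk shell, proportional to the accessible exchange area and
    inversely to the centre-to-centre distance."""
    pr = params or Parameters()
    return (geom.A_ss_bulk * pr.D_Ca * 1e-3 / geom.x_ss_bulk
            * (Ca_ss - Ca_bulk_outer) * 1e-6)
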