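"""Model parameter set: physical constants, current conductances/permeabilities,
Ca2+ buffering, diffusion, SERCA and RyR parameters.

Values come from three sources, recorded per parameter in the shipped
``data/default_params.yaml``:

* fixed physical/geometric constants of the model cell;
* the Nygren-type sarcolemmal current formulations with this model's
  adjustments (conductance scalings, the refit L-type f1 time constant, the
  Ca2+-dependent L-type inactivation gate, the hyperpolarization-activated
  current fitted to left-atrial data);
* the Ca2+-handling subsystem (buffers, diffusion coefficients, SERCA with an
  explicit pump-bound intermediate, three-gate RyR units), where the RyR time
  constants/permeabilities and the calsequestrin amount are calibrated so the
  emergent 1 Hz Ca2+ dynamics reproduce the reported transient amplitude,
  decay, spatial peak timing and SR content.

Unit conventions
----------------
Voltages mV, time ms, concentrations mM, volumes nL, currents pA.
Rate constants and time constants are stored in their literature unit
(seconds-based where so published) and converted once in :func:`pack`,
which produces the flat float64 vector consumed by the compiled right-hand
side.  The packed vector therefore uses ms-based rates throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import numpy as np
import yaml

from .constants import PhysicalConstants
from .geometry import CellGeometry, build_geometry

# ---------------------------------------------------------------------------
# Packed-parameter index map (order is the layout of the flat vector handed
# to the compiled RHS; append only).
# ---------------------------------------------------------------------------
_PACKED_NAMES = [
    # physics
    "F", "RTF", "Na_o", "Ca_o", "K_o", "C_m",
    # fast Na+
    "P_Na",
    # L-type Ca2+
    "g_CaL", "E_Ca_app", "k_fca", "n_fca", "tau_fca",
    # K+ currents
    "g_to", "g_sus", "g_Ks", "g_Kr", "g_K1", "g_f", "f_f_Na",
    # pumps / exchangers / background
    "I_NaK_max", "k_NaK_K", "k_NaK_Na", "k_NCX", "gamma_NCX", "d_NCX",
    "I_PMCA_max", "k_PMCA", "g_Nab", "g_Cab",
    # buffers
    "BCa", "K_dBCa", "SLlow", "K_dSLlow", "SLhigh", "K_dSLhigh",
    "CSQN", "K_dCSQN",
    # diffusion, per-ms
    "D_Ca", "D_CaBm", "D_CaSR", "D_Na",
    # SERCA (per-ms rates)
    "serca_k1", "serca_k2", "serca_k3", "serca_k4", "serca_cpumps",
    # RyR
    "ryr_tau_act_ss", "ryr_tau_inact_ss", "ryr_tau_act_bulk",
    "ryr_tau_inact_bulk", "ryr_tau_adapt",
    "ryr_nu_ss", "ryr_nu_bulk",
    "ryr_a_base", "ryr_a_amp", "ryr_a_mid", "ryr_a_slope",
    "ryr_o_shift", "ryr_o_slope", "ryr_c_shift", "ryr_c_slope",
    "ryr_srca_mid", "ryr_srca_slope",
    "k_SRleak",
    # geometry-derived scalars
    "V_ss", "A_ss_bulk", "x_ss_bulk", "dr", "V_cytosol", "x_ss_bulk_Na",
]
PIDX = {name: i for i, name in enumerate(_PACKED_NAMES)}
N_PACKED = len(_PACKED_NAMES)


@dataclass
class Parameters:
    """Complete model parameter set (literature units, see module docstring)."""

    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    C_m: float = 0.05            # nF

    # --- fast Na+ current (GHK permeability form), nL/s
    P_Na: float = 0.0016

    # --- L-type Ca2+ current
    g_CaL: float = 19.75       # nS
    E_Ca_app: float = 60.0       # mV, apparent reversal
    k_fca: float = 1.0e-3        # mM, Ca-inactivation midpoint ([Ca2+]_ss)
    n_fca: float = 2.0           # Hill coefficient of Ca-inactivation
    tau_fca: float = 2.0e-3      # s

    # --- K+ currents, nS
    g_to: float = 8.25
    g_sus: float = 2.25
    g_Ks: float = 1.0
    g_Kr: float = 0.5
    g_K1: float = 3.9
    g_f: float = 1.0
    f_f_Na: float = 0.2677       # Na+ fraction of I_f

    # --- pumps, exchangers, background
    I_NaK_max: float = 70.8253   # pA
    k_NaK_K: float = 1.0         # mM
    k_NaK_Na: float = 11.0       # mM
    k_NCX: float = 0.0095        # pA/mM^4
    gamma_NCX: float = 0.45
    d_NCX: float = 0.0003        # 1/mM^4
    I_PMCA_max: float = 2.0      # pA
    k_PMCA: float = 0.0005       # mM
    g_Nab: float = 0.060599      # nS
    g_Cab: float = 0.0952        # nS

    # --- Ca2+ buffering (mM)
    BCa: float = 0.024
    K_dBCa: float = 0.00238
    SLlow: float = 165.0
    K_dSLlow: float = 1.1
    SLhigh: float = 13.0
    K_dSLhigh: float = 0.013
    CSQN: float = 6.7
    K_dCSQN: float = 0.8

    # --- diffusion coefficients, um^2/s
    D_Ca: float = 780.0
    D_CaBm: float = 25.0
    D_CaSR: float = 44.0
    D_Na: float = 0.12

    # --- SERCA (two-step pump with bound intermediate); s-based rates
    serca_K_mf: float = 0.25e-3  # mM, cytosolic half-activation
    serca_K_mr: float = 1.8      # mM, SR half-inhibition (back flux)
    serca_k4: float = 18.0        # 1/s, pump->SR rate
    serca_cpumps: float = 0.04   # mM, pump site concentration

    # --- RyR (three-gate phenomenological units); s-based taus
    ryr_tau_act_ss: float = 5e-3
    ryr_tau_inact_ss: float = 15e-3
    ryr_tau_act_bulk: float = 40e-3
    ryr_tau_inact_bulk: float = 50e-3
    ryr_tau_adapt: float = 1.0
    ryr_nu_ss: float = 375.0     # 1/s, junctional release rate per subspace volume
    ryr_nu_bulk: float = 4.75  # 1/s, bulk release rate per shell volume
    # steady-state sigmoids; cytosolic Ca arguments in uM
    ryr_a_base: float = 0.505
    ryr_a_amp: float = 0.427
    ryr_a_mid: float = 0.29
    ryr_a_slope: float = 0.082
    ryr_o_shift: float = 0.16
    ryr_o_slope: float = 0.03
    ryr_c_shift: float = 0.02
    ryr_c_slope: float = 0.01
    # SR-lumen sensitivity sigmoid (mM)
    ryr_srca_mid: float = 0.3
    ryr_srca_slope: float = 0.1
    k_SRleak: float = 6e-3       # 1/s

    def replace(self, **kw: Any) -> "Parameters":
        return dataclasses.replace(self, **kw)

    # -- derived SERCA rates ------------------------------------------------
    @property
    def serca_k3(self) -> float:
        return self.serca_k4 / self.serca_K_mr**2

    @property
    def serca_k1(self) -> float:
        return 1.0e6 * self.serca_k4

    @property
    def serca_k2(self) -> float:
        return self.serca_k1 * self.serca_K_mf**2

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["constants"] = dataclasses.asdict(self.constants)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def pack(self, geom: CellGeometry) -> np.ndarray:
        """Flatten to the float64 vector used by the compiled RHS (ms-based)."""
        c = self.constants
        p = np.zeros(N_PACKED)

        def put(name, value):
            p[PIDX[name]] = value

        put("F", c.F)
        put("RTF", c.RTF)
        put("Na_o", c.Na_o)
        put("Ca_o", c.Ca_o)
        put("K_o", c.K_o)
        put("C_m", self.C_m)
        put("P_Na", self.P_Na)
        put("g_CaL", self.g_CaL)
        put("E_Ca_app", self.E_Ca_app)
        put("k_fca", self.k_fca)
        put("n_fca", self.n_fca)
        put("tau_fca", self.tau_fca * 1e3)
        put("g_to", self.g_to)
        put("g_sus", self.g_sus)
        put("g_Ks", self.g_Ks)
        put("g_Kr", self.g_Kr)
        put("g_K1", self.g_K1)
        put("g_f", self.g_f)
        put("f_f_Na", self.f_f_Na)
        put("I_NaK_max", self.I_NaK_max)
        put("k_NaK_K", self.k_NaK_K)
        put("k_NaK_Na", self.k_NaK_Na)
        put("k_NCX", self.k_NCX)
        put("gamma_NCX", self.gamma_NCX)
        put("d_NCX", self.d_NCX)
        put("I_PMCA_max", self.I_PMCA_max)
        put("k_PMCA", self.k_PMCA)
        put("g_Nab", self.g_Nab)
        put("g_Cab", self.g_Cab)
        put("BCa", self.BCa)
        put("K_dBCa", self.K_dBCa)
        put("SLlow", self.SLlow)
        put("K_dSLlow", self.K_dSLlow)
        put("SLhigh", self.SLhigh)
        put("K_dSLhigh", self.K_dSLhigh)
        put("CSQN", self.CSQN)
        put("K_dCSQN", self.K_dCSQN)
        put("D_Ca", self.D_Ca * 1e-3)      # um^2/ms
        put("D_CaBm", self.D_CaBm * 1e-3)
        put("D_CaSR", self.D_CaSR * 1e-3)
        put("D_Na", self.D_Na * 1e-3)
        put("serca_k1", self.serca_k1 * 1e-3)
        put("serca_k2", self.serca_k2 * 1e-3)
        put("serca_k3", self.serca_k3 * 1e-3)
        put("serca_k4", self.serca_k4 * 1e-3)
        put("serca_cpumps", self.serca_cpumps)
        put("ryr_tau_act_ss", self.ryr_tau_act_ss * 1e3)
        put("ryr_tau_inact_ss", self.ryr_tau_inact_ss * 1e3)
        put("ryr_tau_act_bulk", self.ryr_tau_act_bulk * 1e3)
        put("ryr_tau_inact_bulk", self.ryr_tau_inact_bulk * 1e3)
        put("ryr_tau_adapt", self.ryr_tau_adapt * 1e3)
        put("ryr_nu_ss", self.ryr_nu_ss * 1e-3)     # 1/ms
        put("ryr_nu_bulk", self.ryr_nu_bulk * 1e-3)
        put("ryr_a_base", self.ryr_a_base)
        put("ryr_a_amp", self.ryr_a_amp)
        put("ryr_a_mid", self.ryr_a_mid)
        put("ryr_a_slope", self.ryr_a_slope)
        put("ryr_o_shift", self.ryr_o_shift)
        put("ryr_o_slope", self.ryr_o_slope)
        put("ryr_c_shift", self.ryr_c_shift)
        put("ryr_c_slope", self.ryr_c_slope)
        put("ryr_srca_mid", self.ryr_srca_mid)
        put("ryr_srca_slope", self.ryr_srca_slope)
        put("k_SRleak", self.k_SRleak * 1e-3)
        put("V_ss", geom.V_ss)
        put("A_ss_bulk", geom.A_ss_bulk)
        put("x_ss_bulk", geom.x_ss_bulk)
        put("dr", geom.dr)
        put("V_cytosol", geom.V_cytosol)
        # Na+ exchange distance: subspace centre to bulk mid-depth
        put("x_ss_bulk_Na", geom.d_junct / 2.0 + 2.0 * geom.dr)
        return p


def default_parameters() -> Parameters:
    """The shipped default parameter set (reads ``data/default_params.yaml``)."""
    path = resources.files("atriasim").joinpath("data/default_params.yaml")
    with path.open("r") as fh:
        return _from_mapping(yaml.safe_load(fh))


def load_parameters(path: str) -> Parameters:
    """Load a parameter file (YAML key/value mapping; unknown keys rejected)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_mapping(data)


def _from_mapping(data: dict) -> Parameters:
    data = dict(data)
    data.pop("units", None)          # documentation block, not parameters
    const_kw = data.pop("constants", {})
    valid = {f.name for f in dataclasses.fields(Parameters)} - {"constants"}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    cvalid = {f.name for f in dataclasses.fields(PhysicalConstants)}
    cunknown = set(const_kw) - cvalid
    if cunknown:
        raise ValueError(f"unknown constant keys: {sorted(cunknown)}")
    return Parameters(constants=PhysicalConstants(**const_kw), **data)
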