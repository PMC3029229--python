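"""Right-hand side of the myocyte ODE system.

Everything here is written as scalar math on flat float64 arrays so the whole
RHS can be compiled with numba (pure-Python fallback works identically, just
slower).  Higher-level modules (`currents`, `calcium`) wrap these kernels
with structured signatures; the `engine` integrates :func:`rhs_core`.

State layout (fixed, four bulk shells; shells ordered axis -> membrane):

====  =========================================================
 0    V_m (mV)
 1-3  I_Na gates m, h1, h2
 4-7  I_CaL gates d, f1, f2, fca
 8-9  I_to gates r, s
10-11 I_sus gates r_sus, s_sus
12    I_Ks gate n
13    I_Kr gate p_a
14    I_f gate y
15    Na_i (mM)      16  K_i (mM)      17  Na_ss (mM, vCaNass)
18    Ca_ss (mM)
19-22 Ca_bulk shells 0..3 (mM)
23-26 Ca_SR shells 0..3 (mM)
27-30 SERCA-bound Ca: bulk units 0..2, junctional unit (mM)
31-42 RyR gates (o, c, a) for units bulk0, bulk1, bulk2, junctional
====  =========================================================

Sign conventions: membrane currents are positive outward and
dV/dt = -sum(I)/C_m.  Fluxes are in nL*mM/ms with an explicit source and
sink; a positive inter-shell diffusion flux moves Ca2+ inward (toward the
axis) when the outer concentration is higher.
"""

from __future__ import annotations

import math

import numpy as np

from .params import PIDX

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


# --- state indices ---------------------------------------------------------
IV = 0
IM, IH1, IH2 = 1, 2, 3
ID, IF1, IF2, IFCA = 4, 5, 6, 7
IR_TO, IS_TO = 8, 9
IR_SUS, IS_SUS = 10, 11
IN_KS = 12
IPA_KR = 13
IY_F = 14
INAI, IKI, INASS = 15, 16, 17
ICASS = 18
ICAB0 = 19          # 4 bulk shells
ICASR0 = 23         # 4 SR shells
ISERCA0 = 27        # 3 bulk units + junctional
IRYR0 = 31          # 4 units x (o, c, a)
N_STATES = 43
N_BULK = 4

STATE_NAMES = (
    ["V", "m", "h1", "h2", "d", "f1", "f2", "fca", "r_to", "s_to",
     "r_sus", "s_sus", "n_ks", "pa_kr", "y_f", "Na_i", "K_i", "Na_ss",
     "Ca_ss"]
    + [f"Ca_bulk{j+1}" for j in range(N_BULK)]
    + [f"Ca_sr{j+1}" for j in range(N_BULK)]
    + ["serca_ca1", "serca_ca2", "serca_ca3", "serca_ca_ss"]
    + [f"ryr_{g}{u}" for u in ("1", "2", "3", "ss") for g in ("o", "c", "a")]
)
GATE_INDICES = (IM, IH1, IH2, ID, IF1, IF2, IFCA, IR_TO, IS_TO,
                IR_SUS, IS_SUS, IN_KS, IPA_KR, IY_F)

# --- context (intervention) vector indices ---------------------------------
CTX_STIM = 0            # stimulus current (pA), nonzero while pulse is on
CTX_SCALE_SS = 1        # junctional RyR release scale (0 block, 1 control)
CTX_SCALE_B0 = 2        # bulk-unit scales, shells 0..2 (axis -> out)
CTX_CAFFEINE = 5        # 1 -> RyR held fully open everywhere
CTX_NCX_REV_BLOCK = 6   # 1 -> NCX clamped to Ca-efflux (forward) mode only
CTX_VARIANT_NASS = 7    # 1 -> subsarcolemmal Na+ compartment active
CTX_NA_CLAMP = 8        # 1 -> intracellular Na+ frozen
CTX_VM_CLAMP = 9        # 1 -> membrane potential frozen (voltage clamp)
CTX_CASS_CLAMP = 10     # 1 -> junctional Ca2+ follows analytic waveform
CTX_CASS_BASE = 11
CTX_CASS_AMP = 12       # peak-normalized amplitude (mM)
CTX_CASS_TAU_R = 13
CTX_CASS_TAU_D = 14
CTX_CASS_PERIOD = 15
CTX_CASS_T0 = 16
CTX_NCX_SCALE = 17
CTX_SERCA_SCALE = 18
CTX_PMCA_SCALE = 19
N_CTX = 20


def default_ctx() -> np.ndarray:
    ctx = np.zeros(N_CTX)
    ctx[CTX_SCALE_SS] = 1.0
    ctx[CTX_SCALE_B0:CTX_SCALE_B0 + 3] = 1.0
    ctx[CTX_NCX_SCALE] = 1.0
    ctx[CTX_SERCA_SCALE] = 1.0
    ctx[CTX_PMCA_SCALE] = 1.0
    return ctx


# Packed-parameter indices as module constants (compile-time for numba).
for _name, _i in PIDX.items():
    globals()["P_" + _name.upper()] = _i


# ===========================================================================
# Gating kinetics (x_inf dimensionless, tau in ms)
# ===========================================================================
@njit(cache=True)
def na_gates(V):
    m_inf = 1.0 / (1.0 + math.exp((V + 27.12) / -8.21))
    tau_m = 0.042 * math.exp(-(((V + 25.57) / 28.8) ** 2)) + 0.024
    h_inf = 1.0 / (1.0 + math.exp((V + 63.6) / 5.3))
    tau_h1 = 30.0 / (1.0 + math.exp((V + 35.1) / 3.2)) + 0.3
    tau_h2 = 120.0 / (1.0 + math.exp((V + 35.1) / 3.2)) + 3.0
    return m_inf, tau_m, h_inf, tau_h1, h_inf, tau_h2


@njit(cache=True)
def cal_gates(V):
    d_inf = 1.0 / (1.0 + math.exp((V + 9.0) / -5.8))
    tau_d = 2.7 * math.exp(-(((V + 35.0) / 30.0) ** 2)) + 2.0
    f_inf = 1.0 / (1.0 + math.exp((V + 27.4) / 7.1))
    # f1 time constant refit: much slower inactivation between -40 and -10 mV
    tau_f1 = 1000.0 * (
        0.98698 * math.exp(-(((V + 30.16047) / 7.09396) ** 2))
        + 0.04275 / (1.0 + math.exp((V - 51.61555) / -80.61331))
        + 0.03576 / (1.0 + math.exp((V + 29.57272) / 13.17552))
        - 0.00821
    )
    tau_f2 = 1332.3 * math.exp(-(((V + 40.0) / 14.2) ** 2)) + 62.6
    return d_inf, tau_d, f_inf, tau_f1, f_inf, tau_f2


@njit(cache=True)
def fca_gate(Cass, k_fca, n_fca):
    return 1.0 / (1.0 + (Cass / k_fca) ** n_fca)


@njit(cache=True)
def to_sus_gates(V):
    r_inf = 1.0 / (1.0 + math.exp((V - 1.0) / -11.0))
    tau_r = 3.5 * math.exp(-((V / 30.0) ** 2)) + 1.5
    s_inf = 1.0 / (1.0 + math.exp((V + 40.5) / 11.5))
    tau_s = 481.2 * math.exp(-(((V + 52.45) / 14.97) ** 2)) + 14.14
    rs_inf = 1.0 / (1.0 + math.exp((V + 4.3) / -8.0))
    tau_rs = 9.0 / (1.0 + math.exp((V + 5.0) / 12.0)) + 0.5
    ss_inf = 0.4 / (1.0 + math.exp((V + 20.0) / 10.0)) + 0.6
    tau_ss = 47.0 / (1.0 + math.exp((V + 60.0) / 10.0)) + 300.0
    return r_inf, tau_r, s_inf, tau_s, rs_inf, tau_rs, ss_inf, tau_ss


@njit(cache=True)
def ks_kr_gates(V):
    n_inf = 1.0 / (1.0 + math.exp((V - 19.9) / -12.7))
    tau_n = 700.0 + 400.0 * math.exp(-(((V - 20.0) / 20.0) ** 2))
    pa_inf = 1.0 / (1.0 + math.exp((V + 15.0) / -6.0))
    tau_pa = 31.18 + 217.18 * math.exp(-(((V + 20.1376) / 22.1996) ** 2))
    return n_inf, tau_n, pa_inf, tau_pa


@njit(cache=True)
def f_gate(V):
    y_inf = 1.0 / (1.0 + math.exp((V + 97.82874) / 12.48025))
    tau_y = 1000.0 / (0.00332 * math.exp(-V / 16.54103)
                      + 23.71839 * math.exp(V / 16.54103))
    return y_inf, tau_y


# ===========================================================================
# Membrane currents (pA, outward positive)
# ===========================================================================
@njit(cache=True)
def i_na(V, m, h1, h2, Na_in, p):
    RTF = p[P_RTF]
    E_Na = RTF * math.log(p[P_NA_O] / Na_in)
    vn = V / RTF
    if abs(vn) < 1e-7:
        vn = 1e-7
    ratio = (math.exp((V - E_Na) / RTF) - 1.0) / (math.exp(vn) - 1.0)
    return p[P_P_NA] * p[P_NA_O] * p[P_F] * vn * ratio * m**3 * (0.9 * h1 + 0.1 * h2)


@njit(cache=True)
def i_cal(V, d, f1, f2, fca, p):
    return p[P_G_CAL] * d * fca * f1 * f2 * (V - p[P_E_CA_APP])


@njit(cache=True)
def i_k(V, r_to, s_to, r_sus, s_sus, n_ks, pa_kr, y_f, K_i, Na_in, p):
    RTF = p[P_RTF]
    E_K = RTF * math.log(p[P_K_O] / K_i)
    E_Na = RTF * math.log(p[P_NA_O] / Na_in)
    I_to = p[P_G_TO] * r_to * s_to * (V - E_K)
    I_sus = p[P_G_SUS] * r_sus * s_sus * (V - E_K)
    I_Ks = p[P_G_KS] * n_ks * (V - E_K)
    pi_kr = 1.0 / (1.0 + math.exp((V + 55.0) / 24.0))
    I_Kr = p[P_G_KR] * pa_kr * pi_kr * (V - E_K)
    I_K1 = (p[P_G_K1] * p[P_K_O] ** 0.4457 * (V - E_K)
            / (1.0 + math.exp(1.5 * (V - E_K + 3.6) / RTF)))
    I_fNa = p[P_G_F] * y_f * p[P_F_F_NA] * (V - E_Na)
    I_fK = p[P_G_F] * y_f * (1.0 - p[P_F_F_NA]) * (V - E_K)
    return I_to, I_sus, I_Ks, I_Kr, I_K1, I_fNa, I_fK


@njit(cache=True)
def i_nak(V, Na_in, p):
    na15 = Na_in ** 1.5
    return (p[P_I_NAK_MAX] * p[P_K_O] / (p[P_K_O] + p[P_K_NAK_K])
            * na15 / (na15 + p[P_K_NAK_NA] ** 1.5)
            * (V + 150.0) / (V + 200.0))


@njit(cache=True)
def i_ncx(V, Na_in, Ca_ss, p, scale, reverse_block):
    RTF = p[P_RTF]
    g = p[P_GAMMA_NCX]
    num = (Na_in**3 * p[P_CA_O] * math.exp(g * V / RTF)
           - p[P_NA_O] ** 3 * Ca_ss * math.exp((g - 1.0) * V / RTF))
    den = 1.0 + p[P_D_NCX] * (p[P_NA_O] ** 3 * Ca_ss + Na_in**3 * p[P_CA_O])
    I = scale * p[P_K_NCX] * num / den
    if reverse_block > 0.5 and I > 0.0:
        # outward current = net Ca2+ influx (reverse mode) -> clamped off
        I = 0.0
    return I


@njit(cache=True)
def i_pmca(Ca_ss, p, scale):
    return scale * p[P_I_PMCA_MAX] * Ca_ss / (Ca_ss + p[P_K_PMCA])


@njit(cache=True)
def i_background(V, Na_in, Ca_ss, p):
    RTF = p[P_RTF]
    E_Na = RTF * math.log(p[P_NA_O] / Na_in)
    E_Ca = 0.5 * RTF * math.log(p[P_CA_O] / Ca_ss)
    return p[P_G_NAB] * (V - E_Na), p[P_G_CAB] * (V - E_Ca)


# ===========================================================================
# Ca2+ subsystem kernels
# ===========================================================================
@njit(cache=True)
def ryr_steady_states(Ca_cyto, Ca_sr, a, p):
    """RyR gate targets.  Ca_cyto in mM (converted to uM inside)."""
    cai = Ca_cyto * 1000.0
    a_inf = p[P_RYR_A_BASE] - p[P_RYR_A_AMP] / (
        1.0 + math.exp((cai - p[P_RYR_A_MID]) / p[P_RYR_A_SLOPE]))
    o_inf = 1.0 - 1.0 / (
        1.0 + math.exp((cai - (a + p[P_RYR_O_SHIFT])) / p[P_RYR_O_SLOPE]))
    c_inf = 1.0 / (
        1.0 + math.exp((cai - (a + p[P_RYR_C_SHIFT])) / p[P_RYR_C_SLOPE]))
    srca = 1.0 - 1.0 / (
        1.0 + math.exp((Ca_sr - p[P_RYR_SRCA_MID]) / p[P_RYR_SRCA_SLOPE]))
    return o_inf, c_inf, a_inf, srca


@njit(cache=True)
def serca_rates(Ca_cyto, Ca_sr, A, p, scale):
    """Two-step SERCA: cytosol->pump and pump->SR rates (mM/ms per unit volume,
    before the x2 Ca-per-cycle factor)."""
    free = p[P_SERCA_CPUMPS] - A
    r_in = scale * (p[P_SERCA_K1] * Ca_cyto**2 * free - p[P_SERCA_K2] * A)
    r_out = scale * (p[P_SERCA_K4] * A - p[P_SERCA_K3] * Ca_sr**2 * free)
    return r_in, r_out


@njit(cache=True)
def buffer_factors(Cass, Ca, CaSR, p, beta_bulk, beta_sr):
    """Rapid-equilibrium buffering factors for subspace / bulk / SR."""
    b = 1.0 + (p[P_SLLOW] * p[P_K_DSLLOW] / (p[P_K_DSLLOW] + Cass) ** 2
               + p[P_SLHIGH] * p[P_K_DSLHIGH] / (p[P_K_DSLHIGH] + Cass) ** 2
               + p[P_BCA] * p[P_K_DBCA] / (p[P_K_DBCA] + Cass) ** 2)
    beta_ss = 1.0 / b
    for j in range(N_BULK):
        beta_bulk[j] = 1.0 / (
            1.0 + p[P_BCA] * p[P_K_DBCA] / (p[P_K_DBCA] + Ca[j]) ** 2)
        beta_sr[j] = 1.0 / (
            1.0 + p[P_CSQN] * p[P_K_DCSQN] / (p[P_K_DCSQN] + CaSR[j]) ** 2)
    return beta_ss


@njit(cache=True)
def clamp_waveform(t, ctx):
    """Analytic junctional Ca2+ waveform: base + amp*(exp(-t/td)-exp(-t/tr)),
    peak-normalized, periodic with the pacing cycle."""
    tw = (t - ctx[CTX_CASS_T0]) % ctx[CTX_CASS_PERIOD]
    tr = ctx[CTX_CASS_TAU_R]
    td = ctx[CTX_CASS_TAU_D]
    tpk = math.log(td / tr) * tr * td / (td - tr)
    norm = math.exp(-tpk / td) - math.exp(-tpk / tr)
    shape = (math.exp(-tw / td) - math.exp(-tw / tr)) / norm
    return ctx[CTX_CASS_BASE] + ctx[CTX_CASS_AMP] * shape


# ===========================================================================
# Full RHS
# ===========================================================================
@njit(cache=True)
def rhs_core(t, y, p, ctx, vb, vsr, af):
    """dy/dt (1/ms).  vb, vsr: accessible shell volumes (nL); af: accessible
    interface areas between shells (um^2), axis -> membrane."""
    dy = np.zeros(N_STATES)

    V = y[IV]
    Na_i = y[INAI]
    K_i = y[IKI]
    variant_nass = ctx[CTX_VARIANT_NASS] > 0.5
    Na_mem = y[INASS] if variant_nass else Na_i

    Cass = y[ICASS]
    if ctx[CTX_CASS_CLAMP] > 0.5:
        Cass = clamp_waveform(t, ctx)

    Ca = y[ICAB0:ICAB0 + N_BULK]
    CaSR = y[ICASR0:ICASR0 + N_BULK]

    # ---- gating ----
    m_inf, tau_m, h1_inf, tau_h1, h2_inf, tau_h2 = na_gates(V)
    dy[IM] = (m_inf - y[IM]) / tau_m
    dy[IH1] = (h1_inf - y[IH1]) / tau_h1
    dy[IH2] = (h2_inf - y[IH2]) / tau_h2

    d_inf, tau_d, f1_inf, tau_f1, f2_inf, tau_f2 = cal_gates(V)
    dy[ID] = (d_inf - y[ID]) / tau_d
    dy[IF1] = (f1_inf - y[IF1]) / tau_f1
    dy[IF2] = (f2_inf - y[IF2]) / tau_f2
    fca_inf = fca_gate(Cass, p[P_K_FCA], p[P_N_FCA])
    dy[IFCA] = (fca_inf - y[IFCA]) / p[P_TAU_FCA]

    r_inf, tau_r, s_inf, tau_s, rs_inf, tau_rs, ss_inf, tau_ss = to_sus_gates(V)
    dy[IR_TO] = (r_inf - y[IR_TO]) / tau_r
    dy[IS_TO] = (s_inf - y[IS_TO]) / tau_s
    dy[IR_SUS] = (rs_inf - y[IR_SUS]) / tau_rs
    dy[IS_SUS] = (ss_inf - y[IS_SUS]) / tau_ss

    n_inf, tau_n, pa_inf, tau_pa = ks_kr_gates(V)
    dy[IN_KS] = (n_inf - y[IN_KS]) / tau_n
    dy[IPA_KR] = (pa_inf - y[IPA_KR]) / tau_pa

    y_inf, tau_y = f_gate(V)
    dy[IY_F] = (y_inf - y[IY_F]) / tau_y

    # ---- membrane currents ----
    I_Na = i_na(V, y[IM], y[IH1], y[IH2], Na_mem, p)
    I_CaL = i_cal(V, y[ID], y[IF1], y[IF2], y[IFCA], p)
    I_to, I_sus, I_Ks, I_Kr, I_K1, I_fNa, I_fK = i_k(
        V, y[IR_TO], y[IS_TO], y[IR_SUS], y[IS_SUS], y[IN_KS], y[IPA_KR],
        y[IY_F], K_i, Na_mem, p)
    I_NaK = i_nak(V, Na_mem, p)
    I_NCX = i_ncx(V, Na_mem, Cass, p, ctx[CTX_NCX_SCALE],
                  ctx[CTX_NCX_REV_BLOCK])
    I_PMCA = i_pmca(Cass, p, ctx[CTX_PMCA_SCALE])
    I_Nab, I_Cab = i_background(V, Na_mem, Cass, p)
    I_stim = ctx[CTX_STIM]

    I_tot = (I_Na + I_CaL + I_to + I_sus + I_Ks + I_Kr + I_K1 + I_fNa + I_fK
             + I_NaK + I_NCX + I_PMCA + I_Nab + I_Cab + I_stim)
    if ctx[CTX_VM_CLAMP] > 0.5:
        dy[IV] = 0.0
    else:
        dy[IV] = -I_tot / p[P_C_M] * 1e-3

    # ---- RyR units ----
    caffeine = ctx[CTX_CAFFEINE] > 0.5
    J_rel = np.zeros(N_BULK)          # bulk shells 0..2 (3 stays 0)
    serca_scale = ctx[CTX_SERCA_SCALE]
    J_up_in = np.zeros(N_BULK)        # cytosol -> pump, per unit shell
    J_up_out = np.zeros(N_BULK)       # pump -> SR
    for u in range(3):                # bulk release units on shells 0..2
        io = IRYR0 + 3 * u
        o = y[io]
        c = y[io + 1]
        a = y[io + 2]
        o_inf, c_inf, a_inf, srca = ryr_steady_states(Ca[u], CaSR[u], a, p)
        dy[io] = (o_inf - o) / p[P_RYR_TAU_ACT_BULK]
        dy[io + 1] = (c_inf - c) / p[P_RYR_TAU_INACT_BULK]
        dy[io + 2] = (a_inf - a) / p[P_RYR_TAU_ADAPT]
        popen = 1.0 if caffeine else o * c * srca
        J_rel[u] = (ctx[CTX_SCALE_B0 + u] * p[P_RYR_NU_BULK] * vb[u]
                    * popen * (CaSR[u] - Ca[u]))
        r_in, r_out = serca_rates(Ca[u], CaSR[u], y[ISERCA0 + u], p, serca_scale)
        J_up_in[u] = r_in * vb[u] * 2.0
        J_up_out[u] = r_out * vb[u] * 2.0
        dy[ISERCA0 + u] = 0.5 * (r_in - r_out) * 2.0

    # junctional unit (uses outermost SR shell)
    io = IRYR0 + 9
    o = y[io]
    c = y[io + 1]
    a = y[io + 2]
    o_inf, c_inf, a_inf, srca = ryr_steady_states(Cass, CaSR[3], a, p)
    dy[io] = (o_inf - o) / p[P_RYR_TAU_ACT_SS]
    dy[io + 1] = (c_inf - c) / p[P_RYR_TAU_INACT_SS]
    dy[io + 2] = (a_inf - a) / p[P_RYR_TAU_ADAPT]
    popen = 1.0 if caffeine else o * c * srca
    J_rel_ss = (ctx[CTX_SCALE_SS] * p[P_RYR_NU_SS] * p[P_V_SS]
                * popen * (CaSR[3] - Cass))
    r_in, r_out = serca_rates(Cass, CaSR[3], y[ISERCA0 + 3], p, serca_scale)
    J_up_in_ss = r_in * p[P_V_SS] * 2.0
    J_up_out_ss = r_out * p[P_V_SS] * 2.0
    dy[ISERCA0 + 3] = 0.5 * (r_in - r_out) * 2.0

    # ---- SR leak ----
    J_leak = np.zeros(N_BULK)
    for u in range(3):
        J_leak[u] = p[P_K_SRLEAK] * (CaSR[u] - Ca[u]) * vb[u]
    J_leak_ss = p[P_K_SRLEAK] * (CaSR[3] - Cass) * p[P_V_SS]

    # ---- buffering factors ----
    beta_bulk = np.zeros(N_BULK)
    beta_sr = np.zeros(N_BULK)
    beta_ss = buffer_factors(Cass, Ca, CaSR, p, beta_bulk, beta_sr)

    # ---- diffusion (finite volume; fluxes carry free Ca + mobile complex) --
    dr = p[P_DR]
    dca = p[P_D_CA]
    dcab = p[P_D_CABM]
    dcasr = p[P_D_CASR]
    kd = p[P_K_DBCA]
    bca = p[P_BCA]
    net_bulk = np.zeros(N_BULK)
    net_sr = np.zeros(N_BULK)
    srf = vsr[0] / vb[0]          # SR/bulk volume (and face-area) fraction
    for j in range(N_BULK - 1):
        cb_lo = bca * Ca[j] / (kd + Ca[j])
        cb_hi = bca * Ca[j + 1] / (kd + Ca[j + 1])
        flux = af[j] * (dca * (Ca[j + 1] - Ca[j])
                        + dcab * (cb_hi - cb_lo)) / dr * 1e-6
        net_bulk[j] += flux
        net_bulk[j + 1] -= flux
        srflux = af[j] * srf * dcasr * (CaSR[j + 1] - CaSR[j]) / dr * 1e-6
        net_sr[j] += srflux
        net_sr[j + 1] -= srflux

    # junctional <-> outermost bulk shell exchange
    J_ss_bulk = (p[P_A_SS_BULK] * dca / p[P_X_SS_BULK]
                 * (Cass - Ca[N_BULK - 1]) * 1e-6)

    # ---- bulk / SR Ca2+ balance ----
    for j in range(N_BULK):
        tot = net_bulk[j] + J_rel[j] - J_up_in[j] + J_leak[j]
        if j == N_BULK - 1:
            tot += J_ss_bulk
        dy[ICAB0 + j] = beta_bulk[j] * tot / vb[j]

        sr_tot = net_sr[j] - J_rel[j] + J_up_out[j] - J_leak[j]
        if j == N_BULK - 1:
            sr_tot += -J_rel_ss + J_up_out_ss - J_leak_ss
        dy[ICASR0 + j] = beta_sr[j] * sr_tot / vsr[j]

    # ---- junctional subspace Ca2+ ----
    F = p[P_F]
    J_ca_mem = -(I_CaL + I_Cab + I_PMCA - 2.0 * I_NCX) * 1e-3 / (2.0 * F)
    if ctx[CTX_CASS_CLAMP] > 0.5:
        dy[ICASS] = 0.0
    else:
        dy[ICASS] = beta_ss * (
            -J_ss_bulk + J_rel_ss - J_up_in_ss + J_leak_ss + J_ca_mem
        ) / p[P_V_SS]

    # ---- Na+ / K+ bookkeeping ----
    I_Na_tot = I_Na + I_Nab + 3.0 * I_NaK + 3.0 * I_NCX + I_fNa
    I_K_tot = (I_to + I_sus + I_K1 + I_Kr + I_Ks + I_fK - 2.0 * I_NaK
               + I_stim)
    V_cyt = p[P_V_CYTOSOL]
    if ctx[CTX_NA_CLAMP] > 0.5:
        dy[INAI] = 0.0
        dy[INASS] = 0.0
    elif variant_nass:
        V_bulk_tot = V_cyt - p[P_V_SS]
        J_na = (p[P_D_NA] * p[P_A_SS_BULK] / p[P_X_SS_BULK_NA]
                * (y[INASS] - Na_i) * 1e-6)
        dy[INASS] = -I_Na_tot * 1e-3 / (F * p[P_V_SS]) - J_na / p[P_V_SS]
        dy[INAI] = J_na / V_bulk_tot
    else:
        dy[INAI] = -I_Na_tot * 1e-3 / (F * V_cyt)
        dy[INASS] = 0.0
    dy[IKI] = -I_K_tot * 1e-3 / (F * V_cyt)

    return dy


@njit(cache=True)
def compute_currents_core(t, y, p, ctx):
    """Instantaneous membrane currents (pA) for a single state sample."""
    V = y[IV]
    Na_i = y[INAI]
    Na_mem = y[INASS] if ctx[CTX_VARIANT_NASS] > 0.5 else Na_i
    Cass = y[ICASS]
    if ctx[CTX_CASS_CLAMP] > 0.5:
        Cass = clamp_waveform(t, ctx)
    I_Na = i_na(V, y[IM], y[IH1], y[IH2], Na_mem, p)
    I_CaL = i_cal(V, y[ID], y[IF1], y[IF2], y[IFCA], p)
    I_to, I_sus, I_Ks, I_Kr, I_K1, I_fNa, I_fK = i_k(
        V, y[IR_TO], y[IS_TO], y[IR_SUS], y[IS_SUS], y[IN_KS], y[IPA_KR],
        y[IY_F], y[IKI], Na_mem, p)
    I_NaK = i_nak(V, Na_mem, p)
    I_NCX = i_ncx(V, Na_mem, Cass, p, ctx[CTX_NCX_SCALE],
                  ctx[CTX_NCX_REV_BLOCK])
    I_PMCA = i_pmca(Cass, p, ctx[CTX_PMCA_SCALE])
    I_Nab, I_Cab = i_background(V, Na_mem, Cass, p)
    return (I_Na, I_CaL, I_to, I_sus, I_Kr, I_Ks, I_K1, I_fNa + I_fK,
            I_NaK, I_NCX, I_PMCA, I_Nab, I_Cab, I_fNa, I_fK)


CURRENT_NAMES = ("I_Na", "I_CaL", "I_to", "I_sus", "I_Kr", "I_Ks", "I_K1",
                 "I_f", "I_NaK", "I_NCX", "I_PMCA", "I_Nab", "I_Cab",
                 "I_fNa", "I_fK")
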