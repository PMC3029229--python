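"""Declarative virtual experiments.

Each protocol function builds a segment schedule, runs the engine and
returns traces plus protocol-specific measurements.  All protocols accept a
``Protocol`` description (serializable) or keyword arguments; results are
deterministic for identical inputs.

Conventions used throughout:

* "steady state" means starting from the cached 1 Hz paced state of the
  requested variant (see :func:`atriasim.state.default_initial_state`).
* release-site block targets: ``junctional`` (subspace unit), ``bulk``
  (all three non-junctional units), ``all``.
* the caffeine pulse is applied under voltage clamp at the holding
  potential, mirroring the experimental configuration it reproduces; RyR
  units are held fully open for the pulse duration and the NCX current is
  integrated over the evoked transient against its post-transient plateau.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from . import rhs as R
from . import metrics as M
from .engine import (Segment, SolverConfig, Trace, integrate_segments, pace,
                     pacing_segments, STIM_AMPLITUDE, STIM_DURATION)
from .params import Parameters
from .state import default_initial_state, quiescent_state

BLOCK_TARGETS = ("junctional", "bulk", "all")
PROTOCOL_KINDS = ("steady_pacing", "vclamp", "caffeine", "release_block",
                  "release_scale", "ca_clamp", "na_clamp", "rate_staircase",
                  "long_pacing", "ext_ca_step", "s1s2", "frequency_staircase")


@dataclass(frozen=True)
class Protocol:
    """Serializable description of a virtual experiment."""

    kind: str = "steady_pacing"
    frequency_hz: float = 1.0
    n_beats: int = 5
    bcl_list: tuple = ()
    step_duration_ms: float = 60_000.0
    block_target: str = "all"
    t_on_ms: float = 1000.0
    scale: float = 1.0
    s2_interval_ms: float | None = None
    clamp_mode: str = "decay_normal"
    na_clamp_mm: float | None = None
    ca_o_mm: float | None = None
    ncx_reverse_block: bool = False
    variant: str = "vCa"
    stim_amp_pA: float = STIM_AMPLITUDE
    stim_dur_ms: float = STIM_DURATION

    def __post_init__(self):
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.block_target not in BLOCK_TARGETS:
            raise ValueError(f"invalid block target {self.block_target!r}")
        if self.n_beats <= 0 or self.step_duration_ms <= 0:
            raise ValueError("durations must be positive")
        if any(b <= 0 for b in self.bcl_list):
            raise ValueError("BCL list must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _run_config(params, solver):
    return params or Parameters(), solver or SolverConfig()


# ---------------------------------------------------------------------------
# Basic pacing
# ---------------------------------------------------------------------------
def steady_pacing(freq_hz: float = 1.0, n_beats: int = 5,
                  variant: str = "vCa", y0=None,
                  params: Parameters | None = None,
                  solver: SolverConfig | None = None,
                  base_ctx: np.ndarray | None = None,
                  stim_amp: float = STIM_AMPLITUDE) -> Trace:
    """Pace at a fixed frequency from the cached steady state (or ``y0``)."""
    params, solver = _run_config(params, solver)
    if y0 is None:
        y0 = default_initial_state(variant)
    bcl = 1000.0 / freq_hz
    return pace(y0, bcl, n_beats, base_ctx=base_ctx, params=params,
                solver=solver, variant=variant, stim_amp=stim_amp)


# ---------------------------------------------------------------------------
# Release-site interventions
# ---------------------------------------------------------------------------
def _block_ctx(target: str, scale: float = 0.0) -> np.ndarray:
    ctx = R.default_ctx()
    if target in ("junctional", "all"):
        ctx[R.CTX_SCALE_SS] = scale
    if target in ("bulk", "all"):
        ctx[R.CTX_SCALE_B0:R.CTX_SCALE_B0 + 3] = scale
    return ctx


def release_block(target: str = "all", t_on: float = 1000.0,
                  n_beats: int = 6, bcl: float = 1000.0,
                  variant: str = "vCa", y0=None,
                  params: Parameters | None = None,
                  solver: SolverConfig | None = None) -> dict:
    """Block RyR release (junctional / bulk / all units) during pacing.

    Pacing starts from steady state; the targeted release scales are set to
    zero from ``t_on`` onward.  Returns control and intervention traces plus
    the relative amplitude/APD90 changes, averaged over blocked beats 2-5
    (under junctional block the model settles into mild beat-to-beat
    alternation of autonomous bulk firing, so a beat average is reported).
    """
    if target not in BLOCK_TARGETS:
        raise ValueError(f"invalid block target {target!r}")
    params, solver = _run_config(params, solver)
    if y0 is None:
        y0 = default_initial_state(variant)
    n_pre = max(int(round(t_on / bcl)), 1)
    segs_pre, on_pre = pacing_segments(bcl, n_pre, solver=solver)
    segs_post, on_post = pacing_segments(
        bcl, n_beats, base_ctx=_block_ctx(target), t0=n_pre * bcl,
        solver=solver)
    blocked = integrate_segments(y0, segs_pre + segs_post, params=params,
                                 solver=solver, variant=variant,
                                 stim_times=on_pre + on_post)
    control = pace(y0, bcl, n_pre + n_beats, params=params, solver=solver,
                   variant=variant)
    amp_c = M.ca_metrics(control, beat=n_pre).amplitude
    apd_c = M.ap_metrics(control, beat=n_pre).APD90
    beats = [n_pre + b for b in (1, 2, 3, 4) if b < n_beats]
    amp_red = float(np.mean(
        [100.0 * (1 - M.ca_metrics(blocked, beat=b).amplitude / amp_c)
         for b in beats]))
    apd_red = float(np.mean(
        [100.0 * (1 - M.ap_metrics(blocked, beat=b).APD90 / apd_c)
         for b in beats]))
    return {"control": control, "blocked": blocked,
            "amplitude_reduction_pct": amp_red,
            "apd90_reduction_pct": apd_red}


def release_scale(factor: float, s1s2_interval: float | None = None,
                  n_beats: int = 4, bcl: float = 1000.0,
                  variant: str = "vCa", y0=None,
                  params: Parameters | None = None,
                  solver: SolverConfig | None = None) -> Trace:
    """Scale all RyR release (0 = block, 1 = control, 3 = triple release).

    With ``s1s2_interval`` set, a premature S2 stimulus is applied that long
    after the last regular S1 stimulus (refractoriness test).
    """
    if factor < 0:
        raise ValueError("release scale must be >= 0")
    params, solver = _run_config(params, solver)
    if y0 is None:
        y0 = default_initial_state(variant)
    ctx = _block_ctx("all", scale=factor)
    segs, onsets = pacing_segments(bcl, n_beats, base_ctx=ctx, solver=solver)
    if s1s2_interval is not None:
        t2 = (n_beats - 1) * bcl + s1s2_interval
        stim_ctx = ctx.copy()
        stim_ctx[R.CTX_STIM] = STIM_AMPLITUDE
        # carve the S2 stimulus out of the final cycle
        last = segs[-1]
        segs[-1] = Segment(last.t0, t2, last.ctx, last.sample_ms)
        segs.append(Segment(t2, t2 + STIM_DURATION, stim_ctx,
                            solver.fine_sample_ms))
        segs.append(Segment(t2 + STIM_DURATION, t2 + STIM_DURATION + 15.0,
                            ctx.copy(), solver.fine_sample_ms))
        segs.append(Segment(t2 + STIM_DURATION + 15.0, n_beats * bcl + 600.0,
                            ctx.copy(), solver.sample_ms))
        onsets = onsets + [t2]
    return integrate_segments(y0, segs, params=params, solver=solver,
                              variant=variant, stim_times=onsets)


# ---------------------------------------------------------------------------
# Caffeine pulse
# ---------------------------------------------------------------------------
def caffeine_pulse(duration: float = 1000.0, hold_mv: float = -80.0,
                   window: float = 6000.0, variant: str = "vCa", y0=None,
                   params: Parameters | None = None,
                   solver: SolverConfig | None = None) -> dict:
    """Caffeine application from 1 Hz steady-state diastole.

    Pacing is stopped, the membrane is clamped at ``hold_mv`` and all RyR
    units are held fully open for ``duration`` ms.  Returns the trace and
    the NCX current integral over the evoked transient (amol of Ca2+ per pF;
    3Na:1Ca stoichiometry, i.e. +1 net charge per extruded Ca2+).
    """
    params, solver = _run_config(params, solver)
    if y0 is None:
        y0 = default_initial_state(variant)
    y0 = np.asarray(y0, float).copy()
    y0[R.IV] = hold_mv
    ctx_on = R.default_ctx()
    ctx_on[R.CTX_CAFFEINE] = 1.0
    ctx_on[R.CTX_VM_CLAMP] = 1.0
    ctx_off = R.default_ctx()
    ctx_off[R.CTX_VM_CLAMP] = 1.0
    segs = [Segment(0.0, duration, ctx_on, 1.0),
            Segment(duration, window, ctx_off, 1.0)]
    tr = integrate_segments(y0, segs, params=params, solver=solver,
                            variant=variant)
    incx = tr.currents()["I_NCX"].to_numpy()
    baseline = incx[-1]                      # post-transient plateau
    charge_pA_ms = -float(np.trapezoid(incx - baseline, tr.t))
    # pA*ms = 1e-15 C; /F -> mol; 1 amol = 1e-18 mol
    amol = charge_pA_ms * 1e-15 / params.constants.F * 1e18
    amol_per_pf = amol / (params.C_m * 1e3)
    return {"trace": tr, "ncx_integral_amol_per_pF": amol_per_pf}


# ---------------------------------------------------------------------------
# Junctional Ca2+ clamp (analytic waveform)
# ---------------------------------------------------------------------------
CA_CLAMP_MODES = ("decay_slow", "decay_normal", "decay_fast",
                  "amp_low", "amp_normal", "amp_high")


def fit_cass_waveform(tr: Trace, bcl: float = 1000.0) -> dict:
    """Fit base + amp*(exp(-t/tau_d) - exp(-t/tau_r)) (peak-normalized) to
    the junctional Ca2+ transient of the final beat of ``tr``."""
    t0 = tr.stim_times[-1]
    m = tr.t >= t0
    t = tr.t[m] - t0
    ca = tr.ca_ss()[m]

    def model(tt, base, amp, tau_r, tau_d):
        tpk = math.log(tau_d / tau_r) * tau_r * tau_d / (tau_d - tau_r)
        norm = math.exp(-tpk / tau_d) - math.exp(-tpk / tau_r)
        return base + amp * (np.exp(-tt / tau_d) - np.exp(-tt / tau_r)) / norm

    p0 = (float(ca.min()), float(ca.max() - ca.min()), 15.0, 200.0)
    popt, _ = curve_fit(model, t, ca, p0=p0, maxfev=40000)
    base, amp, tau_r, tau_d = map(float, popt)
    return {"base": base, "amp": amp, "tau_rise": tau_r, "tau_decay": tau_d,
            "period": bcl, "t0": 0.0}


def ca_clamp(mode: str = "decay_normal", n_beats: int = 4,
             bcl: float = 1000.0, variant: str = "vCa", y0=None,
             waveform: dict | None = None,
             params: Parameters | None = None,
             solver: SolverConfig | None = None) -> Trace:
    """Replace junctional [Ca2+] with an analytic rise/decay waveform.

    Decay modes scale the decay time constant (x2 slowed / x0.5 accelerated);
    amplitude modes scale the peak (x0.5 / x1.5).  The control waveform is
    fitted to a steady-pacing run unless ``waveform`` is supplied.
    """
    if mode not in CA_CLAMP_MODES:
        raise ValueError(f"unknown clamp mode {mode!r}")
    params, solver = _run_config(params, solver)
    if y0 is None:
        y0 = default_initial_state(variant)
    if waveform is None:
        ctl = steady_pacing(1000.0 / bcl, 3, variant, y0, params, solver)
        waveform = fit_cass_waveform(ctl, bcl)
    w = dict(waveform)
    if mode == "decay_slow":
        w["tau_decay"] *= 2.0
    elif mode == "decay_fast":
        w["tau_decay"] *= 0.5
    elif mode == "amp_low":
        w["amp"] *= 0.5
    elif mode == "amp_high":
        w["amp"] *= 1.5
    ctx = R.default_ctx()
    ctx[R.CTX_CASS_CLAMP] = 1.0
    ctx[R.CTX_CASS_BASE] = w["base"]
    ctx[R.CTX_CASS_AMP] = w["amp"]
    ctx[R.CTX_CASS_TAU_R] = w["tau_rise"]
    ctx[R.CTX_CASS_TAU_D] = w["tau_decay"]
    ctx[R.CTX_CASS_PERIOD] = w["period"]
    ctx[R.CTX_CASS_T0] = 0.0
    return steady_pacing(1000.0 / bcl, n_beats, variant, y0, params, solver,
                         base_ctx=ctx)


# ---------------------------------------------------------------------------
# Rate dependence
# ---------------------------------------------------------------------------
def rate_staircase(bcl_list: Sequence[float] = (1600, 1200, 800, 600, 400, 300),
                   step_duration: float = 60_000.0,
                   mode: str = "staircase",
                   na_clamp: float | None = None,
                   variant: str = "vCa", y0=None,
                   params: Parameters | None = None,
                   solver: SolverConfig | None = None) -> dict:
    """APD rate dependence over a list of basic cycle lengths.

    ``mode="staircase"``: BCLs applied consecutively (stepwise reduction),
    metrics from the final beat of each step.  ``mode="independent"``: each
    BCL run separately from the same starting state for ``step_duration``.
    ``na_clamp`` freezes intracellular Na+ at the given value (mM).
    Capture failures are flagged per BCL rather than raised.
    """
    if mode not in ("staircase", "independent"):
        raise ValueError(f"unknown staircase mode {mode!r}")
    params, solver = _run_config(params, solver)
    if y0 is None:
        # rate-dependence runs start from the quiescent steady state
        y0 = quiescent_state(variant)
    y0 = np.asarray(y0, float).copy()
    base_ctx = R.default_ctx()
    if na_clamp is not None:
        base_ctx[R.CTX_NA_CLAMP] = 1.0
        y0[R.INAI] = na_clamp
        y0[R.INASS] = na_clamp
    rows = []
    y = y0.copy()
    for bcl in bcl_list:
        n = max(int(round(step_duration / bcl)), 2)
        start = y0.copy() if mode == "independent" else y
        tr = pace(start, bcl, n, base_ctx=base_ctx, params=params,
                  solver=solver, variant=variant)
        y = tr.Y[-1]
        row = {"bcl": float(bcl), "Na_i": float(y[R.INAI]),
               "Na_ss": float(y[R.INASS]), "captured": True,
               "APD30": np.nan, "APD90": np.nan}
        # capture requires a normal AP on every one of the last 5 beats
        check = range(max(n - 5, 0), n)
        try:
            for b in check:
                ap = M.ap_metrics(tr, beat=b)
            row["APD30"], row["APD90"] = ap.APD30, ap.APD90
        except M.NoAPError:
            row["captured"] = False
        rows.append(row)
    return {"per_bcl": rows, "mode": mode, "variant": variant}


def frequency_staircase_ca(freqs_hz: Sequence[float] = (1.0, 2.0, 3.0),
                           step_duration: float = 300_000.0,
                           ncx_reverse_block: bool = False,
                           variant: str = "vCaNass", y0=None,
                           params: Parameters | None = None,
                           solver: SolverConfig | None = None) -> dict:
    """Continuous frequency staircase; reports the mean-cytosolic-Ca2+
    peak time (ms after stimulus) of the final beat at each frequency."""
    params, solver = _run_config(params, solver)
    if y0 is None:
        y0 = default_initial_state(variant)
    ctx = R.default_ctx()
    if ncx_reverse_block:
        ctx[R.CTX_NCX_REV_BLOCK] = 1.0
    y = np.asarray(y0, float).copy()
    peak_times = {}
    for f in freqs_hz:
        bcl = 1000.0 / f
        n = max(int(round(step_duration / bcl)), 2)
        tr = pace(y, bcl, n, base_ctx=ctx, params=params, solver=solver,
                  variant=variant)
        y = tr.Y[-1]
        peak_times[f] = ca_peak_time(tr)
    return {"peak_time_ms": peak_times, "ncx_reverse_block": ncx_reverse_block}


def ca_peak_time(tr: Trace, beat: int = -1) -> float:
    """Time from stimulus to the mean-cytosolic-Ca2+ peak, refined by a
    local parabolic fit (sub-sample resolution)."""
    t0 = tr.stim_times[beat]
    m = tr.t >= t0
    t = tr.t[m] - t0
    ca = M.mean_cytosolic_ca(tr)[m]
    i = int(np.argmax(ca))
    sl = slice(max(i - 3, 0), min(i + 4, len(t)))
    if sl.stop - sl.start < 3:
        return float(t[i])
    coef = np.polyfit(t[sl], ca[sl], 2)
    return float(-coef[1] / (2 * coef[0]))


def ncx_reverse_block_delay(freq_hz: float = 1.0, n_beats: int = 3,
                            variant: str = "vCa", y0=None,
                            params: Parameters | None = None,
                            solver: SolverConfig | None = None) -> dict:
    """Delay of the Ca2+ transient peak caused by blocking reverse-mode NCX
    at a fixed pacing rate (matched runs from the same steady state)."""
    params, solver = _run_config(params, solver)
    if y0 is None:
        y0 = default_initial_state(variant)
    ctl = steady_pacing(freq_hz, n_beats, variant, y0, params, solver)
    ctx = R.default_ctx()
    ctx[R.CTX_NCX_REV_BLOCK] = 1.0
    blk = steady_pacing(freq_hz, n_beats, variant, y0, params, solver,
                        base_ctx=ctx)
    tc, tb = ca_peak_time(ctl), ca_peak_time(blk)
    return {"control_peak_ms": tc, "blocked_peak_ms": tb,
            "delay_ms": tb - tc}


def reduced_extrusion_scenario(scale: float = 0.33, n_beats: int = 4,
                               variant: str = "vCa", y0=None,
                               params: Parameters | None = None,
                               solver: SolverConfig | None = None) -> Trace:
    """Canned demonstration: NCX, SERCA and PMCA maxima scaled (default to
    33% of control) so cytosolic Ca2+ accumulates and the slow RyR
    adaptation shifts the release threshold within a few beats."""
    params, solver = _run_config(params, solver)
    if y0 is None:
        y0 = default_initial_state(variant)
    ctx = R.default_ctx()
    ctx[R.CTX_NCX_SCALE] = scale
    ctx[R.CTX_SERCA_SCALE] = scale
    ctx[R.CTX_PMCA_SCALE] = scale
    return steady_pacing(1.0, n_beats, variant, y0, params, solver,
                         base_ctx=ctx)


# ---------------------------------------------------------------------------
# Extracellular Ca2+ step
# ---------------------------------------------------------------------------
def ext_ca_step(ca_o_low: float = 0.9, ca_o_high: float = 3.2,
                adapt_beats: int = 60, variant: str = "vCa", y0=None,
                params: Parameters | None = None,
                solver: SolverConfig | None = None) -> dict:
    """Percent change of diastolic and systolic mean [Ca2+]_i when
    extracellular Ca2+ is raised from ``ca_o_low`` to ``ca_o_high`` mM.
    The model is paced to a new quasi-steady state at each level."""
    params, solver = _run_config(params, solver)
    if y0 is None:
        y0 = default_initial_state(variant)
    out = {}
    for label, cao in (("low", ca_o_low), ("high", ca_o_high)):
        pp = params.replace(
            constants=dataclasses.replace(params.constants, Ca_o=cao))
        tr = pace(np.asarray(y0, float), 1000.0, adapt_beats, params=pp,
                  solver=solver, variant=variant)
        out[label] = M.ca_metrics(tr)
    lo, hi = out["low"], out["high"]
    return {
        "low": lo, "high": hi,
        "diastolic_change_pct": 100.0 * (hi.diastolic / lo.diastolic - 1.0),
        "systolic_change_pct": 100.0 * (hi.systolic / lo.systolic - 1.0),
    }


# ---------------------------------------------------------------------------
# Voltage clamp: biphasic CaT upstroke
# ---------------------------------------------------------------------------
def vclamp_biphasic(hold_mv: float = -80.0, step_mv: float = 10.0,
                    step_ms: float = 300.0, pre_ms: float = 500.0,
                    block_bulk: bool = False, variant: str = "vCa", y0=None,
                    params: Parameters | None = None,
                    solver: SolverConfig | None = None) -> dict:
    """Voltage-clamp step; two-segment linear fit of the normalized CaT
    upstroke (early junctional-release phase vs late propagated phase).

    Returns the normalized transient and both slopes (1/s).  The breakpoint
    is chosen by least squares over candidate split points between the 10%
    and 90% rise levels.
    """
    params, solver = _run_config(params, solver)
    if y0 is None:
        y0 = default_initial_state(variant)
    y0 = np.asarray(y0, float).copy()
    ctx = R.default_ctx()
    ctx[R.CTX_VM_CLAMP] = 1.0
    if block_bulk:
        ctx[R.CTX_SCALE_B0:R.CTX_SCALE_B0 + 3] = 0.0
    plan = [(pre_ms, hold_mv, 1.0), (step_ms, step_mv, 0.5),
            (500.0, hold_mv, 1.0)]
    t_cursor = 0.0
    y = y0
    ts, cas = [], []
    for dur, vm, dt in plan:
        y = y.copy()
        y[R.IV] = vm
        tr = integrate_segments(
            y, [Segment(t_cursor, t_cursor + dur, ctx, dt)],
            params=params, solver=solver, variant=variant)
        ts.append(tr.t)
        cas.append(tr.mean_cyto_ca())
        y = tr.Y[-1]
        t_cursor += dur
    t = np.concatenate(ts)
    ca = np.concatenate(cas)
    m = (t >= pre_ms) & (t <= pre_ms + step_ms)
    tt = t[m] - pre_ms
    cc = ca[m]
    span = cc.max() - cc[0]
    if span <= 0:
        raise ValueError("degenerate fit window for biphasic upstroke")
    norm = (cc - cc[0]) / span
    ipk = int(np.argmax(norm))
    rise_t, rise_c = tt[:ipk + 1], norm[:ipk + 1]
    lo = int(np.argmax(rise_c >= 0.10))
    hi = int(np.argmax(rise_c >= 0.90))
    if hi - lo < 5:
        raise ValueError("degenerate fit window for biphasic upstroke")
    best = None
    for k in range(lo + 2, hi - 1):
        p1 = np.polyfit(rise_t[lo:k + 1], rise_c[lo:k + 1], 1)
        p2 = np.polyfit(rise_t[k:hi + 1], rise_c[k:hi + 1], 1)
        res = (np.sum((np.polyval(p1, rise_t[lo:k + 1]) - rise_c[lo:k + 1]) ** 2)
               + np.sum((np.polyval(p2, rise_t[k:hi + 1]) - rise_c[k:hi + 1]) ** 2))
        if best is None or res < best[0]:
            best = (res, p1[0], p2[0], rise_t[k])
    _, slope_early, slope_late, t_break = best
    return {"t_ms": tt, "normalized_ca": norm, "span_uM": float(span) * 1e3,
            "early_slope_per_s": slope_early * 1e3,
            "late_slope_per_s": slope_late * 1e3,
            "breakpoint_ms": float(t_break)}


# ---------------------------------------------------------------------------
# Protocol dispatch (config-file entry point)
# ---------------------------------------------------------------------------
def run_protocol(proto: Protocol, params: Parameters | None = None,
                 solver: SolverConfig | None = None):
    """Execute a declarative :class:`Protocol`; returns protocol output."""
    kw = dict(params=params, solver=solver)
    v = proto.variant
    if proto.kind == "steady_pacing":
        return steady_pacing(proto.frequency_hz, proto.n_beats, v, **kw)
    if proto.kind == "release_block":
        return release_block(proto.block_target, proto.t_on_ms,
                             proto.n_beats, 1000.0 / proto.frequency_hz,
                             v, **kw)
    if proto.kind in ("release_scale", "s1s2"):
        return release_scale(proto.scale, proto.s2_interval_ms,
                             proto.n_beats, 1000.0 / proto.frequency_hz,
                             v, **kw)
    if proto.kind == "caffeine":
        return caffeine_pulse(variant=v, **kw)
    if proto.kind == "ca_clamp":
        return ca_clamp(proto.clamp_mode, proto.n_beats,
                        1000.0 / proto.frequency_hz, v, **kw)
    if proto.kind in ("rate_staircase", "long_pacing", "na_clamp"):
        mode = "independent" if proto.kind == "long_pacing" else "staircase"
        return rate_staircase(proto.bcl_list or (1600, 1200, 800, 600, 400),
                              proto.step_duration_ms, mode=mode,
                              na_clamp=proto.na_clamp_mm, variant=v, **kw)
    if proto.kind == "frequency_staircase":
        return frequency_staircase_ca(
            ncx_reverse_block=proto.ncx_reverse_block, variant=v,
            step_duration=proto.step_duration_ms, **kw)
    if proto.kind == "ext_ca_step":
        return ext_ca_step(variant=v, **kw)
    if proto.kind == "vclamp":
        return vclamp_biphasic(variant=v, **kw)
    raise ValueError(f"unhandled protocol kind {proto.kind!r}")
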