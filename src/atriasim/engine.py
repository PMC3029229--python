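"""Stiff-ODE integration engine: RHS assembly, stimulus/clamp scheduling,
and the Trace container.

A simulation is a sequence of *segments*; within a segment the intervention
context (stimulus on/off, release scales, clamps, ...) is constant, and the
integrator is restarted at segment boundaries so events are hit exactly.
The integrator is SciPy's BDF (adaptive stiff multistep).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import rhs as R
from .geometry import CellGeometry, build_geometry
from .params import Parameters
from .state import StateLayout


class SolverError(RuntimeError):
    """Integration failure; carries the last accepted state."""

    def __init__(self, message: str, t_last: float, y_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last


@dataclass(frozen=True)
class SolverConfig:
    """Integrator tolerances and output sampling."""

    rtol: float = 1e-6
    atol_gates: float = 1e-8
    atol_vm: float = 1e-5
    atol_ca: float = 1e-11
    atol_casr: float = 1e-9
    atol_ions: float = 1e-7
    sample_ms: float = 0.5       # default output interval
    fine_sample_ms: float = 0.02  # sampling during the upstroke window
    fine_window_ms: float = 15.0  # dense window after each stimulus
    max_step_ms: float = math.inf

    def atol_vector(self) -> np.ndarray:
        atol = np.full(R.N_STATES, self.atol_gates)
        atol[R.IV] = self.atol_vm
        atol[R.INAI] = atol[R.IKI] = atol[R.INASS] = self.atol_ions
        atol[R.ICASS] = self.atol_ca
        atol[R.ICAB0:R.ICAB0 + R.N_BULK] = self.atol_ca
        atol[R.ICASR0:R.ICASR0 + R.N_BULK] = self.atol_casr
        atol[R.ISERCA0:R.ISERCA0 + 4] = self.atol_ca * 10
        return atol


@dataclass(frozen=True)
class ClampSpec:
    """State clamp: hold a state at a fixed value or analytic waveform.

    Supported targets: ``"Na_i"`` (fixed), ``"V"`` (fixed), ``"Ca_ss"``
    (analytic rise/decay waveform, see :func:`rhs.clamp_waveform`).
    """

    target: str
    mode: str = "fixed"           # "fixed" | "analytic"
    value: float | None = None
    waveform: dict | None = None  # for Ca_ss: base, amp, tau_rise, tau_decay,
                                  # period, t0 (ms / mM)

    def apply(self, ctx: np.ndarray) -> np.ndarray:
        ctx = ctx.copy()
        if self.target == "Na_i":
            ctx[R.CTX_NA_CLAMP] = 1.0
        elif self.target == "V":
            ctx[R.CTX_VM_CLAMP] = 1.0
        elif self.target == "Ca_ss":
            if not self.waveform:
                raise ValueError("Ca_ss clamp requires waveform parameters")
            w = self.waveform
            ctx[R.CTX_CASS_CLAMP] = 1.0
            ctx[R.CTX_CASS_BASE] = w["base"]
            ctx[R.CTX_CASS_AMP] = w["amp"]
            ctx[R.CTX_CASS_TAU_R] = w["tau_rise"]
            ctx[R.CTX_CASS_TAU_D] = w["tau_decay"]
            ctx[R.CTX_CASS_PERIOD] = w["period"]
            ctx[R.CTX_CASS_T0] = w.get("t0", 0.0)
        else:
            raise KeyError(f"unknown clamp target {self.target!r}")
        return ctx


@dataclass(frozen=True)
class Segment:
    """Half-open time interval [t0, t1) with a constant context."""

    t0: float
    t1: float
    ctx: np.ndarray
    sample_ms: float = 0.5


@dataclass
class Trace:
    """Columnar recording of a simulation (time in ms)."""

    t: np.ndarray
    Y: np.ndarray                       # (n_t, n_states)
    segments: tuple                     # of Segment
    params: Parameters
    geom: CellGeometry
    variant: str = "vCa"
    stats: dict = field(default_factory=dict)
    stim_times: tuple = ()              # stimulus onset times (ms)

    # -- access -------------------------------------------------------------
    def state(self, name: str) -> np.ndarray:
        return self.Y[:, StateLayout.idx(name)]

    @property
    def V(self) -> np.ndarray:
        return self.Y[:, R.IV]

    def ctx_at(self, t: float) -> np.ndarray:
        for seg in self.segments:
            if seg.t0 <= t < seg.t1:
                return seg.ctx
        return self.segments[-1].ctx

    def ca_ss(self) -> np.ndarray:
        """Junctional [Ca2+] including any analytic clamp substitution."""
        out = self.Y[:, R.ICASS].copy()
        for seg in self.segments:
            if seg.ctx[R.CTX_CASS_CLAMP] > 0.5:
                m = (self.t >= seg.t0) & (self.t < seg.t1)
                out[m] = [R.clamp_waveform(ti, seg.ctx) for ti in self.t[m]]
        return out

    def mean_cyto_ca(self) -> np.ndarray:
        """Accessible-volume-weighted mean cytosolic [Ca2+] (mM)."""
        g = self.geom
        w = np.concatenate(([g.V_ss], g.V_bulk))
        cols = np.column_stack(
            [self.ca_ss()] +
            [self.Y[:, R.ICAB0 + j] for j in range(g.n_bulk)])
        return cols @ (w / w.sum())

    def currents(self) -> pd.DataFrame:
        """Recompute instantaneous membrane currents (pA) along the trace."""
        pk = self.params.pack(self.geom)
        out = np.empty((len(self.t), len(R.CURRENT_NAMES)))
        for i, ti in enumerate(self.t):
            out[i] = R.compute_currents_core(ti, self.Y[i], pk, self.ctx_at(ti))
        return pd.DataFrame(out, columns=list(R.CURRENT_NAMES),
                            index=pd.Index(self.t, name="t_ms"))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Y, columns=list(StateLayout.names))
        df.insert(0, "t_ms", self.t)
        return df

    def last_window(self, duration: float) -> "Trace":
        m = self.t >= (self.t[-1] - duration)
        return replace_trace(self, self.t[m], self.Y[m])


def replace_trace(tr: Trace, t: np.ndarray, Y: np.ndarray) -> Trace:
    return Trace(t=t, Y=Y, segments=tr.segments, params=tr.params,
                 geom=tr.geom, variant=tr.variant, stats=tr.stats,
                 stim_times=tr.stim_times)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------
def _sample_times(t0: float, t1: float, dt: float) -> np.ndarray:
    n = max(int(round((t1 - t0) / dt)), 1)
    return np.linspace(t0, t1, n + 1)


def integrate_segments(
    y0: np.ndarray,
    segments: Sequence[Segment],
    params: Parameters | None = None,
    geom: CellGeometry | None = None,
    solver: SolverConfig | None = None,
    variant: str = "vCa",
    stim_times: Iterable[float] = (),
) -> Trace:
    """Integrate over a schedule of constant-context segments."""
    params = params or Parameters()
    geom = geom or build_geometry()
    solver = solver or SolverConfig()
    pk = params.pack(geom)
    vb, vsr, af = geom.V_bulk, geom.V_sr, geom.A_faces
    atol = solver.atol_vector()

    y = np.asarray(y0, dtype=float).copy()
    ts, ys = [], []
    stats = {"nfev": 0, "njev": 0, "nlu": 0, "segments": 0}

    for seg in segments:
        ctx = seg.ctx.copy()
        if variant == "vCaNass":
            ctx[R.CTX_VARIANT_NASS] = 1.0
        fun = lambda t, yy: R.rhs_core(t, yy, pk, ctx, vb, vsr, af)
        t_eval = _sample_times(seg.t0, seg.t1, seg.sample_ms)
        sol = solve_ivp(fun, (seg.t0, seg.t1), y, method="BDF",
                        t_eval=t_eval, rtol=solver.rtol, atol=atol,
                        max_step=solver.max_step_ms)
        stats["nfev"] += sol.nfev
        stats["njev"] += sol.njev
        stats["nlu"] += sol.nlu
        stats["segments"] += 1
        if not sol.success:
            t_last = sol.t[-1] if sol.t.size else seg.t0
            y_last = sol.y[:, -1] if sol.t.size else y
            bad = np.where(~np.isfinite(y_last))[0]
            detail = (f"; non-finite states: "
                      f"{[StateLayout.names[i] for i in bad]}" if bad.size else "")
            raise SolverError(
                f"integration failed at t={t_last:.3f} ms: {sol.message}{detail}",
                t_last, y_last)
        if ts and math.isclose(sol.t[0], ts[-1][-1]):
            ts.append(sol.t[1:])
            ys.append(sol.y[:, 1:].T)
        else:
            ts.append(sol.t)
            ys.append(sol.y.T)
        y = sol.y[:, -1].copy()

    return Trace(
        t=np.concatenate(ts), Y=np.vstack(ys), segments=tuple(segments),
        params=params, geom=geom, variant=variant, stats=stats,
        stim_times=tuple(stim_times),
    )


def integrate(y0: np.ndarray, duration: float,
              ctx: np.ndarray | None = None,
              params: Parameters | None = None,
              geom: CellGeometry | None = None,
              solver: SolverConfig | None = None,
              variant: str = "vCa") -> Trace:
    """Integrate a constant-context interval [0, duration]."""
    if duration < 0:
        raise ValueError("duration must be >= 0")
    solver = solver or SolverConfig()
    ctx = R.default_ctx() if ctx is None else ctx
    if duration == 0:
        params = params or Parameters()
        geom = geom or build_geometry()
        return Trace(t=np.array([0.0]), Y=np.asarray(y0, float)[None, :],
                     segments=(Segment(0.0, 0.0, ctx, solver.sample_ms),),
                     params=params, geom=geom, variant=variant)
    seg = Segment(0.0, duration, ctx, solver.sample_ms)
    return integrate_segments(y0, [seg], params, geom, solver, variant)


# ---------------------------------------------------------------------------
# Pacing schedules
# ---------------------------------------------------------------------------
STIM_AMPLITUDE = -2800.0   # pA, ~2x diastolic threshold
STIM_DURATION = 1.0        # ms


def pacing_segments(bcl: float, n_beats: int,
                    base_ctx: np.ndarray | None = None,
                    stim_amp: float = STIM_AMPLITUDE,
                    stim_dur: float = STIM_DURATION,
                    t0: float = 0.0,
                    solver: SolverConfig | None = None) -> tuple[list[Segment], list[float]]:
    """Build the segment schedule for a regular stimulus train.

    Each beat: a stimulus segment (densely sampled), a short post-stimulus
    dense window covering the upstroke, then the remainder of the cycle at
    the default sampling interval.  Returns (segments, stimulus onsets).
    """
    solver = solver or SolverConfig()
    base_ctx = R.default_ctx() if base_ctx is None else base_ctx
    segs: list[Segment] = []
    onsets = []
    for b in range(n_beats):
        ts = t0 + b * bcl
        onsets.append(ts)
        stim_ctx = base_ctx.copy()
        stim_ctx[R.CTX_STIM] = stim_amp
        segs.append(Segment(ts, ts + stim_dur, stim_ctx, solver.fine_sample_ms))
        fine_end = ts + stim_dur + solver.fine_window_ms
        segs.append(Segment(ts + stim_dur, fine_end, base_ctx.copy(),
                            solver.fine_sample_ms))
        segs.append(Segment(fine_end, ts + bcl, base_ctx.copy(),
                            solver.sample_ms))
    return segs, onsets


def pace(y0: np.ndarray, bcl: float, n_beats: int,
         base_ctx: np.ndarray | None = None,
         params: Parameters | None = None,
         geom: CellGeometry | None = None,
         solver: SolverConfig | None = None,
         variant: str = "vCa",
         stim_amp: float = STIM_AMPLITUDE,
         stim_dur: float = STIM_DURATION) -> Trace:
    """Convenience wrapper: regular pacing for ``n_beats`` at cycle length ``bcl``."""
    segs, onsets = pacing_segments(bcl, n_beats, base_ctx, stim_amp, stim_dur,
                                   solver=solver or SolverConfig())
    return integrate_segments(y0, segs, params, geom, solver, variant,
                              stim_times=onsets)
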