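"""Scalar measurements extracted from simulated traces.

All metrics are pure functions of a :class:`~atriasim.engine.Trace` (or of
plain time/value arrays); nothing here mutates state.  Conventions:

* APD_x is measured from the maximum-dV/dt point of the upstroke to x%
  repolarization of the beat amplitude (RMP -> peak of the same beat), with
  linear interpolation between samples.  RMP is the potential immediately
  before the stimulus.
* Ca2+ transient decay is a single-exponential least-squares fit from the
  transient peak to the end of diastole.
* The Ca2+ transient duration is the time from 10% rise to 90% recovery.
* Propagation speed is the inverse slope of a linear fit of half-peak time
  versus shell-centre depth from the membrane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from . import rhs as R
from .engine import Trace


class NoAPError(ValueError):
    """No action potential detected in the analysis window (capture failure)."""


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------
def _beat_window(tr: Trace, beat: int = -1) -> tuple[float, float]:
    """Time window [stimulus onset, next onset or end] of a beat."""
    if not tr.stim_times:
        return float(tr.t[0]), float(tr.t[-1])
    onsets = list(tr.stim_times)
    t0 = onsets[beat]
    later = [s for s in onsets if s > t0]
    t1 = later[0] if later else float(tr.t[-1])
    return float(t0), float(t1)


def _interp_crossing(t: np.ndarray, v: np.ndarray, level: float,
                     falling: bool = True) -> float:
    """First linear-interpolated crossing time of ``level``."""
    if falling:
        idx = np.where((v[:-1] > level) & (v[1:] <= level))[0]
    else:
        idx = np.where((v[:-1] < level) & (v[1:] >= level))[0]
    if idx.size == 0:
        raise ValueError("level not crossed")
    i = idx[0]
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


# ---------------------------------------------------------------------------
# Action potential metrics
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class APMetrics:
    RMP: float          # mV
    peak: float         # mV
    amplitude: float    # mV
    dVdt_max: float     # mV/ms
    APD30: float        # ms
    APD90: float        # ms
    t_upstroke: float   # ms, time of max dV/dt (absolute trace time)


def ap_metrics(tr: Trace, beat: int = -1,
               min_amplitude: float = 40.0) -> APMetrics:
    """AP characteristics of one beat; raises :class:`NoAPError` on capture
    failure (depolarization smaller than ``min_amplitude``)."""
    t0, t1 = _beat_window(tr, beat)
    m = (tr.t >= t0) & (tr.t <= t1)
    t, V = tr.t[m], tr.V[m]
    rmp = float(V[0])
    peak = float(V.max())
    amp = peak - rmp
    if amp < min_amplitude:
        raise NoAPError(f"no AP captured (amplitude {amp:.1f} mV)")
    dv = np.gradient(V, t)
    iup = int(np.argmax(dv))
    t_up = float(t[iup])
    out = {}
    ipk = int(np.argmax(V))
    for frac, name in ((0.30, "APD30"), (0.90, "APD90")):
        level = peak - frac * amp
        try:
            tx = _interp_crossing(t[ipk:], V[ipk:], level, falling=True)
        except ValueError:
            # no full repolarization within the cycle: not a normal AP
            raise NoAPError(
                f"incomplete repolarization ({name} level never crossed)")
        out[name] = tx - t_up
    return APMetrics(RMP=rmp, peak=peak, amplitude=amp,
                     dVdt_max=float(dv.max()), APD30=out["APD30"],
                     APD90=out["APD90"], t_upstroke=t_up)


# ---------------------------------------------------------------------------
# Ca2+ transient metrics
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CaMetrics:
    diastolic: float        # uM
    systolic: float         # uM
    amplitude: float        # uM
    t_peak: float           # ms from stimulus
    decay_tau: float        # ms
    decay_rate: float       # 1/s
    t50_relax: float        # ms, 50% recovery after peak
    duration: float         # ms, 10% rise -> 90% recovery


def mean_cytosolic_ca(tr: Trace) -> np.ndarray:
    """Accessible-volume-weighted mean cytosolic [Ca2+] in uM."""
    return tr.mean_cyto_ca() * 1e3


def decay_fit(t: np.ndarray, ca: np.ndarray) -> float:
    """Single-exponential decay constant tau (ms) fitted from the peak on.

    ``t`` and ``ca`` should cover the decaying segment (peak to end of
    diastole).  Raises ``ValueError`` for non-decaying input.
    """
    ca = np.asarray(ca, float)
    if ca[0] <= ca[-1]:
        raise ValueError("input is not decaying")
    t = np.asarray(t, float) - t[0]

    def model(tt, amp, tau, base):
        return base + amp * np.exp(-tt / tau)

    amp0 = ca[0] - ca[-1]
    tau0 = max((t[-1] - t[0]) / 3.0, 1.0)
    popt, _ = curve_fit(model, t, ca, p0=(amp0, tau0, ca[-1]), maxfev=20000)
    return float(popt[1])


def ca_metrics(tr: Trace, beat: int = -1) -> CaMetrics:
    """Metrics of the volume-weighted mean cytosolic Ca2+ transient."""
    t0, t1 = _beat_window(tr, beat)
    m = (tr.t >= t0) & (tr.t <= t1)
    t, ca = tr.t[m], mean_cytosolic_ca(tr)[m]
    dia = float(ca[0])
    ipk = int(np.argmax(ca))
    sys_ = float(ca[ipk])
    amp = sys_ - dia
    tau = decay_fit(t[ipk:], ca[ipk:])
    half = dia + 0.5 * amp
    t50 = _interp_crossing(t[ipk:], ca[ipk:], half, falling=True) - t[ipk]
    lo = dia + 0.1 * amp
    t_on = _interp_crossing(t[:ipk + 1], ca[:ipk + 1], lo, falling=False)
    try:
        t_off = _interp_crossing(t[ipk:], ca[ipk:], lo, falling=True)
    except ValueError:
        t_off = float(t[-1])
    return CaMetrics(diastolic=dia, systolic=sys_, amplitude=amp,
                     t_peak=float(t[ipk] - t0), decay_tau=tau,
                     decay_rate=1000.0 / tau, t50_relax=t50,
                     duration=t_off - t_on)


# ---------------------------------------------------------------------------
# Spatial propagation
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PropagationMetrics:
    depths: np.ndarray        # um from membrane (subspace + shells)
    t_peak: np.ndarray        # ms from stimulus
    t_half_peak: np.ndarray   # ms from stimulus
    speed: float              # um/s from linear fit of half-peak times


def propagation_metrics(tr: Trace, beat: int = -1) -> PropagationMetrics:
    """Per-compartment Ca2+ timing and radial propagation speed."""
    t0, t1 = _beat_window(tr, beat)
    m = (tr.t >= t0) & (tr.t <= t1)
    t = tr.t[m] - t0
    g = tr.geom
    if g.n_bulk < 3:
        raise ValueError("propagation metrics require >= 3 shells")
    depths = [g.d_junct / 2.0] + list(g.depth_centers)
    series = [tr.ca_ss()[m]] + [
        tr.Y[m, R.ICAB0 + j] for j in range(g.n_bulk - 1, -1, -1)]
    t_pk, t_half = [], []
    for ca in series:
        ipk = int(np.argmax(ca))
        t_pk.append(float(t[ipk]))
        half = ca[0] + 0.5 * (ca[ipk] - ca[0])
        t_half.append(_interp_crossing(t[:ipk + 1], ca[:ipk + 1], half,
                                       falling=False))
    depths_a = np.asarray(depths)
    t_half_a = np.asarray(t_half)
    if np.ptp(t_half_a) <= 0:
        raise ValueError("non-propagating (flat) input")
    slope = np.polyfit(depths_a, t_half_a, 1)[0]    # ms/um
    speed = 1000.0 / slope                          # um/s
    return PropagationMetrics(depths=depths_a, t_peak=np.asarray(t_pk),
                              t_half_peak=t_half_a, speed=float(speed))


# ---------------------------------------------------------------------------
# SR content and release fraction
# ---------------------------------------------------------------------------
def sr_content(tr: Trace, idx: int = -1) -> float:
    """SR Ca2+ content (free + calsequestrin-bound) in uM of accessible
    bulk-cytosolic volume, at trace sample ``idx``."""
    g, p = tr.geom, tr.params
    casr = tr.Y[idx, R.ICASR0:R.ICASR0 + g.n_bulk]
    bound = p.CSQN * casr / (p.K_dCSQN + casr)
    total_mm = float(np.sum(g.V_sr * (casr + bound)))        # nL*mM
    return total_mm / g.V_bulk_total * 1e3                   # uM


def sr_release_fraction(control: Trace, blocked: Trace) -> float:
    """Percent of the CaT amplitude attributable to SR release:
    100*(1 - amplitude_blocked / amplitude_control) on matched protocols."""
    if len(control.stim_times) != len(blocked.stim_times) or not math.isclose(
            control.stim_times[-1], blocked.stim_times[-1]):
        raise ValueError("protocols are not matched (stimulus schedules differ)")
    amp_c = ca_metrics(control).amplitude
    amp_b = ca_metrics(blocked).amplitude
    return 100.0 * (1.0 - amp_b / amp_c)
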