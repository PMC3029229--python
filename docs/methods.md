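# Methods

## The model

`atriasim` simulates a single human atrial myocyte as a stiff ODE system
coupling Hodgkin–Huxley sarcolemmal ion currents to a spatially resolved
intracellular Ca²⁺ system. The cell is a cylinder (length 122.051 µm,
radius 6.52 µm). The outermost 0.02 µm of cytosol is the junctional
subspace, the single microdomain where the L-type Ca²⁺ current, NCX, PMCA
and the background Ca²⁺ current deliver or remove Ca²⁺. The remaining
cytosol and the sarcoplasmic reticulum (SR) are discretized into four
annular shells of width 1.625 µm. The SR occupies 2.25% of the bulk
cytosol shell by shell, and only 50% of every cytosolic/SR volume (and of
the junctional↔bulk exchange area) is accessible to Ca²⁺.

Key assumptions:

* Atrial myocytes lack transverse tubules, so sarcolemmal Ca²⁺ entry is
  confined to the cell surface. Excitation–contraction coupling therefore
  proceeds centripetally: the junctional SR release unit responds to
  L-type Ca²⁺ influx, and the three non-junctional units (one per inner
  bulk shell) are recruited by Ca²⁺ diffusion in fire–diffuse–fire
  fashion. The outermost bulk shell carries no release unit; it receives
  Ca²⁺ only by diffusion from the subspace and the deeper shells.
* Channel gating is deterministic Hodgkin–Huxley (`dx/dt = (x∞−x)/τ`).
  Markov chains and stochastic single-channel behaviour are out of scope.
* Fast buffers (sarcolemmal sites in the subspace, calsequestrin in the
  SR, a single mobile cytosolic buffer with calmodulin's mobility and
  K_d) are at rapid equilibrium, entering the ODEs through
  concentration-dependent β factors. The mobile buffer also carries Ca²⁺
  between shells (Wagner–Keizer complex-diffusion treatment).
* SERCA is a two-step pump with an explicit pump-bound Ca²⁺ intermediate,
  which produces the observed delay between cytosol→pump and pump→SR
  fluxes, plus a thermodynamic back-flux at high SR Ca²⁺.

## RyR release units

Each release unit has three gates: a fast open gate `o`, a slower closed
(inactivation) gate `c`, and a slow adaptation variable `a` (τ = 1 s) that
shifts the midpoints of the `o` and `c` steady-state sigmoids along the
local Ca²⁺ axis. Open probability is `o·c`, further scaled by a sigmoid of
local SR [Ca²⁺] (midpoint 0.3 mM), and the release flux is
`ν·V·o·c·f(Ca_SR)·(Ca_SR − Ca_cyto)`. Adaptation reproduces the transient
(peak-then-decline) response of release to a maintained Ca²⁺ step.
Junctional gating is fast (τ_act 5 ms, τ_inact 15 ms); non-junctional units
are slower (τ_act 40 ms, τ_inact 50 ms) so central release is spread wider
in space and time than the junctional signal.

## Numerical scheme

Radial diffusion (free Ca²⁺ at 780 µm²/s, buffer complex at 25 µm²/s,
SR Ca²⁺ at 44 µm²/s) is discretized with a finite-volume operator on the
shell grid: inter-shell fluxes are antisymmetric, so Ca²⁺ mass is conserved
exactly, and the β factors convert total-Ca flux into free-Ca rate of
change. The junctional↔bulk exchange is an analytic diffusion flux over the
centre-to-centre distance with the 50% accessible area. With calsequestrin
buffering, the effective SR diffusivity is 8–12 µm²/s for SR [Ca²⁺]
between 0.3 and 0.6 mM; setting calsequestrin to zero recovers the free
coefficient.

The full right-hand side (43 states) is compiled with numba and integrated
with SciPy's BDF method (rtol 1e-6; absolute tolerances per state group,
e.g. 1e-11 mM for cytosolic Ca²⁺). Simulations are split into segments with
constant intervention context (stimulus on/off, clamps, release scales);
the integrator restarts at segment boundaries so events are hit exactly,
and output is sampled at 0.02 ms through each stimulus/upstroke window and
0.5 ms elsewhere. Runs are deterministic: identical inputs give
bit-identical traces on one platform.

Stimulus: square pulse, 1 ms, −2800 pA (≈2× diastolic threshold). The
stimulus charge is booked against K⁺ so that long pacing runs do not leak
total ionic charge.

## Units

mV, ms, mM, nL, pA throughout the compiled core. Literature rate constants
(seconds-based) and diffusion coefficients (µm²/s) are stored in their
source units in `Parameters`/`data/default_params.yaml` and converted once
when the parameter vector is packed.

## Parameter provenance and calibration

Fixed physical constants, geometry, extracellular concentrations and
buffering parameters are taken directly from their published values (see
`data/default_params.yaml`). The sarcolemmal currents use the published
human-atrial Hodgkin–Huxley formulations with this model's documented
modifications: a dynamic Ca²⁺-dependent inactivation gate for the L-type
current driven by subspace Ca²⁺ (midpoint 1 µM, Hill 2, τ 2 ms), a refit
voltage-dependent f₁ time constant that is much slower between −40 and
−10 mV, and a hyperpolarization-activated current (I_f) fitted to left
atrial data (activation midpoint −97.8 mV) that is negligible above
−80 mV.

Parameters that the source formulation leaves free — RyR time constants,
permeabilities and the open-gate threshold shift, calsequestrin
concentration, the SERCA turnover scale, SR leak, and the conductance-level
adjustments g_CaL 19.75 nS, g_K1 3.9 nS, k_NCX 0.0095, P_Na 0.0016 nL/s —
were calibrated once so that the emergent 1 Hz behaviour of the assembled
cell reproduces the benchmark set: APD90 ≈ 240 ms, resting potential
−77 mV, upstroke 170 mV/ms, mean-cytosolic Ca²⁺ transient 0.13 → 0.73 µM
with a 142 ms decay constant, SR content ≈ 79 µM of accessible cytosolic
volume, 77% of the transient amplitude generated by SR release, and the
centripetal activation sequence (subspace peak ≈ 35 ms, centre ≈ 104 ms).
The calibration is part of the shipped default parameter set and is not
re-run at test time.

## Initial conditions

Steady states are derived, not tabulated: a documented quiescent seed state
(gates at their V = −77 mV steady state, uniform 0.16 µM cytosolic Ca²⁺,
0.62 mM SR Ca²⁺, Na⁺ 9.3 mM, K⁺ 134 mM) is paced at 1 Hz for 10 minutes of
model time, and the final diastolic state is cached as a JSON fixture per
variant (`data/steady_state_1hz_*.json`). The quiescent steady state
(`data/quiescent_vca.json`, Na⁺ → 8.12 mM) is obtained by letting the paced
state relax unpaced for 40 minutes; it is the starting point of the
rate-dependence protocols. The fixtures can be regenerated with the
library itself: pace `seed_state()` with `engine.pace` and serialize the
final state with `state.save_steady_state`.

## Model variants

* `vCa` — the base model: one intracellular Na⁺ pool.
* `vCaNass` — adds a subsarcolemmal Na⁺ compartment (the subspace volume)
  sensed by I_Na, NKA, NCX and I_f,Na, exchanging with the bulk pool by
  diffusion. Reverse-NCX analyses are run on this variant.
* A third published variant with updated K⁺-current kinetics is an
  extension point only and is not implemented.

## Protocol conventions

* **Release-site block** — the targeted release scales are set to zero at
  t = 1 s of a 1 Hz run from the paced steady state. Relative
  amplitude/APD90 changes are averaged over blocked beats 2–5: under
  junctional block the model settles into a mild beat-to-beat alternation
  of autonomous bulk firing, so one late beat is not representative.
* **Caffeine pulse** — pacing stops, the membrane is clamped at −80 mV
  (the experiment this reproduces is voltage-clamped), all RyR units are
  held fully open for 1 s, and the NCX current is integrated over the
  evoked transient against its post-transient plateau; charge converts to
  Ca²⁺ moles 1:1 (3Na:1Ca stoichiometry), normalized by C_m. A maintained
  (≥5 s) caffeine application instead recovers essentially the full SR
  content (~12 amol/pF); the 1 s pulse, after which SERCA re-sequesters
  part of the released Ca²⁺, reproduces the partial estimate that makes
  the NCX-integral method undershoot true content.
* **Junctional Ca²⁺ clamp** — the subspace Ca²⁺ state is replaced by the
  analytic waveform `base + amp·(e^(−t/τ_d) − e^(−t/τ_r))`
  (peak-normalized), fitted to the control transient. "Slowed/accelerated
  decay" scales τ_d by 2/0.5; "amplitude modes" scale the peak by 0.5/1.5.
  The double-exponential cannot capture both the sharp junctional upstroke
  and the late shoulder perfectly, so the clamped control reproduces the
  unclamped APD90 to ≈3%, not exactly.
* **Rate staircase** — BCL sequence 1600, 1200, 800, 600, 400, 300 ms,
  60 s per step, starting from the quiescent steady state (the replicated
  experimental protocol stabilizes ≥1 min per rate; 30 s steps
  underestimate the slow Na⁺-mediated component). The independent mode
  runs each BCL for 5 min from the same quiescent state. A step counts as
  captured only if each of its last five beats shows a normal,
  fully-repolarizing AP.
* **Biphasic upstroke** — voltage-clamp step from −80 mV to +10 mV; the
  normalized mean-cytosolic transient is fitted with two line segments
  between its 10% and 90% rise levels, the breakpoint chosen by least
  squares.

## Known limitations

* The supplementary equation-level sources of the original formulation
  were not available; re-fitted components (RyR kinetics, calsequestrin,
  conductance deltas) reproduce the benchmark outputs to 5–15% but are
  not guaranteed to be term-by-term identical. The centre-shell time to
  peak (≈104 ms vs ≈124 ms reported) is the one timing quantity outside
  the 15% band: making central release slow enough to match it degrades
  the transient decay constant and the bulk-block amplitude effect, and
  the reported value itself was read from a contour plot.
* The compiled right-hand side is fixed to the four-shell geometry; the
  grid-generic diffusion operators in `atriasim.calcium` support arbitrary
  shell counts and are used for the fine-grid cross-checks, but the full
  cell model does not run on refined grids.
* The junctional-block "new steady behaviour" is an alternating state;
  averaged metrics are reported (see above).
* No contraction, CaMKII signalling, mitochondria, or tissue coupling.
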