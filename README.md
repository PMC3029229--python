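# atriasim

A simulator for human atrial myocyte electrophysiology with spatially
detailed intracellular Ca²⁺ dynamics, for cellular electrophysiologists and
modellers who need the atrial-specific coupling between sarcolemmal ion
currents and sarcoplasmic-reticulum (SR) Ca²⁺ release.

Atrial myocytes lack transverse tubules: Ca²⁺ release starts in a thin
junctional subspace under the sarcolemma and propagates to the cell centre
by fire–diffuse–fire recruitment of non-junctional SR release sites. The
model couples

* Hodgkin–Huxley sarcolemmal currents (I_Na, I_CaL, I_to, I_sus, I_Kr,
  I_Ks, I_K1, I_f, NKA, NCX, PMCA, backgrounds) with
  `dV_m/dt = −ΣI/C_m`,
* a cylindrical cell (122.05 µm × 6.52 µm radius) whose cytosol and SR are
  discretized into a 0.02 µm junctional subspace plus four 1.625 µm
  annular shells,
* radial Ca²⁺ diffusion (free Ca²⁺ and a mobile buffer complex;
  rapid-equilibrium β factors for sarcolemmal sites, calsequestrin and the
  mobile buffer),
* a three-gate phenomenological ryanodine-receptor (RyR) unit per release
  site — fast open gate, slower closed gate, and a slow adaptation
  variable that shifts both steady-state sigmoids along the local Ca²⁺
  axis — with release flux `ν·o·c·f([Ca²⁺]_SR)·([Ca²⁺]_SR − [Ca²⁺]_i)`,
* a two-step SERCA pump with an explicit pump-bound intermediate, and a
  passive SR leak.

Two variants are provided: `vCa` (base) and `vCaNass` (adds a
subsarcolemmal Na⁺ compartment). See `docs/methods.md` for the full model
description, unit conventions, calibration provenance and limitations.

## Worked example

```python
from atriasim import protocols, metrics

trace = protocols.steady_pacing(freq_hz=1.0, n_beats=6)   # 1 Hz, vCa
ap = metrics.ap_metrics(trace)
ca = metrics.ca_metrics(trace)
print(f"APD90 {ap.APD90:.1f} ms, RMP {ap.RMP:.1f} mV, "
      f"upstroke {ap.dVdt_max:.0f} mV/ms")
print(f"CaT {ca.diastolic:.3f} -> {ca.systolic:.3f} uM, "
      f"decay tau {ca.decay_tau:.0f} ms")
print(f"SR content {metrics.sr_content(trace):.1f} uM")
```

prints

```
APD90 241.0 ms, RMP -76.9 mV, upstroke 170 mV/ms
CaT 0.130 -> 0.734 uM, decay tau 142 ms
SR content 79.1 uM
```

i.e. a triangular atrial action potential lasting ~240 ms from a resting
potential of −77 mV, a volume-weighted mean cytosolic Ca²⁺ transient of
~0.6 µM amplitude decaying with τ ≈ 142 ms, and a diastolic SR Ca²⁺ load of
~79 µmol per litre of accessible cytosol. `protocols` also implements
release-site blocks, release scaling with premature (S1–S2) stimuli,
caffeine pulses, junctional-Ca²⁺ clamps, Na⁺ clamps, rate staircases and
voltage-clamp steps; each returns traces and derived measurements.

There is also a CLI:

```
atriasim simulate run.yaml -o out/      # protocol described in YAML
atriasim metrics out/trace.csv
atriasim sweep run.yaml --param g_CaL --values 15,20,25
```

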