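# ca1rhythms

A conductance-based model of the rhythms of the hippocampal CA1 field:
theta (4–12 Hz), slow (30–50 Hz), middle (50–90 Hz) and fast (90–150 Hz)
gamma, and ripple oscillations (110–200 Hz), together with a
volume-conductor LFP forward model and the cross-frequency analysis battery
used to characterize them.

The package is aimed at computational neuroscientists who want a desk-scale,
fully reproducible CA1 rhythm simulator: a Hodgkin–Huxley-formalism network
of pyramidal cells and eight interneuron classes (PV and CCK basket,
axo-axonic, bistratified, OLM, neurogliaform, ivy and
Schaffer-collateral-associated cells), driven by structured spike generators
that emulate CA3 (spatial place-field and background inputs, 7 Hz theta +
35 Hz slow-gamma modulated), the medial entorhinal cortex (grid-like
envelopes, 63 Hz middle-gamma modulated), and the medial septum (theta
trough-locked GABAergic Teevra pacing and cholinergic tone). Nearly all
rhythms are imposed by these inputs rather than generated intrinsically;
the network turns them into the laminar current patterns that shape the
extracellular field.

## Model in brief

* **Cells** — reduced multicompartment HH neurons. Pyramidal cells have six
  compartments at fixed laminar depths (axon-initial segment, soma, basal,
  proximal/distal radiatum, lacunosum-moleculare) with Na, K-DR and
  adaptation (K-M) currents; interneurons are single-compartment with
  class-specific kinetics (fast-spiking PV/axo-axonic, H-current OLM,
  adapting CCK/ivy). Integration is exponential-Euler for gating with an
  implicit Hines solve for the cable step, dt = 0.1 ms.
* **Synapses** — bi-exponential AMPA, GABA_A (fast perisomatic and slow
  dendritic) and nicotinic conductances, `I = g(t) (V − E)`; gap junctions
  within the PV basket and neurogliaform populations.
* **Inputs** — inhomogeneous Poisson generators,
  `rate(t) = r̄ · envelope(t) · Π (1 + d_i cos(2π f_i t + φ_i))`,
  sampled by thinning. The non-theta/ripple transform compresses the CA3
  place-field envelope 40-fold (preserving its integral), adds 170 Hz
  modulation, converges the envelope centers and switches the Teevra drive
  to a constant rate.
* **LFP** — point-source volume conductor,
  `φ_e(t) = Σ_k I_k(t) / (4π σ r_ek)`, summing pyramidal transmembrane
  currents only (their laminar alignment makes the field dipolar).
* **Analysis** — zero-phase Butterworth filters, Hilbert phase (0° = peak,
  180° = trough), circular spike-phase statistics with Rayleigh tests, the
  Kullback–Leibler phase–amplitude modulation index
  `MI = KL(P‖uniform)/log N`, the n:m phase–phase test
  `R(m) = |⟨exp(i(m·φ_θ − φ_m))⟩|` with time-shift surrogates, Morlet
  phase–frequency amplitude maps, circular-linear phase-precession fits and
  ripple-event detection.

All population sizes, channel densities, synaptic weights, connection
probabilities and generator parameters live in one editable file,
`src/ca1rhythms/params/defaults.yaml`, and can be overridden from a run
config.

## Worked example

Simulate 20 s of the theta state at 5% scale and analyze the pyramidal-layer
LFP:

```bash
ca1rhythms run --state theta --scale 0.05 --duration 20000 --seed 5 \
    --out run.h5
ca1rhythms analyze --in run.h5 --report report.json
```

Or from Python:

```python
from ca1rhythms import analysis, lfp, network

net = network.build_network(
    {"simulation": {"scale": 0.05, "duration": 20000.0, "state": "theta"}},
    seed=1)
rec = network.run_simulation(net, seed=5)
x = lfp.lfp_from_recording(rec).channel_at_depth(0.0)  # pyramidal layer
theta = analysis.bandpass(x, analysis.default_bands()["theta"], rec.fs)
phase = analysis.instantaneous_phase(theta)
for pop in ("pvbas", "cckbas", "olm", "aac"):
    ids, ts = rec.spikes[pop]
    pref, rbar, p = analysis.spike_phase_stats(ts, phase, rec.t)
    print(f"{pop:7s} rate {ts.size / net.populations[pop].size / 20:5.1f} Hz"
          f"  preferred phase {pref:5.1f} deg  R = {rbar:.2f}")
```

which prints (0° = LFP theta peak, 180° = trough):

```
pvbas   rate  22.2 Hz  preferred phase 107.5 deg  R = 0.32
cckbas  rate  25.2 Hz  preferred phase 316.9 deg  R = 0.70
olm     rate  50.1 Hz  preferred phase 188.9 deg  R = 0.22
aac     rate  38.1 Hz  preferred phase  20.7 deg  R = 0.70
```

i.e. PV basket cells fire on the descending phase, CCK basket cells on the
ascending phase, OLM cells at the trough and axo-axonic cells at the peak —
the canonical CA1 theta coupling scheme.

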