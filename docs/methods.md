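# Methods

This note documents the model, its numerical choices, the synthetic drives,
and the design decisions taken where the literature leaves the parameters
open. Units throughout: ms, mV, nA, µS, mS/cm², µF/cm², µm; track positions
are normalized to [0, 1].

## Cell models

Nine cell classes are modeled with the Hodgkin–Huxley formalism in reduced
compartmental form. The pyramidal cell has six cylindrical compartments at
fixed laminar depths — axon-initial segment (+10 µm), soma (0), basal
dendrite (+100), proximal and distal stratum-radiatum sections (−100, −250)
and a lacunosum-moleculare section (−400). This is the coarsest geometry
that still separates the laminar transmembrane currents the LFP model
needs; it makes no claim of morphological realism. Interneurons are single
compartments.

Channel kinetics follow the reduced Traub–Miles scheme (transient Na with
m³h, delayed-rectifier K with n⁴); rate functions are finite on
[−120, +60] mV. Excitability is differentiated per class:

* **pyr** — Na/K-DR plus a slow M-type K current (τ = 100 ms) giving
  spike-frequency adaptation; passive dendrites.
* **pvbas, aac** — fast-spiking: doubled h/n rate kinetics, high leak
  (membrane τ ≈ 3 ms), no adaptation.
* **olm** — an H-current (τ = 180 ms, E = −30 mV) producing sag and
  rebound; leak reversal −72 mV so the cell is silent at rest.
* **cckbas, ivy** — M-current adaptation (3.0 and 1.0 mS/cm²): these
  classes discharge as bursts when released from rhythmic inhibition,
  which is what locks them to the ascending theta phase.
* **ngf, bis, sca** — Na/K-DR/leak with per-class leak densities.

Because the Na window current near −65 mV makes these kinetics
spontaneously active at the customary leak reversal, interneuron leak
reversals sit at −70 mV (−72 for OLM); every default cell type has a
zero firing rate at zero injected current.

**Integration.** Gating variables advance by exponential Euler; the voltage
step is fully implicit: synaptic and ionic conductances enter the diagonal
of a per-cell tree system that is solved exactly by Hines elimination each
step. Gap junctions use the partner's previous-step voltage
(semi-implicit). Default dt = 0.1 ms. Spikes are upward crossings of
−10 mV at the soma with a 2 ms refractory latch. Convergence: halving dt
leaves single-cell interspike intervals within 0.1 ms and changes network
population-rate profiles by r > 0.9; individual network spike times
diverge chaotically, as expected for threshold dynamics, so timing
agreement is asserted on first-spike latencies and population statistics
rather than worst-case spike pairs.

## Synapses

Chemical synapses are bi-exponential conductances normalized so the
single-spike peak equals the connection weight, with linear superposition.
Defaults: AMPA (0.5, 3) ms at 0 mV; perisomatic GABA_A (0.5, 6) ms and
dendritic GABA_A (3, 30) ms at −75 mV — the slow variant models the long
neurogliaform/ivy IPSPs; nicotinic (1, 8) ms at 0 mV. Sign convention:
`I = g (V − E)`, positive outward. Delays are rounded to integration steps
(minimum one step). Gap junctions are ohmic, position-independent, and are
sampled between nearest neighbours within the PV basket and neurogliaform
populations (p = 0.5, 1 nS).

## External drives

Each generator is an inhomogeneous Poisson process,

    rate(t) = r̄ · envelope(t) · (1 + d_θ cos(2π f_θ t + φ))
                              · (1 + d_γ cos(2π f_γ t))
                              · (1 + d_r cos(2π f_r t)),  clipped at 0,

sampled by thinning against the closed-form rate bound. Envelopes are
Gaussians along the traversal (optionally periodic, which serves both the
grid-like MEC drive and recurring ripple events). Defaults: theta 7 Hz
(depth 0.6), slow gamma 35 Hz and middle gamma 63 Hz (depth 0.4), ripple
170 Hz (depth 0.6); mean rates 5 Hz (CA3, MEC), 25 Hz (Teevra), 10 Hz
(cholinergic); 100 CA3-spatial, 100 CA3-background, 100 MEC, 40 Teevra and
20 cholinergic generators. The MEC envelope peaks 500 ms before the paired
CA3 envelope (grid period 4 s). Teevra generators are theta-paced at depth
0.9 with per-generator phase offsets within ±50° of their mean; the
cholinergic (nicotinic) drive to OLM is placed at the theta trough, and
muscarinic tone is a constant 0.09 nA into CCK basket cells.

The place-field envelope sigma is 950 ms. This value is pinned jointly by
the two stated properties of the ripple mode: a 40-fold compression of the
discharge time and a compressed discharge sequence of ~100 ms (width above
10% of the pooled-rate peak; a Gaussian crosses that threshold over
4.29 σ).

**Non-theta transform.** MEC, background CA3 and cholinergic drives are
removed; Teevra generators become constant-rate; CA3 spatial envelopes are
divided by 40 with the envelope integral preserved (mean rate × 40),
their centers converge to a common event time (recurring once per second
by default), 170 Hz modulation is added, 35 Hz retained, and the theta
modulation is removed — the non-theta state carries no theta component.

**Phase architecture.** Generator phases are quoted on a shared 7 Hz clock.
The defaults place the CA3 drive peak 65° before the clock origin and the
Teevra peak at 60°; with the default weights this yields a pyramidal-layer
LFP whose theta peak leads the CA3 volley by ≈ 95°, so that the CA3 drive
arrives on the descending phase — the model's core mechanism. The septal
pacing then sets the rest of the scheme: axo-axonic cells (paced by the
late-phase half of the Teevra population) fire at the LFP peak, CCK basket
cells (early-phase half, plus PV inhibition and their own adaptation) on
the ascending phase, PV baskets follow the CA3 volley on the descending
phase, pyramidal cells discharge in the perisomatic disinhibition gap at
the trough, OLM and bistratified cells follow the pyramidal volley, ivy
cells fire in the window left by PV and OLM inhibition, and neurogliaform
cells (released from trough-locked OLM inhibition) return at the peak.

## Network

Populations at full scale: 9000 pyr, 160 cck, 200 pvbas, 60 aac, 70 bis,
80 olm, 130 ngf, 260 ivy, 40 sca; a run at scale s instantiates
⌈s·N⌉ cells. Cells are evenly spaced on the track; the place-modulated
half of the pyramidal population is interleaved 1:1 with the unmodulated
half. Connections are Bernoulli-sampled per rule with truncated-Gaussian
weights; spatially profiled rules multiply the weight by exp(−d²/2σ²)
(CA3/MEC onto place cells, CA3 onto PV baskets) or by
1 − 0.95·exp(−d²/2σ²) (PV baskets inhibit mainly distant pyramidal
cells). At reduced scale, cell-to-cell weights are multiplied by 1/s
(capped at 20×) to preserve the expected synaptic input; generator counts
and weights are not scaled, since the drives are external axons.

The complete connection matrix (about thirty rules) is a declared default:
the hippocampome-derived table the full-size model used is not recoverable,
so the rules cover every pathway named above plus the interneuron
interactions required by the coupling scheme (mutual PV–CCK inhibition,
OLM→PV/ngf/ivy, ngf→PV, PV→bis/ivy, pyr→PV/OLM/bis/ivy feedback). Weights
were tuned once so that the default reduced network reproduces the
phase-coupling scheme; they live in `params/defaults.yaml` and are not
per-experiment knobs.

Known limitation inherited from the modeling approach: axo-axonic cells
run at a high rate (~40 Hz). Their population is small and their target is
the pyramidal axon initial segment only, so this does not disturb the
rhythm mechanisms, but it is not physiological.

## LFP

Each binned group of pyramidal compartments (32 track bins × 6 laminar
depths by default; track length 4 mm) is a point source in an infinite
homogeneous medium, σ = 0.3 S/m, with a 10 µm distance clamp:
φ_e = Σ I_k/(4πσ r). With currents in nA and distances in µm this gives mV
directly. Transmembrane currents are computed as net axial influx, which
makes per-cell sums vanish identically (the dipole condition). Only
pyramidal currents contribute. Currents and voltages are recorded at
1 kHz as boxcar means over each sampling interval (a first-order
anti-alias); electrodes default to a column at the track center at depths
+100, 0, −100, −250, −400 µm.

## Analysis battery

Filtering is 4th-order Butterworth applied forward–backward; phases come
from the analytic signal with 0° at the band-limited peak and 180° at the
trough. Rayleigh p-values use the standard circular test. The modulation
index is the Tort-style KL divergence over 18 phase bins, normalized to
[0, 1], with circular time-shift surrogates (shift ≥ 1/10 of the signal).
The n:m test centers each comparison band at m·f_θ (half-width f_θ/2),
where f_θ is the theta-band PSD peak of the same signal, and uses ≥ 200
time-shifted surrogates; m·f_θ beyond Nyquist is skipped. The
phase–frequency amplitude map uses complex Morlet wavelets on a 20–200 Hz
grid with 20 theta-phase bins, row-normalized. Phase-precession fits
maximize the resultant length of φ − a·x over a 1°/unit slope grid on
[−720, 720]. Ripple events are threshold crossings of the ripple-band
Hilbert envelope (mean + 3 SD, with an absolute floor of 5% of the
broadband RMS so that out-of-band signals yield no events), merged across
< 10 ms gaps and kept for durations in [30, 300] ms; the intra-event
frequency comes from zero crossings.

The synthetic-LFP fixture generator builds composite signals from cosine
components with envelopes, theta-phase gates, integer phase locking to the
base component and white noise, and returns ground-truth annotations. The
base (theta) component can carry a slow frequency drift (Gaussian-filtered
noise, default SD 0.4 Hz, correlation 1 s). The drift matters: a strictly
periodic signal is invariant under circular time shifts, so shift
surrogates can only destroy coupling when the rhythm's phase diffuses, as
it does in real and simulated LFP.

## What the synthetic drives do and do not emulate

The generators reproduce the spectral content (7/35/63/170 Hz), envelope
timing (MEC 500 ms before CA3; 40× ripple compression) and septal phase
structure of the inputs, as stationary rate models. They do not emulate
spike-count correlations beyond the shared rate, learning or remapping of
place fields, 2-D grid geometry, or theta-frequency drift of the real
septal pacemaker (the simulated theta is locked to 7 Hz). Passing tests
therefore certify the mechanisms under stationary, stereotyped drive, not
performance on behaving-animal data.

## Reduced-scale study conditions

Network properties are asserted at scale 0.05 (450 pyramidal cells, ~50
interneurons), 60 s of theta state for the coupling scheme and 30 s for
the out-of-field sparsity condition; these sizes keep a full simulation
within tens of seconds on one CPU while leaving ≥ 400 theta cycles for
circular statistics. The full 9000-cell configuration is reachable from
the run config but is not exercised by the default test run. At desk
scale the two pyramidal phase components (place cells on the descending
phase, background cells at the trough) are ~40–50° apart and overlap, so
the bimodality of the pooled phase histogram is asserted as component
separation (distinct preferred phases of the two cell groups) rather than
as two visually distinct histogram peaks.
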