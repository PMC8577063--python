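"""Conductance-based chemical synapses and electrical gap junctions.

Chemical kinetics are bi-exponential: after a presynaptic spike (plus axonal
delay) the conductance follows ``g(t) = g_max * norm * (exp(-t/tau_decay) -
exp(-t/tau_rise))`` where ``norm`` makes the single-spike peak equal
``g_max``.  Responses to successive spikes superpose linearly.  Three
receptor families are distinguished by reversal potential and time constants:
AMPA and nicotinic (excitatory, E = 0 mV) and GABA_A (inhibitory,
E = -75 mV) in a fast perisomatic and a slow dendritic variant.

Sign convention (consistent with the membrane step): the postsynaptic
current is ``I = g(t) * (V_post - reversal)``, positive outward; a positive
I hyperpolarizes the compartment.

Gap junctions are ohmic: ``I_i = g_gap * (V_j - V_i)`` is the current
injected into cell i (positive depolarizes i), and ``I_j = -I_i``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from . import params

SYNAPSE_KINDS = ("AMPA", "GABA_A", "nicotinic")

_KIND_TO_CLASS = {"AMPA": "ampa", "GABA_A": "gaba_fast", "nicotinic": "nicotinic"}


def peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the conductance peak after onset (ms)."""
    return (tau_rise * tau_decay / (tau_decay - tau_rise)) * np.log(tau_decay / tau_rise)


def peak_norm(tau_rise: float, tau_decay: float) -> float:
    """Normalization so a unit-weight spike peaks at unit conductance."""
    tp = peak_time(tau_rise, tau_decay)
    return 1.0 / (np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise))


@dataclass(frozen=True)
class SynapseSpec:
    kind: str                   # AMPA | GABA_A | nicotinic
    g_max: float                # uS, peak conductance per spike
    tau_rise: float             # ms
    tau_decay: float            # ms
    reversal: float             # mV
    delay: float = 1.0          # ms
    target_compartment: str = "soma"

    def __post_init__(self):
        if self.kind not in SYNAPSE_KINDS:
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")


def make_synapse(kind: str, g_max: float, delay: float = 1.0,
                 target_compartment: str = "soma", slow: bool = False) -> SynapseSpec:
    """SynapseSpec with the default kinetics table for the receptor family."""
    cls = "gaba_slow" if (kind == "GABA_A" and slow) else _KIND_TO_CLASS[kind]
    tab = params.defaults()["synapse_classes"][cls]
    return SynapseSpec(kind=kind, g_max=g_max, tau_rise=tab["tau_rise"],
                       tau_decay=tab["tau_decay"], reversal=tab["reversal"],
                       delay=delay, target_compartment=target_compartment)


@dataclass
class SynapseState:
    """Rise/decay kinetic variables plus the pending (delayed) spike queue."""

    a_rise: float = 0.0
    a_decay: float = 0.0
    t: float = 0.0
    pending: list = field(default_factory=list)  # heap of onset times (ms)


def on_presynaptic_spike(spec: SynapseSpec, state: SynapseState,
                         t: float) -> SynapseState:
    """Register a presynaptic spike at time ``t`` (conductance onset at
    ``t + delay``).  The state is advanced to ``t`` first."""
    if t < state.t:
        raise ValueError("presynaptic spike time precedes the synapse clock")
    state = advance(spec, state, t)
    heapq.heappush(state.pending, t + spec.delay)
    return state


def advance(spec: SynapseSpec, state: SynapseState, t: float) -> SynapseState:
    """Advance the kinetic variables to time ``t``, consuming due onsets."""
    norm = peak_norm(spec.tau_rise, spec.tau_decay)
    a_r, a_d, now = state.a_rise, state.a_decay, state.t
    pending = list(state.pending)
    heapq.heapify(pending)
    while pending and pending[0] <= t:
        onset = heapq.heappop(pending)
        a_r *= np.exp(-(onset - now) / spec.tau_rise)
        a_d *= np.exp(-(onset - now) / spec.tau_decay)
        a_r += spec.g_max * norm
        a_d += spec.g_max * norm
        now = onset
    a_r *= np.exp(-(t - now) / spec.tau_rise)
    a_d *= np.exp(-(t - now) / spec.tau_decay)
    return SynapseState(a_rise=a_r, a_decay=a_d, t=t, pending=pending)


def conductance(spec: SynapseSpec, state: SynapseState, t: float) -> float:
    """Instantaneous conductance (uS) at time ``t >= state.t``."""
    state = advance(spec, state, t)
    return max(state.a_decay - state.a_rise, 0.0)


def synaptic_current(spec: SynapseSpec, state: SynapseState,
                     v_post: float, t: float) -> float:
    """Postsynaptic current I = g(t) (V_post - E), nA, positive outward."""
    return conductance(spec, state, t) * (v_post - spec.reversal)


@dataclass(frozen=True)
class GapJunctionSpec:
    cell_pair: tuple[int, int]
    compartment_pair: tuple[str, str] = ("soma", "soma")
    g_gap: float = 0.001  # uS

    def __post_init__(self):
        if self.g_gap < 0:
            raise ValueError("g_gap must be >= 0")


def gap_junction_currents(v_i: float, v_j: float,
                          spec: GapJunctionSpec) -> tuple[float, float]:
    """Currents injected into the two coupled cells (nA); they sum to zero."""
    i_i = spec.g_gap * (v_j - v_i)
    return i_i, -i_i
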