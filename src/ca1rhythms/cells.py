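"""Reduced-compartment Hodgkin-Huxley neuron models for the CA1 populations.

Nine cell types are supported: pyramidal cells (``pyr``) and eight
interneuron classes (``pvbas``, ``olm``, ``cckbas``, ``ivy``, ``ngf``,
``bis``, ``aac``, ``sca``).  Pyramidal cells are reduced to six compartments
at fixed laminar depths (axon-initial segment, soma, basal dendrite and
three apical sections down to stratum lacunosum-moleculare) so that the
laminar separation of transmembrane currents -- what the LFP forward model
needs -- is representable.  Interneurons are single-compartment.

Channel complement per type (declared defaults, editable in
``params/defaults.yaml``): pyramidal cells carry transient Na, delayed
rectifier K and a slow M-type K current (spike-frequency adaptation); PV
basket and axo-axonic cells are fast-spiking (scaled gate kinetics, high
leak); OLM cells add an H-current (sag/rebound, trough-locked firing); the
remaining types are Na/K-DR/leak with per-type excitability set via leak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine, params

CELL_TYPES = ("pyr", "pvbas", "olm", "cckbas", "ivy", "ngf", "bis", "aac", "sca")

#: laminar compartment labels, somatic layer at depth 0, apical negative
COMPARTMENT_LABELS = ("axon-initial", "soma", "basal", "rad-proximal",
                      "rad-distal", "lm")

_CHANNEL_NAMES = ("na", "kdr", "km", "h", "leak")


@dataclass(frozen=True)
class ChannelDef:
    """One voltage-gated (or leak) conductance on a compartment.

    ``gating`` names the kinetic scheme; the rate functions live in
    :mod:`ca1rhythms.engine` and are finite on [-120, +60] mV.
    """

    name: str
    max_conductance: float  # mS/cm2
    reversal: float         # mV
    gating: str = ""

    def __post_init__(self):
        if self.max_conductance < 0:
            raise ValueError(f"negative conductance for channel {self.name!r}")


@dataclass(frozen=True)
class Compartment:
    label: str
    depth: float        # um along the somato-dendritic axis, apical < 0
    length: float       # um
    diameter: float     # um
    capacitance: float  # uF/cm2
    channels: tuple[ChannelDef, ...]
    axial_conductance_to_parent: float = 0.0  # uS, 0 for the root
    parent: int | None = None                  # index into CellSpec.compartments
    phi: float = 1.0                           # gate-kinetics rate scale

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0 or self.capacitance <= 0:
            raise ValueError(f"non-positive geometry in compartment {self.label!r}")

    @property
    def area_cm2(self) -> float:
        return np.pi * self.diameter * self.length * 1e-8


@dataclass(frozen=True)
class CellSpec:
    cell_type: str
    compartments: tuple[Compartment, ...]
    spike_threshold: float  # mV, upward crossing on the soma defines a spike
    refractory: float = 2.0  # ms latch after a detected spike
    position: float = 0.5    # normalized track coordinate

    def compartment_index(self, label: str) -> int:
        for i, comp in enumerate(self.compartments):
            if comp.label == label:
                return i
        raise KeyError(f"cell type {self.cell_type!r} has no compartment {label!r}")


@dataclass
class CellState:
    """Dynamic state: per-compartment voltage and gating variables in [0,1]."""

    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    z: np.ndarray
    r: np.ndarray
    t: float = 0.0
    last_spike_time: float | None = None


def _build_channels(chan_map: dict, reversals: dict, e_leak: float):
    out = []
    for name, dens in chan_map.items():
        if name not in _CHANNEL_NAMES:
            raise ValueError(f"unknown channel {name!r}; valid: {_CHANNEL_NAMES}")
        rev = e_leak if name == "leak" else reversals[name]
        out.append(ChannelDef(name=name, max_conductance=float(dens),
                              reversal=float(rev), gating=name))
    return tuple(out)


def build_cell(cell_type: str, overrides: dict | None = None,
               position: float = 0.5) -> CellSpec:
    """Construct the default :class:`CellSpec` for one of the nine types.

    ``overrides`` is merged into the YAML defaults for that type (same
    nesting, e.g. ``{"compartments": [{"channels": {"na": 120.0}}]}`` is not
    supported -- overrides address the per-type table:
    ``{"spike_threshold": -20.0}`` or a full ``compartments`` list).
    """
    table = params.defaults()
    if cell_type not in table["cells"]:
        raise ValueError(
            f"unknown cell type {cell_type!r}; valid types: {CELL_TYPES}")
    spec_d = params.deep_merge(table["cells"][cell_type], overrides or {})
    reversals = table["reversals"]
    comps = []
    labels = []
    for cd in spec_d["compartments"]:
        parent = None
        if cd.get("parent") is not None:
            parent = labels.index(cd["parent"])
        comps.append(Compartment(
            label=cd["label"],
            depth=float(cd["depth"]),
            length=float(cd["length"]),
            diameter=float(cd["diameter"]),
            capacitance=float(cd.get("cm", 1.0)),
            channels=_build_channels(cd.get("channels", {}), reversals,
                                     float(cd.get("e_leak", -65.0))),
            axial_conductance_to_parent=float(cd.get("g_axial", 0.0)),
            parent=parent,
            phi=float(cd.get("phi", 1.0)),
        ))
        labels.append(cd["label"])
    spec = CellSpec(cell_type=cell_type,
                    compartments=tuple(comps),
                    spike_threshold=float(spec_d["spike_threshold"]),
                    refractory=float(spec_d.get("refractory_ms", 2.0)),
                    position=position)
    if cell_type == "pyr":
        depths = {c.label: c.depth for c in comps}
        if not (depths["lm"] < depths["rad-distal"] < depths["rad-proximal"]
                < 0 <= depths["soma"] <= depths["basal"]):
            raise ValueError("pyramidal laminar depth ordering violated")
    return spec


class PackedCells:
    """Flat per-compartment arrays for a list of cells, in engine layout."""

    def __init__(self, specs: list[CellSpec], reversals: dict | None = None):
        reversals = reversals or params.defaults()["reversals"]
        ncomp = sum(len(s.compartments) for s in specs)
        self.specs = specs
        self.parent = np.full(ncomp, -1, dtype=np.int64)
        self.gax = np.zeros(ncomp)
        self.cm = np.zeros(ncomp)       # nF
        self.g = {name: np.zeros(ncomp) for name in _CHANNEL_NAMES}
        self.eleak = np.full(ncomp, -65.0)
        self.phi = np.ones(ncomp)
        self.depth = np.zeros(ncomp)
        self.offset = np.zeros(len(specs) + 1, dtype=np.int64)
        self.soma_idx = np.zeros(len(specs), dtype=np.int64)
        self.thresh = np.zeros(len(specs))
        self.refrac = np.zeros(len(specs))
        self.cell_of_comp = np.zeros(ncomp, dtype=np.int64)
        pos = 0
        for i, spec in enumerate(specs):
            self.offset[i] = pos
            root_seen = False
            for j, comp in enumerate(spec.compartments):
                c = pos + j
                if comp.parent is None:
                    if root_seen:
                        raise ValueError("cell has more than one root compartment")
                    root_seen = True
                else:
                    if comp.parent >= j:
                        raise ValueError("parent compartments must precede children")
                    self.parent[c] = pos + comp.parent
                    self.gax[c] = comp.axial_conductance_to_parent
                area = comp.area_cm2
                self.cm[c] = comp.capacitance * area * 1e3  # uF -> nF
                for ch in comp.channels:
                    self.g[ch.name][c] += ch.max_conductance * area * 1e3  # mS -> uS
                    if ch.name == "leak":
                        self.eleak[c] = ch.reversal
                self.phi[c] = comp.phi
                self.depth[c] = comp.depth
                self.cell_of_comp[c] = i
                if comp.label == "soma":
                    self.soma_idx[i] = c
            pos += len(spec.compartments)
            self.thresh[i] = spec.spike_threshold
            self.refrac[i] = spec.refractory
        self.offset[-1] = pos
        self.ena = float(reversals["na"])
        self.ek = float(reversals["kdr"])
        self.eh = float(reversals["h"])

    @property
    def n_comp(self) -> int:
        return self.parent.size

    def engine_args(self):
        return (self.parent, self.gax, self.cm, self.g["na"], self.g["kdr"],
                self.g["km"], self.g["h"], self.g["leak"], self.eleak,
                self.phi, self.ena, self.ek, self.eh)

    def init_state_arrays(self, v0: np.ndarray | None = None):
        """Voltages at leak reversal (or ``v0``), gates at steady state."""
        nc = self.n_comp
        v = self.eleak.copy() if v0 is None else np.asarray(v0, dtype=float).copy()
        m = np.zeros(nc)
        h = np.zeros(nc)
        n = np.zeros(nc)
        z = np.zeros(nc)
        r = np.zeros(nc)
        for c in range(nc):
            am, bm, ah, bh, an, bn = engine.rate_constants(v[c])
            m[c] = am / (am + bm)
            h[c] = ah / (ah + bh)
            n[c] = an / (an + bn)
            z[c] = 1.0 / (1.0 + np.exp(-(v[c] + 35.0) / 10.0))
            r[c] = 1.0 / (1.0 + np.exp((v[c] + 80.0) / 10.0))
        return v, m, h, n, z, r


def init_state(spec: CellSpec) -> CellState:
    packed = PackedCells([spec])
    v, m, h, n, z, r = packed.init_state_arrays()
    return CellState(v=v, m=m, h=h, n=n, z=z, r=r)


def membrane_step(spec: CellSpec, state: CellState,
                  external_currents: np.ndarray, dt: float
                  ) -> tuple[CellState, bool]:
    """Advance one cell by ``dt`` ms with per-compartment injected currents.

    Returns the new state and a spike flag (upward threshold crossing on the
    soma, honoring the refractory latch).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    nc = len(spec.compartments)
    for name, arr in (("v", state.v), ("m", state.m), ("h", state.h),
                      ("n", state.n), ("z", state.z), ("r", state.r)):
        if arr.shape != (nc,):
            raise ValueError(f"state array {name!r} does not match the spec")
        bad = np.where(~np.isfinite(arr))[0]
        if bad.size:
            raise FloatingPointError(
                f"non-finite state variable {name!r} in compartment "
                f"{spec.compartments[bad[0]].label!r}")
    iext = np.asarray(external_currents, dtype=float)
    if iext.shape != (nc,):
        raise ValueError("external_currents must have one entry per compartment")
    packed = PackedCells([spec])
    new = CellState(v=state.v.copy(), m=state.m.copy(), h=state.h.copy(),
                    n=state.n.copy(), z=state.z.copy(), r=state.r.copy(),
                    t=state.t + dt, last_spike_time=state.last_spike_time)
    gs = np.zeros(nc)
    diag = np.empty(nc)
    rhs = np.empty(nc)
    engine.step_compartments(new.v, new.m, new.h, new.n, new.z, new.r,
                             *packed.engine_args(), gs, iext, dt, diag, rhs)
    soma = spec.compartment_index("soma")
    spike = bool(new.v[soma] >= spec.spike_threshold
                 and state.v[soma] < spec.spike_threshold)
    if spike and state.last_spike_time is not None \
            and new.t - state.last_spike_time < spec.refractory:
        spike = False
    if spike:
        new.last_spike_time = new.t
    return new, spike


def run_cell(spec: CellSpec, currents_by_label: dict[str, float],
             duration: float, dt: float = 0.1):
    """Integrate one isolated cell with constant injected currents.

    Returns (spike_times ms, soma voltage trace, time base).
    """
    packed = PackedCells([spec])
    v, m, h, n, z, r = packed.init_state_arrays()
    iext = np.zeros(packed.n_comp)
    for label, amp in currents_by_label.items():
        iext[spec.compartment_index(label)] = amp
    n_steps = int(round(duration / dt))
    v_trace = np.empty(n_steps)
    spk = np.empty(max(n_steps // 10, 16))
    nspk = engine.run_single_cell(
        n_steps, dt, *packed.engine_args(), v, m, h, n, z, r,
        iext, spec.spike_threshold, int(round(spec.refractory / dt)),
        v_trace, spk)
    t = (np.arange(n_steps) + 1) * dt
    return spk[:min(nspk, spk.size)].copy(), v_trace, t


def fi_curve(spec: CellSpec, currents, duration: float = 1000.0,
             dt: float = 0.1, transient: float = 100.0):
    """Steady-state firing rate (Hz) for each somatic current level (nA)."""
    currents = list(currents)
    if not currents:
        raise ValueError("fi_curve needs at least one current level")
    if duration < 500.0:
        raise ValueError("duration must be >= 500 ms for a steady-state rate")
    rates = []
    for amp in currents:
        spikes, _, _ = run_cell(spec, {"soma": float(amp)}, duration, dt)
        n_spk = int(np.sum(spikes > transient))
        rates.append(n_spk / (duration - transient) * 1e3)
    return rates
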