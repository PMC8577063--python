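"""CA1 network construction and the simulation loop.

``build_network`` instantiates the nine populations at ``ceil(scale * N)``
cells, places them on the normalized track, wires chemical connections by
per-rule Bernoulli sampling with truncated-Gaussian weights and optional
spatial weight profiles, adds gap junctions within the PV basket and
neurogliaform populations, and attaches the external generator ensemble.
Identical (config, seed) pairs produce identical networks.

At reduced scale the cell-to-cell weights are multiplied by 1/scale (capped)
so the expected total synaptic input per cell is preserved; weights from
external generators are not rescaled because the generator count does not
scale with the network.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import cells, engine, inputs, params

POPULATIONS = ("pyr", "cckbas", "pvbas", "aac", "bis", "olm", "ngf", "ivy", "sca")

SYN_CLASSES = ("ampa", "gaba_fast", "gaba_slow", "nicotinic")


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size_full: int        # count at scale 1
    size: int             # instantiated count
    template: cells.CellSpec


@dataclass(frozen=True)
class ConnectionRule:
    pre: str              # population or generator source name
    post: str
    probability: float
    weight_mean: float    # uS
    weight_sd: float
    kind: str             # synapse class name
    target: str           # compartment label
    delay: float = 1.0    # ms
    profile: str = "none"  # none | gaussian | inverted_gaussian
    sigma: float = 0.1     # track units
    floor: float = 0.0     # inverted_gaussian floor
    subset: str = "all"    # all | spatial | nonspatial (post side, pyr only)
    pre_phase_bias: str = "none"  # none | early | late: for generator sources
    # with distributed phase offsets, connect only the earlier/later half

    def __post_init__(self):
        if not 0 <= self.probability <= 1:
            raise ValueError(f"rule {self.pre}->{self.post}: probability not in [0,1]")
        if self.weight_sd < 0:
            raise ValueError(f"rule {self.pre}->{self.post}: negative weight sd")
        if self.profile not in ("none", "gaussian", "inverted_gaussian"):
            raise ValueError(f"rule {self.pre}->{self.post}: unknown profile")


def spatial_weight(profile: str, distance, sigma: float = 0.1,
                   floor: float = 0.0):
    """Distance-dependent weight multiplier in (0, 1].

    ``gaussian`` concentrates weight on nearby targets; ``inverted_gaussian``
    (PV basket -> pyramidal) spares nearby targets and inhibits mainly
    distant ones, with a non-zero floor at zero distance.
    """
    d = np.abs(np.asarray(distance, dtype=float))
    if profile == "gaussian":
        return np.exp(-0.5 * (d / sigma) ** 2)
    if profile == "inverted_gaussian":
        return 1.0 - (1.0 - floor) * np.exp(-0.5 * (d / sigma) ** 2)
    if profile == "none":
        return np.ones_like(d)
    raise ValueError(f"unknown profile {profile!r}")


@dataclass
class Network:
    populations: dict
    cell_specs: list
    packed: cells.PackedCells
    positions: np.ndarray          # per cell, track units
    spatial_mask: np.ndarray       # per cell, True for place-modulated pyr
    pop_of_cell: np.ndarray        # population index per cell
    pop_slices: dict               # name -> slice into the cell index
    # chemical edges
    edge_pre_unit: np.ndarray      # cells 0..ncell-1, generators ncell+i
    edge_post_comp: np.ndarray     # global compartment index
    edge_class: np.ndarray         # index into SYN_CLASSES
    edge_weight: np.ndarray        # uS
    edge_delay: np.ndarray         # ms
    # gap junctions
    gj_comp_a: np.ndarray
    gj_comp_b: np.ndarray
    gj_g: np.ndarray
    itonic: np.ndarray             # per compartment, nA
    generators: list               # GeneratorSpec list
    state_config: inputs.StateConfig
    config: dict
    seed: int
    scale: float

    @property
    def n_cells(self) -> int:
        return self.pop_of_cell.size

    def cells_of(self, pop: str) -> np.ndarray:
        return np.arange(self.pop_slices[pop].start, self.pop_slices[pop].stop)

    @property
    def provenance(self) -> dict:
        text = json.dumps(self.config, sort_keys=True, default=float)
        return {"config_hash": hashlib.sha256(text.encode()).hexdigest(),
                "seed": int(self.seed), "scale": float(self.scale)}


@dataclass
class Recording:
    """Spikes, sampled voltages, laminar current channels and the time base."""

    spikes: dict                   # pop -> (cell_id within pop, t ms)
    vm: dict                       # pop -> (cell ids, array [nt, k])
    currents: np.ndarray           # [nt, n_channels] nA, pyramidal membrane
    current_positions: np.ndarray  # [n_channels, 2] (x um, depth um)
    current_labels: list           # compartment label per channel
    t: np.ndarray                  # ms, LFP sampling grid
    fs: float                      # Hz
    dt: float
    duration: float
    meta: dict = field(default_factory=dict)


def _truncated_gaussian(rng, mean, sd, size):
    """Nonnegative weights: Gaussian resampled (then clipped) at zero."""
    w = rng.normal(mean, sd, size=size)
    for _ in range(8):
        bad = w < 0
        if not bad.any():
            break
        w[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(w, 0.0, None)


def _rules_from_config(conf) -> list[ConnectionRule]:
    rules = []
    for rd in conf["connections"]:
        rules.append(ConnectionRule(
            pre=rd["pre"], post=rd["post"], probability=float(rd["p"]),
            weight_mean=float(rd["w"]), weight_sd=float(rd.get("w_sd", 0.0)),
            kind=rd["kind"], target=rd.get("target", "soma"),
            delay=float(rd.get("delay", 1.0)),
            profile=rd.get("profile", "none"),
            sigma=float(rd.get("sigma", 0.1)),
            floor=float(rd.get("floor", 0.0)),
            subset=rd.get("subset", "all"),
            pre_phase_bias=rd.get("pre_phase_bias", "none"),
        ))
    valid_pre = set(POPULATIONS) | set(inputs.SOURCES)
    bad = [f"{r.pre}->{r.post}" for r in rules
           if r.pre not in valid_pre or r.post not in POPULATIONS]
    if bad:
        raise ValueError(f"connection rules with invalid endpoints: {bad}")
    return rules


def build_network(config: dict | None = None, seed: int = 0) -> Network:
    """Deterministically build the network from a resolved config and seed."""
    conf = params.deep_merge(params.defaults(), config or {})
    sim = conf["simulation"]
    scale = float(sim.get("scale", 1.0))
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    state_cfg = inputs.StateConfig(
        state=sim.get("state", "theta"),
        traversal_ms=float(sim.get("duration", 1000.0)),
        out_of_field=bool(sim.get("out_of_field", False)),
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))

    pops = {}
    specs_all = []
    positions = []
    pop_of_cell = []
    pop_slices = {}
    spatial_mask = []
    start = 0
    for pi, name in enumerate(POPULATIONS):
        n_full = int(conf["populations"][name])
        n = max(1, math.ceil(scale * n_full))
        template = cells.build_cell(name)
        pops[name] = PopulationSpec(name=name, size_full=n_full, size=n,
                                    template=template)
        xs = (np.arange(n) + 0.5) / n
        for j in range(n):
            specs_all.append(template)
            positions.append(xs[j])
            pop_of_cell.append(pi)
            # place-modulated half of pyr interleaved 1:1 with unmodulated
            spatial_mask.append(name == "pyr" and j % 2 == 0)
        pop_slices[name] = slice(start, start + n)
        start += n
    ncell = start
    positions = np.array(positions)
    spatial_mask = np.array(spatial_mask)
    pop_of_cell = np.array(pop_of_cell)
    packed = cells.PackedCells(specs_all, conf["reversals"])

    generators = inputs.build_input_ensemble(
        state_cfg, scale=scale, seed=seed, overrides=conf.get("generators_override"))
    gen_positions = np.array([np.nan if g.place_position is None
                              else g.place_position for g in generators])
    gen_source = np.array([g.source for g in generators])

    rescale = min(1.0 / scale, float(sim.get("weight_rescale_cap", 20.0)))
    rules = _rules_from_config(conf)
    e_pre, e_comp, e_cls, e_w, e_d = [], [], [], [], []
    for rule in rules:
        post_cells = np.arange(pop_slices[rule.post].start,
                               pop_slices[rule.post].stop)
        if rule.subset == "spatial":
            post_cells = post_cells[spatial_mask[post_cells]]
        elif rule.subset == "nonspatial":
            post_cells = post_cells[~spatial_mask[post_cells]]
        template = pops[rule.post].template
        tgt_off = template.compartment_index(rule.target)
        post_comp = packed.offset[post_cells] + tgt_off
        if rule.pre in pop_slices:
            pre_units = np.arange(pop_slices[rule.pre].start,
                                  pop_slices[rule.pre].stop)
            pre_pos = positions[pre_units]
            w_scale = rescale
        else:
            gsel = np.where(gen_source == rule.pre)[0]
            if rule.pre_phase_bias != "none" and gsel.size > 1:
                phases = np.array([generators[i].theta[2] for i in gsel])
                order = gsel[np.argsort(phases, kind="stable")]
                half = order.size // 2
                gsel = order[:half] if rule.pre_phase_bias == "early" else order[half:]
            pre_units = ncell + gsel
            pre_pos = gen_positions[gsel]
            w_scale = 1.0
        if pre_units.size == 0 or post_cells.size == 0:
            continue
        conn = rng.random((pre_units.size, post_cells.size)) < rule.probability
        if rule.pre in pop_slices:  # no autapses
            same = pre_units[:, None] == post_cells[None, :]
            conn &= ~same
        ii, jj = np.nonzero(conn)
        if ii.size == 0:
            continue
        w = _truncated_gaussian(rng, rule.weight_mean, rule.weight_sd, ii.size)
        if rule.profile != "none":
            d = np.abs(pre_pos[ii] - positions[post_cells[jj]])
            w = w * spatial_weight(rule.profile, d, rule.sigma, rule.floor)
        e_pre.append(pre_units[ii])
        e_comp.append(post_comp[jj])
        e_cls.append(np.full(ii.size, SYN_CLASSES.index(rule.kind)))
        e_w.append(w * w_scale)
        e_d.append(np.full(ii.size, rule.delay))

    cat = (lambda parts, dtype: np.concatenate(parts).astype(dtype)
           if parts else np.empty(0, dtype=dtype))
    edge_pre = cat(e_pre, np.int64)
    edge_comp = cat(e_comp, np.int64)
    edge_cls = cat(e_cls, np.int64)
    edge_w = cat(e_w, np.float64)
    edge_delay = cat(e_d, np.float64)

    gj_a, gj_b, gj_g = [], [], []
    for name, gc in conf["gap_junctions"].items():
        idx = np.arange(pop_slices[name].start, pop_slices[name].stop)
        order = idx[np.argsort(positions[idx])]
        for a, b in zip(order[:-1], order[1:]):
            if rng.random() < float(gc["p"]):
                gj_a.append(packed.soma_idx[a])
                gj_b.append(packed.soma_idx[b])
                gj_g.append(float(gc["g"]))

    itonic = np.zeros(packed.n_comp)
    tonic_groups = [conf["tonic_currents"].get("background", {})]
    if state_cfg.cholinergic:
        tonic_groups.append(conf["tonic_currents"].get("cholinergic", {}))
    for group in tonic_groups:
        for name, amp in group.items():
            for c in range(pop_slices[name].start, pop_slices[name].stop):
                itonic[packed.soma_idx[c]] += float(amp)

    return Network(
        populations=pops, cell_specs=specs_all, packed=packed,
        positions=positions, spatial_mask=spatial_mask,
        pop_of_cell=pop_of_cell, pop_slices=pop_slices,
        edge_pre_unit=edge_pre, edge_post_comp=edge_comp,
        edge_class=edge_cls, edge_weight=edge_w, edge_delay=edge_delay,
        gj_comp_a=np.array(gj_a, dtype=np.int64),
        gj_comp_b=np.array(gj_b, dtype=np.int64),
        gj_g=np.array(gj_g, dtype=np.float64),
        itonic=itonic, generators=generators, state_config=state_cfg,
        config=conf, seed=seed, scale=scale)


def run_simulation(network: Network, generator_specs=None,
                   duration: float | None = None, dt: float | None = None,
                   record: dict | None = None, seed: int = 0) -> Recording:
    """Integrate the network and return a :class:`Recording`.

    ``record`` options: ``vm`` (cells per population to sample, default 2),
    ``n_xbins`` (spatial binning of pyramidal current channels),
    ``fs`` (current/voltage sampling rate, Hz).
    """
    conf = network.config
    sim = conf["simulation"]
    duration = float(sim["duration"] if duration is None else duration)
    dt = float(sim["dt"] if dt is None else dt)
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    record = record or {}
    gens = network.generators if generator_specs is None else generator_specs
    packed = network.packed
    ncell = network.n_cells
    n_steps = int(round(duration / dt))

    trains = inputs.sample_ensemble(gens, duration, seed)
    ev_step = []
    ev_unit = []
    for gi, tr in enumerate(trains):
        steps = np.floor(tr / dt).astype(np.int64)
        steps = steps[steps < n_steps]
        ev_step.append(steps)
        ev_unit.append(np.full(steps.size, ncell + gi, dtype=np.int64))
    ext_step = np.concatenate(ev_step) if ev_step else np.empty(0, np.int64)
    ext_unit = np.concatenate(ev_unit) if ev_unit else np.empty(0, np.int64)
    order = np.argsort(ext_step, kind="stable")
    ext_step = ext_step[order]
    ext_unit = ext_unit[order]

    n_units = ncell + len(gens)
    if network.edge_pre_unit.size:
        n_units = max(n_units, int(network.edge_pre_unit.max()) + 1)
    delay_steps = np.maximum(np.round(network.edge_delay / dt).astype(np.int64), 1)
    order = np.argsort(network.edge_pre_unit, kind="stable")
    proj_comp = network.edge_post_comp[order]
    proj_k = network.edge_class[order]
    proj_w = network.edge_weight[order]
    proj_delay = delay_steps[order]
    counts = np.bincount(network.edge_pre_unit, minlength=n_units)
    proj_ptr = np.zeros(n_units + 1, dtype=np.int64)
    np.cumsum(counts, out=proj_ptr[1:])

    D = int(proj_delay.max() if proj_delay.size else 1) + 2
    ring_cap = 1 << 15
    ring_count = np.zeros(D, dtype=np.int64)
    ring_comp = np.zeros((D, ring_cap), dtype=np.int64)
    ring_k = np.zeros((D, ring_cap), dtype=np.int64)
    ring_w = np.zeros((D, ring_cap), dtype=np.float64)

    syn_tab = conf["synapse_classes"]
    taur = np.array([syn_tab[k]["tau_rise"] for k in SYN_CLASSES])
    taud = np.array([syn_tab[k]["tau_decay"] for k in SYN_CLASSES])
    syn_e = np.array([syn_tab[k]["reversal"] for k in SYN_CLASSES])
    tp = (taur * taud / (taud - taur)) * np.log(taud / taur)
    syn_norm = 1.0 / (np.exp(-tp / taud) - np.exp(-tp / taur))
    Ar = np.zeros((packed.n_comp, len(SYN_CLASSES)))
    Ad = np.zeros_like(Ar)

    fs = float(record.get("fs", conf["lfp"]["fs_hz"]))
    rec_every = max(int(round(1e3 / fs / dt)), 1)
    nt_rec = n_steps // rec_every

    # laminar current channels: pyramidal compartments binned along the track
    n_xbins = int(record.get("n_xbins", conf["lfp"]["n_xbins"]))
    track_um = float(conf["lfp"]["track_length_um"])
    pyr_cells = network.cells_of("pyr")
    pyr_template = network.populations["pyr"].template
    labels = [c.label for c in pyr_template.compartments]
    depths = np.array([c.depth for c in pyr_template.compartments])
    imem_chan = np.full(packed.n_comp, -1, dtype=np.int64)
    xbin = np.minimum((network.positions * n_xbins).astype(int), n_xbins - 1)
    for ci in pyr_cells:
        for j in range(len(labels)):
            imem_chan[packed.offset[ci] + j] = xbin[ci] * len(labels) + j
    nchan = n_xbins * len(labels)
    chan_pos = np.zeros((nchan, 2))
    chan_labels = []
    for b in range(n_xbins):
        for j, lab in enumerate(labels):
            chan_pos[b * len(labels) + j, 0] = (b + 0.5) / n_xbins * track_um
            chan_pos[b * len(labels) + j, 1] = depths[j]
            chan_labels.append(lab)
    imem_out = np.zeros((nt_rec, nchan))

    n_vm = int(record.get("vm", 2))
    vm_cells = []
    for name in POPULATIONS:
        cs = network.cells_of(name)[:n_vm]
        vm_cells.extend(cs.tolist())
    vm_cells = np.array(vm_cells, dtype=np.int64)
    vm_idx = packed.soma_idx[vm_cells]
    vm_out = np.zeros((nt_rec, vm_idx.size))

    cap = int(record.get("spike_capacity", ncell * max(duration, 1.0) / 1000.0 * 60 + 1e5))
    spk_cell = np.zeros(cap, dtype=np.int64)
    spk_time = np.zeros(cap, dtype=np.float64)
    last_spike_step = np.full(ncell, -10 ** 9, dtype=np.int64)
    refrac_steps = int(round(float(packed.refrac[0]) / dt))

    v, m, h, n, z, r = packed.init_state_arrays()
    nspk, status, bad_comp, bad_step = engine.run_network(
        n_steps, dt, *packed.engine_args(),
        v, m, h, n, z, r,
        packed.soma_idx, packed.thresh, refrac_steps, last_spike_step,
        taur, taud, syn_e, syn_norm, Ar, Ad,
        ring_count, ring_comp, ring_k, ring_w,
        proj_ptr, proj_comp, proj_k, proj_w, proj_delay,
        ext_step, ext_unit, network.itonic,
        network.gj_comp_a, network.gj_comp_b, network.gj_g,
        rec_every, imem_chan, imem_out, vm_idx, vm_out,
        spk_cell, spk_time)
    if status == engine.ERR_BLOWUP:
        ci = int(packed.cell_of_comp[bad_comp])
        pop = POPULATIONS[network.pop_of_cell[ci]]
        raise RuntimeError(
            f"numerical blow-up (|V| > 200 mV) in {pop} cell {ci} "
            f"at t = {bad_step * dt:.2f} ms")
    if status != engine.OK:
        raise RuntimeError(f"simulation aborted with status {status} "
                           f"at step {bad_step} (buffer overflow)")

    spikes = {}
    vm = {}
    cell_arr = spk_cell[:nspk]
    time_arr = spk_time[:nspk]
    for name in POPULATIONS:
        sl = network.pop_slices[name]
        sel = (cell_arr >= sl.start) & (cell_arr < sl.stop)
        spikes[name] = (cell_arr[sel] - sl.start, time_arr[sel])
        vsel = (vm_cells >= sl.start) & (vm_cells < sl.stop)
        vm[name] = (vm_cells[vsel] - sl.start, vm_out[:, vsel])

    t = (np.arange(nt_rec) + 1) * rec_every * dt
    meta = dict(network.provenance)
    meta.update({"state": network.state_config.state, "duration": duration,
                 "dt": dt, "run_seed": int(seed)})
    return Recording(spikes=spikes, vm=vm, currents=imem_out,
                     current_positions=chan_pos, current_labels=chan_labels,
                     t=t, fs=1e3 / (rec_every * dt), dt=dt, duration=duration,
                     meta=meta)
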