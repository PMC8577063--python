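"""External spike drives: CA3, MEC and medial-septum generators.

Each drive is an inhomogeneous Poisson process whose rate is a product of a
mean rate, a (possibly periodic) Gaussian envelope along the simulated
traversal, and multiplicative cosine modulations:

    rate(t) = mean_rate * envelope(t)
              * (1 + d_theta * cos(2 pi f_theta t + phi))
              * (1 + d_gamma * cos(2 pi f_gamma t))
              * (1 + d_ripple * cos(2 pi f_ripple t)),  clipped at 0.

Source families (theta state):

* ``ca3_spatial`` -- CA3 place cells: Gaussian envelope at the generator's
  place position, 7 Hz theta plus 35 Hz slow-gamma modulation.
* ``ca3_nonspatial`` -- CA3 background: flat envelope, theta only.
* ``mec`` -- entorhinal layer-3 grid-like cells: slow periodic envelope
  peaking 500 ms before the paired CA3 envelope, theta plus 63 Hz
  middle-gamma modulation.
* ``ms_teevra`` -- GABAergic septal pacemakers locked to the theta trough.
* ``ms_ach`` -- cholinergic (nicotinic) drive to OLM cells, trough-locked.

The non-theta/ripple transform compresses the CA3 spatial envelope 40-fold
(preserving its integral), adds 170 Hz ripple modulation, converges the
envelope centers, and switches Teevra generators to a constant rate.

Phase convention: generator phase offsets are quoted as the clock phase (deg)
at which the rate peaks; the CA3 drive peak defines clock phase 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import params

SOURCES = ("ca3_spatial", "ca3_nonspatial", "mec", "ms_teevra", "ms_ach")


@dataclass(frozen=True)
class GeneratorSpec:
    source: str
    mean_rate: float                     # Hz
    envelope_center: float | None = None  # ms; None = flat envelope
    envelope_width: float | None = None   # ms (Gaussian sigma); None = flat
    envelope_period: float | None = None  # ms; None = single bump
    theta: tuple[float, float, float] = (7.0, 0.0, 0.0)  # (Hz, depth, peak deg)
    gamma: tuple[float, float] | None = None             # (Hz, depth)
    ripple: tuple[float, float] | None = None            # (Hz, depth)
    place_position: float | None = None                  # track units

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; valid: {SOURCES}")
        if self.mean_rate < 0:
            raise ValueError("mean_rate must be >= 0")
        for mod in (self.theta[1:2], () if self.gamma is None else (self.gamma[1],),
                    () if self.ripple is None else (self.ripple[1],)):
            for d in mod:
                if not 0 <= d <= 1:
                    raise ValueError("modulation depths must lie in [0, 1]")

    @property
    def rate_bound(self) -> float:
        """Upper bound of the rate function (Hz), used by the thinning sampler."""
        b = self.mean_rate * (1.0 + self.theta[1])
        if self.gamma is not None:
            b *= 1.0 + self.gamma[1]
        if self.ripple is not None:
            b *= 1.0 + self.ripple[1]
        return b


def envelope(spec: GeneratorSpec, t):
    """Gaussian (optionally periodic) envelope in [0, 1]; flat = 1."""
    t = np.asarray(t, dtype=float)
    if spec.envelope_width is None or spec.envelope_center is None:
        return np.ones_like(t)
    d = t - spec.envelope_center
    if spec.envelope_period is not None:
        p = spec.envelope_period
        d = (d + p / 2.0) % p - p / 2.0
    return np.exp(-0.5 * (d / spec.envelope_width) ** 2)


def rate_function(spec: GeneratorSpec, t):
    """Instantaneous rate (Hz) at time(s) ``t`` (ms); deterministic."""
    t = np.asarray(t, dtype=float)
    rate = spec.mean_rate * envelope(spec, t)
    f, d, peak = spec.theta
    rate = rate * (1.0 + d * np.cos(2e-3 * np.pi * f * t - np.deg2rad(peak)))
    if spec.gamma is not None:
        f, d = spec.gamma
        rate = rate * (1.0 + d * np.cos(2e-3 * np.pi * f * t))
    if spec.ripple is not None:
        f, d = spec.ripple
        rate = rate * (1.0 + d * np.cos(2e-3 * np.pi * f * t))
    return np.clip(rate, 0.0, None)


def sample_spike_train(spec: GeneratorSpec, t_end: float, seed) -> np.ndarray:
    """One realization of the inhomogeneous Poisson process on [0, t_end] ms.

    Thinning sampler: homogeneous candidates at the rate bound are accepted
    with probability rate(t)/bound.  Reproducible for a fixed seed.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(seed)
    bound = spec.rate_bound
    if bound <= 0:
        return np.empty(0)
    n_cand = rng.poisson(bound * t_end * 1e-3)
    cand = np.sort(rng.uniform(0.0, t_end, size=n_cand))
    accept = rng.uniform(0.0, bound, size=n_cand) < rate_function(spec, cand)
    times = cand[accept]
    return np.unique(times)  # defensive de-duplication; ties are measure-zero


def pooled_rate(trains, t_end: float, bin_ms: float = 1.0):
    """Pooled spike count per bin across trains; returns (counts, bin centers)."""
    edges = np.arange(0.0, t_end + bin_ms, bin_ms)
    counts = np.zeros(edges.size - 1)
    for tr in trains:
        c, _ = np.histogram(tr, bins=edges)
        counts += c
    return counts, (edges[:-1] + edges[1:]) / 2.0


@dataclass(frozen=True)
class StateConfig:
    """Which drives are active and in which mode.

    ``non_theta`` implies: no MEC, no non-spatial CA3, no cholinergic input,
    Teevra in constant-rate mode, CA3 spatial generators ripple-transformed.
    ``out_of_field`` silences the spatially tuned drives (their place fields
    lie outside the simulated traversal).
    """

    state: str = "theta"                # theta | non_theta
    traversal_ms: float = 60000.0       # duration of one track traversal
    out_of_field: bool = False
    nontheta_event_center_ms: float = 500.0

    def __post_init__(self):
        if self.state not in ("theta", "non_theta"):
            raise ValueError("state must be 'theta' or 'non_theta'")

    @property
    def teevra_mode(self) -> str:
        return "rhythmic" if self.state == "theta" else "constant"

    @property
    def cholinergic(self) -> bool:
        return self.state == "theta"

    @property
    def active_sources(self) -> tuple[str, ...]:
        if self.state == "theta":
            return ("ca3_spatial", "ca3_nonspatial", "mec", "ms_teevra", "ms_ach")
        return ("ca3_spatial", "ms_teevra")


def apply_nontheta_transform(spec: GeneratorSpec,
                             converge_center: float | None = None,
                             gen_params: dict | None = None) -> GeneratorSpec:
    """Ripple-mode transform of a single generator.

    CA3 spatial generators: envelope sigma divided by the compression factor
    (40 by default) with the envelope integral preserved by scaling the mean
    rate, 170 Hz ripple modulation enabled, 35 Hz slow gamma retained, and
    (when given) the envelope center moved to the common ``converge_center``.
    Teevra generators: theta modulation removed (constant discharge mode).
    """
    g = gen_params or params.defaults()["generators"]
    if spec.source == "ms_teevra":
        return replace(spec, theta=(spec.theta[0], 0.0, spec.theta[2]))
    if spec.source != "ca3_spatial":
        raise ValueError(
            "non-theta transform applies to ca3_spatial or ms_teevra sources")
    comp = float(g["nontheta_compression"])
    width = spec.envelope_width
    if width is None:
        raise ValueError("ca3_spatial generator must have an envelope to compress")
    center = converge_center if converge_center is not None else spec.envelope_center
    return replace(
        spec,
        envelope_width=width / comp,
        mean_rate=spec.mean_rate * comp,
        envelope_center=center,
        envelope_period=float(g["nontheta_event_period_ms"]),
        # the non-theta state carries no theta modulation: only slow gamma
        # (retained) and ripple-frequency modulation remain
        theta=(spec.theta[0], 0.0, spec.theta[2]),
        ripple=(float(g["ripple_freq"]), float(g["ripple_depth"])),
    )


def build_input_ensemble(state: StateConfig, scale: float = 1.0, seed: int = 0,
                         overrides: dict | None = None) -> list[GeneratorSpec]:
    """The full generator ensemble for one simulated state.

    Generator counts are independent of the network ``scale`` (the drives are
    external axons; keeping them fixed preserves the input statistics of the
    reduced network).  Deterministic for fixed (state, seed).
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    g = params.deep_merge(params.defaults()["generators"], overrides or {})
    rng = np.random.default_rng(seed)
    f_th = float(g["theta_freq"])
    d_th = float(g["theta_depth"])
    specs: list[GeneratorSpec] = []

    n_sp = int(g["counts"]["ca3_spatial"])
    positions = (np.arange(n_sp) + 0.5) / n_sp
    for x in positions:
        specs.append(GeneratorSpec(
            source="ca3_spatial",
            mean_rate=0.0 if state.out_of_field else float(g["rates"]["ca3_spatial"]),
            envelope_center=x * state.traversal_ms,
            envelope_width=float(g["envelope_sigma_ms"]),
            theta=(f_th, d_th, float(g["phase_peak_deg"]["ca3"])),
            gamma=(float(g["slow_gamma_freq"]), float(g["gamma_depth"])),
            place_position=float(x),
        ))

    if "ca3_nonspatial" in state.active_sources:
        for _ in range(int(g["counts"]["ca3_nonspatial"])):
            specs.append(GeneratorSpec(
                source="ca3_nonspatial",
                mean_rate=float(g["rates"]["ca3_nonspatial"]),
                theta=(f_th, d_th, float(g["phase_peak_deg"]["ca3"])),
            ))

    if "mec" in state.active_sources:
        n_mec = int(g["counts"]["mec"])
        positions = (np.arange(n_mec) + 0.5) / n_mec
        for x in positions:
            specs.append(GeneratorSpec(
                source="mec",
                mean_rate=0.0 if state.out_of_field else float(g["rates"]["mec"]),
                envelope_center=x * state.traversal_ms - float(g["mec_lead_ms"]),
                envelope_width=float(g["envelope_sigma_ms"]),
                envelope_period=float(g["mec_period_ms"]),
                theta=(f_th, d_th, float(g["phase_peak_deg"]["mec"])),
                gamma=(float(g["middle_gamma_freq"]), float(g["gamma_depth"])),
                place_position=float(x),
            ))

    jit = float(g["teevra_phase_jitter_deg"])
    for _ in range(int(g["counts"]["ms_teevra"])):
        phase = float(g["phase_peak_deg"]["ms_teevra"]) + rng.uniform(-jit, jit)
        depth = (float(g.get("teevra_depth", d_th))
                 if state.teevra_mode == "rhythmic" else 0.0)
        specs.append(GeneratorSpec(
            source="ms_teevra",
            mean_rate=float(g["rates"]["ms_teevra"]),
            theta=(f_th, depth, phase % 360.0),
        ))

    if "ms_ach" in state.active_sources:
        for _ in range(int(g["counts"]["ms_ach"])):
            specs.append(GeneratorSpec(
                source="ms_ach",
                mean_rate=float(g["rates"]["ms_ach"]),
                theta=(f_th, d_th, float(g["phase_peak_deg"]["ms_ach"])),
            ))

    if state.state == "non_theta":
        out = []
        for s in specs:
            if s.source == "ca3_spatial":
                out.append(apply_nontheta_transform(
                    s, converge_center=state.nontheta_event_center_ms,
                    gen_params=g))
            elif s.source == "ms_teevra":
                out.append(s)  # already constant (depth 0 above)
        specs = out
    return specs


def sample_ensemble(specs, t_end: float, seed: int) -> list[np.ndarray]:
    """Sample every generator with a per-generator child seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs))
    return [sample_spike_train(s, t_end, c) for s, c in zip(specs, children)]


def export_trains_csv(path, trains) -> None:
    """Write sampled trains as CSV rows (generator_id, spike_time_ms)."""
    with open(path, "w") as fh:
        fh.write("generator_id,spike_time_ms\n")
        for gid, tr in enumerate(trains):
            for t in tr:
                fh.write(f"{gid},{t:.6f}\n")
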