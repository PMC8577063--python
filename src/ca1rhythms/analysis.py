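"""Rhythm and cross-frequency analysis battery.

Implements the standard CA1 signal-analysis toolchain: zero-phase band-pass
filtering, analytic-signal phase, spike-phase statistics (circular mean,
resultant length, Rayleigh test), Tort-style phase-amplitude modulation
index, n:m phase-phase coupling with time-shift surrogates, theta-phase /
frequency amplitude maps (Morlet wavelets), circular-linear phase-precession
fits, and ripple-event detection, plus a deterministic synthetic-LFP fixture
generator so every operation can be tested without running the network.

Phase convention (all operations): 0 deg at the band-limited signal's local
maxima (peak), 180 deg at minima (trough); (0, 180) is the descending and
(180, 360) the ascending half-cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from . import params


@dataclass(frozen=True)
class BandDef:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError(f"band {self.name!r}: need 0 < low < high")


def default_bands() -> dict[str, BandDef]:
    return {name: BandDef(name, lo, hi)
            for name, (lo, hi) in params.defaults()["bands"].items()}


@dataclass
class RippleEvent:
    start: float              # ms
    end: float                # ms
    peak_envelope: float
    frequency: float          # Hz, intra-event oscillation frequency

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("ripple event must have end > start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class CouplingResult:
    """Container for the outputs of the analysis battery."""

    phase_histograms: dict = field(default_factory=dict)
    spike_stats: dict = field(default_factory=dict)   # pop -> (phase, R, p)
    modulation_index: dict = field(default_factory=dict)
    nm_curve: tuple | None = None                     # (m, R(m), thresholds)
    phase_amplitude_map: tuple | None = None          # (freqs, bins, map)
    precession: dict = field(default_factory=dict)
    ripples: list = field(default_factory=list)


def bandpass(x, band: BandDef, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (filtered forward and backward)."""
    x = np.asarray(x, dtype=float)
    if band.high >= fs / 2:
        raise ValueError(f"band {band.name!r} exceeds the Nyquist frequency")
    if x.size <= 3 * 2 * order:
        raise ValueError("signal too short for the filter order")
    sos = sps.butter(order, [band.low, band.high], btype="band", fs=fs,
                     output="sos")
    return sps.sosfiltfilt(sos, x)


def instantaneous_phase(filtered: np.ndarray) -> np.ndarray:
    """Analytic-signal phase in degrees [0, 360); 0 at peaks, 180 at troughs."""
    phase = np.angle(sps.hilbert(np.asarray(filtered, dtype=float)))
    return np.rad2deg(phase) % 360.0


def phase_at_times(times, phase_series, t) -> np.ndarray:
    """Phase (deg) at arbitrary times by interpolating the unwrapped series."""
    unwrapped = np.unwrap(np.deg2rad(phase_series))
    return np.rad2deg(np.interp(times, t, unwrapped)) % 360.0


def _rayleigh_p(n: int, rbar: float) -> float:
    # Standard approximation to the Rayleigh test (good for n >= 10)
    z = n * rbar ** 2
    p = np.exp(np.sqrt(1.0 + 4 * n + 4 * (n ** 2 - (rbar * n) ** 2)) - (1 + 2 * n))
    return float(min(max(p, 0.0), 1.0))


def spike_phase_stats(spike_times, phase_series, t):
    """Circular statistics of spike phases against a reference rhythm.

    Returns (preferred phase deg, resultant vector length, Rayleigh p).
    With fewer than 10 spikes the statistics are still returned but the
    p-value is flagged unreliable (NaN).
    """
    phases = np.deg2rad(phase_at_times(spike_times, phase_series, t))
    n = phases.size
    if n == 0:
        return np.nan, np.nan, np.nan
    vec = np.exp(1j * phases).mean()
    pref = np.rad2deg(np.angle(vec)) % 360.0
    rbar = np.abs(vec)
    if n < 10:
        return float(pref), float(rbar), float("nan")
    try:
        from pingouin.circular import circ_rayleigh
        _, p = circ_rayleigh(phases)
        p = float(p)
    except Exception:  # pragma: no cover - fallback approximation
        p = _rayleigh_p(n, rbar)
    return float(pref), float(rbar), p


def modulation_index(phase_series, amplitude_series, n_bins: int = 18) -> float:
    """Phase-amplitude modulation index (Kullback-Leibler based, in [0, 1]).

    The mean amplitude per phase bin is normalized to a distribution P and
    MI = KL(P || uniform) / log(n_bins); 0 for phase-independent amplitude,
    1 when all amplitude mass falls in a single bin.
    """
    phase = np.asarray(phase_series, dtype=float) % 360.0
    amp = np.asarray(amplitude_series, dtype=float)
    if phase.shape != amp.shape:
        raise ValueError("phase and amplitude series must have equal length")
    bins = np.minimum((phase / 360.0 * n_bins).astype(int), n_bins - 1)
    mean_amp = np.zeros(n_bins)
    for b in range(n_bins):
        sel = bins == b
        if sel.any():
            mean_amp[b] = amp[sel].mean()
    total = mean_amp.sum()
    if total <= 0:
        return 0.0
    p = mean_amp / total
    nz = p > 0
    kl = np.sum(p[nz] * np.log(p[nz] * n_bins))
    return float(kl / np.log(n_bins))


def mi_surrogates(phase_series, amplitude_series, n_surrogates: int = 200,
                  n_bins: int = 18, seed: int = 0, min_shift: int | None = None):
    """MI of circularly time-shifted amplitude series (null distribution)."""
    rng = np.random.default_rng(seed)
    amp = np.asarray(amplitude_series, dtype=float)
    n = amp.size
    lo = n // 10 if min_shift is None else min_shift
    out = np.empty(n_surrogates)
    for i in range(n_surrogates):
        shift = int(rng.integers(lo, n - lo))
        out[i] = modulation_index(phase_series, np.roll(amp, shift), n_bins)
    return out


def theta_peak_frequency(x, fs: float, band=(4.0, 12.0)) -> float:
    """Frequency of the power-spectrum peak inside the theta band."""
    f, p = sps.welch(np.asarray(x, float), fs=fs, nperseg=min(len(x), 4096))
    sel = (f >= band[0]) & (f <= band[1])
    return float(f[sel][np.argmax(p[sel])])


def nm_coupling(theta_phase, x, fs: float, m_values=range(1, 13),
                f_theta: float | None = None, n_surrogates: int = 200,
                seed: int = 0, min_shift_s: float = 1.0):
    """n:m phase-phase coupling between theta and faster rhythms.

    For each integer m the broadband signal is filtered around m * f_theta
    (half-width f_theta / 2) and R(m) = |<exp(i(m phi_theta - phi_m))>| is
    computed, with a 95th-percentile significance threshold from circularly
    time-shifted surrogates.  Frequencies beyond Nyquist are skipped
    (R = NaN).  Returns (m array, R array, threshold array).
    """
    x = np.asarray(x, dtype=float)
    theta_rad = np.deg2rad(np.asarray(theta_phase, dtype=float))
    if f_theta is None:
        f_theta = theta_peak_frequency(x, fs)
    rng = np.random.default_rng(seed)
    min_shift = int(min_shift_s * fs)
    m_values = np.asarray(list(m_values))
    R = np.full(m_values.size, np.nan)
    thr = np.full(m_values.size, np.nan)
    for i, m in enumerate(m_values):
        fc = m * f_theta
        lo, hi = fc - f_theta / 2.0, fc + f_theta / 2.0
        if hi >= fs / 2:
            continue
        band = BandDef(f"m{m}", lo, hi)
        phi_m = np.deg2rad(instantaneous_phase(bandpass(x, band, fs)))
        R[i] = np.abs(np.exp(1j * (m * theta_rad - phi_m)).mean())
        sur = np.empty(n_surrogates)
        for srr in range(n_surrogates):
            shift = int(rng.integers(min_shift, x.size - min_shift))
            sur[srr] = np.abs(
                np.exp(1j * (m * theta_rad - np.roll(phi_m, shift))).mean())
        thr[i] = np.percentile(sur, 95.0)
    return m_values, R, thr


def amplitude_by_theta_phase(x, fs: float, freqs=None, n_phase_bins: int = 20,
                             theta_band=(4.0, 12.0)):
    """Morlet amplitude per (frequency, theta phase) bin, row-normalized.

    Returns (freqs, phase bin centers deg, map [n_freq, n_bins]) with each
    row summing to 1.
    """
    x = np.asarray(x, dtype=float)
    if freqs is None:
        freqs = np.arange(20.0, 201.0, 5.0)
    freqs = np.asarray(freqs, dtype=float)
    theta = bandpass(x, BandDef("theta", *theta_band), fs)
    phase = instantaneous_phase(theta)
    bins = np.minimum((phase / 360.0 * n_phase_bins).astype(int),
                      n_phase_bins - 1)
    wavelet = "cmor1.5-1.0"
    fc = pywt.central_frequency(wavelet)
    scales = fc * fs / freqs
    coef, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs)
    amp = np.abs(coef)
    out = np.zeros((freqs.size, n_phase_bins))
    for b in range(n_phase_bins):
        sel = bins == b
        if sel.any():
            out[:, b] = amp[:, sel].mean(axis=1)
    row_sum = out.sum(axis=1, keepdims=True)
    row_sum[row_sum == 0] = 1.0
    out /= row_sum
    centers = (np.arange(n_phase_bins) + 0.5) * 360.0 / n_phase_bins
    return freqs, centers, out


def phase_precession(spike_times, positions, phase_series, t,
                     slope_grid=None):
    """Circular-linear fit of spike theta phase against in-field position.

    Maximizes the resultant length of (phase - slope * position) over a
    slope grid (deg per track unit); a negative slope is phase precession.
    Returns (slope, offset deg, circular-linear r).  Requires >= 20 spikes.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size < 20:
        raise ValueError("phase precession fit requires at least 20 spikes")
    phases = np.deg2rad(phase_at_times(spike_times, phase_series, t))
    if slope_grid is None:
        slope_grid = np.arange(-720.0, 721.0, 1.0)
    best = (0.0, 0.0)
    for a in slope_grid:
        r = np.abs(np.exp(1j * (phases - np.deg2rad(a) * positions)).mean())
        if r > best[1]:
            best = (a, r)
    slope, r = best
    offset = np.angle(np.exp(1j * (phases - np.deg2rad(slope) * positions)).mean())
    return float(slope), float(np.rad2deg(offset) % 360.0), float(r)


def detect_ripples(x, fs: float, band: BandDef | None = None,
                   threshold_sd: float = 3.0, min_duration: float = 30.0,
                   max_duration: float = 300.0, merge_gap: float = 10.0,
                   min_peak_fraction: float = 0.05):
    """Ripple events from the band-limited envelope.

    Events where the Hilbert envelope of the ripple band exceeds
    mean + threshold_sd * SD; events closer than ``merge_gap`` ms are merged
    and only durations within [min_duration, max_duration] ms are kept.
    The intra-event frequency comes from zero crossings of the filtered
    signal within the event.  Candidate events whose peak envelope is below
    ``min_peak_fraction`` of the broadband RMS are discarded (a signal with
    no ripple-band content otherwise triggers on numerical noise).
    """
    x = np.asarray(x, dtype=float)
    if band is None:
        band = default_bands()["ripple"]
    filt = bandpass(x, band, fs)
    env = np.abs(sps.hilbert(filt))
    thr = env.mean() + threshold_sd * env.std()
    floor = min_peak_fraction * np.sqrt(np.mean(x ** 2))
    above = env > max(thr, floor)
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = np.where(edges == 1)[0] + 1
    ends = np.where(edges == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    # merge close events
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if (s - merged[-1][1]) * 1e3 / fs < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = []
    for s, e in merged:
        dur = (e - s) * 1e3 / fs
        if not min_duration <= dur <= max_duration:
            continue
        seg = filt[s:e]
        zc = np.sum(np.diff(np.signbit(seg)) != 0)
        freq = zc / 2.0 / (dur * 1e-3)
        events.append(RippleEvent(start=s * 1e3 / fs, end=e * 1e3 / fs,
                                  peak_envelope=float(env[s:e].max()),
                                  frequency=float(freq)))
    return events


def synth_lfp_fixture(spec: dict, seed: int = 0):
    """Deterministic composite LFP test signal with ground-truth annotations.

    ``spec`` keys: ``duration_s``, ``fs``, ``noise_sd`` and ``components``,
    a list of dicts with ``freq`` (Hz), ``amp``, optional ``phase_deg``,
    optional ``theta_gate`` ((lo, hi) theta-phase window in deg that gates
    the component on), optional ``bursts`` (list of (start_ms, end_ms)
    windows), and optional ``phase_lock`` (lock the component's phase to m x
    the 0-indexed component's phase, for n:m fixtures).

    Returns (signal, t_ms, annotations).  Annotations carry the exact phase
    of each component and the realized gate/burst windows.
    """
    rng = np.random.default_rng(seed)
    fs = float(spec.get("fs", 1000.0))
    n = int(round(float(spec.get("duration_s", 10.0)) * fs))
    t = np.arange(n) / fs  # seconds
    base_phase = None
    x = np.zeros(n)
    ann = {"components": [], "t_ms": t * 1e3}
    # slow drift of the base (theta) frequency: without it, time-shift
    # surrogates cannot destroy coupling in a strictly periodic signal
    drift = spec.get("base_freq_drift")
    dfreq = np.zeros(n)
    if drift:
        from scipy.ndimage import gaussian_filter1d
        tau = float(drift.get("tau_s", 1.0))
        raw = rng.normal(0.0, 1.0, n)
        smooth = gaussian_filter1d(raw, tau * fs, mode="wrap")
        smooth /= max(smooth.std(), 1e-12)
        dfreq = float(drift.get("sd_hz", 0.3)) * smooth
    for i, comp in enumerate(spec.get("components", [])):
        f = float(comp["freq"])
        amp = float(comp.get("amp", 1.0))
        phi0 = np.deg2rad(float(comp.get("phase_deg", 0.0)))
        if comp.get("phase_lock") is not None and base_phase is not None:
            phase = comp["phase_lock"] * base_phase + phi0
        elif i == 0:
            phase = 2 * np.pi * np.cumsum(f + dfreq) / fs + phi0
        else:
            phase = 2 * np.pi * f * t + phi0
        if i == 0:
            base_phase = phase
        gate = np.ones(n)
        if comp.get("theta_gate") is not None and base_phase is not None:
            lo, hi = comp["theta_gate"]
            theta_deg = np.rad2deg(base_phase) % 360.0
            gate = ((theta_deg >= lo) & (theta_deg < hi)).astype(float)
        if comp.get("bursts"):
            gate = np.zeros(n)
            for (b0, b1) in comp["bursts"]:
                gate[(t * 1e3 >= b0) & (t * 1e3 < b1)] = 1.0
        x += amp * gate * np.cos(phase)
        ann["components"].append({
            "freq": f, "amp": amp,
            "phase_deg": np.rad2deg(phase) % 360.0,
            "gate": gate.copy(),
        })
    x += rng.normal(0.0, float(spec.get("noise_sd", 0.0)), size=n)
    return x, t * 1e3, ann
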