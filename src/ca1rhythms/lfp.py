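"""Laminar extracellular potentials by the linear volume-conductor model.

Each pyramidal compartment (or binned group of compartments) is treated as
a point current source in an infinite homogeneous medium of conductivity
sigma, so the potential at electrode e is

    phi_e(t) = sum_k I_k(t) / (4 pi sigma r_ek)

with a minimum-distance clamp.  With currents in nA, sigma in S/m and
distances in um this yields phi in mV directly.  Only pyramidal membrane
currents contribute: the ordered laminar arrangement of their processes is
what makes the CA1 field potential dipolar; interneuron contributions are
neglected.  Because every cell's transmembrane currents sum to zero, the
far field decays faster than a monopole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import params

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElectrodeSpec:
    """A column of recording sites spanning oriens -> lacunosum-moleculare."""

    positions: tuple          # ((x um, depth um), ...), depths strictly ordered
    sigma: float = 0.3        # S/m
    min_distance: float = 10.0  # um clamp around point sources

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("conductivity must be positive")
        if len(self.positions) < 2:
            raise ValueError("need at least 2 electrodes")
        depths = [p[1] for p in self.positions]
        if not (all(np.diff(depths) > 0) or all(np.diff(depths) < 0)):
            raise ValueError("electrode depths must be strictly ordered")


def default_electrodes(track_x_um: float | None = None) -> ElectrodeSpec:
    """Electrode column at the track center, one site per pyramidal layer."""
    conf = params.defaults()["lfp"]
    x = conf["track_length_um"] / 2.0 if track_x_um is None else track_x_um
    pos = tuple((x, d) for d in sorted(conf["electrode_depths_um"]))
    return ElectrodeSpec(positions=pos, sigma=conf["sigma_sm"],
                         min_distance=conf["min_distance_um"])


@dataclass
class LfpTrace:
    potentials: np.ndarray    # [n_electrodes, nt] mV
    depths: np.ndarray        # um, per electrode
    fs: float                 # Hz

    def channel_at_depth(self, depth: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.depths - depth)))
        return self.potentials[i]


def compute_lfp(currents: np.ndarray, positions: np.ndarray,
                electrodes: ElectrodeSpec, fs: float = 1000.0,
                conservation_groups: np.ndarray | None = None) -> LfpTrace:
    """Forward-model the LFP from transmembrane currents.

    Parameters
    ----------
    currents : array [nt, n_sources], nA.
    positions : array [n_sources, 2], (x, depth) um per source.
    conservation_groups : optional per-source cell labels; when given, the
        per-cell current sums are checked to vanish (relative tolerance 1e-6)
        before summation, since the dipolar far field relies on it.
    """
    currents = np.asarray(currents, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if currents.ndim != 2 or positions.shape != (currents.shape[1], 2):
        raise ValueError("currents must be [nt, n_sources] with matching positions")
    if conservation_groups is not None:
        scale = np.abs(currents).sum(axis=1) + 1e-30
        for gid in np.unique(conservation_groups):
            resid = currents[:, conservation_groups == gid].sum(axis=1)
            if np.any(np.abs(resid) > 1e-6 * scale):
                raise ValueError(
                    f"transmembrane currents of cell group {gid} do not sum to zero")
    epos = np.asarray(electrodes.positions, dtype=float)
    dx = epos[:, 0:1] - positions[None, :, 0]
    dz = epos[:, 1:2] - positions[None, :, 1]
    r = np.sqrt(dx ** 2 + dz ** 2)
    clamped = r < electrodes.min_distance
    if clamped.any():
        log.warning("%d source-electrode distances clamped to %.1f um",
                    int(clamped.sum()), electrodes.min_distance)
        r = np.maximum(r, electrodes.min_distance)
    transfer = 1.0 / (4.0 * np.pi * electrodes.sigma * r)  # mV per nA
    phi = currents @ transfer.T
    return LfpTrace(potentials=phi.T, depths=epos[:, 1], fs=fs)


def lfp_from_recording(rec, electrodes: ElectrodeSpec | None = None) -> LfpTrace:
    """LFP at the default electrode column from a simulation recording."""
    electrodes = electrodes or default_electrodes()
    return compute_lfp(rec.currents, rec.current_positions, electrodes,
                       fs=rec.fs)
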