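"""HDF5 recording I/O.

Layout::

    /spikes/<pop>/cell_id, /spikes/<pop>/t      spike tables per population
    /vm/<pop>/cell_id, /vm/<pop>/v              sampled somatic voltages
    /currents/pyr/<compartment>                 [nt, n_xbins] nA per layer
    /currents/x_um, /currents/depths_um         source-channel geometry
    /lfp/<depth_um>                             optional LFP traces (mV)
    /meta                                       config hash, seed, time base

Round trips are exact: all float arrays are written at full precision.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .network import Recording


def write_recording(rec: Recording, path, lfp_trace=None) -> None:
    labels = list(dict.fromkeys(rec.current_labels))  # unique, order-stable
    n_lab = len(labels)
    nch = len(rec.current_labels)
    n_bins = nch // n_lab if n_lab else 0
    with h5py.File(path, "w") as f:
        g = f.create_group("spikes")
        for pop, (ids, times) in rec.spikes.items():
            gp = g.create_group(pop)
            gp.create_dataset("cell_id", data=np.asarray(ids, dtype=np.int64))
            gp.create_dataset("t", data=np.asarray(times, dtype=np.float64))
        g = f.create_group("vm")
        for pop, (ids, v) in rec.vm.items():
            gp = g.create_group(pop)
            gp.create_dataset("cell_id", data=np.asarray(ids, dtype=np.int64))
            gp.create_dataset("v", data=np.asarray(v, dtype=np.float64))
        g = f.create_group("currents")
        gp = g.create_group("pyr")
        for j, lab in enumerate(labels):
            cols = [b * n_lab + j for b in range(n_bins)]
            gp.create_dataset(lab, data=rec.currents[:, cols])
        g.create_dataset("x_um",
                         data=rec.current_positions[::n_lab, 0]
                         if n_lab else np.empty(0))
        g.create_dataset(
            "depths_um",
            data=np.array([rec.current_positions[j, 1] for j in range(n_lab)]))
        g.attrs["labels"] = json.dumps(labels)
        if lfp_trace is not None:
            g = f.create_group("lfp")
            for i, depth in enumerate(lfp_trace.depths):
                g.create_dataset(f"{depth:+.0f}", data=lfp_trace.potentials[i])
            g.attrs["fs"] = lfp_trace.fs
        meta = f.create_group("meta")
        meta.create_dataset("t", data=rec.t)
        meta.attrs["fs"] = rec.fs
        meta.attrs["dt"] = rec.dt
        meta.attrs["duration"] = rec.duration
        meta.attrs["meta_json"] = json.dumps(rec.meta, default=float)


def read_recording(path) -> Recording:
    try:
        with h5py.File(path, "r") as f:
            spikes = {}
            for pop in f["spikes"]:
                gp = f["spikes"][pop]
                spikes[pop] = (gp["cell_id"][...], gp["t"][...])
            vm = {}
            for pop in f.get("vm", {}):
                gp = f["vm"][pop]
                vm[pop] = (gp["cell_id"][...], gp["v"][...])
            g = f["currents"]
            labels = json.loads(g.attrs["labels"])
            x_um = g["x_um"][...]
            depths = g["depths_um"][...]
            n_lab = len(labels)
            n_bins = x_um.size
            t = f["meta"]["t"][...]
            currents = np.zeros((t.size, n_bins * n_lab))
            positions = np.zeros((n_bins * n_lab, 2))
            chan_labels = []
            for j, lab in enumerate(labels):
                arr = g["pyr"][lab][...]
                for b in range(n_bins):
                    currents[:, b * n_lab + j] = arr[:, b]
            for b in range(n_bins):
                for j, lab in enumerate(labels):
                    positions[b * n_lab + j] = (x_um[b], depths[j])
            chan_labels = [labels[j] for _ in range(n_bins) for j in range(n_lab)]
            meta = json.loads(f["meta"].attrs["meta_json"])
            return Recording(
                spikes=spikes, vm=vm, currents=currents,
                current_positions=positions, current_labels=chan_labels,
                t=t, fs=float(f["meta"].attrs["fs"]),
                dt=float(f["meta"].attrs["dt"]),
                duration=float(f["meta"].attrs["duration"]), meta=meta)
    except (KeyError, OSError) as exc:
        raise IOError(f"not a valid recording file: {path} ({exc})") from exc
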