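"""Reading and writing the recording container and results files.

The on-disk container is HDF5 (or NPZ with the same dataset names):

* ``potentials``   — channels x samples x trials
* ``depths_um``    — per-channel depth, micrometres
* ``fs_hz``        — scalar sampling rate
* ``trial_onsets`` — per-trial stimulus-onset sample index
* ``stim_labels``  — optional per-trial condition label
* ``spikes/<structure>/<cell_id>`` — optional ragged spike-time arrays

Signals and fit results are written to HDF5 groups with a versioned schema
string; every CLI run also writes a JSON provenance record (config, seeds,
package version) alongside its output.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from . import __version__
from .containers import LaminarRecording, LaminarSignal, SpikeTrains

__all__ = [
    "read_recording",
    "write_recording",
    "read_signal",
    "write_signal",
    "write_provenance",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "lpa-container-1"
_REQUIRED = ("potentials", "depths_um", "fs_hz", "trial_onsets")


class SchemaError(ValueError):
    """A container file is missing a dataset or has inconsistent shapes."""


def _require(store, names, path) -> None:
    for name in names:
        if name not in store:
            raise SchemaError(f"{path}: missing required dataset {name!r}")


def read_recording(path) -> LaminarRecording:
    """Load a LaminarRecording from an HDF5 or NPZ container."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as npz:
            _require(npz.files, _REQUIRED, path)
            labels = npz["stim_labels"].astype(str).tolist() \
                if "stim_labels" in npz.files else None
            rec = _build_recording(npz["potentials"], npz["depths_um"],
                                   float(npz["fs_hz"]), npz["trial_onsets"],
                                   labels, path)
        return rec
    with h5py.File(path, "r") as f:
        _require(f, _REQUIRED, path)
        labels = None
        if "stim_labels" in f:
            labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in f["stim_labels"][()]]
        return _build_recording(f["potentials"][()], f["depths_um"][()],
                                float(f["fs_hz"][()]), f["trial_onsets"][()],
                                labels, path)


def _build_recording(potentials, depths, fs, onsets, labels, path):
    if labels is None:
        labels = ["unknown"] * np.asarray(potentials).shape[-1]
        logger.warning("%s: no stim_labels dataset; defaulting labels", path)
    try:
        return LaminarRecording(potentials=potentials, depths_um=depths,
                                fs_hz=fs, trial_onsets=onsets,
                                stim_labels=labels)
    except ValueError as err:
        raise SchemaError(f"{path}: {err}") from err


def write_recording(path, rec: LaminarRecording,
                    spikes: Optional[SpikeTrains] = None) -> None:
    """Write a LaminarRecording (and optional spike trains) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        f.create_dataset("potentials", data=rec.potentials)
        f.create_dataset("depths_um", data=rec.depths_um)
        f.create_dataset("fs_hz", data=rec.fs_hz)
        f.create_dataset("trial_onsets", data=rec.trial_onsets)
        if rec.stim_labels is not None:
            f.create_dataset(
                "stim_labels",
                data=np.array([str(s) for s in rec.stim_labels], dtype="S"),
            )
        if spikes is not None:
            g = f.create_group("spikes")
            g.attrs["n_trials"] = spikes.n_trials
            g.attrs["window"] = np.array(
                [spikes.window[0], min(spikes.window[1], np.finfo(float).max)]
            )
            for name, cells in spikes.trains.items():
                sg = g.create_group(name)
                for i, cell in enumerate(cells):
                    sg.create_dataset(str(i), data=cell)


def read_spikes(path) -> SpikeTrains:
    """Load spike trains stored under ``spikes/<structure>/<cell_id>``."""
    with h5py.File(path, "r") as f:
        if "spikes" not in f:
            raise SchemaError(f"{path}: missing required dataset 'spikes'")
        g = f["spikes"]
        trains = {}
        for name in g:
            cells = [g[name][cid][()] for cid in
                     sorted(g[name], key=lambda s: int(s))]
            trains[name] = cells
        window = tuple(g.attrs.get("window", (0.0, np.inf)))
        n_trials = int(g.attrs.get("n_trials", 1))
    return SpikeTrains(trains=trains, window=window, n_trials=n_trials)


def write_signal(path, sig: LaminarSignal, group: str = "signal") -> None:
    path = Path(path)
    mode = "a" if path.exists() else "w"
    with h5py.File(path, mode) as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.attrs["schema"] = SCHEMA_VERSION
        g.attrs["kind"] = sig.kind
        g.attrs["dt"] = sig.dt
        g.create_dataset("values", data=sig.values)
        g.create_dataset("depths_um", data=sig.depths_um)
        g.create_dataset("t", data=sig.t)


def read_signal(path, group: str = "signal") -> LaminarSignal:
    with h5py.File(path, "r") as f:
        if group not in f:
            raise SchemaError(f"{path}: missing group {group!r}")
        g = f[group]
        _require(g, ("values", "depths_um", "t"), path)
        return LaminarSignal(values=g["values"][()], depths_um=g["depths_um"][()],
                             t=g["t"][()], dt=float(g.attrs["dt"]),
                             kind=str(g.attrs["kind"]))


def write_provenance(path, config: dict) -> None:
    """Write a JSON provenance record (config, seeds, package version)."""
    record = {"package": "lpa", "version": __version__, "config": config}
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
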