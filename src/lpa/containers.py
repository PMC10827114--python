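"""Core in-memory containers for laminar probe data.

Conventions used throughout the package:

* depth is measured in micrometres, increasing with cortical depth (pia = 0);
* time is in seconds relative to stimulus onset, with half-open bins [t, t+dt);
* trial-resolved potentials are stored channels x samples x trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["LaminarRecording", "LaminarSignal", "SpikeTrains"]


@dataclass
class LaminarRecording:
    """Raw multi-channel extracellular potentials with trial structure.

    Parameters
    ----------
    potentials : ndarray, shape (n_channels, n_samples, n_trials)
        Extracellular potential in consistent units (e.g. volts).
    depths_um : ndarray, shape (n_channels,)
        Depth coordinate of each contact, micrometres, strictly monotone.
    fs_hz : float
        Sampling rate in Hz.
    trial_onsets : ndarray of int, shape (n_trials,)
        Stimulus-onset sample index within each trial's sample axis.
    stim_labels : sequence of str, optional
        Per-trial condition label (e.g. ``"white"``, ``"black"``).
    """

    potentials: np.ndarray
    depths_um: np.ndarray
    fs_hz: float
    trial_onsets: np.ndarray
    stim_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=int)
        if self.potentials.ndim != 3:
            raise ValueError("potentials must be channels x samples x trials")
        if self.depths_um.shape[0] != self.potentials.shape[0]:
            raise ValueError("depths length must equal channel count")
        d = np.diff(self.depths_um)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("depths must be strictly monotone")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.trial_onsets.shape[0] != self.potentials.shape[2]:
            raise ValueError("one trial onset per trial required")
        if np.any(self.trial_onsets < 0) or np.any(
            self.trial_onsets >= self.potentials.shape[1]
        ):
            raise ValueError("trial onsets must lie within the sample range")

    @property
    def n_channels(self) -> int:
        return self.potentials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.potentials.shape[1]

    @property
    def n_trials(self) -> int:
        return self.potentials.shape[2]


@dataclass
class LaminarSignal:
    """A trial-averaged channels x time matrix (MUA, LFP, or CSD)."""

    values: np.ndarray
    depths_um: np.ndarray
    t: np.ndarray
    dt: float
    kind: str

    _KINDS = ("MUA", "LFP", "CSD")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if self.values.ndim != 2:
            raise ValueError("values must be channels x time bins")
        if self.values.shape[0] != self.depths_um.shape[0]:
            raise ValueError("values row count must equal depths length")
        if self.values.shape[1] != self.t.shape[0]:
            raise ValueError("values column count must equal time axis length")
        if self.t.size > 1 and not np.allclose(np.diff(self.t), self.dt, rtol=1e-6):
            raise ValueError("t spacing must equal dt")
        if self.kind == "MUA" and np.any(self.values < 0):
            raise ValueError("MUA must be elementwise nonnegative")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray, kind: Optional[str] = None) -> "LaminarSignal":
        return LaminarSignal(
            values=np.asarray(values, dtype=float),
            depths_um=self.depths_um.copy(),
            t=self.t.copy(),
            dt=self.dt,
            kind=self.kind if kind is None else kind,
        )


@dataclass
class SpikeTrains:
    """Per-structure spike times, one array of sorted times per cell.

    ``trains`` maps a structure name to a list of per-cell spike-time arrays,
    seconds relative to trial onset.  ``window`` is the (start, stop) of the
    trial window in the same time base; spikes outside it are ignored by
    downstream rate estimation.
    """

    trains: dict
    window: tuple = (0.0, np.inf)
    n_trials: int = 1

    structures: list = field(init=False)

    def __post_init__(self) -> None:
        cleaned = {}
        for name, cells in self.trains.items():
            cleaned[name] = [np.sort(np.asarray(c, dtype=float)) for c in cells]
        self.trains = cleaned
        self.structures = list(self.trains)

    def n_cells(self, structure: str) -> int:
        return len(self.trains[structure])
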