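"""Preprocessing of raw extracellular potentials and spike trains.

Splits the broadband potential into LFP (low-pass) and MUA (high-pass) with a
zero-phase Butterworth filter, rectifies and bins the high-passed signal into a
nonnegative trial-averaged MUA matrix, and turns spike trains into smoothed
population firing rates.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps
from scipy import ndimage

from .containers import LaminarRecording, LaminarSignal, SpikeTrains

__all__ = ["butterworth_split", "mua_envelope", "lfp_average", "population_rate"]

logger = logging.getLogger(__name__)


def butterworth_split(
    rec: LaminarRecording, cutoff_hz: float = 300.0, order: int = 5
) -> Tuple[np.ndarray, np.ndarray]:
    """Split a recording into low-pass (LFP) and high-pass (MUA) branches.

    Both branches use the same Butterworth order and cutoff and are applied
    forward-backward (``filtfilt``) for zero phase distortion, per trial.

    Parameters
    ----------
    rec : LaminarRecording
    cutoff_hz : float
        Cutoff frequency; must lie strictly below the Nyquist frequency.
    order : int
        Filter order (the zero-phase application doubles the effective order).

    Returns
    -------
    (lfp_raw, mua_raw) : two ndarrays with the shape of ``rec.potentials``.
    """
    nyq = rec.fs_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyq}) Hz")
    if order < 1:
        raise ValueError("order must be >= 1")
    b_lo, a_lo = sps.butter(order, cutoff_hz, btype="low", fs=rec.fs_hz)
    b_hi, a_hi = sps.butter(order, cutoff_hz, btype="high", fs=rec.fs_hz)
    x = rec.potentials
    lfp = sps.filtfilt(b_lo, a_lo, x, axis=1)
    mua = sps.filtfilt(b_hi, a_hi, x, axis=1)
    return lfp, mua


def _bin_trial_average(
    x: np.ndarray,
    rec: LaminarRecording,
    target_dt: float,
    reducer,
) -> Tuple[np.ndarray, np.ndarray]:
    """Bin a filtered trial-resolved array into (channels x bins), averaging trials.

    Bins are half-open [t, t+dt) relative to each trial's onset sample.
    """
    samples_per_bin = int(round(target_dt * rec.fs_hz))
    if samples_per_bin < 1:
        raise ValueError("target_dt must cover at least one sample")
    n_ch, n_samp, n_trials = x.shape
    # use the longest window common to all trials
    min_pre = int(np.min(rec.trial_onsets))
    min_post = int(np.min(n_samp - rec.trial_onsets))
    n_bins_pre = min_pre // samples_per_bin
    n_bins_post = min_post // samples_per_bin
    n_bins = n_bins_pre + n_bins_post
    out = np.zeros((n_ch, n_bins))
    for tr in range(n_trials):
        start = int(rec.trial_onsets[tr]) - n_bins_pre * samples_per_bin
        seg = x[:, start : start + n_bins * samples_per_bin, tr]
        out += reducer(seg.reshape(n_ch, n_bins, samples_per_bin))
    out /= n_trials
    t = (np.arange(n_bins) - n_bins_pre) * target_dt
    return out, t


def mua_envelope(
    mua_raw: np.ndarray,
    rec: LaminarRecording,
    target_dt: float = 1e-3,
    method: str = "abs",
) -> LaminarSignal:
    """Rectify, bin, and trial-average the high-passed signal into MUA.

    The default rectification is the mean absolute value per bin, which keeps
    the binned MUA approximately linear in the local spike count — the scaling
    the bilinear MUA decomposition assumes.  ``method="rms"`` is available as
    an alternative envelope.
    """
    if target_dt < 1.0 / rec.fs_hz:
        raise ValueError("target_dt must be at least one sample long")
    if method == "abs":
        reducer = lambda seg: np.abs(seg).mean(axis=2)
    elif method == "rms":
        reducer = lambda seg: np.sqrt((seg**2).mean(axis=2))
    else:
        raise ValueError("method must be 'abs' or 'rms'")
    values, t = _bin_trial_average(mua_raw, rec, target_dt, reducer)
    return LaminarSignal(values=values, depths_um=rec.depths_um.copy(), t=t,
                         dt=target_dt, kind="MUA")


def lfp_average(
    lfp_raw: np.ndarray, rec: LaminarRecording, target_dt: float = 1e-3
) -> LaminarSignal:
    """Bin (mean) and trial-average the low-passed signal into an LFP matrix."""
    if target_dt < 1.0 / rec.fs_hz:
        raise ValueError("target_dt must be at least one sample long")
    values, t = _bin_trial_average(
        lfp_raw, rec, target_dt, lambda seg: seg.mean(axis=2)
    )
    return LaminarSignal(values=values, depths_um=rec.depths_um.copy(), t=t,
                         dt=target_dt, kind="LFP")


def population_rate(
    spikes: SpikeTrains,
    structure: str,
    t: np.ndarray,
    dt: float = 1e-3,
    sigma_bins: float = 2.0,
) -> np.ndarray:
    """Smoothed population firing rate for one structure, spikes/s per cell.

    Spike counts over all cells are histogrammed in ``dt`` bins on the time
    axis ``t`` (bin edges t[k], t[k]+dt), smoothed with a Gaussian of width
    ``sigma_bins`` bins (reflective padding, which conserves spike mass near
    the window edges), divided by ``n_cells * dt`` and averaged over trials.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if sigma_bins < 0:
        raise ValueError("sigma_bins must be nonnegative")
    cells = spikes.trains[structure]
    if len(cells) == 0:
        raise ValueError(f"structure {structure!r} has no cells")
    edges = np.concatenate([t, [t[-1] + dt]])
    lo, hi = edges[0], edges[-1]
    counts = np.zeros(t.shape[0])
    n_out = 0
    for cell in cells:
        inside = cell[(cell >= lo) & (cell < hi)]
        n_out += cell.size - inside.size
        counts += np.histogram(inside, bins=edges)[0]
    if n_out:
        logger.warning("%d spikes outside the trial window were ignored", n_out)
    if sigma_bins > 0:
        counts = ndimage.gaussian_filter1d(counts, sigma_bins, mode="reflect")
    rate = counts / (len(cells) * dt * spikes.n_trials)
    return rate
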