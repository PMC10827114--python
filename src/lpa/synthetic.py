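"""Ground-truth synthetic laminar recordings for validating the decomposition.

Emulates the flash-evoked laminar setting used to validate the method: a
probe spanning a layered structure, populations with trapezoid MUA
footprints, transient evoked firing ~50 ms after stimulus onset and offset,
per-population exponential synaptic kernels, and per-population dipolar CSD
patterns.  Everything is generated from an analytic forward model — the same
equations the decomposition inverts — with known parameters, so recovery can
be scored exactly.

The synchrony knob ``rho`` mixes a shared evoked template into each
population's response modulation:

    m_n = rho * s + (1 - rho) * u_n,

with the shared template s and the population-specific terms u_n normalized
to unit variance, so the pairwise rate correlation rises monotonically from
~0 (independent latencies and noise) to 1 (perfect synchrony).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .containers import LaminarSignal, SpikeTrains
from .csd import KernelParams, postsynaptic_profiles
from .icsd import ICSDConfig, delta_icsd_forward
from .mua import TrapezoidParams, evaluate_profiles

__all__ = ["SyntheticConfig", "SyntheticDataset", "evoked_rate", "generate",
           "pairwise_correlation", "spike_trains_from_rate"]

# mouse V1 layer thicknesses (L1, L2/3, L4, L5, L6), used as proportions
_LAYER_THICKNESS_UM = np.array([100.0, 160.0, 150.0, 200.0, 250.0])
_LAYER_NAMES = ["L1", "L2/3", "L4", "L5", "L6"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic forward model (defaults are the study conditions)."""

    n_channels: int = 26
    spacing_um: float = 40.0
    n_internal: int = 5
    n_external: int = 0
    # time axis: stimulus onset at t = 0, flash lasts stim_duration_s
    dt: float = 1e-3
    t_pre_s: float = 0.1
    stim_duration_s: float = 0.25
    t_post_s: float = 0.25
    # evoked rates
    baseline_hz: float = 5.0
    amplitude_hz: float = 30.0
    latency_s: float = 0.05
    alpha_tau_s: float = 0.012
    latency_spread_s: tuple = (0.03, 0.09)
    offset_gain: float = 0.7
    noise_frac: float = 0.35
    jitter: float = 0.2
    rho: float = 0.3
    n_trials: int = 10
    # synaptic kernels (truth); drawn per population from these ranges
    tau_range_s: tuple = (6e-3, 28e-3)
    delta_range_s: tuple = (2e-3, 12e-3)
    # CSD spatial patterns
    zero_sum: bool = True
    csd_pattern_width_um: float = 120.0
    # additive Gaussian noise levels, as signal-RMS / noise-SD;
    # None disables the noise term
    snr_mua: Optional[float] = 10.0
    snr_csd: Optional[float] = 10.0
    # "white" or "colored"; colored noise is smoothed over time and channels,
    # emulating residual structure (model mismatch) rather than sensor noise
    noise_color: str = "white"
    noise_color_t_s: float = 10e-3
    noise_color_ch: float = 1.0
    icsd: ICSDConfig = field(default_factory=ICSDConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.n_internal < 1:
            raise ValueError("need at least one internal population")
        if self.noise_color not in ("white", "colored"):
            raise ValueError("noise_color must be 'white' or 'colored'")

    @property
    def n_populations(self) -> int:
        return self.n_internal + self.n_external

    @property
    def depths_um(self) -> np.ndarray:
        return np.arange(self.n_channels) * self.spacing_um

    @property
    def t(self) -> np.ndarray:
        n_pre = int(round(self.t_pre_s / self.dt))
        n_span = int(round((self.stim_duration_s + self.t_post_s) / self.dt))
        return (np.arange(-n_pre, n_span)) * self.dt

    def layer_edges(self) -> np.ndarray:
        """Depth edges of the true layers, stretched over the probe span."""
        span = self.depths_um[-1] - self.depths_um[0]
        if self.n_internal == len(_LAYER_THICKNESS_UM):
            thickness = _LAYER_THICKNESS_UM
        else:
            thickness = np.ones(self.n_internal)
        frac = np.concatenate([[0.0], np.cumsum(thickness / thickness.sum())])
        return self.depths_um[0] + frac * span

    def layer_names(self) -> list:
        if self.n_internal == len(_LAYER_NAMES):
            return list(_LAYER_NAMES)
        return [f"L{k + 1}" for k in range(self.n_internal)]

    def true_trapezoids(self) -> list:
        """One trapezoid per internal population, tiling its layer.

        Each support spans its layer exactly (adjacent supports touch),
        mirroring cortical layers, which abut rather than leave gaps.
        """
        edges = self.layer_edges()
        params = []
        for k in range(self.n_internal):
            lo, hi = edges[k], edges[k + 1]
            w = hi - lo
            slope = 0.15 * w
            top = w - 2 * slope
            params.append(TrapezoidParams(z_um=(lo + hi) / 2.0, top_um=top,
                                          slope_um=slope))
        return params


@dataclass
class SyntheticDataset:
    """A generated recording with every ground-truth quantity attached."""

    config: SyntheticConfig
    mua: LaminarSignal
    lfp: LaminarSignal
    csd: LaminarSignal
    rates: np.ndarray
    trapezoids: list
    M_true: np.ndarray
    L_true: np.ndarray
    kernels_true: list
    contributions_true: np.ndarray
    layer_edges: np.ndarray
    layer_names: list

    @property
    def channel_layers(self) -> list:
        """True layer label of each channel."""
        idx = np.clip(
            np.searchsorted(self.layer_edges, self.csd.depths_um, side="right") - 1,
            0, len(self.layer_names) - 1,
        )
        return [self.layer_names[i] for i in idx]


def _alpha(t: np.ndarray, tau: float) -> np.ndarray:
    """Alpha function (t/tau) e^{1 - t/tau} for t >= 0, peak 1 at t = tau."""
    s = np.clip(t, 0, None) / tau
    return np.where(t >= 0, s * np.exp(1.0 - s), 0.0)


def _unit_var(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def evoked_rate(cfg: SyntheticConfig, seed: int) -> np.ndarray:
    """Per-population flash-evoked firing rates, spikes/s, shape (n_pop, B).

    Each population's modulation is rho * shared + (1 - rho) * independent,
    where the shared term is an alpha transient ~latency_s after stimulus
    onset and offset, and the independent term is an alpha transient at a
    population-specific latency plus smoothed trial noise.  Trial-to-trial
    amplitude jitter is averaged over ``n_trials``.  Rates are clipped at 0.
    """
    rng = np.random.default_rng(seed)
    t = cfg.t
    n_pop = cfg.n_populations
    onset, offset = 0.0, cfg.stim_duration_s

    shared = _unit_var(
        _alpha(t - onset - cfg.latency_s, cfg.alpha_tau_s)
        + cfg.offset_gain * _alpha(t - offset - cfg.latency_s, cfg.alpha_tau_s)
    )
    lat_lo, lat_hi = cfg.latency_spread_s
    pop_latency = rng.uniform(lat_lo, lat_hi, size=n_pop)
    pop_sign = rng.choice([-1.0, 1.0], size=n_pop)  # some pops lead, some lag

    sigma_bins = max(cfg.alpha_tau_s / cfg.dt, 1.0)
    rates = np.empty((n_pop, t.size))
    # population-specific modulations are orthogonalized (Gram-Schmidt)
    # against the shared template and each other, so the modulation-term
    # correlation is exactly rho^2 / (rho^2 + (1-rho)^2): ~0 when rho = 0
    # and 1 when rho = 1, monotone in between
    basis = [shared / np.linalg.norm(shared)]
    for n in range(n_pop):
        transient = _unit_var(
            _alpha(t - onset - pop_latency[n], cfg.alpha_tau_s)
            + cfg.offset_gain * _alpha(t - offset - pop_latency[n], cfg.alpha_tau_s)
        )
        # smoothed noise, averaged over trials with amplitude jitter
        noise = np.zeros(t.size)
        gain = 0.0
        for _ in range(cfg.n_trials):
            noise += ndimage.gaussian_filter1d(rng.standard_normal(t.size),
                                               sigma_bins, mode="reflect")
            gain += max(rng.normal(1.0, cfg.jitter), 0.0)
        noise /= cfg.n_trials
        gain /= cfg.n_trials
        raw = transient + pop_sign[n] * cfg.noise_frac * _unit_var(noise)
        raw = raw - raw.mean()  # centred space => Pearson equals cosine
        for q in basis:
            raw = raw - (raw @ q) * q
        basis.append(raw / np.linalg.norm(raw))
        indep = _unit_var(raw)
        m = cfg.rho * shared + (1.0 - cfg.rho) * indep
        rates[n] = cfg.baseline_hz + gain * cfg.amplitude_hz * 0.25 * m
    return np.clip(rates, 0.0, None)


def pairwise_correlation(rates: np.ndarray) -> float:
    """Mean off-diagonal Pearson correlation between rate rows."""
    c = np.corrcoef(rates)
    n = c.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return float(c[mask].mean())


def _csd_patterns(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-population dipolar depth patterns, (n_channels x n_pop)."""
    depths = cfg.depths_um
    span = depths[-1] - depths[0]
    n_pop = cfg.n_populations
    centers = depths[0] + span * (np.arange(n_pop) + 0.5) / n_pop
    centers = centers + rng.uniform(-0.05, 0.05, n_pop) * span
    w = cfg.csd_pattern_width_um
    L = np.empty((cfg.n_channels, n_pop))
    for n in range(n_pop):
        x = (depths - centers[n]) / w
        # derivative-of-Gaussian dipole: sink above, source below
        pattern = -x * np.exp(-0.5 * x**2)
        if cfg.zero_sum:
            pattern = pattern - pattern.mean()
        peak = np.max(np.abs(pattern))
        L[:, n] = pattern / peak if peak > 0 else pattern
    return L


def _add_noise(x: np.ndarray, snr: Optional[float], rng: np.random.Generator,
               cfg: Optional[SyntheticConfig] = None) -> np.ndarray:
    if snr is None:
        return x
    e = rng.standard_normal(x.shape)
    if cfg is not None and cfg.noise_color == "colored":
        e = ndimage.gaussian_filter(
            e, (cfg.noise_color_ch, cfg.noise_color_t_s / cfg.dt)
        )
        e /= np.sqrt(np.mean(e**2))
    target_sd = float(np.sqrt(np.mean(x**2))) / snr
    return x + target_sd * e


def generate(cfg: SyntheticConfig, seed: int) -> SyntheticDataset:
    """Draw a full synthetic dataset (MUA, LFP, CSD and all ground truths).

    MUA = M_true^T r + noise (clipped at 0) over the internal populations;
    CSD = sum_n L_n (h_n (*) r_n) + noise over all populations; LFP is the
    delta iCSD forward map of the noiseless-geometry CSD.  Fully reproducible
    given (cfg, seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1A]))
    t = cfg.t
    depths = cfg.depths_um

    rates = evoked_rate(cfg, seed=int(rng.integers(2**31)))

    trapezoids = cfg.true_trapezoids()
    M_true = evaluate_profiles(trapezoids, depths)
    mua_clean = M_true.T @ rates[: cfg.n_internal]
    mua = np.clip(_add_noise(mua_clean, cfg.snr_mua, rng), 0.0, None)

    kernels = [
        KernelParams(
            tau_s=float(rng.uniform(*cfg.tau_range_s)),
            delta_s=float(rng.uniform(*cfg.delta_range_s)),
        )
        for _ in range(cfg.n_populations)
    ]
    R = postsynaptic_profiles(rates, kernels, cfg.dt)
    L_true = _csd_patterns(cfg, rng)
    contributions = np.einsum("in,nj->nij", L_true, R)
    csd_vals = _add_noise(contributions.sum(axis=0), cfg.snr_csd, rng, cfg)

    F = delta_icsd_forward(depths, cfg.icsd)
    lfp_vals = F @ csd_vals

    mk = lambda v, kind: LaminarSignal(values=v, depths_um=depths.copy(),
                                       t=t.copy(), dt=cfg.dt, kind=kind)
    return SyntheticDataset(
        config=cfg,
        mua=mk(mua, "MUA"),
        lfp=mk(lfp_vals, "LFP"),
        csd=mk(csd_vals, "CSD"),
        rates=rates,
        trapezoids=trapezoids,
        M_true=M_true,
        L_true=L_true,
        kernels_true=kernels,
        contributions_true=contributions,
        layer_edges=cfg.layer_edges(),
        layer_names=cfg.layer_names(),
    )


def spike_trains_from_rate(
    rate_hz: np.ndarray,
    t: np.ndarray,
    dt: float,
    n_cells: int,
    n_trials: int,
    seed: int,
    structure: str = "pop",
) -> SpikeTrains:
    """Inhomogeneous-Poisson spikes realizing a rate profile (for rate-estimation tests)."""
    rng = np.random.default_rng(seed)
    p = np.clip(rate_hz * dt, 0.0, 1.0)
    cells = []
    for _ in range(n_cells):
        times = []
        for _ in range(n_trials):
            hits = rng.random(t.size) < p
            times.append(t[hits] + dt * rng.random(hits.sum()))
        cells.append(np.sort(np.concatenate(times)))
    return SpikeTrains(trains={structure: cells},
                       window=(float(t[0]), float(t[-1] + dt)),
                       n_trials=n_trials)
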