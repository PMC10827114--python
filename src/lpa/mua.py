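"""Stage 1 of Laminar Population Analysis: decomposing the MUA.

The trial-averaged MUA matrix phi_M (channels x time bins) is modelled as a
bilinear product

    phi_M,est(z_i, t_j) = sum_n M_n(z_i) r_n(t_j),

where the spatial profiles M_n are non-overlapping trapezoids of height 1
(position z_n, plateau width a_n, slope width b_n) and the temporal profiles
r_n are the population firing rates up to scale.  Given candidate trapezoids,
the optimal rates follow from the pseudoinverse, r = pinv(M) phi_M, and the
trapezoid parameters are optimized globally (differential evolution) to
minimize the relative mean square error of the reconstruction.  Fixing the
trapezoid height at 1 resolves the bilinear scale degeneracy.

Non-overlap is enforced exactly by reparameterization: the optimizer works on
nonnegative gap and width variables whose cumulative sum tiles the probe span,
so every candidate parameter vector corresponds to a feasible, ordered,
non-overlapping configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .containers import LaminarSignal
from .metrics import UNASSIGNED, relative_mse

__all__ = [
    "TrapezoidParams",
    "trapezoid_eval",
    "trapezoid_overlap",
    "infer_rates",
    "MUAModel",
    "MUAResults",
]

logger = logging.getLogger(__name__)


@dataclass
class TrapezoidParams:
    """One population's spatial profile: plateau centre, top width, slope width.

    All in micrometres; the profile is 1 on [z - a/2, z + a/2], ramps linearly
    to 0 over width b on each side, and is 0 outside the support
    [z - a/2 - b, z + a/2 + b].
    """

    z_um: float
    top_um: float
    slope_um: float

    def __post_init__(self) -> None:
        if self.top_um < 0 or self.slope_um < 0:
            raise ValueError("widths must be nonnegative")

    @property
    def support(self) -> tuple:
        half = self.top_um / 2.0 + self.slope_um
        return (self.z_um - half, self.z_um + half)


def trapezoid_eval(
    z_um: float, top_um: float, slope_um: float, depths_um: np.ndarray
) -> np.ndarray:
    """Evaluate a height-1 trapezoid profile on the depth grid.

    Degenerate a = b = 0 yields an indicator at the single nearest grid point.
    """
    if top_um < 0 or slope_um < 0:
        raise ValueError("widths must be nonnegative")
    depths_um = np.asarray(depths_um, dtype=float)
    d = np.abs(depths_um - z_um)
    if top_um == 0 and slope_um == 0:
        out = np.zeros_like(depths_um)
        out[np.argmin(d)] = 1.0
        return out
    if slope_um == 0:
        return (d <= top_um / 2.0).astype(float)
    return np.clip((top_um / 2.0 + slope_um - d) / slope_um, 0.0, 1.0)


def trapezoid_overlap(p: TrapezoidParams, lo: float, hi: float) -> float:
    """Exact integral of the trapezoid profile over the depth interval [lo, hi]."""
    a2 = p.top_um / 2.0
    b = p.slope_um
    knots = np.array([p.z_um - a2 - b, p.z_um - a2, p.z_um + a2, p.z_um + a2 + b])
    pts = np.unique(np.clip(np.concatenate([knots, [lo, hi]]), lo, hi))
    if pts.size < 2:
        return 0.0
    vals = trapezoid_eval(p.z_um, p.top_um, max(p.slope_um, 0.0), pts) \
        if (p.top_um or p.slope_um) else np.zeros_like(pts)
    # piecewise-linear => trapezoid rule on its knots is exact
    return float(np.trapezoid(vals, pts))


def evaluate_profiles(
    params: Sequence[TrapezoidParams], depths_um: np.ndarray
) -> np.ndarray:
    """Stack trapezoid profiles into the (n_pop x n_channels) spatial matrix M."""
    return np.array(
        [trapezoid_eval(p.z_um, p.top_um, p.slope_um, depths_um) for p in params]
    )


def infer_rates(M: np.ndarray, phi_m: np.ndarray) -> tuple:
    """Least-squares temporal profiles given spatial profiles.

    With M the (n_pop x n_channels) spatial matrix and phi_M the
    (n_channels x B) MUA, solves phi_M ~ M^T r by pseudoinverse:
    r = pinv(M^T) phi_M, shape (n_pop x B).  Returns ``(r, full_rank)``;
    no nonnegativity constraint is imposed.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    rank = np.linalg.matrix_rank(M)
    full_rank = rank == M.shape[0]
    if not full_rank:
        logger.warning("spatial matrix is rank deficient (rank %d < %d)",
                       rank, M.shape[0])
    return np.linalg.pinv(M.T) @ phi_m, full_rank


def _units_to_params(
    u: np.ndarray,
    n_pop: int,
    z_lo: float,
    z_hi: float,
    min_top_um: float,
    min_slope_um: float,
) -> list:
    """Map unit-box optimizer variables to an ordered non-overlapping layout.

    ``u`` holds n_pop+1 gap weights, n_pop top-width weights and n_pop
    slope-width weights, all in [0, 1].  Minimum widths are reserved first;
    the remaining span is distributed proportionally to the weights, so the
    gaps and supports always tile [z_lo, z_hi] exactly.
    """
    span = z_hi - z_lo
    gaps_w = np.asarray(u[: n_pop + 1], dtype=float)
    tops_w = np.asarray(u[n_pop + 1 : 2 * n_pop + 1], dtype=float)
    slopes_w = np.asarray(u[2 * n_pop + 1 :], dtype=float)
    reserved = n_pop * (min_top_um + 2 * min_slope_um)
    free = span - reserved
    if free < 0:
        raise ValueError("populations cannot fit on the probe span")
    # effective span consumed per unit weight: gaps count once, slopes twice
    weight_total = gaps_w.sum() + tops_w.sum() + 2 * slopes_w.sum()
    if weight_total <= 0:
        scale = 0.0
    else:
        scale = free / weight_total
    tops = min_top_um + tops_w * scale
    slopes = min_slope_um + slopes_w * scale
    gaps = gaps_w * scale
    params = []
    cursor = z_lo
    for n in range(n_pop):
        cursor += gaps[n]
        z = cursor + slopes[n] + tops[n] / 2.0
        params.append(TrapezoidParams(z_um=z, top_um=tops[n], slope_um=slopes[n]))
        cursor += tops[n] + 2 * slopes[n]
    return params


class MUAModel:
    """Trapezoid-population decomposition of a trial-averaged MUA matrix.

    Parameters
    ----------
    mua : LaminarSignal with kind "MUA"
    n_populations : int
        Number of laminar populations assumed a priori.
    min_top_um, min_slope_um : float
        Minimum plateau and slope widths (micrometres) reserved per
        population; defaults are one contact spacing and 0.
    """

    def __init__(
        self,
        mua: LaminarSignal,
        n_populations: int,
        min_top_um: Optional[float] = None,
        min_slope_um: float = 0.0,
    ) -> None:
        if mua.kind != "MUA":
            raise ValueError("MUAModel expects a signal of kind 'MUA'")
        if n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        self.mua = mua
        self.n_populations = int(n_populations)
        spacing = float(np.median(np.abs(np.diff(mua.depths_um))))
        self.min_top_um = spacing if min_top_um is None else float(min_top_um)
        self.min_slope_um = float(min_slope_um)
        # let supports extend half a contact spacing beyond the outermost
        # contacts: populations are not clipped by where the probe ends, and
        # the edge channels stay coverable by a plateau
        self.z_lo = float(np.min(mua.depths_um)) - spacing / 2.0
        self.z_hi = float(np.max(mua.depths_um)) + spacing / 2.0
        reserved = self.n_populations * (self.min_top_um + 2 * self.min_slope_um)
        if reserved > self.z_hi - self.z_lo:
            raise ValueError("populations cannot fit on the probe span")

    @classmethod
    def from_arrays(
        cls, values: np.ndarray, depths_um: np.ndarray, dt: float,
        n_populations: int, **kw
    ) -> "MUAModel":
        t = np.arange(np.asarray(values).shape[1]) * dt
        sig = LaminarSignal(values=values, depths_um=depths_um, t=t, dt=dt,
                            kind="MUA")
        return cls(sig, n_populations, **kw)

    # -- objective ---------------------------------------------------------

    def _objective(self, u: np.ndarray) -> float:
        params = _units_to_params(
            u, self.n_populations, self.z_lo, self.z_hi,
            self.min_top_um, self.min_slope_um,
        )
        M = evaluate_profiles(params, self.mua.depths_um)
        r, _ = infer_rates(M, self.mua.values)
        return relative_mse(self.mua.values, M.T @ r)

    def fit(
        self,
        seed: int = 0,
        maxiter: int = 120,
        popsize: int = 15,
        tol: float = 1e-7,
        polish: bool = True,
    ) -> "MUAResults":
        """Fit trapezoid parameters by differential evolution (deterministic per seed)."""
        ndim = 3 * self.n_populations + 1
        bounds = [(0.0, 1.0)] * ndim
        result = differential_evolution(
            self._objective,
            bounds,
            seed=seed,
            maxiter=maxiter,
            popsize=popsize,
            tol=tol,
            polish=polish,
            init="sobol",
        )
        params = _units_to_params(
            result.x, self.n_populations, self.z_lo, self.z_hi,
            self.min_top_um, self.min_slope_um,
        )
        M = evaluate_profiles(params, self.mua.depths_um)
        rates, full_rank = infer_rates(M, self.mua.values)
        e_m = relative_mse(self.mua.values, M.T @ rates)
        return MUAResults(
            model=self, params=params, M=M, rates=rates, e_m=e_m,
            full_rank=full_rank, seed=seed, optimizer_result=result,
        )


@dataclass
class MUAResults:
    """Fitted stage-1 decomposition: spatial profiles, rates and diagnostics."""

    model: MUAModel
    params: list
    M: np.ndarray
    rates: np.ndarray
    e_m: float
    full_rank: bool
    seed: int
    optimizer_result: object = field(repr=False, default=None)

    @property
    def reconstruction(self) -> np.ndarray:
        """phi_M,est = M^T r, channels x time bins."""
        return self.M.T @ self.rates

    @property
    def rates_normalized(self) -> np.ndarray:
        """Rates normalized to the highest value across all populations."""
        peak = np.max(np.abs(self.rates))
        return self.rates / peak if peak > 0 else self.rates

    @property
    def centers_um(self) -> np.ndarray:
        return np.array([p.z_um for p in self.params])

    def assign_layers(self, layer_edges, layer_names) -> tuple:
        """Label populations and channels with anatomical layers.

        Each population gets the layer its profile overlaps most with (exact
        piecewise-linear integral; ties go to the shallower layer).  Each
        channel gets the layer of the population whose support contains it;
        channels outside every support are labelled "unassigned".

        Returns ``(channel_labels, population_labels)``.
        """
        layer_edges = np.asarray(layer_edges, dtype=float)
        if layer_edges.size != len(layer_names) + 1:
            raise ValueError("need len(layer_names) + 1 edges")
        pop_labels = []
        for p in self.params:
            overlaps = np.array([
                trapezoid_overlap(p, layer_edges[k], layer_edges[k + 1])
                for k in range(len(layer_names))
            ])
            # round so that constructed symmetric ties resolve to the
            # shallower layer rather than to float noise
            pop_labels.append(layer_names[int(np.argmax(overlaps.round(9)))])
        chan_labels = []
        for z in self.model.mua.depths_um:
            label = UNASSIGNED
            for p, lab in zip(self.params, pop_labels):
                lo, hi = p.support
                if lo <= z <= hi:
                    label = lab
                    break
            chan_labels.append(label)
        return chan_labels, pop_labels

    def summary(self) -> pd.DataFrame:
        """Per-population table of fitted trapezoid parameters."""
        df = pd.DataFrame(
            {
                "center_um": [p.z_um for p in self.params],
                "top_um": [p.top_um for p in self.params],
                "slope_um": [p.slope_um for p in self.params],
                "support_lo_um": [p.support[0] for p in self.params],
                "support_hi_um": [p.support[1] for p in self.params],
                "peak_rate": np.max(self.rates, axis=1),
            },
            index=[f"pop{n}" for n in range(len(self.params))],
        )
        df.attrs["relative_mse"] = self.e_m
        return df
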