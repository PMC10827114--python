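"""PCA and ICA decompositions of the CSD, for head-to-head comparison.

Both operate on the channels x time CSD matrix with channels as variables and
time bins as observations (spatial decomposition).  Each component is an
(loading over channels, score over time) pair whose outer product is that
component's CSD; matching components to ground-truth population contributions
uses maximum |correlation| assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import FastICA

from .metrics import pearson_corr

__all__ = ["ComponentSet", "pca_decompose", "ica_decompose", "match_components"]

logger = logging.getLogger(__name__)


@dataclass
class ComponentSet:
    """k spatial/temporal component pairs with per-component CSD.

    loadings : (n_channels, k); scores : (k, n_bins).
    ``component_csd[i] = outer(loadings[:, i], scores[i])``.
    ``variance_fractions`` is populated for PCA only.
    """

    method: str
    loadings: np.ndarray
    scores: np.ndarray
    mean: np.ndarray
    variance_fractions: Optional[np.ndarray] = None
    converged: bool = True

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def component_csd(self) -> np.ndarray:
        return np.einsum("ik,kj->kij", self.loadings, self.scores)

    def reconstruction(self, include_mean: bool = True) -> np.ndarray:
        rec = self.loadings @ self.scores
        if include_mean:
            rec = rec + self.mean[:, None]
        return rec


def pca_decompose(C: np.ndarray, k: int) -> ComponentSet:
    """Principal components of the CSD via SVD of the per-channel-centred matrix."""
    C = np.asarray(C, dtype=float)
    n_ch, n_bins = C.shape
    if not 1 <= k <= min(n_ch, n_bins):
        raise ValueError(f"k must lie in [1, {min(n_ch, n_bins)}]")
    mean = C.mean(axis=1)
    X = C - mean[:, None]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    fractions = var / var.sum()
    loadings = U[:, :k]
    scores = (s[:k, None] * Vt[:k])
    return ComponentSet(method="pca", loadings=loadings, scores=scores,
                        mean=mean, variance_fractions=fractions[:k])


def ica_decompose(C: np.ndarray, k: int, seed: int = 0,
                  max_iter: int = 500) -> ComponentSet:
    """Spatial FastICA of the CSD; sign/order canonicalized by peak score amplitude."""
    C = np.asarray(C, dtype=float)
    n_ch, n_bins = C.shape
    if not 1 <= k <= n_ch:
        raise ValueError(f"k must lie in [1, {n_ch}]")
    mean = C.mean(axis=1)
    X = (C - mean[:, None]).T  # samples (time bins) x features (channels)
    converged = True
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[k - 1] <= 1e-10 * sv[0]:
        # duplicated / collinear sources: the unmixing problem is degenerate
        converged = False
        logger.warning("input is numerically rank deficient (rank < k); "
                       "ICA unmixing is degenerate")
    # arbitrary-variance whitening: robust to exactly rank-deficient input
    # (the component CSD outer products are scale-convention invariant)
    ica = FastICA(n_components=k, random_state=seed, max_iter=max_iter,
                  whiten="arbitrary-variance")
    import warnings

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        S = ica.fit_transform(X)  # (n_bins, k) temporal sources
        for w in caught:
            if "did not converge" in str(w.message).lower() or \
               "convergence" in str(w.message).lower():
                converged = False
                logger.warning("FastICA did not converge: %s", w.message)
    loadings = ica.mixing_  # (n_channels, k)
    scores = S.T
    # canonical order: decreasing component CSD energy; canonical sign: the
    # loading's largest-|.| entry is positive
    energy = (loadings**2).sum(axis=0) * (scores**2).sum(axis=1)
    order = np.argsort(energy)[::-1]
    loadings = loadings[:, order]
    scores = scores[order]
    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                             np.arange(k)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    scores = scores * signs[:, None]
    return ComponentSet(method="ica", loadings=loadings, scores=scores,
                        mean=mean, converged=converged)


def match_components(component_csd: np.ndarray,
                     true_contributions: np.ndarray) -> tuple:
    """Assign components to true contributions by maximum |correlation|.

    Returns ``(assignment, corr_matrix)`` where ``assignment[i]`` is the true
    contribution index matched to component i (one-to-one, Hungarian
    assignment on |r|).
    """
    n_comp = component_csd.shape[0]
    n_true = true_contributions.shape[0]
    corr = np.zeros((n_comp, n_true))
    for i in range(n_comp):
        for j in range(n_true):
            corr[i, j] = pearson_corr(component_csd[i], true_contributions[j])
    rows, cols = linear_sum_assignment(-np.abs(corr))
    assignment = dict(zip(rows.tolist(), cols.tolist()))
    return assignment, corr
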