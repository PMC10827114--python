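"""Classification and similarity metrics for validating laminar decompositions.

Layer identification from spatial profiles is a multiclass classification
problem over probe channels; it is scored with a confusion matrix
(predicted layer on rows, true layer on columns, rows normalized to
proportions) and the per-layer precision, recall and F1 derived from it.
Similarity between estimated and true firing rates or CSD patterns is scored
with the Pearson correlation over the flattened arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionResult", "confusion_matrix", "pearson_corr", "relative_mse"]

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class ConfusionResult:
    """Confusion matrix (predicted rows x true columns) with per-layer scores."""

    counts: pd.DataFrame
    proportions: pd.DataFrame
    precision: pd.Series
    recall: pd.Series
    f1: pd.Series
    n_excluded: int = 0

    @property
    def layers(self) -> list:
        return list(self.counts.index)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"precision": self.precision, "recall": self.recall, "f1": self.f1}
        )


def confusion_matrix(pred, true, layer_order) -> ConfusionResult:
    """Tally per-channel predicted vs true layers and derive P/R/F1 per layer.

    Channels predicted as ``"unassigned"`` (outside every population support)
    are excluded from the tally; the count of exclusions is logged and
    returned.  Row k, column l counts channels predicted in layer k that truly
    lie in layer l; proportions normalize each row by its sum.
    """
    pred = list(pred)
    true = list(true)
    if len(pred) != len(true):
        raise ValueError("pred and true must have equal length")
    layer_order = list(layer_order)
    known = set(layer_order)
    for lab in true:
        if lab not in known:
            raise ValueError(f"unknown true label {lab!r}")
    for lab in pred:
        if lab not in known and lab != UNASSIGNED:
            raise ValueError(f"unknown predicted label {lab!r}")

    keep = [i for i, p in enumerate(pred) if p != UNASSIGNED]
    n_excluded = len(pred) - len(keep)
    if n_excluded:
        logger.info("%d unassigned channels excluded from confusion matrix",
                    n_excluded)

    k = len(layer_order)
    idx = {lab: i for i, lab in enumerate(layer_order)}
    counts = np.zeros((k, k), dtype=int)
    for i in keep:
        counts[idx[pred[i]], idx[true[i]]] += 1

    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(row_sums[:, None] > 0, counts / row_sums[:, None], 0.0)
    for i, lab in enumerate(layer_order):
        if row_sums[i] == 0:
            logger.warning("layer %s has no predicted channels", lab)

    tp = np.diag(counts).astype(float)
    col_sums = counts.sum(axis=0)
    precision = np.where(row_sums > 0, tp / np.maximum(row_sums, 1), 0.0)
    recall = np.where(col_sums > 0, tp / np.maximum(col_sums, 1), 0.0)
    denom = precision + recall
    f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)

    counts_df = pd.DataFrame(counts, index=layer_order, columns=layer_order)
    props_df = pd.DataFrame(props, index=layer_order, columns=layer_order)
    return ConfusionResult(
        counts=counts_df,
        proportions=props_df,
        precision=pd.Series(precision, index=layer_order),
        recall=pd.Series(recall, index=layer_order),
        f1=pd.Series(f1, index=layer_order),
        n_excluded=n_excluded,
    )


def pearson_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation coefficient over the flattened arrays."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("arrays must have the same shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])


def relative_mse(x: np.ndarray, x_est: np.ndarray) -> float:
    """Relative mean square error: sum((x - x_est)^2) / sum(x^2).

    The scale-free fit criterion used for both the MUA and CSD stages.
    """
    x = np.asarray(x, dtype=float)
    x_est = np.asarray(x_est, dtype=float)
    if x.shape != x_est.shape:
        raise ValueError("arrays must have the same shape")
    denom = float(np.sum(x**2))
    if denom == 0:
        raise ValueError("relative MSE undefined for an all-zero reference")
    return float(np.sum((x - x_est) ** 2) / denom)
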