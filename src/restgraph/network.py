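"""Subject-level connectivity: full partial correlations and graph weights.

The partial correlation between two nodes conditions on all remaining
nodes via the precision matrix: pcorr_ij = -P_ij / sqrt(P_ii P_jj) where
P is the inverse of the covariance of the N series.  Absolute values of
the off-diagonal entries become the weights of a fully weighted,
undirected graph; positive and negative couplings of equal magnitude are
deliberately given the same weight.
"""

from __future__ import annotations

import numpy as np
from sklearn.covariance import ledoit_wolf

from .core import ConnectivityMatrix, RoiTimeSeries, WeightedGraph

__all__ = [
    "partial_correlation",
    "partial_correlation_from_covariance",
    "to_weighted_graph",
    "connectivity_graph",
]

# Plain inversion is used unless the sample covariance is ill-conditioned or
# the number of retained volumes is too small relative to N.
CONDITION_LIMIT = 1e8


def partial_correlation_from_covariance(cov: np.ndarray) -> np.ndarray:
    """Exact partial-correlation matrix of a (population) covariance."""
    cov = np.asarray(cov, dtype=float)
    precision = np.linalg.inv(cov)
    return _standardize_precision(precision)


def _standardize_precision(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    pcorr = -precision / np.outer(d, d)
    np.fill_diagonal(pcorr, 1.0)
    return (pcorr + pcorr.T) / 2.0


def partial_correlation(
    ts: RoiTimeSeries, allow_shrinkage: bool = True
) -> ConnectivityMatrix:
    """Full-conditioning partial correlations of the uncensored volumes.

    The sample covariance is inverted directly when well-posed; a
    Ledoit-Wolf shrinkage covariance replaces it when the condition number
    exceeds ``CONDITION_LIMIT`` or fewer than 2N uncensored volumes remain.
    The estimator actually used is recorded on the result.
    """
    data = ts.uncensored()
    t_eff, n = data.shape
    if n < 3:
        raise ValueError("need at least 3 nodes for partial correlation")
    if t_eff <= n:
        if not allow_shrinkage:
            raise ValueError(
                f"ill-posed: {t_eff} uncensored volumes for {n} nodes and shrinkage disabled"
            )
        return _shrinkage_estimate(data, ts.node_labels, cond=np.inf)

    cov = np.cov(data, rowvar=False)
    cond = np.linalg.cond(cov)
    if cond > CONDITION_LIMIT or t_eff <= 2 * n:
        if not allow_shrinkage:
            raise ValueError(
                f"ill-posed: condition number {cond:.3g} with shrinkage disabled"
            )
        return _shrinkage_estimate(data, ts.node_labels, cond=cond)
    pcorr = _standardize_precision(np.linalg.inv(cov))
    return ConnectivityMatrix(pcorr, "pseudo-inverse", float(cond), ts.node_labels)


def _shrinkage_estimate(
    data: np.ndarray, labels: list[str] | None, cond: float
) -> ConnectivityMatrix:
    shrunk, _ = ledoit_wolf(data)
    pcorr = _standardize_precision(np.linalg.inv(shrunk))
    return ConnectivityMatrix(pcorr, "shrinkage", float(cond), labels)


def to_weighted_graph(c: ConnectivityMatrix) -> WeightedGraph:
    """Graph weights = |partial correlation|, zero diagonal."""
    w = np.abs(c.pcorr)
    np.fill_diagonal(w, 0.0)
    w = np.clip(w, 0.0, 1.0)
    return WeightedGraph(w, c.node_labels)


def connectivity_graph(ts: RoiTimeSeries, allow_shrinkage: bool = True) -> WeightedGraph:
    """Convenience: partial correlation followed by the weight transform."""
    return to_weighted_graph(partial_correlation(ts, allow_shrinkage=allow_shrinkage))
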