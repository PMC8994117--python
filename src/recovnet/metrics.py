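"""Global properties of thresholded weighted networks.

Three scalars per network: total connectivity strength (sum of
suprathreshold edge weights), global efficiency (mean inverse weighted
shortest-path length over node pairs; integration) and local efficiency
(mean, over nodes, of the global efficiency of each node's
neighbourhood-induced subgraph; segregation). Edges carry connectivity
weights; path lengths use the standard reciprocal convention
length = 1 / weight, so stronger connections are shorter. Disconnected
node pairs contribute an inverse path length of 0.

Patient values are referenced to the control distribution as
Z = (P - mean) / SD with the sample (n-1) standard deviation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import ConnectivityMatrix, GlobalNetworkProperties

__all__ = [
    "fc_strength",
    "global_efficiency",
    "local_efficiency",
    "network_properties",
    "network_zscore",
    "ControlZScorer",
]


def _weight_matrix(net: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Dense weight matrix with 0 meaning 'no edge'; validates positivity."""
    if isinstance(net, ConnectivityMatrix):
        w = net.weights()
    else:
        w = np.asarray(net, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        w = w.copy()
    np.fill_diagonal(w, 0.0)
    if np.any(w < 0):
        raise ValueError("edge weights must be positive (threshold the network first)")
    return w


def fc_strength(net: ConnectivityMatrix | np.ndarray) -> float:
    """Sum of surviving edge weights, each undirected edge counted once."""
    w = _weight_matrix(net)
    return float(np.triu(w, 1).sum())


def _pairwise_lengths(w: np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path lengths with length = 1/weight."""
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    return shortest_path(lengths, method="D", directed=False, unweighted=False)


def global_efficiency(net: ConnectivityMatrix | np.ndarray) -> float:
    """Mean of 1/d(i,j) over unordered node pairs; disconnected pairs count 0."""
    w = _weight_matrix(net)
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = _pairwise_lengths(w)
    iu = np.triu_indices(n, 1)
    dv = d[iu]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dv) & (dv > 0), 1.0 / dv, 0.0)
    return float(inv.mean())


def local_efficiency(net: ConnectivityMatrix | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of the neighbourhood subgraph.

    The subgraph induced by node i's neighbours keeps the original edge
    weights between neighbours and excludes i itself; nodes with fewer
    than 2 neighbours contribute 0 (and stay in the denominator).
    """
    w = _weight_matrix(net)
    n = w.shape[0]
    if n == 0:
        return 0.0
    effs = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        effs[i] = global_efficiency(w[np.ix_(nbrs, nbrs)])
    return float(effs.mean())


def network_properties(net: ConnectivityMatrix) -> GlobalNetworkProperties:
    """All three global properties of one thresholded network."""
    return GlobalNetworkProperties(
        fc_strength=fc_strength(net),
        global_efficiency=global_efficiency(net),
        local_efficiency=local_efficiency(net),
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
    )


def network_zscore(value: float, control_values: Sequence[float]) -> float:
    """Z = (P - mean) / SD against the control group, SD with denominator n-1."""
    controls = np.asarray(control_values, dtype=float)
    if controls.size < 2:
        raise ValueError("need at least 2 control values")
    sd = controls.std(ddof=1)
    if sd == 0:
        raise ValueError("control values have zero standard deviation")
    return float((value - controls.mean()) / sd)


class NetworkMetricsExtractor(BaseEstimator, TransformerMixin):
    """Transformer: list of connectivity matrices -> (n_subjects, 3) DataFrame."""

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        if isinstance(X, ConnectivityMatrix):
            X = [X]
        rows = [network_properties(cm).as_dict() for cm in X]
        return pd.DataFrame(rows, columns=["fc_strength", "global_efficiency",
                                           "local_efficiency"])


class ControlZScorer(BaseEstimator, TransformerMixin):
    """Control-referenced Z-scoring, fit on the control group's metric values.

    Like a standard scaler but with the sample (ddof=1) standard
    deviation, matching Z = (P - mean) / SD against controls. Fitted
    attributes: ``mean_``, ``scale_``, ``n_controls_``.
    """

    def __init__(self):
        pass

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] < 2:
            raise ValueError("need at least 2 control observations")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0):
            raise ValueError("control values have zero standard deviation")
        self.n_controls_ = X.shape[0]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        Z = (X - self.mean_) / self.scale_
        return Z[:, 0] if squeeze else Z
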