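"""Networks of interest and functional-connectivity matrices.

Connectivity is pairwise Pearson correlation over surviving volumes,
variance-stabilized by the Fisher r-to-z transform. Weak edges are
eliminated with a correlation threshold (r > 0.2 by default; r > 0.1 and
r > 0.3 are the sensitivity variants). Thresholding is always expressed
on r even when edge weights are carried as Fisher z, and uses the strict
inequality, so negative correlations never survive a positive threshold.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import ConnectivityMatrix, NetworkDefinition, Node, SubjectTimeSeries

__all__ = [
    "BUILTIN_NETWORKS",
    "builtin_network",
    "correlation_matrix",
    "fisher_z",
    "threshold_network",
    "classify_edges",
    "fc_bin",
    "ConnectivityExtractor",
]

BUILTIN_NETWORKS = ("language", "co_fp", "dmn", "men")

#: Descriptive functional-connectivity bins on r. The fair/moderate naming
#: follows common usage; boundaries are a package convention.
FC_BINS = (("fair", 0.2, 0.4), ("moderate", 0.4, 0.6), ("strong", 0.6, 1.0 + 1e-12))


def _network_from_dict(payload: dict) -> NetworkDefinition:
    nodes = []
    for nd in payload["nodes"]:
        if "hemisphere" not in nd:
            raise ValueError(f"node {nd.get('id')!r} lacks a hemisphere label")
        mni = tuple(nd["mni"]) if nd.get("mni") else None
        nodes.append(Node(id=nd["id"], hemisphere=nd["hemisphere"],
                          region=nd.get("region", ""), mni=mni))
    return NetworkDefinition(name=payload["name"], nodes=nodes)


def builtin_network(name: str) -> NetworkDefinition:
    """Load a packaged node table.

    ``language``: 68 cortical ROIs (34 per hemisphere) over IFG, MFG, SFG,
    STG, MTG, ITG, PrG, PoG and IPL. ``co_fp``: the cingulo-opercular
    (7 ROIs) plus fronto-parietal (11 ROIs) cognitive-control set.
    ``dmn`` and ``men`` are the default-mode and motor-execution
    specificity references.
    """
    if name not in BUILTIN_NETWORKS:
        raise ValueError(f"unknown built-in network {name!r}; "
                         f"available: {BUILTIN_NETWORKS}")
    ref = resources.files("recovnet.data").joinpath(f"network_{name}.json")
    payload = json.loads(ref.read_text())
    return _network_from_dict(payload)


def correlation_matrix(
    ts: SubjectTimeSeries | np.ndarray,
    node_ids: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Pairwise Pearson correlations over the surviving volumes.

    Zero-variance nodes get all their edges set to 0 with a warning.
    """
    if isinstance(ts, SubjectTimeSeries):
        data = ts.data
        ids = list(ts.node_ids)
        if node_ids is not None:
            missing = [n for n in node_ids if n not in ids]
            if missing:
                raise KeyError(f"requested nodes not present: {missing}")
            cols = [ids.index(n) for n in node_ids]
            data = data[:, cols]
            ids = list(node_ids)
    else:
        data = np.asarray(ts, dtype=float)
        ids = list(node_ids) if node_ids is not None else [
            f"n{i}" for i in range(data.shape[1])]
    if data.shape[0] < 3:
        raise ValueError("need at least 3 surviving volumes for correlation")
    degenerate = np.flatnonzero(np.ptp(data, axis=0) == 0)
    if degenerate.size:
        warnings.warn(
            f"zero-variance node(s) {[ids[i] for i in degenerate]}; "
            "their edges are set to 0", stacklevel=2)
        data = data.copy()
        # give flat nodes unit noise-free variance placeholder, zero edges after
        data[:, degenerate] = 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(data, rowvar=False)
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
        r = np.nan_to_num(r, nan=0.0)
    else:
        r = np.corrcoef(data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(node_ids=ids, r=r, weight_kind="pearson_r")


def fisher_z(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Declare Fisher-z weight semantics: z = atanh(r) element-wise.

    Correlations at exactly +/-1 are clamped to +/-(1 - 1e-7) before the
    transform (logged as a warning).
    """
    if cm.weight_kind != "pearson_r":
        raise ValueError("fisher_z expects a pearson_r matrix")
    if np.any(np.abs(cm.r) >= 1.0):
        warnings.warn("|r| = 1 clamped to 1 - 1e-7 before atanh", stacklevel=2)
    return ConnectivityMatrix(node_ids=list(cm.node_ids), r=cm.r.copy(),
                              weight_kind="fisher_z", threshold_r=cm.threshold_r,
                              mask=None if cm.mask is None else cm.mask.copy())


def threshold_network(
    cm: ConnectivityMatrix,
    r_threshold: float = 0.2,
    weight_kind: str = "fisher_z",
) -> ConnectivityMatrix:
    """Eliminate weak connections: keep edges with r strictly above threshold.

    Surviving edge weights are Fisher z of r by default (``weight_kind``
    can be set to ``pearson_r`` for sensitivity checks).
    """
    if not (-1.0 < r_threshold < 1.0):
        raise ValueError(f"r_threshold must be in (-1, 1), got {r_threshold}")
    mask = cm.r > r_threshold
    np.fill_diagonal(mask, False)
    return ConnectivityMatrix(node_ids=list(cm.node_ids), r=cm.r.copy(),
                              weight_kind=weight_kind, threshold_r=r_threshold,
                              mask=mask)


def fc_bin(r: float) -> str:
    """Descriptive strength bin for a correlation value."""
    for name, lo, hi in FC_BINS:
        if lo <= r < hi:
            return name
    return "weak" if r < 0.2 else "out_of_range"


def classify_edges(network: NetworkDefinition, cm: ConnectivityMatrix) -> pd.DataFrame:
    """Long-format edge table with hemisphere class and strength bin.

    Classes: ``ipsi_left`` / ``ipsi_right`` for within-hemisphere edges
    (a midline endpoint counts as ipsilateral to the other endpoint's
    side), ``interhemispheric`` for L-R edges, and ``midline`` for
    midline-midline edges (reported separately).
    """
    hemi = {}
    for nid in cm.node_ids:
        hemi[nid] = network.hemisphere_of(nid)  # KeyError if unlabeled
    adj = cm.adjacency()
    w = cm.weights()
    rows = []
    n = cm.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            if not adj[i, j]:
                continue
            a, b = cm.node_ids[i], cm.node_ids[j]
            ha, hb = hemi[a], hemi[b]
            sides = {ha, hb} - {"midline"}
            if not sides:
                cls = "midline"
            elif len(sides) == 1:
                cls = "ipsi_left" if sides == {"L"} else "ipsi_right"
            else:
                cls = "interhemispheric"
            r = cm.r[i, j]
            rows.append({"node_a": a, "node_b": b, "r": r,
                         "z": float(np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))),
                         "weight": w[i, j], "class": cls, "bin": fc_bin(r)})
    return pd.DataFrame(rows, columns=["node_a", "node_b", "r", "z", "weight",
                                       "class", "bin"])


class ConnectivityExtractor(BaseEstimator, TransformerMixin):
    """Transformer: cleaned subject time series -> thresholded connectivity.

    Parameters mirror the study defaults: r > 0.2 threshold, Fisher-z edge
    weights. ``exclude_nodes`` drops lesioned ROIs from the matrix (the
    same exclusion must be applied to the control reference when
    comparing; :class:`~recovnet.metrics.ControlZScorer` is fit per node
    set, so use one scaler per exclusion pattern).
    """

    def __init__(self, r_threshold: float = 0.2, weight_kind: str = "fisher_z",
                 node_ids: Sequence[str] | None = None,
                 exclude_nodes: Sequence[str] | None = None):
        self.r_threshold = r_threshold
        self.weight_kind = weight_kind
        self.node_ids = node_ids
        self.exclude_nodes = exclude_nodes

    def fit(self, X=None, y=None):
        if not (-1.0 < self.r_threshold < 1.0):
            raise ValueError("r_threshold must be in (-1, 1)")
        return self

    def _one(self, ts: SubjectTimeSeries) -> ConnectivityMatrix:
        ids = list(self.node_ids) if self.node_ids is not None else list(ts.node_ids)
        if self.exclude_nodes:
            ids = [n for n in ids if n not in set(self.exclude_nodes)]
        cm = correlation_matrix(ts, node_ids=ids)
        return threshold_network(cm, self.r_threshold, self.weight_kind)

    def transform(self, X):
        if isinstance(X, SubjectTimeSeries):
            return self._one(X)
        return [self._one(ts) for ts in X]
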