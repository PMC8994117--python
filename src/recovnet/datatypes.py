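"""Core containers shared across the pipeline.

The analysis moves ROI-level BOLD-like signal through four representations:
a :class:`SubjectTimeSeries` (volumes x nodes, with its motion trace), a
:class:`ConnectivityMatrix` (node x node Pearson r, optionally Fisher-z
weighted and thresholded), :class:`GlobalNetworkProperties` (three scalars
per network), and behavioural :class:`LanguageRecord` /
:class:`RecoveryTrajectory` objects for the five observation timepoints
(preoperative, 2 weeks, 1 month, 3 months, 6 months).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

#: Canonical timepoint order used everywhere.
TIMEPOINTS: tuple[str, ...] = ("pre", "w2", "m1", "m3", "m6")
#: Post-operative subacute-phase timepoints (2 weeks, 1 month).
SUBACUTE_TIMEPOINTS: tuple[str, ...] = ("w2", "m1")
#: Chronic-phase timepoints (3 months, 6 months).
CHRONIC_TIMEPOINTS: tuple[str, ...] = ("m3", "m6")

#: Western-Aphasia-Battery-style subscore ranges: spontaneous speech,
#: comprehension, repetition, naming.
SUBSCORE_MAX = {"ss": 20.0, "com": 230.0, "rep": 100.0, "nam": 100.0}


def timepoint_index(tp: str) -> int:
    try:
        return TIMEPOINTS.index(tp)
    except ValueError:
        raise ValueError(f"unknown timepoint {tp!r}; expected one of {TIMEPOINTS}") from None


@dataclass
class Node:
    """One network node (ROI)."""

    id: str
    hemisphere: str  # "L" | "R" | "midline"
    region: str = ""
    mni: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R", "midline"):
            raise ValueError(f"node {self.id!r}: hemisphere must be L, R or midline, "
                             f"got {self.hemisphere!r}")


@dataclass
class NetworkDefinition:
    """A named node set with hemisphere labels and region metadata.

    The built-in node sets are symmetric between hemispheres (apart from
    midline nodes), so the contralateral homologue of a node is well
    defined: the node with the same within-hemisphere index on the
    opposite side.
    """

    name: str
    nodes: list[Node]

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"network {self.name!r}: duplicate node ids")

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def hemisphere_of(self, node_id: str) -> str:
        for n in self.nodes:
            if n.id == node_id:
                return n.hemisphere
        raise KeyError(node_id)

    def nodes_in_hemisphere(self, hemisphere: str) -> list[Node]:
        return [n for n in self.nodes if n.hemisphere == hemisphere]

    def homologue(self, node_id: str) -> str | None:
        """Contralateral homologue: same within-hemisphere index, opposite side.

        Midline nodes have no homologue (returns None).
        """
        hemi = self.hemisphere_of(node_id)
        if hemi == "midline":
            return None
        same = [n.id for n in self.nodes_in_hemisphere(hemi)]
        other_hemi = "R" if hemi == "L" else "L"
        other = [n.id for n in self.nodes_in_hemisphere(other_hemi)]
        idx = same.index(node_id)
        if idx >= len(other):
            return None
        return other[idx]


@dataclass
class SubjectTimeSeries:
    """Node-labelled signal matrix (volumes x nodes) with acquisition metadata.

    ``motion`` is the per-volume 6-parameter rigid-body trace (tx, ty, tz in
    mm; rx, ry, rz in radians). ``wm``/``csf``/``global_signal`` are
    node-level nuisance signals; when no measured global signal is given,
    the mean across nodes stands in for it. ``kept_volumes`` records which
    of the original volumes survived scrubbing (None before preprocessing).
    """

    data: np.ndarray
    node_ids: list[str]
    tr: float
    motion: np.ndarray | None = None
    wm: np.ndarray | None = None
    csf: np.ndarray | None = None
    global_signal: np.ndarray | None = None
    subject_id: str = ""
    timepoint: str | None = None
    kept_volumes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (volumes x nodes)")
        if self.data.shape[1] != len(self.node_ids):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but {len(self.node_ids)} node ids")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (self.data.shape[0], 6):
                raise ValueError(
                    f"motion trace shape {self.motion.shape} does not match "
                    f"({self.data.shape[0]}, 6)")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_nodes(self) -> int:
        return int(self.data.shape[1])

    def get_global_signal(self) -> np.ndarray:
        """The measured global signal, or the mean across nodes as a fallback."""
        if self.global_signal is not None:
            return np.asarray(self.global_signal, dtype=float)
        return self.data.mean(axis=1)


@dataclass
class ConnectivityMatrix:
    """Symmetric functional-connectivity matrix.

    ``r`` always holds the underlying Pearson correlations (diagonal stored
    as 0). ``weight_kind`` declares the semantics of :meth:`weights`:
    raw r or Fisher z = atanh(r). ``threshold_r`` records the correlation
    threshold that was applied (None if unthresholded); thresholding is
    always expressed on r, regardless of the weight kind.
    """

    node_ids: list[str]
    r: np.ndarray
    weight_kind: str = "pearson_r"  # "pearson_r" | "fisher_z"
    threshold_r: float | None = None
    mask: np.ndarray | None = None  # boolean adjacency of surviving edges

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.node_ids)
        if self.r.shape != (n, n):
            raise ValueError(f"matrix shape {self.r.shape} does not match {n} node ids")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if self.weight_kind not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown weight_kind {self.weight_kind!r}")
        np.fill_diagonal(self.r, 0.0)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.r.shape:
                raise ValueError("mask shape mismatch")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def adjacency(self) -> np.ndarray:
        """Boolean matrix of present edges (mask if thresholded, else all off-diagonal)."""
        if self.mask is not None:
            return self.mask.copy()
        adj = np.ones_like(self.r, dtype=bool)
        np.fill_diagonal(adj, False)
        return adj

    def weights(self) -> np.ndarray:
        """Edge-weight matrix under ``weight_kind``; absent edges are 0."""
        adj = self.adjacency()
        if self.weight_kind == "fisher_z":
            clipped = np.clip(self.r, -1 + 1e-7, 1 - 1e-7)
            w = np.arctanh(clipped)
        else:
            w = self.r.copy()
        w = np.where(adj, w, 0.0)
        np.fill_diagonal(w, 0.0)
        return w

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency(), 1).sum())


@dataclass
class GlobalNetworkProperties:
    """The three global properties of a thresholded weighted network."""

    fc_strength: float
    global_efficiency: float
    local_efficiency: float
    n_nodes: int
    n_edges: int

    def as_dict(self) -> dict[str, float]:
        return {
            "fc_strength": self.fc_strength,
            "global_efficiency": self.global_efficiency,
            "local_efficiency": self.local_efficiency,
        }


@dataclass
class LanguageRecord:
    """One subject x timepoint set of language scores.

    Subscores: spontaneous speech (0-20), comprehension (0-230),
    repetition (0-100), naming (0-100). The aphasia quotient (AQ, 0-100)
    is derived from them; if both AQ and subscores are given they must be
    consistent within 0.01.
    """

    subject: str
    timepoint: str
    ss: float | None = None
    com: float | None = None
    rep: float | None = None
    nam: float | None = None
    aq: float | None = None
    bnt: float | None = None
    mmse: float | None = None
    kps: float | None = None

    def __post_init__(self) -> None:
        timepoint_index(self.timepoint)
        subs = (self.ss, self.com, self.rep, self.nam)
        if all(s is not None for s in subs):
            from .recovery import compute_aq  # local import to avoid cycle

            derived = compute_aq(self.ss, self.com, self.rep, self.nam)
            if self.aq is None:
                self.aq = derived
            elif abs(self.aq - derived) > 0.01:
                raise ValueError(
                    f"{self.subject} {self.timepoint}: AQ {self.aq} inconsistent with "
                    f"subscores (derived {derived:.4f})")
        if self.aq is not None and not (0.0 <= self.aq <= 100.0):
            raise ValueError(f"AQ {self.aq} outside [0, 100]")
        if self.bnt is not None and not (0.0 <= self.bnt <= 30.0):
            raise ValueError(f"BNT {self.bnt} outside [0, 30]")


@dataclass
class RecoveryTrajectory:
    """Ordered per-timepoint scalar (AQ or a network property) for one subject."""

    subject: str
    values: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tp in self.values:
            timepoint_index(tp)
        # canonical chronological order regardless of input order
        self.values = {tp: self.values[tp] for tp in TIMEPOINTS if tp in self.values}
        if "pre" not in self.values:
            raise ValueError(f"{self.subject}: trajectory lacks a preoperative value")
        if not any(tp in self.values for tp in TIMEPOINTS[1:]):
            raise ValueError(f"{self.subject}: trajectory lacks any post-operative value")

    def subacute_value(self) -> tuple[str, float]:
        """Earliest available post-operative observation (2 weeks, else 1 month)."""
        for tp in TIMEPOINTS[1:]:
            if tp in self.values:
                return tp, self.values[tp]
        raise ValueError("no post-operative value")  # unreachable after validation

    def chronic_value(self) -> tuple[str, float]:
        """Latest available chronic-phase observation (6 months, else 3 months)."""
        for tp in reversed(CHRONIC_TIMEPOINTS):
            if tp in self.values:
                return tp, self.values[tp]
        raise ValueError(f"{self.subject}: trajectory lacks a chronic timepoint")


@dataclass
class RecoveryRatio:
    """(chronic - subacute) / (pre - subacute), with the capping rule applied."""

    value: float
    subacute_timepoint: str
    chronic_timepoint: str
    capped: bool = False
    reason: str = ""
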