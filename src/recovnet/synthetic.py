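"""Synthetic cohort generator.

Emulates the study design the downstream analysis assumes: a healthy
control group scanned once, and longitudinal patients observed at up to
five timepoints (preoperative, 2 weeks, 1 month, 3 months, 6 months).
Signals are stationary Gaussian AR(1) node time series whose
cross-sectional covariance has block structure (higher correlation within
a named network than between networks). Post-operatively, connectivity
incident to a peritumoral node neighbourhood and its contralateral
homologues is attenuated, with the attenuation decaying over timepoints
according to a recovery profile. Language scores are generated as a noisy
monotone function of the current network attenuation, so behavioural
recovery is synchronized with network normalization by construction.

The generator produces no haemodynamic or physiological realism (no HRF,
no drift, no 1/f noise); it provides exactly the statistical structure the
pipeline estimates, which is what makes parameter recovery testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .datatypes import (
    SUBSCORE_MAX,
    TIMEPOINTS,
    LanguageRecord,
    NetworkDefinition,
    Node,
    SubjectTimeSeries,
)

__all__ = [
    "CohortConfig",
    "Cohort",
    "make_symmetric_network",
    "build_target_covariance",
    "nearest_psd_correlation",
    "simulate_timeseries",
    "apply_disruption",
    "generate_control",
    "generate_patient",
    "generate_cohort",
]

#: Largest entry-wise change the PSD repair may introduce before the
#: requested correlation structure is declared impossible.
MAX_PSD_REPAIR_DELTA = 0.05


@dataclass
class CohortConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study: 26 controls, 34 patients,
    240 volumes at TR = 2 s, and a patient baseline AQ distribution of
    roughly 90 +/- 9. ``disruption_frac`` is the fraction by which
    peritumoral connectivity is attenuated at the subacute nadir;
    ``recovery_profile`` maps each post-operative timepoint to the
    fraction of that disruption still present (1.0 at the nadir, decaying
    toward 0). ``language_link_slope`` converts the current attenuation
    fraction into AQ points lost (slope x attenuation x 100).
    """

    n_controls: int = 26
    n_patients: int = 34
    n_nodes_per_network: Mapping[str, int] = field(
        default_factory=lambda: {"language": 68, "co_fp": 18})
    n_volumes: int = 240
    tr_seconds: float = 2.0
    base_within_corr: float = 0.45
    base_between_corr: float = 0.08
    ar1_coeff: float = 0.3
    disruption_frac: float = 0.5
    recovery_profile: Mapping[str, float] = field(
        default_factory=lambda: {"w2": 1.0, "m1": 0.7, "m3": 0.25, "m6": 0.1})
    tumour_node_frac: float = 0.25
    language_link_slope: float = 0.4
    language_link_noise_sd: float = 2.0
    baseline_aq_mean: float = 90.1
    baseline_aq_sd: float = 9.0
    global_component_amp: float = 0.5
    motion_jitter_sd_mm: float = 0.02
    n_motion_spikes: int = 1
    spike_magnitude_mm: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.base_within_corr < 1):
            raise ValueError("base_within_corr must be in [0, 1)")
        if not (-1 < self.base_between_corr < 1):
            raise ValueError("base_between_corr must be in (-1, 1)")
        if not (0 <= self.ar1_coeff < 1):
            raise ValueError("ar1_coeff must be in [0, 1)")
        if not (0 <= self.disruption_frac <= 1):
            raise ValueError("disruption_frac must be in [0, 1]")
        if not (0 <= self.tumour_node_frac <= 1):
            raise ValueError("tumour_node_frac must be in [0, 1]")
        for tp, frac in self.recovery_profile.items():
            if tp not in TIMEPOINTS[1:]:
                raise ValueError(f"recovery_profile has unknown timepoint {tp!r}")
            if not (0 <= frac <= 1):
                raise ValueError(f"recovery_profile[{tp!r}]={frac} outside [0, 1]")
        if self.disruption_frac > 0 and self.recovery_profile:
            first = min(self.recovery_profile, key=TIMEPOINTS.index)
            if self.recovery_profile[first] != 1.0:
                raise ValueError(
                    "recovery_profile must equal 1.0 at the subacute (first "
                    f"post-operative) timepoint; got {self.recovery_profile[first]} "
                    f"at {first!r}")
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")


def make_symmetric_network(name: str, n_nodes: int) -> NetworkDefinition:
    """Build a hemispherically symmetric synthetic network definition.

    Odd ``n_nodes`` gets one midline node; the rest split evenly L/R.
    """
    per_hemi, odd = divmod(n_nodes, 2)
    nodes = [Node(id=f"{name}_{h}{i + 1}", hemisphere=h, region=name)
             for h in ("L", "R") for i in range(per_hemi)]
    if odd:
        nodes.append(Node(id=f"{name}_M1", hemisphere="midline", region=name))
    return NetworkDefinition(name=name, nodes=nodes)


def nearest_psd_correlation(mat: np.ndarray) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix onto the PSD cone and restore a unit diagonal.

    Eigenvalues are clipped at 0, the matrix reassembled, then rescaled to
    correlation form. Returns (repaired matrix, max absolute entry change).
    """
    mat = np.asarray(mat, dtype=float)
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= -1e-12:
        out = sym.copy()
        np.fill_diagonal(out, 1.0)
        return out, float(np.abs(out - mat).max())
    clipped = np.clip(vals, 0.0, None)
    repaired = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.abs(repaired - mat).max())


def build_target_covariance(
    config: CohortConfig, networks: Sequence[NetworkDefinition]
) -> tuple[np.ndarray, list[str]]:
    """Block-structured target correlation matrix over the union of networks.

    Off-diagonal entries are ``base_within_corr`` for node pairs in the
    same network and ``base_between_corr`` otherwise; diagonal is 1.
    Returns (matrix, node id order). Raises if networks share nodes or if
    the PSD repair would change any entry by more than 0.05.
    """
    all_ids: list[str] = []
    membership: list[int] = []
    for k, net in enumerate(networks):
        for nid in net.node_ids:
            all_ids.append(nid)
            membership.append(k)
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("networks must be disjoint node sets")
    member = np.asarray(membership)
    same = member[:, None] == member[None, :]
    cov = np.where(same, config.base_within_corr, config.base_between_corr)
    np.fill_diagonal(cov, 1.0)
    repaired, delta = nearest_psd_correlation(cov)
    if delta > MAX_PSD_REPAIR_DELTA:
        raise ValueError(
            f"requested correlation structure is not achievable: PSD repair "
            f"changed entries by up to {delta:.3f} (> {MAX_PSD_REPAIR_DELTA})")
    if delta > 1e-10:
        warnings.warn(f"target covariance repaired to PSD (max change {delta:.2e})",
                      stacklevel=2)
    return repaired, all_ids


def simulate_timeseries(
    cov: np.ndarray,
    n_volumes: int,
    ar1: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw a stationary Gaussian AR(1) series with cross-sectional covariance ``cov``.

    x_t = ar1 * x_{t-1} + e_t with innovation covariance (1 - ar1^2) cov,
    initialised from the stationary distribution, so Cov(x_t) = cov at
    every t. Deterministic given the seed.
    """
    cov = np.asarray(cov, dtype=float)
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    if not (0 <= ar1 < 1):
        raise ValueError("ar1 must be in [0, 1)")
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    if vals.min() < -1e-8:
        raise ValueError("covariance must be positive semi-definite")
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cov.shape[0]
    innov = rng.standard_normal((n_volumes, n)) @ root.T
    # x_t = ar1 x_{t-1} + e_t as an IIR filter; the first row carries the full
    # stationary draw so the process starts in its stationary distribution
    innov[1:] *= np.sqrt(1.0 - ar1 ** 2)
    return lfilter([1.0], [1.0, -ar1], innov, axis=0)


def apply_disruption(
    cov: np.ndarray,
    node_ids: Sequence[str],
    networks: Sequence[NetworkDefinition],
    peritumoral_nodes: Sequence[str],
    attenuation: float,
) -> np.ndarray:
    """Attenuate connectivity around the tumour neighbourhood.

    Off-diagonal entries incident to any peritumoral node or its
    contralateral homologue are multiplied by (1 - attenuation); all other
    entries are untouched. A PSD repair follows (scaling rows/columns of a
    PSD matrix by (1-a) <= 1 keeps it PSD, so the repair is a no-op in
    exact arithmetic; it guards accumulated rounding).
    """
    if not (0 <= attenuation <= 1):
        raise ValueError("attenuation must be in [0, 1]")
    peritumoral_nodes = list(peritumoral_nodes)
    if peritumoral_nodes:
        hemis = set()
        for net in networks:
            for nid in peritumoral_nodes:
                if nid in net.node_ids:
                    hemis.add(net.hemisphere_of(nid))
        if len(hemis) > 1:
            raise ValueError("peritumoral nodes must lie in a single hemisphere")
    if attenuation == 0 or not peritumoral_nodes:
        return np.asarray(cov, dtype=float).copy()

    affected: set[str] = set(peritumoral_nodes)
    for net in networks:
        for nid in peritumoral_nodes:
            if nid in net.node_ids:
                hom = net.homologue(nid)
                if hom is not None:
                    affected.add(hom)
    idx = np.asarray([i for i, nid in enumerate(node_ids) if nid in affected])
    out = np.asarray(cov, dtype=float).copy()
    n = out.shape[0]
    touched = np.zeros((n, n), dtype=bool)
    touched[idx, :] = True
    touched[:, idx] = True
    np.fill_diagonal(touched, False)
    out[touched] *= (1.0 - attenuation)
    repaired, delta = nearest_psd_correlation(out)
    if delta > 1e-8:
        warnings.warn(f"disrupted covariance repaired to PSD (max change {delta:.2e})",
                      stacklevel=2)
        # keep untouched entries bit-identical: repair only if genuinely needed
        out = repaired
    return out


def _simulate_motion(
    n_volumes: int,
    rng: np.random.Generator,
    jitter_sd_mm: float,
    n_spikes: int,
    spike_magnitude_mm: float,
) -> np.ndarray:
    """Random-walk translations with optional single-volume displacement spikes.

    Rotations are held at 0. Spikes are transient jumps in x at interior
    volumes, producing a framewise-displacement excursion at the spike.
    """
    motion = np.zeros((n_volumes, 6))
    steps = rng.normal(0.0, jitter_sd_mm, size=(n_volumes, 3))
    steps[0] = 0.0
    motion[:, :3] = np.cumsum(steps, axis=0)
    if n_spikes > 0 and n_volumes > 8:
        # keep spikes away from the series edges so the censoring window fits
        positions = rng.choice(np.arange(4, n_volumes - 4), size=n_spikes, replace=False)
        for p in positions:
            motion[p, 0] += spike_magnitude_mm
    return motion


def _nuisance_signals(n_volumes: int, ar1: float, rng: np.random.Generator) -> np.ndarray:
    """Independent unit-variance AR(1) WM, CSF and global physiological traces."""
    cov = np.eye(3)
    return simulate_timeseries(cov, n_volumes, ar1, rng)


def _backsolve_subscores(aq: float) -> dict[str, float]:
    """Distribute an AQ proportionally across the four subscores.

    With every subscore at fraction f of its maximum,
    AQ = 2 (20f + 230f/23 + 100f/10 + 100f/10) = 100 f, so the derived AQ
    reproduces the input exactly.
    """
    f = aq / 100.0
    return {k: v * f for k, v in SUBSCORE_MAX.items()}


def _timeseries_for(
    cov: np.ndarray,
    node_ids: Sequence[str],
    config: CohortConfig,
    rng: np.random.Generator,
    subject_id: str,
    timepoint: str | None,
    with_spikes: bool,
) -> SubjectTimeSeries:
    data = simulate_timeseries(cov, config.n_volumes, config.ar1_coeff, rng)
    motion = _simulate_motion(
        config.n_volumes, rng, config.motion_jitter_sd_mm,
        config.n_motion_spikes if with_spikes else 0, config.spike_magnitude_mm)
    nuis = _nuisance_signals(config.n_volumes, config.ar1_coeff, rng)
    # shared physiological component: added to every node and measured as the
    # global signal, so global-signal regression removes it without touching
    # the block correlation structure (as whole-brain GSR would)
    g = nuis[:, 2]
    data = data + config.global_component_amp * g[:, None]
    return SubjectTimeSeries(
        data=data, node_ids=list(node_ids), tr=config.tr_seconds, motion=motion,
        wm=nuis[:, 0], csf=nuis[:, 1], global_signal=g,
        subject_id=subject_id, timepoint=timepoint)


def generate_control(
    config: CohortConfig,
    networks: Sequence[NetworkDefinition],
    subject_id: str = "C000",
    seed: int | np.random.Generator = 0,
) -> SubjectTimeSeries:
    """One healthy-control scan: undisrupted covariance, no motion spikes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov, node_ids = build_target_covariance(config, networks)
    return _timeseries_for(cov, node_ids, config, rng, subject_id, None,
                           with_spikes=False)


def pick_peritumoral_nodes(
    config: CohortConfig,
    networks: Sequence[NetworkDefinition],
    rng: np.random.Generator,
    hemisphere: str = "L",
) -> list[str]:
    """Designate a contiguous left-hemisphere node neighbourhood as peritumoral."""
    first = networks[0]
    hemi_nodes = [n.id for n in first.nodes_in_hemisphere(hemisphere)]
    k = max(1, int(round(config.tumour_node_frac * len(hemi_nodes))))
    start = int(rng.integers(0, max(1, len(hemi_nodes) - k + 1)))
    return hemi_nodes[start:start + k]


def generate_patient(
    config: CohortConfig,
    networks: Sequence[NetworkDefinition],
    timepoints: Sequence[str] = TIMEPOINTS,
    subject_id: str = "P000",
    seed: int | np.random.Generator = 0,
    with_timeseries: bool = True,
) -> tuple[dict[str, SubjectTimeSeries], list[LanguageRecord], list[str]]:
    """One longitudinal patient.

    Returns (timepoint -> SubjectTimeSeries, language records in timepoint
    order, peritumoral node ids). The attenuation at each post-operative
    timepoint is disruption_frac x recovery_profile[tp] (0 preoperatively
    and at timepoints missing from the profile); AQ at each timepoint is
    baseline - slope x attenuation x 100 + N(0, noise_sd), clamped to
    [0, 100], with subscores back-solved proportionally.
    """
    for tp in timepoints:
        if tp not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {tp!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov0, node_ids = build_target_covariance(config, networks)
    peritumoral = pick_peritumoral_nodes(config, networks, rng)
    baseline_aq = float(np.clip(
        rng.normal(config.baseline_aq_mean, config.baseline_aq_sd), 0.0, 100.0))

    series: dict[str, SubjectTimeSeries] = {}
    records: list[LanguageRecord] = []
    for tp in TIMEPOINTS:
        if tp not in timepoints:
            continue
        if tp == "pre":
            att = 0.0
        else:
            att = config.disruption_frac * float(config.recovery_profile.get(tp, 0.0))
        cov = apply_disruption(cov0, node_ids, networks, peritumoral, att)
        if with_timeseries:
            series[tp] = _timeseries_for(cov, node_ids, config, rng, subject_id, tp,
                                         with_spikes=tp != "pre")
        noise = rng.normal(0.0, config.language_link_noise_sd) \
            if config.language_link_noise_sd > 0 else 0.0
        aq = float(np.clip(
            baseline_aq - config.language_link_slope * att * 100.0 + noise, 0.0, 100.0))
        subs = _backsolve_subscores(aq)
        records.append(LanguageRecord(subject=subject_id, timepoint=tp,
                                      ss=subs["ss"], com=subs["com"],
                                      rep=subs["rep"], nam=subs["nam"]))
    return series, records, peritumoral


@dataclass
class Cohort:
    """A generated cohort: controls, longitudinal patients, language scores."""

    config: CohortConfig
    networks: list[NetworkDefinition]
    controls: list[SubjectTimeSeries]
    patients: dict[str, dict[str, SubjectTimeSeries]]
    language: list[LanguageRecord]
    peritumoral: dict[str, list[str]]

    def manifest(self) -> dict:
        return {
            "n_controls": len(self.controls),
            "n_patients": len(self.patients),
            "networks": {net.name: net.n_nodes for net in self.networks},
            "n_volumes": self.config.n_volumes,
            "tr_seconds": self.config.tr_seconds,
            "seed": self.config.seed,
            "patient_timepoints": {
                pid: sorted(tps, key=TIMEPOINTS.index)
                for pid, tps in ((p, list(s)) for p, s in self.patients.items())
            },
        }


def generate_cohort(
    config: CohortConfig,
    networks: Sequence[NetworkDefinition] | None = None,
    patient_timepoints: Mapping[str, Sequence[str]] | None = None,
) -> Cohort:
    """Generate the full cohort deterministically from ``config.seed``.

    Every subject draws from an independent child stream of the master
    seed, so the cohort is bit-reproducible and insensitive to generation
    order.
    """
    if networks is None:
        networks = [make_symmetric_network(name, n)
                    for name, n in config.n_nodes_per_network.items()]
    networks = list(networks)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_controls + config.n_patients)

    controls = [
        generate_control(config, networks, subject_id=f"C{i + 1:03d}",
                         seed=np.random.default_rng(children[i]))
        for i in range(config.n_controls)
    ]
    patients: dict[str, dict[str, SubjectTimeSeries]] = {}
    language: list[LanguageRecord] = []
    peritumoral: dict[str, list[str]] = {}
    for j in range(config.n_patients):
        pid = f"P{j + 1:03d}"
        tps = (patient_timepoints or {}).get(pid, TIMEPOINTS)
        series, records, peri = generate_patient(
            config, networks, timepoints=tps, subject_id=pid,
            seed=np.random.default_rng(children[config.n_controls + j]))
        patients[pid] = series
        language.extend(records)
        peritumoral[pid] = peri
    return Cohort(config=config, networks=networks, controls=controls,
                  patients=patients, language=language, peritumoral=peritumoral)
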