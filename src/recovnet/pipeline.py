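"""End-to-end orchestration: simulate -> clean -> connectivity -> metrics -> recovery.

``run_pipeline`` takes a :class:`RunConfig`, generates (or accepts) a
cohort, and produces per subject x timepoint x network x threshold global
network properties with control-referenced Z-scores, per-patient AQ and
network recovery ratios with recovery classification, and group-level
trajectory statistics (paired t-tests of each post-operative timepoint
against the preoperative baseline, and partial correlations between AQ
and network recovery ratios). Everything is deterministic given the seed,
and the full configuration is mirrored into the output directory for
provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import ConnectivityExtractor
from .datatypes import (
    TIMEPOINTS,
    NetworkDefinition,
    RecoveryTrajectory,
    SubjectTimeSeries,
)
from .metrics import ControlZScorer, network_properties
from .preprocessing import MinimumVolumesError, Preprocessor
from .recovery import classify_recovery, paired_t, partial_correlation, recovery_ratio
from .synthetic import Cohort, CohortConfig, generate_cohort

logger = logging.getLogger("recovnet")

METRICS = ("fc_strength", "global_efficiency", "local_efficiency")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: Sequence[float] = (0.2,)
    use_global_signal: bool = True
    weight_kind: str = "fisher_z"
    exclude_nodes: Mapping[str, Sequence[str]] = field(default_factory=dict)
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ValueError("at least one threshold required")
        for t in self.thresholds:
            if not (0.0 < t < 1.0):
                raise ValueError(f"thresholds must be strictly in (0, 1); got {t}")


@dataclass
class RunReport:
    """All tables produced by one run."""

    properties: pd.DataFrame  # subject, timepoint, network, threshold, metric values
    zscores: pd.DataFrame  # patient rows only, Z per metric
    language: pd.DataFrame  # subject, timepoint, aq
    patients: pd.DataFrame  # per-patient classification + AQ/network ratios
    group_stats: pd.DataFrame  # paired-t trajectories
    correlations: pd.DataFrame  # AQ-ratio vs network-ratio partial correlations
    excluded: list[dict]
    config: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"properties": self.properties, "zscores": self.zscores,
                "language": self.language, "patients": self.patients,
                "group_stats": self.group_stats, "correlations": self.correlations}


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["thresholds"] = list(config.thresholds)
    d["cohort"]["n_nodes_per_network"] = dict(config.cohort.n_nodes_per_network)
    d["cohort"]["recovery_profile"] = dict(config.cohort.recovery_profile)
    d["exclude_nodes"] = {k: list(v) for k, v in config.exclude_nodes.items()}
    return d


def _network_series(ts: SubjectTimeSeries, net: NetworkDefinition) -> SubjectTimeSeries:
    """Restrict a cleaned multi-network series to one network's nodes."""
    cols = [ts.node_ids.index(n) for n in net.node_ids if n in ts.node_ids]
    return SubjectTimeSeries(
        data=ts.data[:, cols], node_ids=[ts.node_ids[c] for c in cols], tr=ts.tr,
        subject_id=ts.subject_id, timepoint=ts.timepoint)


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> RunReport:
    """Execute the full analysis; see the module docstring for outputs."""
    if cohort is None:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        cohort = generate_cohort(cohort_cfg)
    networks = cohort.networks

    pre = Preprocessor(use_global_signal=config.use_global_signal)
    excluded: list[dict] = []

    def clean_or_skip(ts: SubjectTimeSeries):
        try:
            return pre.clean(ts)
        except MinimumVolumesError as exc:
            logger.warning("excluding %s %s: %s", ts.subject_id, ts.timepoint, exc)
            excluded.append({"subject": ts.subject_id, "timepoint": ts.timepoint,
                             "reason": str(exc)})
            return None

    controls = [c for c in (clean_or_skip(ts) for ts in cohort.controls)
                if c is not None]
    if len(controls) < 2:
        raise RuntimeError("fewer than 2 controls survive preprocessing")
    patient_clean: dict[str, dict[str, SubjectTimeSeries]] = {}
    for pid, series in cohort.patients.items():
        kept = {tp: c for tp, c in ((tp, clean_or_skip(ts))
                                    for tp, ts in series.items()) if c is not None}
        if kept:
            patient_clean[pid] = kept

    # --- connectivity + global properties per network x threshold -------------
    prop_rows = []
    z_rows = []
    scalers: dict[tuple[str, float], ControlZScorer] = {}
    for net in networks:
        for thr in config.thresholds:
            extractor = ConnectivityExtractor(
                r_threshold=thr, weight_kind=config.weight_kind)
            ctrl_props = []
            for ts in controls:
                props = network_properties(extractor.transform(_network_series(ts, net)))
                ctrl_props.append([getattr(props, m) for m in METRICS])
                prop_rows.append({"subject": ts.subject_id, "role": "control",
                                  "timepoint": "control", "network": net.name,
                                  "threshold": thr, **props.as_dict()})
            scaler = ControlZScorer().fit(np.asarray(ctrl_props))
            scalers[(net.name, thr)] = scaler
            for pid, series in patient_clean.items():
                excl = set(config.exclude_nodes.get(pid, ()))
                if excl:
                    # drop lesioned nodes from patient AND control reference
                    sub_extractor = ConnectivityExtractor(
                        r_threshold=thr, weight_kind=config.weight_kind,
                        exclude_nodes=sorted(excl))
                    ref = np.asarray([
                        [getattr(network_properties(
                            sub_extractor.transform(_network_series(ts, net))), m)
                         for m in METRICS] for ts in controls])
                    sub_scaler = ControlZScorer().fit(ref)
                else:
                    sub_extractor, sub_scaler = extractor, scaler
                for tp, ts in series.items():
                    props = network_properties(
                        sub_extractor.transform(_network_series(ts, net)))
                    vals = np.asarray([[getattr(props, m) for m in METRICS]])
                    z = sub_scaler.transform(vals)[0]
                    prop_rows.append({"subject": pid, "role": "patient",
                                      "timepoint": tp, "network": net.name,
                                      "threshold": thr, **props.as_dict()})
                    z_rows.append({"subject": pid, "timepoint": tp,
                                   "network": net.name, "threshold": thr,
                                   **dict(zip(METRICS, z))})

    properties = pd.DataFrame(prop_rows)
    zscores = pd.DataFrame(z_rows)

    # --- language trajectories ------------------------------------------------
    lang_rows = [{"subject": r.subject, "timepoint": r.timepoint, "aq": r.aq}
                 for r in cohort.language]
    language = pd.DataFrame(lang_rows)

    patient_rows = []
    for pid, grp in language.groupby("subject"):
        values = dict(zip(grp["timepoint"], grp["aq"]))
        try:
            traj = RecoveryTrajectory(subject=pid, values=values)
            cls = classify_recovery(traj)
            rr = recovery_ratio(traj)
        except ValueError as exc:
            logger.warning("skipping recovery stats for %s: %s", pid, exc)
            continue
        row = {"subject": pid, "recovery_class": cls, "aq_ratio": rr.value,
               "aq_ratio_capped": rr.capped, "aq_pre": values.get("pre")}
        for net in networks:
            for thr in config.thresholds:
                sub = zscores[(zscores.subject == pid) & (zscores.network == net.name)
                              & (zscores.threshold == thr)]
                for metric in METRICS:
                    zv = dict(zip(sub["timepoint"], sub[metric]))
                    if "pre" in zv and any(t in zv for t in TIMEPOINTS[1:]):
                        try:
                            net_traj = RecoveryTrajectory(subject=pid, values=zv)
                            net_rr = recovery_ratio(net_traj)
                            row[f"{net.name}_{metric}_ratio_thr{thr}"] = net_rr.value
                        except ValueError:
                            pass
        patient_rows.append(row)
    patients = pd.DataFrame(patient_rows)

    # --- group-level paired-t trajectories ------------------------------------
    stat_rows = []
    good = set(patients[patients.recovery_class == "good"].subject) \
        if len(patients) else set()
    wide_aq = language.pivot_table(index="subject", columns="timepoint", values="aq")

    def paired_rows(wide: pd.DataFrame, measure: str, network: str, thr):
        for tp in TIMEPOINTS[1:]:
            if "pre" not in wide.columns or tp not in wide.columns:
                continue
            both = wide[["pre", tp]].dropna()
            both = both[both.index.isin(good)]
            if len(both) < 2:
                continue
            try:
                t, df, p = paired_t(both["pre"], both[tp])
            except ValueError:
                continue
            stat_rows.append({"measure": measure, "network": network,
                              "threshold": thr, "timepoint": tp, "n": len(both),
                              "t": t, "df": df, "p": p})

    paired_rows(wide_aq, "aq", "", None)
    for net in networks:
        for thr in config.thresholds:
            sub = zscores[(zscores.network == net.name) & (zscores.threshold == thr)]
            for metric in METRICS:
                wide = sub.pivot_table(index="subject", columns="timepoint",
                                       values=metric)
                paired_rows(wide, metric, net.name, thr)
    group_stats = pd.DataFrame(stat_rows)

    # --- AQ-ratio vs network-ratio partial correlations -----------------------
    corr_rows = []
    if len(patients) >= 5:
        cov_cols = [c for c in ("sex", "age", "education", "grade")
                    if c in patients.columns]
        for net in networks:
            for thr in config.thresholds:
                for metric in METRICS:
                    col = f"{net.name}_{metric}_ratio_thr{thr}"
                    if col not in patients.columns:
                        continue
                    sub = patients[["aq_ratio", col] + cov_cols].dropna()
                    if len(sub) < len(cov_cols) + 4:
                        continue
                    cov = sub[cov_cols].to_numpy() if cov_cols else None
                    try:
                        r, p = partial_correlation(sub["aq_ratio"], sub[col], cov)
                    except ValueError:
                        continue
                    corr_rows.append({"network": net.name, "threshold": thr,
                                      "metric": metric, "n": len(sub),
                                      "r_partial": r, "p": p})
    correlations = pd.DataFrame(corr_rows)

    report = RunReport(properties=properties, zscores=zscores, language=language,
                       patients=patients, group_stats=group_stats,
                       correlations=correlations, excluded=excluded,
                       config=_config_dict(config))
    if config.output_dir:
        write_report(report, config.output_dir)
    return report


def estimate_subacute_zscore_drop(
    disruption_frac: float,
    seed: int,
    n_controls: int = 8,
    n_patients: int = 3,
    n_nodes: int = 16,
    threshold: float = 0.2,
    metric: str = "global_efficiency",
) -> float:
    """Mean patient Z-score change (subacute minus preoperative) for one metric.

    Runs the full estimation path - simulate, clean, correlate, threshold,
    graph metric, control-referenced Z - on a compact cohort observed at
    the preoperative and subacute (2 week) timepoints only. Used to check
    that the pipeline's estimated network disruption is monotone in the
    true disruption fraction.
    """
    cohort_cfg = CohortConfig(
        n_controls=n_controls, n_patients=n_patients,
        n_nodes_per_network={"net": n_nodes},
        disruption_frac=disruption_frac, seed=seed)
    tps = {f"P{j + 1:03d}": ("pre", "w2") for j in range(n_patients)}
    cohort = generate_cohort(cohort_cfg, patient_timepoints=tps)
    pre = Preprocessor()
    extractor = ConnectivityExtractor(r_threshold=threshold)

    def metric_of(ts: SubjectTimeSeries) -> float:
        props = network_properties(extractor.transform(pre.clean(ts)))
        return getattr(props, metric)

    scaler = ControlZScorer().fit(
        np.asarray([metric_of(ts) for ts in cohort.controls])[:, None])
    drops = []
    for series in cohort.patients.values():
        z = {tp: float(scaler.transform(np.asarray([[metric_of(ts)]]))[0, 0])
             for tp, ts in series.items()}
        drops.append(z["w2"] - z["pre"])
    return float(np.mean(drops))


def write_report(report: RunReport, output_dir) -> None:
    """Mirror all report tables and the configuration into a directory."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.tables().items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    (out / "excluded.json").write_text(json.dumps(report.excluded, indent=1))
    (out / "config.json").write_text(json.dumps(report.config, indent=1, default=str))
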