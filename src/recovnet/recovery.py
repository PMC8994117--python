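"""Language scoring, recovery classification and recovery-ratio statistics.

The aphasia quotient (AQ, 0-100) summarizes four Western-Aphasia-Battery
style subscores:

    AQ = (S_ss + S_com / 23 + S_rep / 10 + S_nam / 10) * 2

Recovery is classified from the AQ trajectory over the five observation
timepoints: *good* if the AQ returns to 80% of the preoperative baseline
by 3 months or to 85% by 6 months, otherwise *poor*.

The recovery ratio divides the total recovery (chronic minus subacute
score) by the transient decline (preoperative minus subacute score),
where the subacute score is the earliest post-operative observation
(2 weeks, else 1 month) and the chronic score is the latest available
chronic observation (6 months, else 3 months). A ratio of 1 means full
return to baseline. The ratio is capped at 1 when there is no transient
decline to recover from: either the subacute score is not below baseline
(denominator <= 0), or the trajectory shows no gain after the subacute
timepoint while the subacute score already satisfies the good-recovery
criterion against baseline - i.e. recovery completed within the subacute
phase. The same ratio applies verbatim to Z-scored network-property
trajectories.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .datatypes import (
    SUBSCORE_MAX,
    TIMEPOINTS,
    RecoveryRatio,
    RecoveryTrajectory,
)

__all__ = [
    "compute_aq",
    "classify_recovery",
    "recovery_ratio",
    "paired_t",
    "two_sample_t",
    "chi_square_2xk",
    "partial_correlation",
    "summarize_cohort",
]

#: Good-recovery thresholds: fraction of baseline AQ required by 3 / 6 months.
GOOD_RECOVERY_M3_FRAC = 0.80
GOOD_RECOVERY_M6_FRAC = 0.85
#: Denominator below this is treated as "no transient decline".
CAP_EPS = 1e-9


def compute_aq(ss: float, com: float, rep: float, nam: float) -> float:
    """Aphasia quotient from the four subscores."""
    for name, value in (("ss", ss), ("com", com), ("rep", rep), ("nam", nam)):
        hi = SUBSCORE_MAX[name]
        if not (0.0 <= value <= hi):
            raise ValueError(f"subscore {name}={value} outside [0, {hi}]")
    return (ss + com / 23.0 + rep / 10.0 + nam / 10.0) * 2.0


def classify_recovery(traj: RecoveryTrajectory) -> str:
    """``good`` iff AQ(3m) >= 80% of AQ(pre) or AQ(6m) >= 85% of AQ(pre).

    A missing chronic timepoint simply skips its clause; at least one of
    the two must be present.
    """
    pre = traj.values["pre"]
    m3 = traj.values.get("m3")
    m6 = traj.values.get("m6")
    if m3 is None and m6 is None:
        raise ValueError(f"{traj.subject}: no chronic (3 or 6 month) observation")
    if m3 is not None and m3 >= GOOD_RECOVERY_M3_FRAC * pre:
        return "good"
    if m6 is not None and m6 >= GOOD_RECOVERY_M6_FRAC * pre:
        return "good"
    return "poor"


def recovery_ratio(traj: RecoveryTrajectory) -> RecoveryRatio:
    """(chronic - subacute) / (pre - subacute) with the capping rule.

    Capped at 1.0 (``capped=True``) when the transient decline is absent:
    denominator <= 0, or no post-subacute gain while the subacute score
    already meets the good-recovery criterion relative to baseline.
    """
    pre = traj.values["pre"]
    sub_tp, sub = traj.subacute_value()
    if sub_tp not in ("w2", "m1"):
        raise ValueError(f"{traj.subject}: no subacute (2 week / 1 month) observation")
    chron_tp, chron = traj.chronic_value()
    denom = pre - sub
    num = chron - sub
    if denom <= CAP_EPS:
        return RecoveryRatio(1.0, sub_tp, chron_tp, capped=True,
                             reason="no transient decline (subacute >= baseline)")
    if num <= 0 and sub >= GOOD_RECOVERY_M3_FRAC * pre:
        return RecoveryRatio(1.0, sub_tp, chron_tp, capped=True,
                             reason="recovered within the subacute phase")
    return RecoveryRatio(float(num / denom), sub_tp, chron_tp)


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences; t undefined")
    res = sp_stats.ttest_rel(x, y)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided pooled-variance Student's t-test; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    pooled = (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    if pooled == 0:
        raise ValueError("zero pooled variance; t undefined")
    res = sp_stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), int(a.size + b.size - 2), float(res.pvalue)


def chi_square_2xk(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square test of independence without continuity correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    chi2, p, df, _ = sp_stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Sequence[Sequence[float]] | np.ndarray | None = None,
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Correlates the least-squares residuals of x and y on the covariates
    (plus intercept); p-value from t = r sqrt((n-k-2)/(1-r^2)) with
    n-k-2 degrees of freedom, k = number of covariates. With no
    covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have the same length")
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariates must align with x and y")
    k = C.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        import warnings

        warnings.warn("collinear covariates; using least-norm fit", stacklevel=2)
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    if denom == 0:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float((rx * ry).sum() / denom)
    r = max(-1.0, min(1.0, r))
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sp_stats.t.sf(abs(t), df))
    return r, p


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default everywhere)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def _trajectory_from_row(row: pd.Series, prefix: str = "aq_") -> RecoveryTrajectory:
    values = {}
    for tp in TIMEPOINTS:
        v = row.get(f"{prefix}{tp}")
        if v is not None and pd.notna(v):
            values[tp] = float(v)
    meta = {c: row[c] for c in ("group", "sex", "age", "education", "grade",
                                "location", "resection") if c in row.index}
    return RecoveryTrajectory(subject=str(row["subject"]), values=values,
                              metadata=meta)


def summarize_cohort(scores: pd.DataFrame, aq_cutoff: float = 93.8) -> dict:
    """Cohort report from a Table-2-style score table.

    Expects columns ``subject, group, sex, age, education, grade,
    location, resection, aq_pre, aq_w2, aq_m1, aq_m3, aq_m6`` (missing
    observations blank). Reports per-timepoint AQ means/SDs, counts by
    grade, location, sex and labelled recovery group, the number of
    patients below the preoperative AQ cutoff, per-patient recovery
    ratios and classifications, the ratio range per labelled group, and
    any patients whose label disagrees with the stated classification
    rule.
    """
    trajectories = [_trajectory_from_row(row) for _, row in scores.iterrows()]
    per_tp = {}
    for tp in TIMEPOINTS:
        col = scores.get(f"aq_{tp}")
        if col is None:
            continue
        vals = col.dropna().astype(float)
        if len(vals):
            per_tp[tp] = {"n": int(len(vals)), "mean": float(vals.mean()),
                          "sd": float(vals.std(ddof=1))}

    ratios: dict[str, RecoveryRatio] = {}
    classes: dict[str, str] = {}
    for traj in trajectories:
        ratios[traj.subject] = recovery_ratio(traj)
        classes[traj.subject] = classify_recovery(traj)

    labels = dict(zip(scores["subject"].astype(str), scores.get("group", pd.Series())))
    mismatches = sorted(s for s, c in classes.items()
                        if labels.get(s) is not None and labels.get(s) != c)

    ratio_range = {}
    for grp in sorted(set(filter(pd.notna, labels.values()))):
        vals = [ratios[s].value for s in ratios if labels.get(s) == grp]
        ratio_range[grp] = {"min": float(min(vals)), "max": float(max(vals)),
                            "n": len(vals)}

    return {
        "n_subjects": int(len(scores)),
        "aq_by_timepoint": per_tp,
        "n_below_cutoff_pre": int((scores["aq_pre"].astype(float) < aq_cutoff).sum()),
        "aq_cutoff": aq_cutoff,
        "counts": {
            "grade": scores["grade"].value_counts().to_dict()
            if "grade" in scores else {},
            "location": scores["location"].value_counts().to_dict()
            if "location" in scores else {},
            "sex": scores["sex"].value_counts().to_dict() if "sex" in scores else {},
            "group": scores["group"].value_counts().to_dict()
            if "group" in scores else {},
        },
        "recovery_ratio": {s: rr.value for s, rr in ratios.items()},
        "capped": sorted(s for s, rr in ratios.items() if rr.capped),
        "rule_classification": classes,
        "rule_label_mismatches": mismatches,
        "ratio_range_by_group": ratio_range,
    }
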