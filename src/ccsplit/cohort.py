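"""Cohort-level statistics over subject scores.

The statistical layer of the assay: Shapiro-Wilk normality checks, one-way
ANOVA with Tukey's HSD post-hoc over the study groups, paired t-tests for the
vehicle-vs-MLi2 comparison, Spearman correlations between continuous
readouts, and the ROC c-statistic for case/control stratification. Normality
failures are logged, not acted on (results stay parametric); no
multiple-testing correction is applied across the report.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedCorrelationError

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class GroupComparison:
    summary: pd.DataFrame       # group, n, mean, sd, sem, shapiro_p
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame         # group_a, group_b, mean_diff, p_adj
    warnings: list[str]


@dataclasses.dataclass
class PairedTestResult:
    n_pairs: int
    n_dropped: int
    mean_delta: float
    t: float
    df: int
    p: float


@dataclasses.dataclass
class CorrelationResult:
    method: str
    rho: float
    p: float
    n: int


@dataclasses.dataclass
class RocResult:
    auc: float
    n_cases: int
    n_controls: int
    n_tied_pairs: int


def compare_groups(subjects: pd.DataFrame, score_col: str = "pct_split",
                   group_col: str = "group") -> GroupComparison:
    """Descriptives, Shapiro-Wilk, one-way ANOVA and Tukey HSD by group."""
    grouped = {g: np.asarray(v[score_col], dtype=float)
               for g, v in subjects.groupby(group_col, sort=False)}
    if len(grouped) < 2:
        raise InsufficientDataError("need at least 2 groups")
    small = [g for g, v in grouped.items() if len(v) < 3]
    if small:
        raise InsufficientDataError(
            f"groups with fewer than 3 subjects: {small}")

    warnings: list[str] = []
    rows = []
    for g, v in grouped.items():
        shapiro_p = float(stats.shapiro(v).pvalue)
        if shapiro_p < 0.05:
            msg = f"group {g!r} fails Shapiro-Wilk normality (p={shapiro_p:.3g})"
            warnings.append(msg)
            logger.warning(msg)
        rows.append({
            "group": g, "n": len(v), "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)),
            "sem": float(np.std(v, ddof=1) / np.sqrt(len(v))),
            "shapiro_p": shapiro_p,
        })
    summary = pd.DataFrame(rows)

    names = list(grouped)
    samples = [grouped[g] for g in names]
    f_stat, f_p = stats.f_oneway(*samples)
    hsd = stats.tukey_hsd(*samples)
    tukey_rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            tukey_rows.append({
                "group_a": names[i], "group_b": names[j],
                "mean_diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                "p_adj": float(hsd.pvalue[i, j]),
            })
    return GroupComparison(summary=summary, anova_f=float(f_stat),
                           anova_p=float(f_p),
                           tukey=pd.DataFrame(tukey_rows), warnings=warnings)


def paired_condition_test(subjects: pd.DataFrame,
                          condition_a: str = "vehicle",
                          condition_b: str = "MLi2",
                          score_col: str = "pct_split",
                          subject_col: str = "subject_id",
                          condition_col: str = "condition"
                          ) -> PairedTestResult:
    """Classical paired t-test on per-subject condition deltas (a − b).

    Subjects missing either condition are dropped and counted.
    """
    wide = subjects.pivot_table(index=subject_col, columns=condition_col,
                                values=score_col, aggfunc="mean")
    for c in (condition_a, condition_b):
        if c not in wide.columns:
            wide[c] = np.nan
    complete = wide[[condition_a, condition_b]].dropna()
    n_dropped = len(wide) - len(complete)
    if len(complete) < 2:
        raise InsufficientDataError(
            f"need >= 2 complete pairs, have {len(complete)}")
    a = complete[condition_a].to_numpy(dtype=float)
    b = complete[condition_b].to_numpy(dtype=float)
    deltas = a - b
    if np.ptp(deltas) == 0:
        # identical deltas: t is 0/0 when delta==0, infinite otherwise
        t = 0.0 if deltas[0] == 0 else np.inf * np.sign(deltas[0])
        p = 1.0 if deltas[0] == 0 else 0.0
    else:
        t, p = stats.ttest_rel(a, b)
    return PairedTestResult(n_pairs=len(complete), n_dropped=int(n_dropped),
                            mean_delta=float(deltas.mean()), t=float(t),
                            df=len(complete) - 1, p=float(p))


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be 1-D of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise InsufficientDataError("need >= 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input vector")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(method="spearman", rho=float(rho), p=float(p),
                             n=len(x))


def roc_cstat(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """ROC area under the curve (c-statistic) via the rank/Mann-Whitney form.

    AUC is the probability that a randomly chosen case outscores a randomly
    chosen control, with tied case/control score pairs counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise InsufficientDataError("scores and labels must be 1-D, equal length")
    n_cases = int(labels.sum())
    n_controls = int((~labels).sum())
    if n_cases == 0 or n_controls == 0:
        raise InsufficientDataError("both classes must be present")

    ranks = stats.rankdata(scores)  # average ranks handle ties
    rank_sum_cases = ranks[labels].sum()
    u = rank_sum_cases - n_cases * (n_cases + 1) / 2
    auc = u / (n_cases * n_controls)

    case_counts = pd.Series(scores[labels]).value_counts()
    ctrl_counts = pd.Series(scores[~labels]).value_counts()
    shared = case_counts.index.intersection(ctrl_counts.index)
    n_tied = int(sum(case_counts[v] * ctrl_counts[v] for v in shared))
    return RocResult(auc=float(auc), n_cases=n_cases, n_controls=n_controls,
                     n_tied_pairs=n_tied)


def test_retest_difference(a: float, b: float) -> float:
    """Test-retest reliability readout: absolute percent-splitting difference."""
    return abs(a - b)


def cohort_report(subjects: pd.DataFrame,
                  control_group: str = "control",
                  case_groups: Sequence[str] = ("R1441G_PD", "G2019S_PD"),
                  score_col: str = "pct_split") -> dict[str, pd.DataFrame]:
    """Standard cohort analysis bundle over a subject × condition score table.

    Returns CSV-ready tables: per-group descriptives with normality checks,
    Tukey-adjusted pairwise comparisons, the vehicle-vs-MLi2 paired t-test,
    and the case-vs-control ROC c-statistic on vehicle scores.
    """
    vehicle = subjects[subjects["condition"] == "vehicle"]
    comparison = compare_groups(vehicle, score_col=score_col)
    paired = paired_condition_test(subjects, "vehicle", "MLi2",
                                   score_col=score_col)

    roc_subset = vehicle[vehicle["group"].isin([control_group, *case_groups])]
    roc = roc_cstat(roc_subset[score_col].to_numpy(),
                    roc_subset["group"].isin(case_groups).to_numpy())

    tables = {
        "group_summary": comparison.summary.assign(
            anova_f=comparison.anova_f, anova_p=comparison.anova_p),
        "tukey_pairs": comparison.tukey,
        "paired_mli2": pd.DataFrame([dataclasses.asdict(paired)]),
        "roc": pd.DataFrame([dataclasses.asdict(roc)]),
    }
    return tables
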