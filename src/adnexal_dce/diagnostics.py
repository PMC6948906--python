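"""Group comparisons and ROC-based diagnostic performance.

Each kinetic or semi-quantitative parameter is compared across the three
pathology groups (benign, borderline, malignant) by one-way ANOVA, and
pairwise (benign vs malignant; benign vs borderline+malignant) by Student's
t-test when both groups pass Shapiro-Wilk normality at alpha = 0.05, by the
Mann-Whitney U-test otherwise.  Diagnostic value for separating benign from
borderline/malignant lesions is summarised by the rank-statistic AUC, its
normal-approximation p-value, and the confusion-matrix metrics at the
Youden-optimal cutoff (sensitivity + specificity - 1 maximised; ties go to
the lower cutoff).  Borderline tumours are grouped with malignant lesions
because of their invasive potential, so "positive" means
borderline-or-malignant throughout, and a value above the cutoff is called
positive (every discriminative parameter here is higher in malignancy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "DiagnosticPerformance",
    "compare_groups",
    "roc_with_cutoff",
    "confusion_metrics",
    "rank_auc",
]

BENIGN, BORDERLINE, MALIGNANT = "benign", "borderline", "malignant"
_CLASSES = (BENIGN, BORDERLINE, MALIGNANT)

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """Three-group summary and significance tests for one parameter."""

    parameter: str
    mean_benign: float
    sd_benign: float
    mean_borderline: float
    sd_borderline: float
    mean_malignant: float
    sd_malignant: float
    p_anova: float
    p_benign_vs_malignant: float
    p_benign_vs_borderline_malignant: float
    test_benign_vs_malignant: str
    test_benign_vs_borderline_malignant: str


@dataclass(frozen=True)
class DiagnosticPerformance:
    """ROC summary and cutoff metrics for one parameter (percent scale)."""

    parameter: str
    auc: float
    p_auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    npv: float | None
    ppv: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    degenerate: bool = False


def _group_stats(x: np.ndarray) -> tuple[float, float]:
    if x.size == 0:
        return np.nan, np.nan
    return float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else np.nan


def _pairwise_test(a: np.ndarray, b: np.ndarray) -> tuple[float, str]:
    """Two-tailed t-test if both samples pass Shapiro-Wilk, else Mann-Whitney.

    Samples too small for the normality test (n < 3) or constant pooled data
    fall through to the rank test; with all values tied the p-value is 1.
    """
    if a.size < 2 or b.size < 2:
        return np.nan, "none"
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0, "mann-whitney"

    def normal(x: np.ndarray) -> bool:
        if x.size < 3 or np.ptp(x) == 0:
            return False
        return stats.shapiro(x).pvalue > NORMALITY_ALPHA

    if normal(a) and normal(b):
        return float(stats.ttest_ind(a, b).pvalue), "t"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue), \
        "mann-whitney"


def compare_groups(
    values: Sequence[float],
    labels: Sequence[str],
    parameter: str = "",
) -> GroupComparison:
    """Compare one parameter across benign/borderline/malignant groups.

    Groups with fewer than two observations are dropped from the ANOVA and
    their pairwise comparisons are reported as NaN.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    unknown = set(labels) - set(_CLASSES)
    if unknown:
        raise ValueError(f"unknown pathology labels: {sorted(unknown)}")

    groups = {c: values[labels == c] for c in _CLASSES}
    anova_groups = [g for g in groups.values() if g.size >= 2]
    if len(anova_groups) >= 2 and np.ptp(np.concatenate(anova_groups)) > 0:
        p_anova = float(stats.f_oneway(*anova_groups).pvalue)
    elif len(anova_groups) >= 2:
        p_anova = 1.0
    else:
        p_anova = np.nan

    p_bm, test_bm = _pairwise_test(groups[BENIGN], groups[MALIGNANT])
    pooled_pos = np.concatenate([groups[BORDERLINE], groups[MALIGNANT]])
    p_bbm, test_bbm = _pairwise_test(groups[BENIGN], pooled_pos)

    mb, sb = _group_stats(groups[BENIGN])
    mo, so = _group_stats(groups[BORDERLINE])
    mm, sm = _group_stats(groups[MALIGNANT])
    return GroupComparison(
        parameter=parameter,
        mean_benign=mb, sd_benign=sb,
        mean_borderline=mo, sd_borderline=so,
        mean_malignant=mm, sd_malignant=sm,
        p_anova=p_anova,
        p_benign_vs_malignant=p_bm,
        p_benign_vs_borderline_malignant=p_bbm,
        test_benign_vs_malignant=test_bm,
        test_benign_vs_borderline_malignant=test_bbm,
    )


def rank_auc(values: np.ndarray, positive: np.ndarray) -> tuple[float, float]:
    """AUC from the Mann-Whitney rank statistic, with its two-sided
    normal-approximation p-value (tie-corrected variance).

    Equivalent to the fraction of positive-negative pairs in which the
    positive case scores higher, counting ties as 1/2.
    """
    values = np.asarray(values, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n1 = int(positive.sum())
    n0 = int((~positive).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(values)
    u = float(ranks[positive].sum()) - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)

    n = n1 + n0
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    if n > 1:
        var_u = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    else:  # pragma: no cover
        var_u = 0.0
    if var_u <= 0:
        return auc, 1.0
    z = (u - n1 * n0 / 2.0) / np.sqrt(var_u)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc, float(min(p, 1.0))


def confusion_metrics(tp: int, fp: int, tn: int, fn: int,
                      decimals: int | None = 1) -> dict[str, float | None]:
    """Percent metrics from a confusion matrix.

    Returns sensitivity, specificity, accuracy, PPV and NPV on the percent
    scale, rounded to ``decimals`` (pass None for full precision).
    Undefined predictive values (empty predicted class) are reported as
    None.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if tp + fn == 0:
        raise ValueError("no positive cases (tp + fn = 0)")
    if tn + fp == 0:
        raise ValueError("no negative cases (tn + fp = 0)")

    def pct(num: float, den: float) -> float | None:
        if den == 0:
            return None
        value = 100.0 * num / den
        return round(value, decimals) if decimals is not None else value

    return {
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "accuracy": pct(tp + tn, tp + fp + tn + fn),
        "ppv": pct(tp, tp + fp),
        "npv": pct(tn, tn + fn),
    }


def roc_with_cutoff(
    values: Sequence[float],
    positive: Sequence[bool],
    parameter: str = "",
) -> DiagnosticPerformance:
    """ROC analysis with a Youden-optimal cutoff for one parameter.

    A case is called positive when its value exceeds the cutoff.  Candidate
    cutoffs are the midpoints between consecutive distinct values plus
    sentinels below and above the data range; among cutoffs with equal
    Youden's J the lowest is returned.  Constant values yield AUC 0.5 and a
    degenerate flag.
    """
    values = np.asarray(values, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if values.shape != positive.shape:
        raise ValueError("values and labels must have equal length")
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")

    degenerate = np.ptp(values) == 0
    auc, p_auc = rank_auc(values, positive)

    uniq = np.unique(values)
    candidates = np.concatenate((
        [uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0],
    ))
    best_cut = None
    best_j = -np.inf
    best_counts = None
    for cut in candidates:
        called = values > cut
        tp = int(np.sum(called & positive))
        fp = int(np.sum(called & ~positive))
        fn = n_pos - tp
        tn = n_neg - fp
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j + 1e-12:
            best_j = j
            best_cut = float(cut)
            best_counts = (tp, fp, tn, fn)

    tp, fp, tn, fn = best_counts
    metrics = confusion_metrics(tp, fp, tn, fn, decimals=1)
    return DiagnosticPerformance(
        parameter=parameter,
        auc=auc, p_auc=p_auc, cutoff=best_cut,
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        accuracy=metrics["accuracy"],
        npv=metrics["npv"], ppv=metrics["ppv"],
        tp=tp, fp=fp, tn=tn, fn=fn,
        degenerate=bool(degenerate),
    )
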