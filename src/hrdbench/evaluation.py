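"""ROC / precision-recall evaluation of a continuous HRD score.

The positive class is "carries biallelic inactivation evidence". AUC is
computed by the trapezoidal rule over the empirical ROC curve, which for
tie-aware thresholds equals the Mann-Whitney pair-counting probability
P(score_pos > score_neg) + 0.5 P(tie). Confidence intervals come from a
stratified (within-class) percentile bootstrap; two correlated AUCs are
compared with DeLong's variance of the per-sample structural components.

A tumor is called HRD-positive when its score is >= the threshold, so
the published CHORD cutoff 0.5 calls a score of exactly 0.5 positive;
pass ``strict=True`` for the > convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as _skm


class DegenerateLabelsError(ValueError):
    """Raised when an operation needs both classes but got one."""


@dataclass(frozen=True)
class RocSummary:
    """ROC points (fpr, tpr, threshold), trapezoidal AUC, optional bootstrap CI."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci: tuple[float, float] | None = None
    ci_level: float | None = None
    ci_replicates: int | None = None
    ci_seed: int | None = None


@dataclass(frozen=True)
class PrSummary:
    """Precision-recall points and average-precision AUPRC."""

    recall: np.ndarray
    precision: np.ndarray
    auprc: float


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_binary(labels: np.ndarray) -> None:
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise DegenerateLabelsError(
            "need at least one positive and one negative label"
        )


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be the same length")
    return s, y


def compute_roc(scores: Sequence[float], labels: Sequence[bool]) -> RocSummary:
    """Empirical ROC curve with thresholds at unique score values."""
    s, y = _as_arrays(scores, labels)
    _check_binary(y)
    fpr, tpr, thr = _skm.roc_curve(y, s, drop_intermediate=False)
    return RocSummary(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_skm.auc(fpr, tpr)))


def auc_bootstrap_ci(
    scores: Sequence[float],
    labels: Sequence[bool],
    replicates: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the AUC, resampling within each class.

    Stratified resampling keeps both classes present in every replicate,
    which matters for small cohorts (the ovarian stratum has 66 tumors).
    """
    s, y = _as_arrays(scores, labels)
    _check_binary(y)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    pos = s[y]
    neg = s[~y]
    aucs = np.empty(replicates)
    for i in range(replicates):
        ps = rng.choice(pos, size=pos.size, replace=True)
        ns = rng.choice(neg, size=neg.size, replace=True)
        aucs[i] = _pair_auc(ps, ns)
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _pair_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC via midranks — O((m+n) log(m+n))."""
    all_s = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_s)  # midranks handle ties
    r_pos = ranks[: pos.size].sum()
    m, n = pos.size, neg.size
    return (r_pos - m * (m + 1) / 2) / (m * n)


def compute_pr(scores: Sequence[float], labels: Sequence[bool]) -> PrSummary:
    """Precision-recall curve; AUPRC by the step-wise average-precision sum."""
    s, y = _as_arrays(scores, labels)
    if y.sum() == 0:
        raise DegenerateLabelsError("precision-recall needs at least one positive")
    precision, recall, _ = _skm.precision_recall_curve(y, s)
    auprc = float(_skm.average_precision_score(y, s))
    return PrSummary(recall=recall, precision=precision, auprc=auprc)


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-sample structural components V10 (positives), V01 (negatives)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    # midrank formulation (Sun & Xu); components from within/combined midranks
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc), v10, v01


def delong_paired_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
) -> tuple[float, float, float, float]:
    """DeLong's paired two-sided test for two correlated AUCs.

    Returns (auc_a, auc_b, z, p). Identical scores (zero variance of the
    AUC difference) report z = 0, p = 1 rather than failing.
    """
    sa, y = _as_arrays(scores_a, labels)
    sb, _ = _as_arrays(scores_b, labels)
    _check_binary(y)
    auc_a, v10_a, v01_a = _delong_components(sa, y)
    auc_b, v10_b, v01_b = _delong_components(sb, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0 or math.isclose(var_diff, 0.0, abs_tol=1e-16):
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


def confusion_at_threshold(
    scores: Sequence[float],
    labels: Sequence[bool],
    threshold: float,
    strict: bool = False,
) -> ConfusionTable:
    """Confusion counts with the >= (default) or > call rule."""
    s, y = _as_arrays(scores, labels)
    pred = s > threshold if strict else s >= threshold
    return ConfusionTable(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
        tn=int(np.sum(~pred & ~y)),
        threshold=float(threshold),
    )


def table_metrics(t: ConfusionTable) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN marks a zero denominator."""
    acc = (t.tp + t.tn) / t.n if t.n else float("nan")
    sens = t.tp / (t.tp + t.fn) if (t.tp + t.fn) else float("nan")
    spec = t.tn / (t.tn + t.fp) if (t.tn + t.fp) else float("nan")
    return acc, sens, spec
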