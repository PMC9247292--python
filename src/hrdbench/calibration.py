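"""Cancer-type-specific decision thresholds by tenfold nested cross-validation.

The published classifiers ship universal cutoffs (CHORD 0.5, HRDetect
0.7) that were not tuned per cancer type. The calibration here searches
the full set of achievable cutoffs — midpoints between consecutive
distinct scores, plus sentinels below the minimum and above the maximum
— and picks the one maximizing classification accuracy (Youden's J is
available as an alternative criterion).

To report an honest threshold and an unbiased estimate of its held-out
accuracy, the search is wrapped in nested stratified cross-validation:
each of the ``outer_k`` outer folds holds out ~10% of the cohort; the
remaining 90% is split again into ``inner_k`` folds, the best cutoff is
fit on each inner-training part, the ``inner_k`` cutoffs are averaged,
and that averaged cutoff is scored on the held-out outer fold. The
reported optimal threshold is the mean of the outer-loop averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .evaluation import DegenerateLabelsError

CRITERIA = ("accuracy", "youden")


@dataclass
class CalibrationResult:
    cancer_type: str
    classifier: str
    optimal_threshold: float
    outer_thresholds: list[float]
    outer_accuracies: list[float]
    mean_accuracy: float
    seed: int | None
    fold_map: dict[str, int] = field(default_factory=dict)


def candidate_thresholds(scores) -> np.ndarray:
    """Ascending cutoffs: midpoints between distinct scores plus sentinels.

    ``n`` distinct scores yield exactly ``n + 1`` candidates — one below
    the minimum (calls everything positive under the >= rule), the
    ``n - 1`` midpoints, and one above the maximum (calls nothing).
    A constant score vector yields its single degenerate candidate.
    """
    uniq = np.unique(np.asarray(scores, dtype=float))
    if uniq.size == 1:
        return uniq.copy()
    delta = np.diff(uniq).min() / 2.0
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[uniq[0] - delta], mids, [uniq[-1] + delta]])


def _criterion_values(
    scores: np.ndarray, labels: np.ndarray, cands: np.ndarray, criterion: str
) -> np.ndarray:
    # broadcast: predictions[i, j] = score_j >= candidate_i
    pred = scores[None, :] >= cands[:, None]
    y = labels[None, :]
    tp = (pred & y).sum(axis=1)
    tn = (~pred & ~y).sum(axis=1)
    if criterion == "accuracy":
        return (tp + tn) / scores.size
    if criterion == "youden":
        n_pos = labels.sum()
        n_neg = scores.size - n_pos
        return tp / n_pos + tn / n_neg - 1.0
    raise ValueError(f"unknown criterion {criterion!r}; use one of {CRITERIA}")


def best_threshold(scores, labels, criterion: str = "accuracy") -> float:
    """Exhaustive sweep over candidate cutoffs; ties go to the smallest.

    The smallest of equally optimal cutoffs maximizes sensitivity,
    favouring not missing HR-deficient tumors.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateLabelsError("threshold fitting needs both classes")
    cands = candidate_thresholds(s)
    values = _criterion_values(s, y, cands, criterion)
    return float(cands[int(np.argmax(values))])  # argmax takes the first (lowest) max


def nested_cv_calibrate(
    scores,
    labels,
    outer_k: int = 10,
    inner_k: int = 10,
    seed: int | None = None,
    criterion: str = "accuracy",
    cancer_type: str = "all",
    classifier: str = "score",
    sample_ids=None,
) -> CalibrationResult:
    """Nested stratified CV threshold calibration.

    For each outer split the inner-fold best thresholds (fit on the
    inner-training parts) are averaged; that average is evaluated on the
    held-out outer fold; the final threshold is the mean of the outer
    averages, clamped to the observed score range of the full cohort.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if min(n_pos, n_neg) < outer_k:
        raise DegenerateLabelsError(
            f"nested CV with outer_k={outer_k} needs >= {outer_k} samples of each "
            f"class; got {n_pos} positives / {n_neg} negatives"
        )
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    outer_thresholds: list[float] = []
    outer_accuracies: list[float] = []
    fold_map: dict[str, int] = {}
    ids = list(sample_ids) if sample_ids is not None else None

    for fold_idx, (train_idx, test_idx) in enumerate(outer.split(s, y)):
        if ids is not None:
            for i in test_idx:
                fold_map[ids[i]] = fold_idx
        s_tr, y_tr = s[train_idx], y[train_idx]
        inner_seed = None if seed is None else seed + 1 + fold_idx
        inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=inner_seed)
        inner_cuts = [
            best_threshold(s_tr[fit_idx], y_tr[fit_idx], criterion)
            for fit_idx, _ in inner.split(s_tr, y_tr)
        ]
        theta = float(np.mean(inner_cuts))
        outer_thresholds.append(theta)
        pred = s[test_idx] >= theta
        outer_accuracies.append(float(np.mean(pred == y[test_idx])))

    optimal = float(np.clip(np.mean(outer_thresholds), s.min(), s.max()))
    return CalibrationResult(
        cancer_type=cancer_type,
        classifier=classifier,
        optimal_threshold=optimal,
        outer_thresholds=outer_thresholds,
        outer_accuracies=outer_accuracies,
        mean_accuracy=float(np.mean(outer_accuracies)),
        seed=seed,
        fold_map=fold_map,
    )
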