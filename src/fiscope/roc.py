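"""ROC construction, AUC with Hanley-McNeil standard error, cutoff
selection, and confusion-matrix metrics.

AUC uses the Mann-Whitney convention (ties get half credit), which equals
the trapezoidal area under the empirical ROC. Candidate cutoffs are
midpoints between adjacent distinct scores (plus sentinels below the
minimum and above the maximum), and the call rule is score >= cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DomainError


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise DomainError("scores and labels must align")
    pos, neg = s[y], s[~y]
    if pos.size == 0 or neg.size == 0:
        raise DomainError("both classes must be present")
    return pos, neg


def auc(scores, labels) -> float:
    """P(score_pos > score_neg) + 0.5 P(equal), via midranks."""
    pos, neg = _split(scores, labels)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = float(np.sum(ranks[: pos.size])) - pos.size * (pos.size + 1) / 2.0
    return u / (pos.size * neg.size)


def roc_points(scores, labels) -> pd.DataFrame:
    """Operating points from (0,0) to (1,1), thresholds descending."""
    pos, neg = _split(scores, labels)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    rows = [(np.inf, 0.0, 0.0)]
    for t in thresholds:
        rows.append((t, float(np.mean(pos >= t)), float(np.mean(neg >= t))))
    return pd.DataFrame(rows, columns=["threshold", "sensitivity", "fpr"])


def trapezoid_auc(scores, labels) -> float:
    """Area under the empirical ROC by trapezoidal integration."""
    pts = roc_points(scores, labels)
    return float(np.trapezoid(pts["sensitivity"], pts["fpr"]))


def auc_se_hanley_mcneil(auc_value: float, n_pos: int, n_neg: int) -> float:
    """Closed-form SE of an empirical AUC (Hanley-McNeil).

    Uses Q1 = A/(2-A) and Q2 = 2A^2/(1+A):
    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos n_neg).
    """
    a = float(auc_value)
    if not 0.0 <= a <= 1.0:
        raise DomainError("AUC must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise DomainError("group sizes must be >= 1")
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])


def select_cutoff(scores, labels, policy: str = "youden") -> float:
    """Choose a cutoff from the realized score midpoints.

    ``youden`` maximizes sensitivity + specificity - 1 (ties broken toward
    the lower threshold). ``max-specificity`` takes, among cutoffs with
    specificity exactly 1, the one maximizing sensitivity; when no midpoint
    clears every negative, it returns a threshold above the largest
    negative score.
    """
    pos, neg = _split(scores, labels)
    all_scores = np.concatenate([pos, neg])
    candidates = _candidate_cutoffs(all_scores)
    sens = np.array([np.mean(pos >= c) for c in candidates])
    spec = np.array([np.mean(neg < c) for c in candidates])
    if policy == "youden":
        j = sens + spec - 1.0
        return float(candidates[int(np.argmax(j == j.max()))])
    if policy == "max-specificity":
        perfect = spec == 1.0
        if not perfect.any():
            return float(neg.max() + 1.0)
        best_sens = sens[perfect].max()
        ok = perfect & (sens == best_sens)
        return float(candidates[int(np.argmax(ok))])
    raise DomainError(f"unknown cutoff policy {policy!r}")


def confusion_metrics(calls, labels) -> dict:
    """Sensitivity, specificity, PPV, NPV and the raw counts.

    Ratios with zero denominators are reported as NaN (missing), never 0.
    """
    c = np.asarray(calls, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if c.shape != y.shape:
        raise DomainError("calls and labels must align")
    tp = int(np.sum(c & y))
    fp = int(np.sum(c & ~y))
    tn = int(np.sum(~c & ~y))
    fn = int(np.sum(~c & y))

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


@dataclass
class ROCResult:
    points: pd.DataFrame
    auc: float
    se: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n_pos: int
    n_neg: int


def roc_analysis(
    scores,
    labels,
    policy: str = "youden",
    cutoff: float | None = None,
) -> ROCResult:
    """Full ROC summary; ``cutoff`` overrides the selection policy."""
    scores = pd.Series(scores, dtype=float)
    labels = pd.Series(labels).astype(bool).reindex(scores.index)
    pos, neg = _split(scores.to_numpy(), labels.to_numpy())
    a = auc(scores.to_numpy(), labels.to_numpy())
    se = auc_se_hanley_mcneil(a, pos.size, neg.size)
    chosen = float(cutoff) if cutoff is not None else select_cutoff(
        scores.to_numpy(), labels.to_numpy(), policy=policy
    )
    calls = scores.to_numpy() >= chosen
    metrics = confusion_metrics(calls, labels.to_numpy())
    return ROCResult(
        points=roc_points(scores.to_numpy(), labels.to_numpy()),
        auc=a,
        se=se,
        cutoff=chosen,
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        ppv=metrics["ppv"],
        npv=metrics["npv"],
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )
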