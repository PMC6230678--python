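"""Composite food-impaction (FI) score.

Transcripts that separate EoE patients with and without food impaction are
weighted by the product of their log2 fold difference and their adjusted
significance, w_g = log2FD_g x (-log10 q_g), gated at q_g < alpha and
L1-normalized so the absolute weights sum to one. Down-regulated
transcripts therefore carry negative weight. Each EoE patient's raw score
is the weighted sum of per-gene standardized log expression,

    s_p = sum_g w_g * z_{g,p},   z from log2(normalized + 1) across the
                                 scored cohort (sample SD, ddof=1),

and the raw scores are z-standardized across the cohort. A patient is
called FI-positive when the standardized score is >= the cutoff (chosen by
ROC analysis, see :mod:`fiscope.roc`).

This is a one-factor projection with fixed, externally derived loadings —
not an iterative factor-analysis fit, which a cohort of a few dozen
patients could not support for a 74-gene loading matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateScoreError, DomainError, EmptySignatureError
from .de import DEResult
from .normalize import NormalizedMatrix

_Q_FLOOR = 1e-300  # keeps -log10 finite for numerically zero q


@dataclass
class TranscriptWeights:
    """Signed per-gene weights; zero outside the significance gate."""

    weights: pd.Series  # gene -> weight, sum(|w|) == 1 when any nonzero
    alpha: float
    normalization_constant: float  # sum |raw weight| before scaling

    def nonzero(self) -> pd.Series:
        return self.weights[self.weights != 0.0]


@dataclass
class FIScoreResult:
    raw: pd.Series  # per scored patient
    standardized: pd.Series
    calls: pd.Series  # bool, True = FI-positive
    cutoff: float
    cohort_mean: float
    cohort_sd: float


def compute_transcript_weights(
    de: DEResult,
    alpha: float = 0.05,
    contrast: str = "fi_vs_nofi",
    rank_based: bool = False,
) -> TranscriptWeights:
    """Weights from fold difference x adjusted significance.

    ``rank_based=True`` replaces the two magnitudes by their within-gate
    ranks (a flatter alternative weighting); the sign still comes from the
    fold-difference direction.
    """
    fd_col, q_col = f"log2fd_{contrast}", "q_fi_vs_nofi"
    if fd_col not in de.table.columns:
        raise DomainError(f"DE result lacks contrast {contrast!r}")
    fd = de.table[fd_col]
    q = de.table[q_col].clip(lower=_Q_FLOOR)
    passing = q < alpha
    if not passing.any():
        raise EmptySignatureError(
            f"empty signature: no transcript with q < {alpha}"
        )
    if rank_based:
        mag_fd = fd.abs().where(passing).rank()
        mag_q = (-np.log10(q)).where(passing).rank()
        raw = np.sign(fd) * mag_fd * mag_q
        raw = raw.fillna(0.0)
    else:
        raw = (fd * (-np.log10(q))).where(passing, 0.0)
    norm_const = float(raw.abs().sum())
    return TranscriptWeights(
        weights=raw / norm_const, alpha=alpha, normalization_constant=norm_const
    )


def compute_raw_fi_score(
    norm: NormalizedMatrix,
    weights: TranscriptWeights,
    cohort: list | pd.Index,
) -> pd.Series:
    """Weighted sum of per-gene standardized log expression over ``cohort``.

    ``cohort`` should be the EoE samples (controls are not scored). Genes
    with zero spread across the cohort contribute nothing.
    """
    cohort = list(cohort)
    if len(cohort) < 3:
        raise DomainError("scoring cohort must have >= 3 samples")
    x = norm.log2_values().loc[cohort]
    w = weights.weights.reindex(x.columns).fillna(0.0)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    z = (x - mu).div(sd.replace(0.0, np.inf), axis=1)
    scores = z.mul(w, axis=1).sum(axis=1)
    scores.name = "raw_score"
    return scores


def standardize_scores(raw_scores: pd.Series) -> pd.Series:
    """(s - mean) / SD across the scored cohort (sample SD, ddof=1)."""
    s = pd.Series(raw_scores, dtype=float)
    if s.size < 3:
        raise DomainError("standardization needs >= 3 scores")
    sd = float(s.std(ddof=1))
    if sd == 0.0:
        raise DegenerateScoreError("degenerate score distribution (zero SD)")
    out = (s - float(s.mean())) / sd
    out.name = "fi_score"
    return out


def call_fi(standardized_scores: pd.Series, cutoff: float) -> pd.Series:
    """FI-positive iff score >= cutoff."""
    if not np.isfinite(cutoff):
        raise DomainError("cutoff must be finite")
    calls = pd.Series(standardized_scores, dtype=float) >= cutoff
    calls.name = "fi_call"
    return calls


def score_cohort(
    norm: NormalizedMatrix,
    de: DEResult,
    fi_labels: pd.Series,
    alpha: float = 0.05,
    cutoff_policy: str = "youden",
) -> tuple[TranscriptWeights, FIScoreResult, "ROCResult"]:
    """Weights -> raw score -> standardization -> ROC cutoff -> calls.

    ``fi_labels`` is a boolean Series over the EoE samples to score (True =
    food impaction). ``cutoff_policy`` is ``youden``, ``max-specificity``
    or ``fixed:<value>``.
    """
    from .roc import roc_analysis  # local import to avoid a cycle

    weights = compute_transcript_weights(de, alpha=alpha)
    cohort = list(fi_labels.index)
    raw = compute_raw_fi_score(norm, weights, cohort)
    standardized = standardize_scores(raw)
    mean, sd = float(raw.mean()), float(raw.std(ddof=1))
    if cutoff_policy.startswith("fixed:"):
        cutoff = float(cutoff_policy.split(":", 1)[1])
        roc = roc_analysis(standardized, fi_labels.astype(bool), cutoff=cutoff)
    else:
        roc = roc_analysis(standardized, fi_labels.astype(bool), policy=cutoff_policy)
        cutoff = roc.cutoff
    calls = call_fi(standardized, cutoff)
    result = FIScoreResult(
        raw=raw,
        standardized=standardized,
        calls=calls,
        cutoff=cutoff,
        cohort_mean=mean,
        cohort_sd=sd,
    )
    return weights, result, roc


def loo_scores(
    norm: NormalizedMatrix,
    groups: pd.Series,
    fi_labels: pd.Series,
    alpha: float = 0.05,
) -> pd.Series:
    """Leave-one-out FI scores: weights and cohort statistics are re-derived
    with each patient held out, and the held-out patient is scored against
    them. A more honest (typically lower-AUC) view than in-sample scoring."""
    from .de import differential_expression

    cohort = list(fi_labels.index)
    out = {}
    for held in cohort:
        rest = [s for s in cohort if s != held]
        sub_groups = groups.drop(held)
        sub_norm = NormalizedMatrix(
            values=norm.values.drop(index=held),
            positive_factors=norm.positive_factors.drop(held, errors="ignore"),
            housekeeping_factors=norm.housekeeping_factors.drop(held, errors="ignore"),
            background=norm.background.drop(held, errors="ignore"),
            qc_flags=norm.qc_flags,
        )
        de = differential_expression(sub_norm, sub_groups)
        weights = compute_transcript_weights(de, alpha=alpha)
        x = norm.log2_values().loc[rest]
        mu, sd = x.mean(axis=0), x.std(axis=0, ddof=1)
        z_held = (norm.log2_values().loc[held] - mu) / sd.replace(0.0, np.inf)
        raw_held = float((z_held * weights.weights.reindex(x.columns).fillna(0.0)).sum())
        rest_raw = compute_raw_fi_score(sub_norm, weights, rest)
        out[held] = (raw_held - float(rest_raw.mean())) / float(rest_raw.std(ddof=1))
    return pd.Series(out, name="fi_score_loo")
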