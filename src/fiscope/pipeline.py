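"""Multi-loop diagnostic gating and the end-to-end pipeline.

The primary gate calls an EoE diagnosis when the composite disease
probability p(EoE) exceeds 25 (strict). Two secondary loops annotate,
independently of each other, (a) elevated esophageal IgE-pathway activity
when the IGHE score exceeds the published 37.5 cutoff and (b) food-impaction
risk from the FI-score against its ROC-derived cutoff. The probability
model behind p(EoE) is deliberately pluggable plumbing — a regularized
multinomial logistic model on standardized log expression — standing behind
a stable interface; the loops only consume its probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.preprocessing import StandardScaler

from .containers import ClinicalTable, RawCountSet
from .de import DEResult, differential_expression
from .errors import DomainError, FiscopeError
from .normalize import NormalizedMatrix, normalize_lanes
from .roc import ROCResult
from .score import FIScoreResult, TranscriptWeights, score_cohort

P_EOE_GATE = 25.0
IGHE_GATE = 37.5
MODEL_CLASSES = ("Control", "EoE", "GERD")


def gate_eoe(p_eoe: float) -> bool:
    """EoE diagnosis gate: true iff p(EoE) > 25 (strict)."""
    if not 0.0 <= p_eoe <= 100.0:
        raise DomainError(f"p(EoE)={p_eoe} outside [0, 100]")
    return p_eoe > P_EOE_GATE


def apply_ighe_loop(ighe_score: float) -> bool:
    """IGHE secondary loop: elevated iff score > 37.5 (strict)."""
    if not np.isfinite(ighe_score):
        raise DomainError("IGHE score must be finite")
    return float(ighe_score) > IGHE_GATE


@dataclass
class ProbabilityModel:
    """Serializable multinomial model returning (p_Control, p_EoE, p_GERD)
    triples on a 0-100 scale summing to 100 per sample."""

    classes: list
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    coef: np.ndarray
    intercept: np.ndarray
    genes: list

    def predict_triples(self, norm: NormalizedMatrix) -> pd.DataFrame:
        x = norm.log2_values()[self.genes].to_numpy()
        x = (x - self.scaler_mean) / self.scaler_scale
        logits = x @ self.coef.T + self.intercept
        if logits.shape[1] == 1:  # sklearn binary layout
            logits = np.hstack([-logits, logits])
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        out = pd.DataFrame(0.0, index=norm.values.index,
                           columns=[f"p_{c}" for c in MODEL_CLASSES])
        for k, cls in enumerate(self.classes):
            out[f"p_{cls}"] = 100.0 * probs[:, k]
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": list(self.classes),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "genes": list(self.genes),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ProbabilityModel":
        d = json.loads(Path(path).read_text())
        return cls(
            classes=d["classes"],
            scaler_mean=np.asarray(d["scaler_mean"]),
            scaler_scale=np.asarray(d["scaler_scale"]),
            coef=np.asarray(d["coef"]),
            intercept=np.asarray(d["intercept"]),
            genes=d["genes"],
        )


def default_probability_model(
    norm: NormalizedMatrix,
    labels: pd.Series,
    seed: int = 0,
    c_reg: float = 1.0,
) -> ProbabilityModel:
    """Fit the default p(EoE)/p(GERD)/p(Control) model.

    ``labels`` take values in {Control, EoE, GERD}; at least two classes
    must be present. Deterministic for a fixed seed.
    """
    labels = labels.reindex(norm.values.index)
    bad = set(labels.dropna()) - set(MODEL_CLASSES)
    if bad:
        raise DomainError(f"unknown model classes: {sorted(bad)}")
    if labels.nunique() < 2:
        raise DomainError("probability model needs >= 2 classes in training labels")
    x = norm.log2_values().to_numpy()
    scaler = StandardScaler().fit(x)
    scaler.scale_[scaler.scale_ == 0.0] = 1.0
    clf = LogisticRegression(
        C=c_reg, max_iter=5000, random_state=seed
    ).fit(scaler.transform(x), labels.to_numpy())
    return ProbabilityModel(
        classes=list(clf.classes_),
        scaler_mean=scaler.mean_,
        scaler_scale=scaler.scale_,
        coef=clf.coef_,
        intercept=clf.intercept_,
        genes=list(norm.values.columns),
    )


def crossfit_probability_triples(
    norm: NormalizedMatrix,
    labels: pd.Series,
    seed: int = 0,
    n_splits: int = 5,
    c_reg: float = 1.0,
) -> pd.DataFrame:
    """Out-of-fold probability triples (stratified k-fold), so no sample is
    gated by a model that saw it during training."""
    labels = labels.reindex(norm.values.index)
    if labels.nunique() < 2:
        raise DomainError("probability model needs >= 2 classes")
    x = StandardScaler().fit_transform(norm.log2_values().to_numpy())
    clf = LogisticRegression(C=c_reg, max_iter=5000, random_state=seed)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    probs = cross_val_predict(clf, x, labels.to_numpy(), cv=cv, method="predict_proba")
    classes = sorted(labels.unique())
    out = pd.DataFrame(0.0, index=norm.values.index,
                       columns=[f"p_{c}" for c in MODEL_CLASSES])
    for k, cls in enumerate(classes):
        out[f"p_{cls}"] = 100.0 * probs[:, k]
    return out


@dataclass
class PipelineConfig:
    background: str = "mean"
    use_positives: bool = True
    use_housekeeping: bool = True
    alpha: float = 0.05
    cutoff_policy: str = "youden"  # or max-specificity, fixed:<x>
    dunn_adjust: str = "bonferroni"
    gene_family: str = "bh"
    use_eoe_gate: bool = False  # gate on modeled p(EoE) instead of labels
    p_eoe_gate: float = P_EOE_GATE
    ighe_gate: float = IGHE_GATE
    seed: int = 0


@dataclass
class PipelineResult:
    normalized: NormalizedMatrix
    de: DEResult
    weights: TranscriptWeights
    scores: FIScoreResult
    roc: ROCResult
    decisions: pd.DataFrame
    probabilities: pd.DataFrame | None = None


def run_pipeline(
    raw: RawCountSet,
    metadata: ClinicalTable,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """normalize -> (optional EoE gate) -> DE -> weights -> FI-score ->
    ROC cutoff -> per-patient decisions.

    The FI loop runs only on EoE samples (gated or labeled); controls never
    receive an FI call. If the metadata carries an ``ighe_score`` column the
    IGHE loop annotates it, independent of the FI loop. Stage failures are
    re-raised with the stage name prefixed.
    """
    config = config or PipelineConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except FiscopeError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    norm = stage("normalize", normalize_lanes, raw,
                 background=config.background,
                 use_positives=config.use_positives,
                 use_housekeeping=config.use_housekeeping)

    meta = metadata.table.reindex(norm.values.index)
    groups = meta["group"]

    probabilities = None
    if config.use_eoe_gate:
        model_labels = groups.map(
            lambda g: "EoE" if g in ("EoE_no_FI", "EoE_FI") else "Control"
        )
        probabilities = stage(
            "probability_gate", crossfit_probability_triples,
            norm, model_labels, seed=config.seed,
        )
        eoe_pass = probabilities["p_EoE"].map(gate_eoe)
        eoe_samples = list(meta.index[eoe_pass & groups.isin(["EoE_no_FI", "EoE_FI"])])
    else:
        eoe_samples = list(meta.index[groups.isin(["EoE_no_FI", "EoE_FI"])])

    de = stage("differential_expression", differential_expression,
               norm, groups, dunn_adjust=config.dunn_adjust,
               gene_family=config.gene_family)

    fi_labels = (groups.loc[eoe_samples] == "EoE_FI")
    weights, scores, roc = stage(
        "fi_score", score_cohort, norm, de, fi_labels,
        alpha=config.alpha, cutoff_policy=config.cutoff_policy,
    )

    decisions = pd.DataFrame(index=norm.values.index)
    decisions["group"] = groups
    if probabilities is not None:
        decisions = decisions.join(probabilities)
        decisions["eoe_gate"] = probabilities["p_EoE"].map(gate_eoe)
    if "ighe_score" in meta.columns:
        ighe = pd.to_numeric(meta["ighe_score"], errors="coerce")
        decisions["ighe_score"] = ighe
        decisions["ighe_elevated"] = ighe.map(
            lambda v: apply_ighe_loop(v) if np.isfinite(v) else pd.NA
        )
    decisions["fi_score"] = scores.standardized.reindex(decisions.index)
    decisions["fi_call"] = scores.calls.reindex(decisions.index).astype("boolean")

    result = PipelineResult(
        normalized=norm, de=de, weights=weights, scores=scores, roc=roc,
        decisions=decisions, probabilities=probabilities,
    )
    if out_dir is not None:
        from .io import write_report

        write_report(
            {
                "normalized": norm,
                "de": de,
                "weights": weights,
                "scores": scores,
                "roc": roc,
                "decisions": decisions,
            },
            out_dir,
        )
    return result
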