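"""Synthetic cohort generator.

Emulates the data structure of a targeted esophageal mRNA panel study of
eosinophilic esophagitis (EoE): three patient groups (healthy controls, EoE
without food impaction, EoE with food impaction), a 74-gene endogenous
panel with 5 housekeeping genes and spike-in controls, per-lane technical
scale, and planted group effects — EoE-wide up-regulation of Th2/eosinophil
transcripts and an impaction-specific *down*-regulation of mast-cell, Th2
and motility genes (CPA3, FCER1B, CCL2, IL4, IL5, NOS2, HIF1A).

Counts follow a negative binomial (Poisson-gamma) law, which captures the
overdispersion of digital count panels; a log-normal per-lane factor models
the technical scale that control-based normalization is meant to remove.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    BINARY_CLINICAL_FIELDS,
    GROUPS,
    ClinicalTable,
    ProbeAnnotation,
    RawCountSet,
)
from .errors import ConfigurationError

NAMED_GENES = ("CPA3", "FCER1B", "CCL2", "CCL26", "IL4", "IL5", "NOS2", "HIF1A")

#: EoE vs Control fold factors shared by both EoE groups (Th2/eosinophil axis
#: up). For the mast-cell/Th2 genes the up-fold roughly inverts the
#: impaction down-fold below, so EoE+FI levels return toward control — the
#: expression pattern the impaction subgroup is characterized by.
DEFAULT_EOE_EFFECT = {
    "CCL26": 12.0,
    "CPA3": 3.3,
    "FCER1B": 2.5,
    "IL5": 3.3,
    "IL4": 2.8,
    "CCL2": 2.5,
    "GENE_009": 5.0,
    "GENE_010": 4.0,
    "GENE_011": 3.0,
    "GENE_012": 6.0,
}

#: EoE+FI vs EoE-no-FI fold factors (all in [0.3, 0.5]): mast-cell/Th2 and
#: motility transcripts down, depths graded to the per-transcript
#: significance tiers the study reports.
DEFAULT_FI_EFFECT = {
    "CPA3": 0.3,
    "FCER1B": 0.4,
    "CCL2": 0.4,
    "IL4": 0.35,
    "IL5": 0.3,
    "NOS2": 0.45,
    "HIF1A": 0.4,
}

#: trait prevalences per group, patterned on the study's cohort table
DEFAULT_PREVALENCES = {
    "EoE_FI": {
        "male": 13 / 14,
        "dysphagia": 1.0,
        "food_impaction": 1.0,
        "chest_pain": 3 / 14,
        "epigastric_pain": 4 / 14,
        "reflux": 4 / 14,
        "feeding_difficulties": 0.0,
        "vomiting": 2 / 14,
        "pallor": 3 / 14,
        "edema": 1 / 14,
        "loss_of_vascularity": 7 / 14,
        "furrowing": 11 / 14,
        "exudate": 6 / 14,
        "eczema": 5 / 14,
        "asthma": 8 / 14,
        "rhinoconjunctivitis": 7 / 14,
        "food_allergy": 4 / 14,
        "rast_positive": 11 / 14,
    },
    "EoE_no_FI": {
        "male": 8 / 13,
        "dysphagia": 9 / 13,
        "food_impaction": 0.0,
        "chest_pain": 0.0,
        "epigastric_pain": 6 / 13,
        "reflux": 6 / 13,
        "feeding_difficulties": 0.0,
        "vomiting": 4 / 13,
        "pallor": 1 / 13,
        "edema": 0.0,
        "loss_of_vascularity": 2 / 13,
        "furrowing": 9 / 13,
        "exudate": 5 / 13,
        "eczema": 3 / 13,
        "asthma": 5 / 13,
        "rhinoconjunctivitis": 9 / 13,
        "food_allergy": 3 / 13,
        "rast_positive": 8 / 13,
    },
    "Control": {
        "male": 6 / 18,
        "dysphagia": 5 / 18,
        "food_impaction": 0.0,
        "chest_pain": 2 / 18,
        "epigastric_pain": 9 / 18,
        "reflux": 11 / 18,
        "feeding_difficulties": 0.0,
        "vomiting": 2 / 18,
        "pallor": 1 / 18,
        "edema": 0.0,
        "loss_of_vascularity": 0.0,
        "furrowing": 3 / 18,
        "exudate": 0.0,
        "eczema": 1 / 18,
        "asthma": 1 / 18,
        "rhinoconjunctivitis": 4 / 18,
        "food_allergy": 0.0,
        "rast_positive": 0.0,
    },
}


def default_panel() -> ProbeAnnotation:
    """The default stand-in panel: 74 endogenous genes (the study's named
    transcripts plus stable placeholders), 5 housekeeping genes, 6 positive
    spike-ins on a 4-fold concentration ladder, and 8 negative controls."""
    rows = []
    endog = list(NAMED_GENES) + [
        f"GENE_{i:03d}" for i in range(9, 9 + 74 - len(NAMED_GENES))
    ]
    def acc(name: str) -> str:
        return f"NM_{zlib.crc32(name.encode()) % 10**6:06d}"

    for name in endog:
        rows.append((name, "Endogenous", acc(name), np.nan))
    for name in ("ACTB", "GAPDH", "RPL19", "TBP", "HPRT1"):
        rows.append((name, "Housekeeping", acc(name), np.nan))
    conc = 128.0
    for letter in "ABCDEF":
        rows.append((f"POS_{letter}({conc:g})", "Positive", "ERCC_SPIKE", conc))
        conc /= 4.0
    for letter in "ABCDEFGH":
        rows.append((f"NEG_{letter}(0)", "Negative", "ERCC_SPIKE", np.nan))
    table = pd.DataFrame(rows, columns=["name", "code_class", "accession", "concentration"])
    return ProbeAnnotation(table)


@dataclass
class SimulationConfig:
    """Generator settings; the defaults reproduce the study conditions
    (group sizes 18/13/14, planted effects above)."""

    n_control: int = 18
    n_eoe_nofi: int = 13
    n_eoe_fi: int = 14
    panel: ProbeAnnotation = field(default_factory=default_panel)
    baseline_mean: float = 1.0  # global multiplier on per-gene baselines
    dispersion: float = 10.0  # negative-binomial size parameter
    eoe_effect: dict = field(default_factory=lambda: dict(DEFAULT_EOE_EFFECT))
    fi_effect: dict = field(default_factory=lambda: dict(DEFAULT_FI_EFFECT))
    lane_scale_sd: float = 0.2  # sigma of the log-normal per-lane factor
    background_mean: float = 10.0  # Poisson lambda of negative controls
    pos_counts_per_fm: float = 150.0  # spike-in response (counts per fM)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_control, self.n_eoe_nofi, self.n_eoe_fi) < 2:
            raise ConfigurationError("all group sizes must be >= 2")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.baseline_mean <= 0 or self.background_mean <= 0:
            raise ConfigurationError("means must be > 0")
        if self.lane_scale_sd < 0:
            raise ConfigurationError("lane_scale_sd must be >= 0")
        measured = set(self.panel.endogenous) | set(self.panel.housekeeping)
        for effect in (self.eoe_effect, self.fi_effect):
            for gene, fold in effect.items():
                if fold <= 0:
                    raise ConfigurationError(f"fold for {gene} must be > 0")
                if gene not in measured:
                    raise ConfigurationError(f"effect gene {gene} not in panel")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    labels: pd.Series  # sample id -> group
    fold_maps: dict  # contrast -> {gene: fold}
    lane_scales: pd.Series  # lane id -> technical factor
    gene_baselines: pd.Series  # gene -> baseline mean count
    signal_means: pd.DataFrame  # lane x gene expected count (incl. background)


def _gene_baselines(panel: ProbeAnnotation, seed: int) -> pd.Series:
    """Log-uniform baselines over [50, 5000], drawn once per panel+seed."""
    genes = panel.endogenous + panel.housekeeping
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBA5E]))
    vals = np.exp(rng.uniform(np.log(50.0), np.log(5000.0), size=len(genes)))
    return pd.Series(vals, index=genes)


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    ids, labels = [], []
    for group, n, tag in (
        ("Control", config.n_control, "CTRL"),
        ("EoE_no_FI", config.n_eoe_nofi, "NOFI"),
        ("EoE_FI", config.n_eoe_fi, "FI"),
    ):
        for i in range(1, n + 1):
            ids.append(f"{tag}_{i:02d}")
            labels.append(group)
    return ids, labels


def simulate_counts(config: SimulationConfig) -> tuple[RawCountSet, GroundTruth]:
    """Draw one raw count set plus the ground truth behind it.

    Endogenous and housekeeping counts are negative binomial around
    ``baseline_mean x gene baseline x group fold x lane scale`` plus a
    Poisson background; positives are Poisson around ``concentration x
    response x lane scale``; negatives are Poisson background. Identical
    seeds give identical output.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0DE]))
    panel = config.panel
    ids, labels = _sample_ids(config)
    n = len(ids)

    baselines = _gene_baselines(panel, config.seed)
    lane_scales = pd.Series(
        np.exp(rng.normal(0.0, config.lane_scale_sd, size=n)), index=ids
    )

    genes = panel.endogenous + panel.housekeeping
    fold = pd.DataFrame(1.0, index=GROUPS, columns=genes)
    for gene, f in config.eoe_effect.items():
        fold.loc["EoE_no_FI", gene] *= f
        fold.loc["EoE_FI", gene] *= f
    for gene, f in config.fi_effect.items():
        fold.loc["EoE_FI", gene] *= f

    signal = (
        config.baseline_mean
        * baselines.to_numpy()[None, :]
        * fold.loc[labels, :].to_numpy()
        * lane_scales.to_numpy()[:, None]
    )
    size = config.dispersion
    p_nb = size / (size + signal)
    measured = rng.negative_binomial(size, p_nb) + rng.poisson(
        config.background_mean, size=signal.shape
    )

    counts = pd.DataFrame(0, index=ids, columns=[r for r in panel.table["name"]])
    counts.loc[:, genes] = measured
    conc = panel.positive_concentrations()
    pos_mean = (
        config.pos_counts_per_fm
        * conc.to_numpy()[None, :]
        * lane_scales.to_numpy()[:, None]
    )
    counts.loc[:, panel.positives] = rng.poisson(pos_mean)
    counts.loc[:, panel.negatives] = rng.poisson(
        config.background_mean, size=(n, len(panel.negatives))
    )

    truth = GroundTruth(
        labels=pd.Series(labels, index=ids, name="group"),
        fold_maps={
            "fi_vs_nofi": dict(config.fi_effect),
            "nofi_vs_control": dict(config.eoe_effect),
            "fi_vs_control": {
                g: config.eoe_effect.get(g, 1.0) * config.fi_effect.get(g, 1.0)
                for g in set(config.eoe_effect) | set(config.fi_effect)
            },
        },
        lane_scales=lane_scales,
        gene_baselines=baselines,
        signal_means=pd.DataFrame(
            signal + config.background_mean, index=ids, columns=genes
        ),
    )
    raw = RawCountSet(counts=counts, annotation=panel)
    return raw, truth


def simulate_metadata(
    config: SimulationConfig,
    prevalences: dict | None = None,
) -> ClinicalTable:
    """Clinical metadata matching :func:`simulate_counts` sample ids.

    Binary traits are independent Bernoulli draws at the per-group
    prevalences (defaults emulate the study cohort); numeric traits get
    plausible group-typical values (controls have zero tissue eosinophilia).
    """
    config.validate()
    prevalences = prevalences if prevalences is not None else DEFAULT_PREVALENCES
    for group, traits in prevalences.items():
        if group not in GROUPS:
            raise ConfigurationError(f"unknown group key: {group}")
        for trait, p in traits.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence {trait}={p} outside [0,1]")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x3E7A]))
    ids, labels = _sample_ids(config)
    rows = {}
    for field_name in BINARY_CLINICAL_FIELDS:
        col = []
        for lab in labels:
            p = prevalences.get(lab, {}).get(field_name)
            if p is None:
                col.append(pd.NA)
            else:
                col.append("yes" if rng.random() < p else "no")
        rows[field_name] = col

    is_eoe = np.array([lab != "Control" for lab in labels])
    age = rng.uniform(9.0, 18.0, size=len(ids))
    rows["age_years"] = np.round(age, 2)
    rows["serum_ige"] = np.round(np.exp(rng.normal(np.log(120.0), 0.8, len(ids))), 1)
    eos_prox = np.where(is_eoe, rng.integers(0, 111, len(ids)), 0)
    eos_dist = np.where(is_eoe, rng.integers(15, 151, len(ids)), 0)
    rows["eos_proximal"] = eos_prox
    rows["eos_distal"] = eos_dist
    rows["eos_max"] = np.maximum(eos_prox, eos_dist)

    table = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))
    table.insert(0, "group", labels)
    return ClinicalTable(table)
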