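"""Core in-memory containers.

The panel annotation, raw lane counts and clinical metadata are thin
dataclasses around pandas objects, validated on construction. Group labels
use the closed vocabulary ``Control`` / ``EoE_no_FI`` / ``EoE_FI``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

CODE_CLASSES = ("Endogenous", "Housekeeping", "Positive", "Negative")

GROUPS = ("Control", "EoE_no_FI", "EoE_FI")
EOE_GROUPS = ("EoE_no_FI", "EoE_FI")

#: tri-state yes/no/missing clinical fields (missing = empty string on disk)
BINARY_CLINICAL_FIELDS = (
    "male",
    "dysphagia",
    "food_impaction",
    "chest_pain",
    "epigastric_pain",
    "reflux",
    "feeding_difficulties",
    "vomiting",
    "pallor",
    "edema",
    "loss_of_vascularity",
    "furrowing",
    "exudate",
    "eczema",
    "asthma",
    "rhinoconjunctivitis",
    "food_allergy",
    "rast_positive",
)

NUMERIC_CLINICAL_FIELDS = (
    "age_years",
    "serum_ige",
    "eos_proximal",
    "eos_distal",
    "eos_max",
)


@dataclass
class ProbeAnnotation:
    """Probe panel: name, code class, accession, spike concentration (fM).

    Concentrations are required for Positive probes (the spike-in ladder)
    and NaN elsewhere.
    """

    table: pd.DataFrame  # columns: name, code_class, accession, concentration

    def __post_init__(self) -> None:
        required = {"name", "code_class", "accession", "concentration"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        if self.table["name"].duplicated().any():
            dupes = self.table.loc[self.table["name"].duplicated(), "name"]
            raise FormatError(f"duplicate probe names: {sorted(set(dupes))}")
        bad = set(self.table["code_class"]) - set(CODE_CLASSES)
        if bad:
            raise FormatError(f"unknown code classes: {sorted(bad)}")
        pos = self.table[self.table["code_class"] == "Positive"]
        if pos["concentration"].isna().any():
            raise FormatError("every Positive probe needs a spike concentration")
        self.table = self.table.reset_index(drop=True)

    def names(self, code_class: str) -> list[str]:
        sub = self.table[self.table["code_class"] == code_class]
        return list(sub["name"])

    @property
    def endogenous(self) -> list[str]:
        return self.names("Endogenous")

    @property
    def housekeeping(self) -> list[str]:
        return self.names("Housekeeping")

    @property
    def positives(self) -> list[str]:
        return self.names("Positive")

    @property
    def negatives(self) -> list[str]:
        return self.names("Negative")

    def positive_concentrations(self) -> pd.Series:
        pos = self.table[self.table["code_class"] == "Positive"]
        return pos.set_index("name")["concentration"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class RawCountSet:
    """Lanes x probes integer counts plus the panel annotation."""

    counts: pd.DataFrame  # index = lane ids, columns = probe names
    annotation: ProbeAnnotation
    lane_attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ann_names = list(self.annotation.table["name"])
        if list(self.counts.columns) != ann_names:
            extra = set(self.counts.columns) - set(ann_names)
            if extra:
                raise FormatError(
                    f"probes absent from annotation: {sorted(extra)}"
                )
            self.counts = self.counts.reindex(columns=ann_names)
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("counts must be nonnegative")
        if self.counts.index.duplicated().any():
            raise FormatError("duplicate lane ids")

    @property
    def lane_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset(self, code_class: str) -> pd.DataFrame:
        return self.counts[self.annotation.names(code_class)]

    def concat(self, other: "RawCountSet") -> "RawCountSet":
        if list(other.counts.columns) != list(self.counts.columns):
            raise FormatError("cannot concatenate: probe sets differ")
        return RawCountSet(
            counts=pd.concat([self.counts, other.counts]),
            annotation=self.annotation,
            lane_attributes={**self.lane_attributes, **other.lane_attributes},
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical metadata.

    ``group`` is from the closed set; tri-state clinical fields hold
    "yes"/"no"/NA; numeric fields hold floats with NaN for missing.
    """

    table: pd.DataFrame  # index = sample ids

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise FormatError("duplicate sample ids")
        if "group" not in self.table.columns:
            raise FormatError("metadata needs a 'group' column")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        for col in NUMERIC_CLINICAL_FIELDS:
            if col in self.table.columns:
                vals = pd.to_numeric(self.table[col], errors="coerce")
                if col.startswith("eos") and (vals.dropna() < 0).any():
                    raise FormatError(f"{col} must be >= 0")
                self.table[col] = vals

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def samples_in(self, *groups: str) -> list[str]:
        return list(self.table.index[self.table["group"].isin(groups)])
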