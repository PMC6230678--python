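"""Readers and writers.

Supported formats:

* RCC-dialect lane files — comma-separated sections bracketed by
  ``<Tag>`` / ``</Tag>``; ``Header``, ``Lane_Attributes`` and
  ``Code_Summary`` are required, any other section is preserved verbatim as
  an opaque lane attribute. ``Code_Summary`` rows are
  ``CodeClass,Name,Accession,Count`` with strictly integral counts.
* TSV/CSV count matrices (probes x lanes) with a separate probe annotation.
* Clinical metadata TSV (missing values as empty strings — distinct from
  an explicit "no").
* A versioned JSON + TSV result report.
"""

from __future__ import annotations

import json
import re
from datetime import datetime, timezone
from pathlib import Path
from warnings import warn

import numpy as np
import pandas as pd

from .containers import (
    BINARY_CLINICAL_FIELDS,
    ClinicalTable,
    ProbeAnnotation,
    RawCountSet,
)
from .errors import FormatError

REPORT_SCHEMA_VERSION = "1.0"

_INT_RE = re.compile(r"^[0-9]+$")
_POS_CONC_RE = re.compile(r"\(([\d.eE+-]+)\)$")


# ---------------------------------------------------------------------------
# RCC lane files
# ---------------------------------------------------------------------------

def _split_sections(lines: list[str]) -> dict[str, list[tuple[int, str]]]:
    sections: dict[str, list[tuple[int, str]]] = {}
    current = None
    for lineno, line in enumerate(lines, start=1):
        text = line.rstrip("\n")
        if not text.strip():
            continue
        m = re.fullmatch(r"<(/?)([A-Za-z_]+)>", text.strip())
        if m:
            closing, tag = m.group(1), m.group(2)
            if closing:
                current = None
            else:
                current = tag
                sections.setdefault(tag, [])
            continue
        if current is not None:
            sections[current].append((lineno, text))
    return sections


def read_rcc(path: str | Path) -> RawCountSet:
    """Parse one RCC-dialect lane file into a single-lane count set."""
    path = Path(path)
    lines = path.read_text().splitlines()
    sections = _split_sections(lines)
    for required in ("Header", "Lane_Attributes", "Code_Summary"):
        if required not in sections:
            raise FormatError(f"{path.name}: missing <{required}> section")

    attrs = {}
    for _, text in sections["Header"] + sections["Lane_Attributes"]:
        key, _, value = text.partition(",")
        attrs[key] = value
    lane_id = attrs.get("ID")
    if not lane_id:
        raise FormatError(f"{path.name}: Lane_Attributes has no ID")

    names, classes, accessions, concs, counts = [], [], [], [], []
    for lineno, text in sections["Code_Summary"]:
        fields = text.split(",")
        if fields[0] == "CodeClass":  # column header row
            continue
        if len(fields) != 4:
            raise FormatError(
                f"{path.name}:{lineno}: expected CodeClass,Name,Accession,Count"
            )
        code_class, name, accession, count = fields
        if not _INT_RE.fullmatch(count.strip()):
            raise FormatError(
                f"{path.name}:{lineno}: non-integer count {count!r}"
            )
        conc = np.nan
        if code_class == "Positive":
            m = _POS_CONC_RE.search(name)
            if not m:
                raise FormatError(
                    f"{path.name}:{lineno}: Positive probe {name!r} lacks a "
                    "(concentration) suffix"
                )
            conc = float(m.group(1))
        names.append(name)
        classes.append(code_class)
        accessions.append(accession)
        concs.append(conc)
        counts.append(int(count))

    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "name": names,
                "code_class": classes,
                "accession": accessions,
                "concentration": concs,
            }
        )
    )
    matrix = pd.DataFrame([counts], index=[lane_id], columns=names)
    extra = {
        tag: [t for _, t in rows]
        for tag, rows in sections.items()
        if tag not in ("Header", "Lane_Attributes", "Code_Summary")
    }
    return RawCountSet(
        counts=matrix,
        annotation=annotation,
        lane_attributes={lane_id: {**attrs, **extra}},
    )


def write_rcc(raw: RawCountSet, out_dir: str | Path) -> list[Path]:
    """Write one RCC-dialect file per lane; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ann = raw.annotation.table
    paths = []
    for lane_id in raw.lane_ids:
        lines = [
            "<Header>",
            "FileVersion,1.7",
            "SoftwareVersion,fiscope",
            "</Header>",
            "<Lane_Attributes>",
            f"ID,{lane_id}",
            "</Lane_Attributes>",
            "<Code_Summary>",
            "CodeClass,Name,Accession,Count",
        ]
        for _, row in ann.iterrows():
            count = int(raw.counts.at[lane_id, row["name"]])
            lines.append(
                f"{row['code_class']},{row['name']},{row['accession']},{count}"
            )
        lines.append("</Code_Summary>")
        path = out_dir / f"{lane_id}.rcc"
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths


def read_rcc_dir(directory: str | Path) -> RawCountSet:
    """Read every ``*.rcc`` file in a directory into one multi-lane set."""
    paths = sorted(Path(directory).glob("*.rcc"))
    if not paths:
        raise FormatError(f"no .rcc files in {directory}")
    combined = read_rcc(paths[0])
    for path in paths[1:]:
        combined = combined.concat(read_rcc(path))
    return combined


# ---------------------------------------------------------------------------
# Matrices and annotations
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_annotation(path: str | Path) -> ProbeAnnotation:
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path))
    if "concentration" not in table.columns:
        table["concentration"] = np.nan
    if "accession" not in table.columns:
        table["accession"] = ""
    return ProbeAnnotation(table[["name", "code_class", "accession", "concentration"]])


def write_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    path = Path(path)
    annotation.table.to_csv(path, sep=_sep_for(path), index=False)


def read_count_matrix(path: str | Path, annotation_path: str | Path) -> RawCountSet:
    """Read a probes x lanes matrix and match probes to an annotation.

    Probes present in the matrix but absent from the annotation are an
    error (listed by name); annotations with no Positive/Negative probes
    parse with a QC warning since control-based normalization stages then
    have nothing to work with.
    """
    path = Path(path)
    annotation = read_annotation(annotation_path)
    matrix = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if matrix.index.duplicated().any():
        dupes = sorted(set(matrix.index[matrix.index.duplicated()]))
        raise FormatError(f"duplicated probe rows: {dupes}")
    known = set(annotation.table["name"])
    unmatched = [p for p in matrix.index if p not in known]
    if unmatched:
        raise FormatError(f"probes absent from annotation: {unmatched}")
    present = [p for p in annotation.table["name"] if p in set(matrix.index)]
    annotation = ProbeAnnotation(
        annotation.table[annotation.table["name"].isin(present)].reset_index(drop=True)
    )
    if not annotation.positives or not annotation.negatives:
        warn("matrix has no Positive/Negative control probes; control-based "
             "normalization stages will be unavailable", stacklevel=2)
    counts = matrix.loc[present].T
    counts.index.name = None
    counts.columns.name = None
    return RawCountSet(counts=counts, annotation=annotation)


def write_count_matrix(raw: RawCountSet, path: str | Path) -> None:
    path = Path(path)
    raw.counts.T.to_csv(path, sep=_sep_for(path), index_label="probe")


# ---------------------------------------------------------------------------
# Clinical metadata
# ---------------------------------------------------------------------------

def read_clinical(path: str | Path) -> ClinicalTable:
    path = Path(path)
    table = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, dtype=str, keep_default_na=False
    )
    for col in BINARY_CLINICAL_FIELDS:
        if col in table.columns:
            vals = table[col].replace("", pd.NA)
            bad = set(vals.dropna()) - {"yes", "no"}
            if bad:
                raise FormatError(f"column {col}: values must be yes/no/empty, got {sorted(bad)}")
            table[col] = vals
    for col in table.columns:
        if col not in BINARY_CLINICAL_FIELDS and col != "group":
            raw = table[col].replace("", np.nan)
            converted = pd.to_numeric(raw, errors="coerce")
            # keep the text column if conversion would destroy real values
            table[col] = raw if (converted.isna() & raw.notna()).any() else converted
    return ClinicalTable(table)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    path = Path(path)
    out = clinical.table.copy()
    out.to_csv(path, sep=_sep_for(path), index_label="sample_id", na_rep="")


# ---------------------------------------------------------------------------
# Result report
# ---------------------------------------------------------------------------

def write_report(results: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write a machine-readable report.

    ``results`` may hold any of: ``normalized`` (NormalizedMatrix), ``de``
    (DEResult), ``weights`` (TranscriptWeights), ``scores`` (FIScoreResult),
    ``roc`` (ROCResult), ``decisions`` (DataFrame). JSON carries scores,
    weights, metrics and decisions; wide tables go to TSV side files.
    Re-running on identical inputs reproduces identical output apart from
    the timestamp field.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    payload: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "generated": datetime.now(timezone.utc).isoformat(),
    }

    if (norm := results.get("normalized")) is not None:
        p = out_dir / "normalized.tsv"
        norm.values.to_csv(p, sep="\t", index_label="sample_id")
        written["normalized"] = p
        payload["normalization"] = {
            "positive_factors": _series_map(norm.positive_factors),
            "housekeeping_factors": _series_map(norm.housekeeping_factors),
            "background": _series_map(norm.background),
            "qc_flags": {k: sorted(v) for k, v in norm.qc_flags.items() if v},
        }
    if (de := results.get("de")) is not None:
        p = out_dir / "de.tsv"
        de.table.to_csv(p, sep="\t", index_label="gene")
        written["de"] = p
        payload["de"] = {"n_genes": int(len(de.table)), "contrasts": list(de.contrasts)}
    if (weights := results.get("weights")) is not None:
        payload["weights"] = {
            "alpha": weights.alpha,
            "normalization_constant": weights.normalization_constant,
            "values": _series_map(weights.weights[weights.weights != 0.0]),
        }
    if (scores := results.get("scores")) is not None:
        p = out_dir / "scores.tsv"
        frame = pd.DataFrame(
            {
                "raw_score": scores.raw,
                "fi_score": scores.standardized,
                "fi_call": scores.calls.map({True: "FI-positive", False: "FI-negative"}),
            }
        )
        frame.to_csv(p, sep="\t", index_label="sample_id")
        written["scores"] = p
        payload["scores"] = {
            "cutoff": scores.cutoff,
            "cohort_mean": scores.cohort_mean,
            "cohort_sd": scores.cohort_sd,
            "fi_score": _series_map(scores.standardized),
            "calls": {k: bool(v) for k, v in scores.calls.items()},
        }
    if (roc := results.get("roc")) is not None:
        payload["roc"] = {
            "auc": roc.auc,
            "se": roc.se,
            "cutoff": roc.cutoff,
            "sensitivity": _none_if_nan(roc.sensitivity),
            "specificity": _none_if_nan(roc.specificity),
            "ppv": _none_if_nan(roc.ppv),
            "npv": _none_if_nan(roc.npv),
            "n_pos": roc.n_pos,
            "n_neg": roc.n_neg,
        }
    if (decisions := results.get("decisions")) is not None:
        p = out_dir / "decisions.tsv"
        decisions.to_csv(p, sep="\t", index_label="sample_id")
        written["decisions"] = p
        payload["decisions"] = json.loads(decisions.to_json(orient="index"))

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    written["report"] = report_path
    return written


def _series_map(s: pd.Series) -> dict:
    return {str(k): (None if pd.isna(v) else float(v)) for k, v in s.items()}


def _none_if_nan(x: float) -> float | None:
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)
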