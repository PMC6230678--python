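"""Exact 2x2 statistics and the cohort characteristics table.

Binary traits are compared pairwise between groups with the two-sided
Fisher exact test under the probability-mass definition (the p-value sums
the hypergeometric mass of every table, at fixed margins, no more probable
than the observed one). Numeric traits get medians with ranges and
Kruskal-Wallis / Dunn p-values. Missing values are excluded per trait, so
denominators can differ across traits within a group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from warnings import warn

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .containers import (
    BINARY_CLINICAL_FIELDS,
    NUMERIC_CLINICAL_FIELDS,
    ClinicalTable,
)
from .de import dunns_test, kruskal_wallis
from .errors import DomainError


@dataclass
class ContingencyTable2x2:
    """Rows = groups, columns = trait present / absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise DomainError("table entries must be nonnegative integers")
        if sum(cells) == 0:
            raise DomainError("table must have at least one nonzero margin")
        self.a, self.b, self.c, self.d = (int(x) for x in cells)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_two_sided(table: ContingencyTable2x2 | list | np.ndarray) -> float:
    """Two-sided Fisher exact p (probability-mass definition).

    A zero row or column margin admits only one table, so p = 1.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = np.asarray(table)
        table = ContingencyTable2x2(a, b, c, d)
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    p = float(fisher_exact(arr, alternative="two-sided")[1])
    return min(1.0, p)


@dataclass
class CohortSummary:
    """Tidy cohort table: per-group trait summaries plus pairwise tests."""

    binary: pd.DataFrame  # trait, group, n_pos, n_total, pct
    numeric: pd.DataFrame  # trait, group, median, min, max, n
    tests: pd.DataFrame  # trait, kind, group_a, group_b, p

    def format(self) -> pd.DataFrame:
        """One row per trait, Table-1 style: 'n/N (pct%)' per group and a
        p-value column per group pair (percentages rounded half-up)."""
        groups = list(dict.fromkeys(self.binary["group"]))
        rows = {}
        for trait, sub in self.binary.groupby("trait", sort=False):
            row = {}
            for g in groups:
                cell = sub[sub["group"] == g]
                if cell.empty or cell["n_total"].iloc[0] == 0:
                    row[g] = "missing"
                else:
                    n, total = int(cell["n_pos"].iloc[0]), int(cell["n_total"].iloc[0])
                    pct = int(np.floor(100.0 * n / total + 0.5))
                    row[g] = f"{n}/{total} ({pct}%)"
            rows[trait] = row
        formatted = pd.DataFrame.from_dict(rows, orient="index")
        for (ga, gb), sub in self.tests[self.tests["kind"] == "fisher"].groupby(
            ["group_a", "group_b"]
        ):
            formatted[f"p {ga} vs {gb}"] = sub.set_index("trait")["p"].round(3)
        return formatted


def cohort_table(
    meta: ClinicalTable,
    groups: list[str] | None = None,
    binary_traits: list[str] | None = None,
    numeric_traits: list[str] | None = None,
) -> CohortSummary:
    """Summaries and exact pairwise statistics of clinical traits.

    Traits absent from the metadata are skipped with a warning. A trait
    whose per-group denominator is 0 (all missing) is reported as missing.
    """
    table = meta.table
    groups = groups or [g for g in ("EoE_FI", "EoE_no_FI", "Control")
                        if (table["group"] == g).any()]
    present = [g for g in groups if (table["group"] == g).any()]
    if len(present) < 2:
        raise DomainError("cohort_table needs >= 2 groups present")
    binary_traits = binary_traits or [
        t for t in BINARY_CLINICAL_FIELDS if t in table.columns
    ]
    numeric_traits = numeric_traits or [
        t for t in NUMERIC_CLINICAL_FIELDS if t in table.columns
    ]
    for requested in (binary_traits, numeric_traits):
        for t in list(requested):
            if t not in table.columns:
                warn(f"trait {t!r} absent from metadata; skipped", stacklevel=2)
                requested.remove(t)

    bin_rows, num_rows, test_rows = [], [], []
    for trait in binary_traits:
        per_group = {}
        for g in present:
            vals = table.loc[table["group"] == g, trait].dropna()
            per_group[g] = (int((vals == "yes").sum()), int(len(vals)))
            bin_rows.append(
                {
                    "trait": trait,
                    "group": g,
                    "n_pos": per_group[g][0],
                    "n_total": per_group[g][1],
                    "pct": (
                        100.0 * per_group[g][0] / per_group[g][1]
                        if per_group[g][1]
                        else np.nan
                    ),
                }
            )
        for ga, gb in combinations(present, 2):
            (pa, na), (pb, nb) = per_group[ga], per_group[gb]
            if na == 0 or nb == 0:
                p = np.nan
            else:
                p = fisher_exact_two_sided(
                    ContingencyTable2x2(pa, na - pa, pb, nb - pb)
                )
            test_rows.append(
                {"trait": trait, "kind": "fisher", "group_a": ga, "group_b": gb, "p": p}
            )

    for trait in numeric_traits:
        grouped = {
            g: table.loc[table["group"] == g, trait].dropna().to_numpy(dtype=float)
            for g in present
        }
        for g in present:
            vals = grouped[g]
            num_rows.append(
                {
                    "trait": trait,
                    "group": g,
                    "median": float(np.median(vals)) if vals.size else np.nan,
                    "min": float(vals.min()) if vals.size else np.nan,
                    "max": float(vals.max()) if vals.size else np.nan,
                    "n": int(vals.size),
                }
            )
        usable = [g for g in present if grouped[g].size > 0]
        if len(usable) >= 2 and sum(grouped[g].size for g in usable) >= 3:
            arrays = [grouped[g] for g in usable]
            _, p_kw = kruskal_wallis(*arrays)
            test_rows.append(
                {"trait": trait, "kind": "kruskal", "group_a": "all",
                 "group_b": "all", "p": p_kw}
            )
            if len(usable) >= 2:
                dunn = dunns_test(arrays)
                for (i, j), (_, p_adj) in dunn.items():
                    test_rows.append(
                        {"trait": trait, "kind": "dunn",
                         "group_a": usable[i], "group_b": usable[j], "p": p_adj}
                    )

    return CohortSummary(
        binary=pd.DataFrame(bin_rows),
        numeric=pd.DataFrame(num_rows),
        tests=pd.DataFrame(test_rows),
    )
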