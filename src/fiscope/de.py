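"""Rank-based three-group differential expression.

Per gene: a tie-corrected Kruskal-Wallis test across Control / EoE-no-FI /
EoE-FI, Dunn's post-hoc z for each pairwise contrast (Bonferroni across the
three pairs by default, Holm optional), a median-based log2 fold difference
per contrast, and a Benjamini-Hochberg q across genes for the FI vs no-FI
contrast — the quantity the transcript weights are built from. All rank
statistics use midranks, so they are invariant under any strictly monotone
transform of the expression values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .normalize import NormalizedMatrix

CONTRASTS = (
    ("fi_vs_nofi", "EoE_FI", "EoE_no_FI"),
    ("fi_vs_control", "EoE_FI", "Control"),
    ("nofi_vs_control", "EoE_no_FI", "Control"),
)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Degenerate input (every observation identical) returns H = 0, p = 1:
    the tie correction removes all rank variation.
    """
    if len(groups) < 2:
        raise DomainError("kruskal_wallis needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise DomainError("kruskal_wallis groups must be nonempty")
    if sum(a.size for a in arrays) < 3:
        raise DomainError("kruskal_wallis needs total N >= 3")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def dunns_test(groups, adjust: str = "bonferroni") -> dict:
    """Dunn's post-hoc rank comparison for every pair of groups.

    Returns ``{(i, j): (z, p_adjusted)}`` keyed by group indices, with
    z = (mean rank i - mean rank j) / SE, the SE carrying the usual tie
    correction, two-sided normal p, adjusted across the k(k-1)/2 pairs.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise DomainError("dunns_test needs >= 2 nonempty groups")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    if n_total < 3:
        raise DomainError("dunns_test needs total N >= 3")
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(float(np.mean(ranks[start : start + a.size])))
        start += a.size
    if np.all(pooled == pooled[0]):
        var_core = 0.0
    else:
        var_core = n_total * (n_total + 1) / 12.0 - _tie_term(pooled) / (
            12.0 * (n_total - 1)
        )

    pairs = list(combinations(range(len(arrays)), 2))
    zs, ps = {}, []
    for i, j in pairs:
        se = np.sqrt(var_core * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        if se == 0.0:
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
        zs[(i, j)] = z
        ps.append(2.0 * stats.norm.sf(abs(z)))

    m = len(pairs)
    if adjust == "bonferroni":
        p_adj = [min(1.0, p * m) for p in ps]
    elif adjust == "holm":
        p_adj = list(multipletests(ps, method="holm")[1])
    elif adjust in ("none", None):
        p_adj = ps
    else:
        raise DomainError(f"unknown adjustment {adjust!r}")
    return {pair: (zs[pair], p_adj[k]) for k, pair in enumerate(pairs)}


def fold_difference(values_a, values_b, pseudocount: float = 1.0) -> float:
    """log2((median_a + c) / (median_b + c)) on the normalized scale."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("fold_difference groups must be nonempty")
    return float(
        np.log2((np.median(a) + pseudocount) / (np.median(b) + pseudocount))
    )


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    if method != "bh":
        raise DomainError(f"unknown method {method!r}")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-gene test table; also carries the volcano-plot quantities
    (log2 fold difference vs -log10 q for the FI vs no-FI contrast)."""

    table: pd.DataFrame
    contrasts: tuple = tuple(name for name, _, _ in CONTRASTS)

    def volcano(self, contrast: str = "fi_vs_nofi") -> pd.DataFrame:
        q = self.table["q_fi_vs_nofi"] if contrast == "fi_vs_nofi" else (
            self.table[f"p_dunn_{contrast}"]
        )
        return pd.DataFrame(
            {
                "log2_fold_difference": self.table[f"log2fd_{contrast}"],
                "minus_log10_q": -np.log10(q.clip(lower=1e-300)),
            }
        )


def differential_expression(
    norm: NormalizedMatrix,
    groups: pd.Series,
    dunn_adjust: str = "bonferroni",
    gene_family: str = "bh",
    pseudocount: float = 1.0,
) -> DEResult:
    """Run the full per-gene analysis on a normalized matrix.

    ``groups`` maps sample id -> group label; only groups present are
    compared. Rank tests run on log2(normalized + 1); fold differences use
    raw normalized medians. The gene-family q (default BH) is computed on
    the unadjusted Dunn p of the FI vs no-FI contrast, matching a
    one-point-per-transcript volcano.
    """
    groups = groups.reindex(norm.values.index).dropna()
    present = [g for g in ("Control", "EoE_no_FI", "EoE_FI") if (groups == g).any()]
    if len(present) < 2:
        raise DomainError("differential expression needs >= 2 groups")
    log_vals = norm.log2_values().loc[groups.index]
    raw_vals = norm.values.loc[groups.index]
    idx = {g: groups.index[groups == g] for g in present}
    pair_index = {g: k for k, g in enumerate(present)}

    rows = {}
    unadj_fi_p = {}
    for gene in norm.values.columns:
        col_log = log_vals[gene]
        col_raw = raw_vals[gene]
        grouped_log = [col_log.loc[idx[g]].to_numpy() for g in present]
        h, p_kw = kruskal_wallis(*grouped_log)
        row = {"H": h, "p_kw": p_kw}
        dunn = dunns_test(grouped_log, adjust=dunn_adjust)
        dunn_raw = dunns_test(grouped_log, adjust="none")
        for name, ga, gb in CONTRASTS:
            if ga in pair_index and gb in pair_index:
                i, j = pair_index[ga], pair_index[gb]
                key, sign = ((i, j), 1.0) if i < j else ((j, i), -1.0)
                z, p_adj = dunn[key]
                row[f"z_{name}"] = sign * z
                row[f"p_dunn_{name}"] = p_adj
                row[f"log2fd_{name}"] = fold_difference(
                    col_raw.loc[idx[ga]], col_raw.loc[idx[gb]], pseudocount
                )
                if name == "fi_vs_nofi":
                    unadj_fi_p[gene] = dunn_raw[key][1]
            else:
                row[f"z_{name}"] = np.nan
                row[f"p_dunn_{name}"] = np.nan
                row[f"log2fd_{name}"] = np.nan
        rows[gene] = row

    table = pd.DataFrame.from_dict(rows, orient="index")
    if unadj_fi_p:
        base = (
            pd.Series(unadj_fi_p)
            if gene_family == "bh"
            else table["p_dunn_fi_vs_nofi"]
        )
        if gene_family == "bh":
            table["q_fi_vs_nofi"] = adjust_pvalues(base.to_numpy())
        elif gene_family == "dunn":
            table["q_fi_vs_nofi"] = table["p_dunn_fi_vs_nofi"]
        else:
            raise DomainError(f"unknown gene_family {gene_family!r}")
    else:
        table["q_fi_vs_nofi"] = np.nan
    return DEResult(table=table)
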