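"""Background subtraction and two-stage control normalization.

Each lane is processed as: (1) subtract the lane's negative-control
background (mean, or mean + 2 SD) from endogenous and housekeeping counts,
flooring at zero; (2) scale all probes so the geometric mean of the
positive spike-ins equals the across-lane grand geometric mean; (3) scale
again so the geometric mean of the housekeeping genes equals its grand
geometric mean. The two factors absorb a multiplicative per-lane technical
effect by construction, and both are reported per lane together with QC
flags for factors outside [0.3, 3].

Zeros inside a control geometric mean are handled by adding a 0.5
pseudocount to that lane's control probes (only when a zero is present),
which keeps the geometric mean defined without perturbing typical counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .containers import ProbeAnnotation, RawCountSet
from .errors import DomainError

QC_FACTOR_WINDOW = (0.3, 3.0)
BACKGROUND_METHODS = ("mean", "mean2sd", "none")


def geometric_mean(values) -> float:
    """exp(mean(log x)) of nonnegative values; 0 if any value is 0."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("geometric mean of empty input")
    if (arr < 0).any():
        raise DomainError("geometric mean needs nonnegative values")
    if (arr == 0).all():
        raise DomainError("geometric mean of all-zero input")
    if (arr == 0).any():
        return 0.0
    return float(gmean(arr))


def _control_geomean(values) -> float:
    """Geometric mean of control counts with the zero-pseudocount policy."""
    arr = np.asarray(values, dtype=float)
    if (arr == 0).any():
        arr = arr + 0.5
    return geometric_mean(arr)


def subtract_background(
    counts, negatives, method: str = "mean"
) -> tuple[np.ndarray, float]:
    """Floor-at-zero background subtraction for one lane.

    ``method="mean"`` subtracts the mean of the negative controls;
    ``"mean2sd"`` subtracts mean + 2 x sample SD (ddof=1); ``"none"``
    subtracts nothing. Returns (adjusted counts, background estimate).
    """
    counts = np.asarray(counts, dtype=float)
    if method == "none":
        return counts.copy(), 0.0
    negatives = np.asarray(negatives, dtype=float)
    if negatives.size == 0:
        raise DomainError(f"background method {method!r} needs negative controls")
    if method == "mean":
        b = float(np.mean(negatives))
    elif method == "mean2sd":
        sd = float(np.std(negatives, ddof=1)) if negatives.size > 1 else 0.0
        b = float(np.mean(negatives)) + 2.0 * sd
    else:
        raise DomainError(f"unknown background method {method!r}")
    return np.maximum(0.0, counts - b), b


@dataclass
class NormalizedMatrix:
    """Samples x endogenous genes normalized expression with lane QC."""

    values: pd.DataFrame  # samples x endogenous genes
    positive_factors: pd.Series
    housekeeping_factors: pd.Series
    background: pd.Series
    qc_flags: dict = field(default_factory=dict)  # lane -> set of flags
    housekeeping_values: pd.DataFrame | None = None

    def log2_values(self) -> pd.DataFrame:
        """log2(normalized + 1), the scale downstream statistics use."""
        return np.log2(self.values + 1.0)


def normalize_matrix(
    counts: pd.DataFrame,
    annotation: ProbeAnnotation,
    background: str = "mean",
    use_positives: bool = True,
    use_housekeeping: bool = True,
) -> NormalizedMatrix:
    """Normalize a lanes x probes matrix (float-valued allowed).

    Lanes whose housekeeping geometric mean is zero are flagged ``invalid``
    and excluded from the output with a warning.
    """
    if background not in BACKGROUND_METHODS:
        raise DomainError(f"unknown background method {background!r}")
    endo = [g for g in annotation.endogenous if g in counts.columns]
    hk = [g for g in annotation.housekeeping if g in counts.columns]
    pos = [g for g in annotation.positives if g in counts.columns]
    neg = [g for g in annotation.negatives if g in counts.columns]
    if use_positives and not pos:
        raise DomainError("positive-control scaling requested but no Positive probes")
    if use_housekeeping and not hk:
        raise DomainError("housekeeping scaling requested but no Housekeeping probes")

    lanes = list(counts.index)
    measured = endo + hk
    adjusted = pd.DataFrame(index=lanes, columns=measured, dtype=float)
    bg = pd.Series(0.0, index=lanes)
    for lane in lanes:
        adj, b = subtract_background(
            counts.loc[lane, measured].to_numpy(),
            counts.loc[lane, neg].to_numpy() if neg else np.array([]),
            method=background,
        )
        adjusted.loc[lane, :] = adj
        bg[lane] = b

    qc: dict[str, set] = {lane: set() for lane in lanes}

    pos_factors = pd.Series(1.0, index=lanes)
    if use_positives:
        lane_geo = pd.Series(
            [_control_geomean(counts.loc[lane, pos].to_numpy()) for lane in lanes],
            index=lanes,
        )
        grand = geometric_mean(lane_geo.to_numpy())
        pos_factors = grand / lane_geo
        adjusted = adjusted.mul(pos_factors, axis=0)

    hk_factors = pd.Series(1.0, index=lanes)
    if use_housekeeping:
        invalid = []
        lane_geo = {}
        for lane in lanes:
            vals = adjusted.loc[lane, hk].to_numpy()
            if (vals == 0).all():
                invalid.append(lane)
                qc[lane].add("invalid")
                continue
            lane_geo[lane] = _control_geomean(vals)
        if invalid:
            warn(f"lanes with zero housekeeping signal excluded: {invalid}",
                 stacklevel=2)
        kept = [lane for lane in lanes if lane not in invalid]
        if not kept:
            raise DomainError("no lane has nonzero housekeeping signal")
        grand = geometric_mean(np.array([lane_geo[lane] for lane in kept]))
        for lane in kept:
            hk_factors[lane] = grand / lane_geo[lane]
        adjusted = adjusted.loc[kept].mul(hk_factors[kept], axis=0)
        lanes = kept

    for lane in lanes:
        combined_checks = []
        if use_positives:
            combined_checks.append(pos_factors[lane])
        if use_housekeeping:
            combined_checks.append(hk_factors[lane])
        if any(not (QC_FACTOR_WINDOW[0] <= f <= QC_FACTOR_WINDOW[1])
               for f in combined_checks):
            qc[lane].add("scale_factor_out_of_range")

    return NormalizedMatrix(
        values=adjusted[endo],
        positive_factors=pos_factors[lanes],
        housekeeping_factors=hk_factors[lanes],
        background=bg[lanes],
        qc_flags=qc,
        housekeeping_values=adjusted[hk] if hk else None,
    )


def normalize_lanes(
    raw: RawCountSet,
    background: str = "mean",
    use_positives: bool = True,
    use_housekeeping: bool = True,
) -> NormalizedMatrix:
    """Normalize a raw count set (see module docstring for the stages)."""
    return normalize_matrix(
        raw.counts,
        raw.annotation,
        background=background,
        use_positives=use_positives,
        use_housekeeping=use_housekeeping,
    )
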