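"""Occupancy scoring and four-way enhancer classification.

The occupancy score of an enhancer E is

    OS(E) = N_E × Σ_f Signal_E(f)

where N_E is the number of TF/cofactor factors with a peak overlapping E and
Signal_E(f) is the per-factor min–max-normalized peak signal (0 where the
factor has no peak). Enhancers are ranked by OS and everything strictly above
the ranked curve's inflection point is "high occupancy". Combined with the
classic ROSE super-enhancer regions this yields the four classes:

    aSE — high occupancy, outside every classic SE region (autonomous SE)
    dSE — high occupancy, inside a classic SE region (dual SE)
    cSE — not high occupancy, inside a classic SE region (constituent SE)
    rEh — neither (regular enhancer)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .enhancer_catalog import ActiveEnhancerSet, ClassicSeCall
from .io_core import PeakSet, overlapping_indices

__all__ = [
    "SignalMatrix",
    "OccupancyResult",
    "EnhancerClassification",
    "CLASS_LABELS",
    "build_signal_matrix",
    "occupancy_score",
    "find_inflection",
    "classify_enhancers",
]

CLASS_LABELS = ("aSE", "dSE", "cSE", "rEh")


@dataclass
class SignalMatrix:
    """Active enhancers × factors signal matrix (raw and min–max normalized).

    raw[e, f] is 0 exactly when factor f has no peak overlapping enhancer e.
    Each normalized column spans [0, 1]; a constant raw column normalizes to
    all zeros so a ubiquitously flat factor contributes no weight.
    """

    enhancer_ids: list[str]
    factor_labels: list[str]
    raw: np.ndarray
    normalized: np.ndarray


@dataclass
class OccupancyResult:
    """Per-enhancer occupancy scores and the high-occupancy call."""

    os: np.ndarray
    n_bound: np.ndarray
    rank: np.ndarray  # ascending-OS rank (0 = lowest)
    cutoff_os: float = float("nan")
    is_high_occupancy: np.ndarray | None = None


@dataclass
class EnhancerClassification:
    """Four-way aSE/dSE/cSE/rEh label per active enhancer."""

    labels: list[str]
    cutoff_os: float
    enhancer_ids: list[str]

    def class_indices(self, label: str) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == label]

    def counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in CLASS_LABELS}


def minmax_normalize(raw: np.ndarray) -> np.ndarray:
    """Column-wise min–max scaling; constant columns map to all zeros."""
    raw = np.asarray(raw, dtype=float)
    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    span = hi - lo
    out = np.zeros_like(raw)
    nz = span > 0
    out[:, nz] = (raw[:, nz] - lo[nz]) / span[nz]
    return out


def build_signal_matrix(
    enhancers: ActiveEnhancerSet,
    factor_peaks: Sequence[PeakSet],
    aggregate: Literal["max", "sum", "mean"] = "max",
) -> SignalMatrix:
    """Overlap each factor's peaks with the active enhancers.

    raw[e, f] aggregates the signalValues of factor f's peaks overlapping
    enhancer e (default: maximum, robust to peak fragmentation) and is 0
    when no peak overlaps. Columns are then min–max normalized across all
    enhancers, zeros included.
    """
    labels = [ps.label for ps in factor_peaks]
    if len(set(labels)) != len(labels):
        raise ValueError("factor labels must be unique")
    n_e = len(enhancers)
    raw = np.zeros((n_e, len(factor_peaks)), dtype=float)
    counts = np.zeros((n_e, len(factor_peaks)), dtype=int)
    enh_peaks = enhancers.enhancers
    for f, ps in enumerate(factor_peaks):
        from .io_core import overlap_pairs

        for e, j in overlap_pairs(enh_peaks, ps, window_bp=0):
            sv = ps[j].signal_value
            if aggregate == "max":
                raw[e, f] = max(raw[e, f], sv)
            else:
                raw[e, f] += sv
            counts[e, f] += 1
    if aggregate == "mean":
        np.divide(raw, counts, out=raw, where=counts > 0)
    return SignalMatrix(
        enhancer_ids=enhancers.enhancer_ids(),
        factor_labels=list(labels),
        raw=raw,
        normalized=minmax_normalize(raw),
    )


def occupancy_score(matrix: SignalMatrix) -> OccupancyResult:
    """OS(E) = N_E × Σ_f normalized signal; N_E counts raw > 0.

    An enhancer bound by zero factors scores 0. N counts raw > 0 so a factor
    whose minimum bound signal normalizes to 0 still counts as bound.
    """
    n_bound = (matrix.raw > 0).sum(axis=1)
    os_vals = n_bound * matrix.normalized.sum(axis=1)
    rank = np.empty(len(os_vals), dtype=int)
    rank[np.argsort(os_vals, kind="stable")] = np.arange(len(os_vals))
    return OccupancyResult(os=os_vals, n_bound=n_bound, rank=rank)


def find_inflection(
    values: Sequence[float],
    mode: Literal["global", "local"] = "global",
) -> tuple[float, int]:
    """Tangent/inflection cutoff on a ranked-value curve (ROSE criterion).

    Values are sorted ascending as y(0..n−1) and the reference slope is
    s* = (max − min)/n. The cutoff rank is the tangency point of a line of
    slope s* slid up against the curve from below — computed stably as the
    rank minimizing y(k) − s*·k (ties resolve to the largest rank, so a flat
    curve cuts at its maximum with nothing above). Everything strictly above
    the cutoff value lies above the elbow. When the minimizer is rank 0 the
    curve rises at least as steeply as the diagonal from the very start
    (e.g. an exactly linear curve, slope (max−min)/(n−1) > s*): there is no
    elbow and the cutoff is the maximum, leaving nothing above.

    ``mode="local"`` first finds the global cutoff g, then recomputes on the
    subset of values ≤ g with g as the new maximum in the reference slope —
    the second step of the two-step predictor cutoff.

    Returns (cutoff_value, cutoff_rank within the sorted (sub)curve).
    """
    y = np.sort(np.asarray(values, dtype=float))
    if y.size < 3:
        raise ValueError("find_inflection requires at least 3 values")

    def cutoff_on(y: np.ndarray, ref_max: float) -> tuple[float, int]:
        n = y.size
        s_star = (ref_max - y[0]) / n
        resid = y - s_star * np.arange(n)
        # largest rank attaining the minimum (within numerical slack scaled
        # to the curve so affine transforms keep the same rank)
        tol = 1e-12 * max(1.0, float(np.ptp(y)))
        k = int(np.nonzero(resid <= resid.min() + tol)[0][-1])
        if k == 0:
            k = n - 1
        return float(y[k]), k

    g_val, g_rank = cutoff_on(y, ref_max=float(y[-1]))
    if mode == "global":
        return g_val, g_rank
    sub = y[y <= g_val]
    if sub.size < 3:
        return g_val, g_rank
    return cutoff_on(sub, ref_max=g_val)


def classify_enhancers(
    occ: OccupancyResult,
    enhancers: ActiveEnhancerSet,
    classic_se: ClassicSeCall,
) -> EnhancerClassification:
    """Assign each active enhancer one of aSE/dSE/cSE/rEh.

    High occupancy is OS strictly above the inflection cutoff of the ranked
    OS curve; SE-region overlap uses plain (window 0) intersection against
    the classic ROSE SE regions.
    """
    n = len(enhancers)
    if occ.os.shape[0] != n:
        raise ValueError(
            f"occupancy result covers {occ.os.shape[0]} enhancers, set has {n}"
        )
    if np.isnan(occ.cutoff_os):
        if n >= 3:
            cutoff, _ = find_inflection(occ.os, mode="global")
        else:
            cutoff = float(occ.os.max()) if n else 0.0
        occ.cutoff_os = cutoff
        occ.is_high_occupancy = occ.os > cutoff
    high = occ.is_high_occupancy
    se_ivs = [r.interval for r in classic_se.se_regions()]
    in_se = overlapping_indices(enhancers.enhancers, se_ivs, window_bp=0)
    labels = []
    for i in range(n):
        if high[i]:
            labels.append("dSE" if i in in_se else "aSE")
        else:
            labels.append("cSE" if i in in_se else "rEh")
    return EnhancerClassification(
        labels=labels, cutoff_os=occ.cutoff_os, enhancer_ids=enhancers.enhancer_ids()
    )
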