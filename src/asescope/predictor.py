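"""Ranking-based prediction of high-occupancy enhancers from single factors.

Active enhancers are ranked by one factor's peak signal (zeros where the
factor is absent); the positive class is aSE ∪ dSE. The operating cutoff is
the two-step inflection rule: a global tangent cutoff on the ranked signal
curve, then a local cutoff recomputed on the lower portion with the global
cutoff as the new maximum. Evaluation is a tie-grouped ROC sweep with
trapezoidal AUC plus TPR/FPR at the two-step cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .occupancy import find_inflection, minmax_normalize

__all__ = [
    "PredictorInput",
    "PredictionEvaluation",
    "two_step_cutoff",
    "roc_evaluate",
    "combine_factors",
]


@dataclass
class PredictorInput:
    enhancer_ids: list[str]
    score: np.ndarray
    truth: np.ndarray  # boolean, True = aSE or dSE

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        self.truth = np.asarray(self.truth, dtype=bool)
        if self.score.shape != self.truth.shape:
            raise ValueError("score/truth length mismatch")
        if not np.all(np.isfinite(self.score)) or np.any(self.score < 0):
            raise ValueError("scores must be finite and non-negative")


@dataclass
class PredictionEvaluation:
    auc: float
    roc_points: list[tuple[float, float]]  # (fpr, tpr)
    cutoff_value: float
    tpr_at_cutoff: float
    fpr_at_cutoff: float


def two_step_cutoff(scores: Sequence[float]) -> float:
    """Global-then-local inflection cutoff on a ranked score curve.

    The global tangent cutoff g is found first; the local cutoff is the
    inflection of the sub-curve of scores ≤ g with g as the reference
    maximum. Predicted positives are scores strictly above the returned
    (local) cutoff; the local cutoff never exceeds the global one.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("two_step_cutoff requires at least 3 scores")
    if np.ptp(scores) == 0:
        return float(scores[0])
    cutoff, _ = find_inflection(scores, mode="local")
    return cutoff


def roc_evaluate(inp: PredictorInput, cutoff_value: float) -> PredictionEvaluation:
    """ROC/AUC for a score vector against the aSE∪dSE truth.

    Thresholds sweep the descending unique scores with ties grouped into one
    step (AUC therefore equals the tie-adjusted Mann–Whitney statistic
    divided by n⁺·n⁻). TPR/FPR at the supplied cutoff use strict > as the
    positive call.
    """
    pos = inp.truth
    if pos.all() or not pos.any():
        raise ValueError("roc_evaluate requires both classes present in truth")
    fpr, tpr, _ = _sk_roc_curve(pos.astype(int), inp.score, drop_intermediate=False)
    auc_val = float(_trapezoid_auc(fpr, tpr))
    called = inp.score > cutoff_value
    tp = np.count_nonzero(called & pos)
    fp = np.count_nonzero(called & ~pos)
    return PredictionEvaluation(
        auc=auc_val,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        cutoff_value=float(cutoff_value),
        tpr_at_cutoff=tp / int(pos.sum()),
        fpr_at_cutoff=fp / int((~pos).sum()),
    )


def combine_factors(
    signal_a: Sequence[float],
    signal_b: Sequence[float],
    mode: Literal["sum", "min", "product"] = "sum",
) -> np.ndarray:
    """Combine two factor signals over one enhancer universe.

    Each signal is min–max normalized (a constant vector normalizes to
    zeros) and combined by sum (default), min, or product.
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("signal vectors must have equal length")
    stacked = minmax_normalize(np.column_stack([a, b]))
    na, nb = stacked[:, 0], stacked[:, 1]
    if mode == "sum":
        return na + nb
    if mode == "min":
        return np.minimum(na, nb)
    if mode == "product":
        return na * nb
    raise ValueError(f"unknown combination mode {mode!r}")
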