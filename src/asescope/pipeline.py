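"""End-to-end convenience wrapper: one call from raw inputs to classified
enhancers, footprint stats, loop clusters and the signal-ranking predictor."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import clusters3d, footprints, predictor
from .enhancer_catalog import ActiveEnhancerSet, ClassicSeCall, call_active_enhancers, rose_classic_se
from .occupancy import (
    EnhancerClassification,
    OccupancyResult,
    SignalMatrix,
    build_signal_matrix,
    classify_enhancers,
    occupancy_score,
)
from .synthetic_data import SyntheticBundle

__all__ = ["PipelineResult", "run_pipeline", "dnase_scores"]


@dataclass
class PipelineResult:
    active: ActiveEnhancerSet
    classic_se: ClassicSeCall
    matrix: SignalMatrix
    occupancy: OccupancyResult
    classes: EnhancerClassification
    footprint_stats: list
    clusters: list
    cluster_labels: list[set[str]]
    target_genes: list[set[str]]


def dnase_scores(active: ActiveEnhancerSet, dnase_peaks) -> np.ndarray:
    """Per-active-enhancer DNase signal (max overlapping peak, 0 if none)."""
    m = build_signal_matrix(active, [dnase_peaks])
    return m.raw[:, 0]


def run_pipeline(bundle: SyntheticBundle, loop_window_bp: int = 1000) -> PipelineResult:
    """Run every stage on a synthetic bundle (or any equivalently shaped inputs)."""
    active = call_active_enhancers(bundle.dnase, bundle.h3k27ac, bundle.tss)
    classic = rose_classic_se(bundle.h3k27ac)
    matrix = build_signal_matrix(active, bundle.factors)
    occ = occupancy_score(matrix)
    classes = classify_enhancers(occ, active, classic)

    kept_fps = footprints.filter_consensus(bundle.footprints, bundle.consensus)
    fp_stats = footprints.footprint_stats(active, kept_fps)

    ann = clusters3d.annotate_loop_arms(bundle.loops, active, bundle.tss, loop_window_bp)
    clusters = clusters3d.build_clusters(bundle.loops, ann)
    targets = clusters3d.assign_target_genes(clusters, bundle.expression)
    labels = clusters3d.classify_clusters(clusters, classes)

    return PipelineResult(
        active=active,
        classic_se=classic,
        matrix=matrix,
        occupancy=occ,
        classes=classes,
        footprint_stats=fp_stats,
        clusters=clusters,
        cluster_labels=labels,
        target_genes=targets,
    )


def evaluate_dnase_predictor(
    bundle: SyntheticBundle, result: PipelineResult, factor2: str | None = None
):
    """ROC evaluation of the DNase (optionally combined) signal ranking against
    the planted aSE∪dSE truth."""
    scores = dnase_scores(result.active, bundle.dnase)
    if factor2 is not None:
        idx = result.matrix.factor_labels.index(factor2)
        scores = predictor.combine_factors(scores, result.matrix.raw[:, idx])
    truth = np.array(
        [bundle.truth.classes[eid] in ("aSE", "dSE") for eid in result.active.enhancer_ids()]
    )
    inp = predictor.PredictorInput(result.active.enhancer_ids(), scores, truth)
    cutoff = predictor.two_step_cutoff(scores)
    return predictor.roc_evaluate(inp, cutoff)
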