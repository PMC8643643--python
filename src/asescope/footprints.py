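"""DNase-footprint characterization of enhancer classes.

Covers consensus filtering of cell-type footprints, per-enhancer footprint
statistics (count, width, inter-footprint gaps, best motif bitscore),
DNA-binding-domain (DBD) family assignment by best bitscore, direct-versus-
indirect TF binding, and the anchoring-TF call: a TF anchors an enhancer
class when it binds >50% of the class's peaks (ChIP) and >50% of those bound
peaks carry a footprint of its own DBD family (direct binding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .enhancer_catalog import ActiveEnhancerSet
from .io_core import GenomicInterval, ParseError, PeakSet, overlap_pairs, overlapping_indices
from .occupancy import CLASS_LABELS, EnhancerClassification

logger = logging.getLogger(__name__)

__all__ = [
    "Footprint",
    "EnhancerFootprintStats",
    "TfBindingAnnotation",
    "AnchoringCall",
    "read_footprint_bed",
    "read_tf_dbd_map",
    "filter_consensus",
    "footprint_stats",
    "assign_dbd",
    "annotate_binding",
    "call_anchoring_tfs",
]


@dataclass
class Footprint:
    interval: GenomicInterval
    motif_matches: list[tuple[str, str, float]] = field(default_factory=list)
    # each match: (motif_id, dbd_family, bitscore)


@dataclass
class EnhancerFootprintStats:
    enhancer_id: str
    n_footprints: int
    widths: list[int]
    inter_footprint_gaps: list[int]
    best_bitscores: list[float]
    dbd_families_present: set[str]


@dataclass
class TfBindingAnnotation:
    tf_label: str
    enhancer_id: str
    bound: bool
    mode: str  # direct | indirect | unbound


@dataclass
class AnchoringCall:
    tf_label: str
    enhancer_class: str
    pct_peaks_bound: float
    pct_bound_with_motif: float
    is_anchor: bool


def read_footprint_bed(path) -> list[Footprint]:
    """Read footprints from BED6+ with extra columns motif_id, dbd_family, bitscore.

    One row per motif match; rows sharing coordinates are collected into one
    Footprint. Rows with only 3–6 columns yield motif-less footprints.
    """
    by_coord: dict[tuple[str, int, int], Footprint] = {}
    order: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                key = (f[0], int(f[1]), int(f[2]))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if key not in by_coord:
                by_coord[key] = Footprint(GenomicInterval(*key))
                order.append(key)
            if len(f) >= 9:
                by_coord[key].motif_matches.append((f[6], f[7], float(f[8])))
    fps = [by_coord[k] for k in order]
    fps.sort(key=lambda fp: (fp.interval.chrom, fp.interval.start, fp.interval.end))
    return fps


def read_tf_dbd_map(path) -> dict[str, str]:
    """TSV of (tf_label, dbd_family); a TF listed twice keeps its first family."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("tf_label"):
                continue
            tf, fam = line.split("\t")[:2]
            mapping.setdefault(tf, fam)
    return mapping


def filter_consensus(
    cell_footprints: Sequence[Footprint],
    consensus: Sequence[GenomicInterval],
) -> list[Footprint]:
    """Keep cell-type footprints overlapping (≥1 bp) any consensus interval."""
    ivs = [fp.interval for fp in cell_footprints]
    keep = overlapping_indices(ivs, list(consensus), window_bp=0)
    return [cell_footprints[i] for i in sorted(keep)]


def assign_dbd(fp: Footprint) -> str | None:
    """DBD family of the highest-bitscore motif match; ties break to the
    lexicographically smallest family name; None without matches."""
    if not fp.motif_matches:
        return None
    return min(fp.motif_matches, key=lambda m: (-m[2], m[1]))[1]


def footprint_stats(
    enhancers: ActiveEnhancerSet,
    footprints: Sequence[Footprint],
    gap_metric: str = "edge",
) -> list[EnhancerFootprintStats]:
    """Per-enhancer footprint statistics.

    A footprint is assigned to every enhancer it overlaps (a straddling
    footprint counts fully in each, with its own unclipped width). Gaps are
    edge-to-edge distances between start-sorted consecutive footprints,
    floored at 0; ``gap_metric="midpoint"`` uses midpoint distances instead.
    """
    ids = enhancers.enhancer_ids()
    fp_ivs = [fp.interval for fp in footprints]
    assigned: dict[int, list[int]] = {i: [] for i in range(len(ids))}
    for e, j in overlap_pairs(enhancers.enhancers, fp_ivs, window_bp=0):
        assigned[e].append(j)
    out: list[EnhancerFootprintStats] = []
    for e, js in assigned.items():
        fps = sorted((footprints[j] for j in js), key=lambda fp: (fp.interval.start, fp.interval.end))
        widths = [fp.interval.width for fp in fps]
        gaps: list[int] = []
        for prev, nxt in zip(fps, fps[1:]):
            if gap_metric == "midpoint":
                g = (nxt.interval.start + nxt.interval.end) // 2 - (
                    prev.interval.start + prev.interval.end
                ) // 2
            else:
                g = nxt.interval.start - prev.interval.end
            gaps.append(max(0, g))
        best = [max(m[2] for m in fp.motif_matches) for fp in fps if fp.motif_matches]
        fams = {assign_dbd(fp) for fp in fps} - {None}
        out.append(
            EnhancerFootprintStats(
                enhancer_id=ids[e],
                n_footprints=len(fps),
                widths=widths,
                inter_footprint_gaps=gaps,
                best_bitscores=best,
                dbd_families_present=fams,
            )
        )
    return out


def annotate_binding(
    tf_peaks: PeakSet,
    tf_dbd: str | None,
    enhancers: ActiveEnhancerSet,
    enhancer_dbd_sets: Sequence[set[str]],
) -> list[TfBindingAnnotation]:
    """Classify one TF's binding at every enhancer as direct/indirect/unbound.

    Bound = ChIP-peak overlap; direct additionally requires a footprint of
    the TF's own DBD family on the enhancer. A TF with unknown DBD family
    can only bind indirectly (logged once).
    """
    ids = enhancers.enhancer_ids()
    if len(enhancer_dbd_sets) != len(ids):
        raise ValueError("enhancer_dbd_sets length mismatch")
    if tf_dbd is None:
        logger.warning("TF %s has no DBD family; all bound calls are indirect", tf_peaks.label)
    bound_idx = overlapping_indices(enhancers.enhancers, tf_peaks, window_bp=0)
    out = []
    for i, eid in enumerate(ids):
        if i not in bound_idx:
            mode = "unbound"
        elif tf_dbd is not None and tf_dbd in enhancer_dbd_sets[i]:
            mode = "direct"
        else:
            mode = "indirect"
        out.append(TfBindingAnnotation(tf_peaks.label, eid, i in bound_idx, mode))
    return out


def call_anchoring_tfs(
    annotations: Mapping[str, Sequence[TfBindingAnnotation]],
    classes: EnhancerClassification,
) -> list[AnchoringCall]:
    """Anchoring-TF call per (TF, enhancer class).

    pct_peaks_bound = % of the class's enhancers with a ChIP peak of the TF;
    pct_bound_with_motif = % of those bound enhancers where binding is
    direct. Both must strictly exceed 50% for an anchor call. Classes with
    no enhancers are skipped.
    """
    calls: list[AnchoringCall] = []
    for cls in CLASS_LABELS:
        members = classes.class_indices(cls)
        if not members:
            logger.warning("enhancer class %s is empty; skipped", cls)
            continue
        for tf, anns in annotations.items():
            if len(anns) != len(classes.labels):
                raise ValueError(f"annotation length mismatch for TF {tf}")
            sub = [anns[i] for i in members]
            n_bound = sum(a.bound for a in sub)
            n_direct = sum(a.mode == "direct" for a in sub)
            pct_bound = 100.0 * n_bound / len(sub)
            pct_motif = 100.0 * n_direct / n_bound if n_bound else 0.0
            calls.append(
                AnchoringCall(
                    tf_label=tf,
                    enhancer_class=cls,
                    pct_peaks_bound=pct_bound,
                    pct_bound_with_motif=pct_motif,
                    is_anchor=pct_bound > 50.0 and pct_motif > 50.0,
                )
            )
    return calls
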