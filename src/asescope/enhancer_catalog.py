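"""Active-enhancer calling and the classic ROSE super-enhancer comparator.

Active enhancers are DNase peaks that (1) overlap an H3K27ac peak and
(2) lie outside ±2.5 kb of every annotated TSS. The ROSE re-implementation
stitches H3K27ac peaks within 12.5 kb and cuts the ranked total-signal curve
at its tangent/inflection point; it works on peak-level signalValues (the
sum over stitched members stands in for integrated read density).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .io_core import GenomicInterval, Peak, PeakSet, TssRecord, overlapping_indices

logger = logging.getLogger(__name__)

__all__ = [
    "ActiveEnhancerSet",
    "StitchedRegion",
    "ClassicSeCall",
    "call_active_enhancers",
    "stitch_peaks",
    "rose_classic_se",
]


@dataclass
class ActiveEnhancerSet:
    """DNase peaks surviving the H3K27ac-overlap and TSS-exclusion filters."""

    enhancers: PeakSet
    n_dnase: int = 0
    n_h3k27ac_overlap: int = 0
    n_after_tss_exclusion: int = 0

    def __len__(self) -> int:
        return len(self.enhancers)

    def enhancer_ids(self) -> list[str]:
        """Stable per-enhancer identifiers (coordinate strings)."""
        return [
            f"{p.interval.chrom}:{p.interval.start}-{p.interval.end}"
            for p in self.enhancers
        ]


@dataclass
class StitchedRegion:
    interval: GenomicInterval
    member_peak_indices: list[int]
    total_signal: float


@dataclass
class ClassicSeCall:
    regions: list[StitchedRegion]
    is_se: list[bool]
    cutoff_signal: float
    ranking: list[int]  # region indices ordered by ascending total_signal

    def se_regions(self) -> list[StitchedRegion]:
        return [r for r, flag in zip(self.regions, self.is_se) if flag]


def call_active_enhancers(
    dnase: PeakSet,
    h3k27ac: PeakSet,
    tss: Sequence[TssRecord],
    tss_exclusion_bp: int = 2500,
    tss_distance_from: str = "edge",
) -> ActiveEnhancerSet:
    """Two-step active-enhancer filter.

    Keeps DNase peaks overlapping ≥1 H3K27ac peak, then removes any whose
    interval touches the closed window [tss − tss_exclusion_bp,
    tss + tss_exclusion_bp] around any TSS. With
    ``tss_distance_from="center"`` the peak midpoint, rather than any edge,
    must fall inside the window for removal.
    """
    if tss_exclusion_bp < 0:
        raise ValueError("tss_exclusion_bp must be >= 0")
    n_dnase = len(dnase)
    kept_idx = overlapping_indices(dnase, h3k27ac, window_bp=0)
    stage1 = [dnase[i] for i in sorted(kept_idx)]
    n_stage1 = len(stage1)

    tss_by_chrom: dict[str, list[int]] = {}
    for t in tss:
        tss_by_chrom.setdefault(t.chrom, []).append(t.position)
    for positions in tss_by_chrom.values():
        positions.sort()

    import bisect

    def near_tss(p: Peak) -> bool:
        positions = tss_by_chrom.get(p.interval.chrom)
        if not positions:
            return False
        if tss_distance_from == "center":
            lo = hi = (p.interval.start + p.interval.end) // 2
        else:
            lo, hi = p.interval.start, p.interval.end - 1
        # any TSS with position in [lo - excl, hi + excl]?
        i = bisect.bisect_left(positions, lo - tss_exclusion_bp)
        return i < len(positions) and positions[i] <= hi + tss_exclusion_bp

    stage2 = [p for p in stage1 if not near_tss(p)]
    return ActiveEnhancerSet(
        enhancers=PeakSet(stage2, label="active_enhancers"),
        n_dnase=n_dnase,
        n_h3k27ac_overlap=n_stage1,
        n_after_tss_exclusion=len(stage2),
    )


def stitch_peaks(peaks: PeakSet, stitch_distance: int = 12500) -> list[StitchedRegion]:
    """Merge consecutive same-chromosome peaks whose gap is ≤ stitch_distance.

    The gap is next.start − current region end; overlapping peaks always
    merge. Region total_signal is the sum of member signalValues.
    """
    regions: list[StitchedRegion] = []
    cur: list[int] = []
    cur_chrom = None
    cur_start = cur_end = 0
    cur_signal = 0.0

    def flush() -> None:
        if cur:
            regions.append(
                StitchedRegion(
                    GenomicInterval(cur_chrom, cur_start, cur_end),
                    list(cur),
                    cur_signal,
                )
            )

    for i, p in enumerate(peaks):
        iv = p.interval
        if cur and iv.chrom == cur_chrom and iv.start - cur_end <= stitch_distance:
            cur.append(i)
            cur_end = max(cur_end, iv.end)
            cur_signal += p.signal_value
        else:
            flush()
            cur = [i]
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            cur_signal = p.signal_value
    flush()
    return regions


def rose_classic_se(
    h3k27ac: PeakSet, stitch_distance: int = 12500
) -> ClassicSeCall:
    """Classic super-enhancer call: stitch, rank by total signal, cut at the elbow.

    Regions with total_signal strictly above the ranked-curve inflection
    cutoff are flagged SE. With fewer than 2 stitched regions no SE is
    called.
    """
    from .occupancy import find_inflection

    regions = stitch_peaks(h3k27ac, stitch_distance)
    totals = [r.total_signal for r in regions]
    ranking = sorted(range(len(regions)), key=lambda i: totals[i])
    if len(regions) < 3:
        logger.warning("fewer than 3 stitched regions; no SE called")
        cutoff = max(totals) if totals else 0.0
        return ClassicSeCall(regions, [False] * len(regions), cutoff, ranking)
    cutoff, _ = find_inflection(totals, mode="global")
    is_se = [t > cutoff for t in totals]
    return ClassicSeCall(regions, is_se, cutoff, ranking)
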