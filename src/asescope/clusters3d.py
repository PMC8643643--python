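"""Chromatin-loop clustering and cluster-level comparisons.

Loop arms (BEDPE) are intersected with active enhancers and TSSs allowing a
1 kb gap (the bedtools-window default); loops sharing an enhancer or TSS on
either arm are grouped into connected-component "clusters". Cluster metrics
follow the printed definitions: unique-enhancer count, summed contacts over
member loops, and span = max(arm end) − min(arm start). Target genes of a
cluster are the expressed genes (FPKM > 2) whose TSS is annotated to any
member arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .enhancer_catalog import ActiveEnhancerSet
from .io_core import GenomicInterval, ParseError, TssRecord, overlap_pairs, rank_sum_test
from .occupancy import CLASS_LABELS, EnhancerClassification

logger = logging.getLogger(__name__)

__all__ = [
    "Loop",
    "ChromatinCluster",
    "read_bedpe",
    "annotate_loop_arms",
    "build_clusters",
    "cluster_metrics",
    "assign_target_genes",
    "classify_clusters",
    "classify_and_compare",
]


@dataclass
class Loop:
    left: GenomicInterval
    right: GenomicInterval
    contacts: int = 1

    def __post_init__(self) -> None:
        if self.contacts < 1:
            raise ValueError("loop contacts must be >= 1")


@dataclass
class ArmAnnotation:
    """Enhancer and gene ids annotated to each arm of each loop."""

    enhancer_ids: tuple[set[str], set[str]]
    gene_ids: tuple[set[str], set[str]]

    def all_enhancers(self) -> set[str]:
        return self.enhancer_ids[0] | self.enhancer_ids[1]

    def all_genes(self) -> set[str]:
        return self.gene_ids[0] | self.gene_ids[1]


@dataclass
class ChromatinCluster:
    loop_indices: set[int]
    enhancer_ids: set[str]
    tss_gene_ids: set[str]
    n_loops: int
    enhancer_count: int
    contacts_total: int
    span_bp: int | None  # None for multi-chromosome clusters


def read_bedpe(path, contacts_column: int = 8) -> list[Loop]:
    """Read loops from BEDPE (chrom1,start1,end1,chrom2,start2,end2,name,score).

    The contact/PET count is taken from ``contacts_column`` (1-based,
    default 8 = the score column); a missing column yields contacts 1.
    """
    loops: list[Loop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: fewer than 6 columns")
            try:
                left = GenomicInterval(f[0], int(f[1]), int(f[2]))
                right = GenomicInterval(f[3], int(f[4]), int(f[5]))
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from None
            contacts = (
                int(round(float(f[contacts_column - 1])))
                if len(f) >= contacts_column
                else 1
            )
            loops.append(Loop(left, right, max(1, contacts)))
    return loops


def annotate_loop_arms(
    loops: Sequence[Loop],
    enhancers: ActiveEnhancerSet,
    tss: Sequence[TssRecord],
    window_bp: int = 1000,
) -> list[ArmAnnotation]:
    """Intersect each loop arm with enhancers and TSSs, allowing ``window_bp`` gap.

    An arm matches an enhancer when the arm expanded by the window shares
    ≥1 bp with the enhancer, and matches a TSS when the point falls inside
    the expanded arm.
    """
    enh_ids = enhancers.enhancer_ids()
    arms: list[GenomicInterval] = []
    for lp in loops:
        arms.append(lp.left)
        arms.append(lp.right)
    # TSS as 1-bp intervals
    tss_ivs = [GenomicInterval(t.chrom, t.position, t.position + 1) for t in tss]

    arm_enh: list[set[str]] = [set() for _ in arms]
    for a, e in overlap_pairs(arms, enhancers.enhancers, window_bp=window_bp):
        arm_enh[a].add(enh_ids[e])
    arm_gene: list[set[str]] = [set() for _ in arms]
    for a, t in overlap_pairs(arms, tss_ivs, window_bp=window_bp):
        arm_gene[a].add(tss[t].gene_id)

    return [
        ArmAnnotation(
            enhancer_ids=(arm_enh[2 * i], arm_enh[2 * i + 1]),
            gene_ids=(arm_gene[2 * i], arm_gene[2 * i + 1]),
        )
        for i in range(len(loops))
    ]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_clusters(
    loops: Sequence[Loop],
    annotations: Sequence[ArmAnnotation],
) -> list[ChromatinCluster]:
    """Group loops sharing an enhancer or TSS (either arm) into clusters.

    Connected components of the loop graph; loops sharing no id form
    singleton clusters. Clusters are ordered deterministically by
    (chrom, min arm start) of their member loops.
    """
    if len(loops) != len(annotations):
        raise ValueError("loops and annotations length mismatch")
    uf = _UnionFind(len(loops))
    by_id: dict[str, int] = {}
    for i, ann in enumerate(annotations):
        for key in (
            [("E", e) for e in ann.all_enhancers()]
            + [("G", g) for g in ann.all_genes()]
        ):
            if key in by_id:
                uf.union(by_id[key], i)
            else:
                by_id[key] = i
    groups: dict[int, list[int]] = {}
    for i in range(len(loops)):
        groups.setdefault(uf.find(i), []).append(i)

    clusters = []
    for members in groups.values():
        clusters.append(_make_cluster(loops, annotations, members))
    clusters.sort(
        key=lambda c: min(
            (min(loops[i].left.chrom, loops[i].right.chrom), _min_start(loops[i]))
            for i in c.loop_indices
        )
    )
    return clusters


def _min_start(lp: Loop) -> int:
    return min(lp.left.start, lp.right.start)


def _make_cluster(
    loops: Sequence[Loop], annotations: Sequence[ArmAnnotation], members: list[int]
) -> ChromatinCluster:
    enh = set().union(*(annotations[i].all_enhancers() for i in members))
    genes = set().union(*(annotations[i].all_genes() for i in members))
    chroms = {loops[i].left.chrom for i in members} | {loops[i].right.chrom for i in members}
    if len(chroms) == 1:
        starts = [min(loops[i].left.start, loops[i].right.start) for i in members]
        ends = [max(loops[i].left.end, loops[i].right.end) for i in members]
        span = max(ends) - min(starts)
    else:
        span = None
    return ChromatinCluster(
        loop_indices=set(members),
        enhancer_ids=enh,
        tss_gene_ids=genes,
        n_loops=len(members),
        enhancer_count=len(enh),
        contacts_total=sum(loops[i].contacts for i in members),
        span_bp=span,
    )


def cluster_metrics(
    cluster: ChromatinCluster,
) -> tuple[int, int, int, int | None]:
    """(enhancer_count, n_loops, contacts_total, span_bp) for a built cluster."""
    return (
        cluster.enhancer_count,
        cluster.n_loops,
        cluster.contacts_total,
        cluster.span_bp,
    )


def assign_target_genes(
    clusters: Sequence[ChromatinCluster],
    expression: Mapping[str, float],
    fpkm_min: float = 2.0,
) -> list[set[str]]:
    """Per-cluster target genes: TSS on a member arm and FPKM strictly > fpkm_min.

    Genes absent from the expression table count as unexpressed (FPKM 0).
    """
    return [
        {g for g in c.tss_gene_ids if expression.get(g, 0.0) > fpkm_min}
        for c in clusters
    ]


def classify_clusters(
    clusters: Sequence[ChromatinCluster],
    classes: EnhancerClassification,
) -> list[set[str]]:
    """Non-exclusive per-cluster labels: '<class>-containing' for each enhancer
    class with ≥1 member enhancer in the cluster."""
    by_id = dict(zip(classes.enhancer_ids, classes.labels))
    out = []
    for c in clusters:
        present = {by_id[e] for e in c.enhancer_ids if e in by_id}
        out.append({f"{cls}-containing" for cls in present})
    return out


def classify_and_compare(
    clusters: Sequence[ChromatinCluster],
    classes: EnhancerClassification,
    targets: Sequence[set[str]],
    expression: Mapping[str, float],
) -> dict:
    """Per-label metric distributions and pairwise rank-sum p-values.

    For each non-exclusive cluster label, collects the distributions of span,
    contacts_total, n_loops, enhancer_count, target-gene FPKM (all target
    genes pooled) and the per-cluster maximum target FPKM, then compares
    every label pair per metric with the Wilcoxon rank-sum test.
    """
    labels_per_cluster = classify_clusters(clusters, classes)
    dists: dict[str, dict[str, list[float]]] = {}
    for c, labs, tg in zip(clusters, labels_per_cluster, targets):
        fpkms = [expression.get(g, 0.0) for g in sorted(tg)]
        for lab in labs:
            d = dists.setdefault(
                lab,
                {
                    "span": [],
                    "contacts": [],
                    "n_loops": [],
                    "enhancer_count": [],
                    "target_fpkm": [],
                    "max_target_fpkm": [],
                },
            )
            if c.span_bp is not None:
                d["span"].append(float(c.span_bp))
            d["contacts"].append(float(c.contacts_total))
            d["n_loops"].append(float(c.n_loops))
            d["enhancer_count"].append(float(c.enhancer_count))
            d["target_fpkm"].extend(fpkms)
            if fpkms:
                d["max_target_fpkm"].append(max(fpkms))

    expected = [f"{c}-containing" for c in CLASS_LABELS]
    for lab in expected:
        if lab not in dists:
            logger.warning("cluster label %s has no clusters; omitted", lab)

    comparisons: dict[tuple[str, str, str], float] = {}
    labs = [l for l in expected if l in dists]
    for i, la in enumerate(labs):
        for lb in labs[i + 1 :]:
            for metric in dists[la]:
                xa, xb = dists[la][metric], dists[lb][metric]
                if xa and xb:
                    _, p = rank_sum_test(xa, xb)
                    comparisons[(la, lb, metric)] = p
    return {"distributions": dists, "pairwise_p": comparisons}
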