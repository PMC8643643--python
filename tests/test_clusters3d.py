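"""Loop-arm annotation, connected-component clustering and cluster metrics."""

import numpy as np
import pytest

from asescope.clusters3d import (
    ArmAnnotation,
    Loop,
    annotate_loop_arms,
    assign_target_genes,
    build_clusters,
    classify_and_compare,
    classify_clusters,
    cluster_metrics,
)
from asescope.enhancer_catalog import ActiveEnhancerSet
from asescope.io_core import GenomicInterval, Peak, PeakSet, TssRecord
from asescope.occupancy import EnhancerClassification


def active_set(spans, chrom="chr1"):
    ps = PeakSet([Peak(GenomicInterval(chrom, s, e), f"e{i}") for i, (s, e) in enumerate(spans)])
    return ActiveEnhancerSet(ps, len(ps), len(ps), len(ps))


def loop(l0, l1, r0, r1, contacts=1, chrom="chr1"):
    return Loop(GenomicInterval(chrom, l0, l1), GenomicInterval(chrom, r0, r1), contacts)


def ann(le=(), re=(), lg=(), rg=()):
    return ArmAnnotation((set(le), set(re)), (set(lg), set(rg)))


class TestAnnotateLoopArms:
    def test_one_kb_window_bridges_gap(self):
        enh = active_set([(6500, 6800)])
        loops = [loop(5000, 6000, 50_000, 51_000)]
        a1 = annotate_loop_arms(loops, enh, [], window_bp=1000)
        assert a1[0].enhancer_ids[0] == {enh.enhancer_ids()[0]}
        a0 = annotate_loop_arms(loops, enh, [], window_bp=0)
        assert a0[0].enhancer_ids[0] == set()

    def test_tss_point_within_expanded_arm(self):
        tss = [TssRecord("g1", "chr1", 51_900)]
        loops = [loop(5000, 6000, 50_000, 51_000)]
        a = annotate_loop_arms(loops, active_set([]), tss, window_bp=1000)
        assert a[0].gene_ids[1] == {"g1"}

    def test_matches_brute_force_distance_check(self):
        rng = np.random.default_rng(21)
        spans = sorted((int(s), int(s) + 300) for s in rng.integers(0, 200_000, 40))
        enh = active_set(spans)
        ids = enh.enhancer_ids()
        loops = [
            loop(int(a), int(a) + 800, int(b), int(b) + 800)
            for a, b in rng.integers(0, 200_000, (30, 2))
        ]
        anns = annotate_loop_arms(loops, enh, [], window_bp=1000)
        for lp, a in zip(loops, anns):
            for arm_iv, got in zip((lp.left, lp.right), a.enhancer_ids):
                expect = {
                    ids[i]
                    for i, p in enumerate(enh.enhancers)
                    if max(0, arm_iv.start - 1000) < p.interval.end
                    and p.interval.start < arm_iv.end + 1000
                }
                assert got == expect


class TestBuildClusters:
    def test_shared_enhancer_groups_loops(self):
        loops = [loop(0, 10, 100, 110), loop(200, 210, 300, 310)]
        anns = [ann(le={"E1"}, re={"E2"}), ann(le={"E2"}, re={"E3"})]
        clusters = build_clusters(loops, anns)
        assert len(clusters) == 1
        assert clusters[0].enhancer_count == 3

    def test_disjoint_ids_stay_separate(self):
        loops = [loop(0, 10, 100, 110), loop(200, 210, 300, 310)]
        anns = [ann(le={"E1"}, re={"E2"}), ann(le={"E3"}, re={"E4"})]
        assert len(build_clusters(loops, anns)) == 2

    def test_every_loop_in_exactly_one_cluster(self):
        rng = np.random.default_rng(8)
        loops, anns = self._random_case(rng, 300)
        clusters = build_clusters(loops, anns)
        covered = sorted(i for c in clusters for i in c.loop_indices)
        assert covered == list(range(300))

    @staticmethod
    def _random_case(rng, n):
        loops, anns = [], []
        for k in range(n):
            s = int(rng.integers(0, 10**6))
            loops.append(loop(s, s + 500, s + 5000, s + 5500))
            ids = {f"E{int(i)}" for i in rng.integers(0, 80, rng.integers(0, 3))}
            genes = {f"g{int(i)}" for i in rng.integers(0, 40, rng.integers(0, 2))}
            anns.append(ArmAnnotation((ids, set()), (set(), genes)))
        return loops, anns

    def test_components_match_transitive_closure_oracle(self):
        rng = np.random.default_rng(17)
        loops, anns = self._random_case(rng, 300)
        clusters = build_clusters(loops, anns)
        # boolean adjacency matrix closure
        n = len(loops)
        adj = np.eye(n, dtype=bool)
        keys = [anns[i].all_enhancers() | {("g", g) for g in anns[i].all_genes()} for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if keys[i] & keys[j]:
                    adj[i, j] = adj[j, i] = True
        closure = adj.copy()
        for _ in range(n):
            new = (closure.astype(np.int32) @ closure.astype(np.int32)) > 0
            if (new == closure).all():
                break
            closure = new
        oracle = {frozenset(np.nonzero(closure[i])[0].tolist()) for i in range(n)}
        got = {frozenset(c.loop_indices) for c in clusters}
        assert got == oracle


class TestClusterMetrics:
    def test_printed_definitions(self):
        loops = [loop(1000, 2000, 5000, 6000, 4), loop(5500, 6500, 9000, 10_000, 6)]
        anns = [ann(le={"E1"}, re={"E2"}), ann(le={"E2"}, re={"E3"})]
        (c,) = build_clusters(loops, anns)
        enh_count, n_loops, contacts, span = cluster_metrics(c)
        assert (enh_count, n_loops, contacts, span) == (3, 2, 10, 9000)

    def test_singleton_span(self):
        (c,) = build_clusters([loop(1000, 2000, 8000, 9000, 2)], [ann(le={"E1"})])
        assert c.span_bp == 8000

    def test_trans_chromosomal_cluster_span_is_na(self):
        lp = Loop(GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 0, 100), 1)
        (c,) = build_clusters([lp], [ann(le={"E1"})])
        assert c.span_bp is None

    def test_metrics_recomputable_from_raw_loops(self):
        rng = np.random.default_rng(30)
        loops, anns = TestBuildClusters._random_case(rng, 200)
        for c in build_clusters(loops, anns):
            member = sorted(c.loop_indices)
            assert c.n_loops == len(member)
            assert c.contacts_total == sum(loops[i].contacts for i in member)
            assert c.enhancer_ids == set().union(*(anns[i].all_enhancers() for i in member))
            starts = [min(loops[i].left.start, loops[i].right.start) for i in member]
            ends = [max(loops[i].left.end, loops[i].right.end) for i in member]
            assert c.span_bp == max(ends) - min(starts)
            assert all(
                c.span_bp >= max(loops[i].left.end, loops[i].right.end)
                - min(loops[i].left.start, loops[i].right.start)
                for i in member
            )


class TestAssignTargetGenes:
    def test_fpkm_threshold_is_strict(self):
        (c,) = build_clusters([loop(0, 10, 100, 110)], [ann(lg={"gA", "gB", "gC"})])
        targets = assign_target_genes([c], {"gA": 2.0, "gB": 15.0}, fpkm_min=2.0)
        # gA at exactly 2.0 excluded; gC missing from the table counts as 0
        assert targets[0] == {"gB"}


class TestClassifyAndCompare:
    def test_nonexclusive_labels(self):
        classes = EnhancerClassification(
            ["aSE", "rEh"], 0.0, ["E1", "E2"]
        )
        loops = [loop(0, 10, 100, 110)]
        anns = [ann(le={"E1", "E2"})]
        clusters = build_clusters(loops, anns)
        labels = classify_clusters(clusters, classes)
        assert labels[0] == {"aSE-containing", "rEh-containing"}

    def test_identical_distributions_give_p_one(self):
        classes = EnhancerClassification(["aSE", "rEh"], 0.0, ["E1", "E2"])
        loops = [loop(0, 10, 5000, 5010, 3), loop(20_000, 20_010, 26_000, 26_010, 3)]
        anns = [ann(le={"E1"}), ann(le={"E2"})]
        clusters = build_clusters(loops, anns)
        res = classify_and_compare(clusters, classes, [set(), set()], {})
        p = res["pairwise_p"][("aSE-containing", "rEh-containing", "contacts")]
        assert p == 1.0

    def test_synthetic_high_clusters_make_more_contacts(self, default_bundle, default_result):
        res = classify_and_compare(
            default_result.clusters,
            default_result.classes,
            default_result.target_genes,
            default_bundle.expression,
        )
        d = res["distributions"]
        assert np.median(d["aSE-containing"]["contacts"]) > np.median(
            d["rEh-containing"]["contacts"]
        )

    def test_planted_high_enhancers_overrepresented_in_clusters(self, default_bundle, default_result):
        truth = default_bundle.truth
        high = truth.high_ids()
        frac_enh = len(high) / len(truth.classes)
        in_cluster = [
            bool(high & c.enhancer_ids) for c in default_result.clusters
        ]
        assert np.mean(in_cluster) > frac_enh
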