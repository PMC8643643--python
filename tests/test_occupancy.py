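"""Signal matrix, occupancy score, inflection cutoff and 4-way classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asescope.enhancer_catalog import ActiveEnhancerSet, ClassicSeCall, StitchedRegion
from asescope.io_core import GenomicInterval, Peak, PeakSet
from asescope.occupancy import (
    SignalMatrix,
    build_signal_matrix,
    classify_enhancers,
    find_inflection,
    minmax_normalize,
    occupancy_score,
)


def active_set(spans, chrom="chr1"):
    ps = PeakSet([Peak(GenomicInterval(chrom, s, e), f"e{i}") for i, (s, e) in enumerate(spans)])
    return ActiveEnhancerSet(ps, len(ps), len(ps), len(ps))


def factor(label, spans, signals, chrom="chr1"):
    return PeakSet(
        [Peak(GenomicInterval(chrom, s, e), f"{label}{i}", sv) for i, ((s, e), sv) in enumerate(zip(spans, signals))],
        label=label,
    )


class TestBuildSignalMatrix:
    def test_max_aggregation_over_multiple_peaks(self):
        enh = active_set([(100, 600)])
        f = factor("A", [(120, 200), (300, 400)], [3.0, 7.0])
        m = build_signal_matrix(enh, [f])
        assert m.raw[0, 0] == 7.0

    @pytest.mark.parametrize("mode,expected", [("sum", 10.0), ("mean", 5.0)])
    def test_alternative_aggregations(self, mode, expected):
        enh = active_set([(100, 600)])
        f = factor("A", [(120, 200), (300, 400)], [3.0, 7.0])
        assert build_signal_matrix(enh, [f], aggregate=mode).raw[0, 0] == expected

    def test_unbound_enhancer_gets_zero(self):
        enh = active_set([(100, 600), (10_000, 10_500)])
        f = factor("A", [(120, 200)], [3.0])
        m = build_signal_matrix(enh, [f])
        assert m.raw[1, 0] == 0.0 and m.normalized[1, 0] == 0.0

    def test_minmax_column(self):
        m = minmax_normalize(np.array([[0.0], [5.0], [10.0]]))
        assert m[:, 0].tolist() == [0.0, 0.5, 1.0]

    def test_constant_column_normalizes_to_zeros(self):
        m = minmax_normalize(np.array([[4.0], [4.0], [4.0]]))
        assert (m == 0).all()

    def test_nonconstant_columns_hit_both_endpoints(self):
        rng = np.random.default_rng(2)
        m = minmax_normalize(rng.exponential(size=(40, 6)))
        assert np.allclose(m.min(axis=0), 0) and np.allclose(m.max(axis=0), 1)

    def test_duplicate_factor_labels_rejected(self):
        enh = active_set([(0, 10)])
        f = factor("A", [(0, 10)], [1.0])
        with pytest.raises(ValueError):
            build_signal_matrix(enh, [f, f])


def mk_matrix(raw):
    raw = np.asarray(raw, dtype=float)
    return SignalMatrix(
        enhancer_ids=[f"e{i}" for i in range(raw.shape[0])],
        factor_labels=[f"f{j}" for j in range(raw.shape[1])],
        raw=raw,
        normalized=minmax_normalize(raw),
    )


class TestOccupancyScore:
    def test_direct_formula_application(self):
        m = SignalMatrix(["e0", "e1"], ["a", "b", "c"],
                         raw=np.array([[2.0, 1.0, 0.5], [0.0, 0.0, 0.0]]),
                         normalized=np.array([[1.0, 0.5, 0.25], [0.0, 0.0, 0.0]]))
        occ = occupancy_score(m)
        assert occ.os[0] == pytest.approx(3 * 1.75)
        assert occ.n_bound.tolist() == [3, 0]
        assert occ.os[1] == 0.0

    def test_matches_per_row_loop_oracle(self):
        rng = np.random.default_rng(7)
        raw = rng.exponential(size=(50, 10)) * (rng.random((50, 10)) < 0.5)
        m = mk_matrix(raw)
        occ = occupancy_score(m)
        for e in range(50):
            n = sum(1 for f in range(10) if raw[e, f] > 0)
            s = sum(m.normalized[e, f] for f in range(10))
            assert occ.os[e] == pytest.approx(n * s)

    def test_all_zero_factor_changes_no_score(self):
        rng = np.random.default_rng(8)
        raw = rng.exponential(size=(30, 5))
        base = occupancy_score(mk_matrix(raw)).os
        padded = occupancy_score(mk_matrix(np.hstack([raw, np.zeros((30, 1))]))).os
        assert np.allclose(base, padded)

    def test_invariant_to_column_and_row_permutation(self):
        rng = np.random.default_rng(9)
        raw = rng.exponential(size=(25, 6)) * (rng.random((25, 6)) < 0.7)
        base = occupancy_score(mk_matrix(raw)).os
        cperm = rng.permutation(6)
        assert np.allclose(base, occupancy_score(mk_matrix(raw[:, cperm])).os)
        rperm = rng.permutation(25)
        assert np.allclose(base[rperm], occupancy_score(mk_matrix(raw[rperm])).os)


class TestFindInflection:
    def test_hockey_stick_cuts_at_flat_ramp_junction(self):
        y = [0.0] * 90 + [10.0 * i for i in range(1, 11)]
        cutoff, rank = find_inflection(y)
        assert cutoff == 0.0 and rank == 89
        assert sum(v > cutoff for v in y) == 10

    def test_constant_vector_has_nothing_above(self):
        cutoff, _ = find_inflection([5.0] * 10)
        assert cutoff == 5.0

    def test_strictly_linear_curve_has_no_elbow(self):
        y = list(map(float, range(1, 101)))
        cutoff, _ = find_inflection(y)
        assert cutoff == 100.0 and sum(v > cutoff for v in y) == 0

    def test_requires_three_values(self):
        with pytest.raises(ValueError):
            find_inflection([1.0, 2.0])

    def test_matches_exhaustive_tangency_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            y = np.sort(rng.exponential(size=int(rng.integers(5, 60))) ** 2)
            s_star = (y[-1] - y[0]) / y.size
            resid = y - s_star * np.arange(y.size)
            ks = [k for k in range(y.size) if resid[k] <= resid.min() + 1e-12]
            expect = y.size - 1 if max(ks) == 0 else max(ks)
            cutoff, rank = find_inflection(y)
            assert rank == expect and cutoff == y[expect]

    @given(
        st.lists(st.floats(0, 1e4, allow_nan=False).map(lambda v: round(v, 4)), min_size=5, max_size=50),
        st.floats(0.1, 50).map(lambda v: round(v, 3)),
        st.floats(-100, 100).map(lambda v: round(v, 3)),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_equivariance_under_positive_affine_maps(self, ys, a, b):
        cut, rank = find_inflection(ys)
        cut2, rank2 = find_inflection([a * v + b for v in ys])
        assert rank2 == rank
        assert cut2 == pytest.approx(a * cut + b, rel=1e-9, abs=1e-6)

    def test_local_mode_never_exceeds_global(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            y = rng.exponential(size=40) ** 2
            g, _ = find_inflection(y, mode="global")
            l, _ = find_inflection(y, mode="local")
            assert l <= g


def classic_call(se_spans, chrom="chr1"):
    regions = [StitchedRegion(GenomicInterval(chrom, s, e), [], 100.0) for s, e in se_spans]
    return ClassicSeCall(regions, [True] * len(regions), 0.0, list(range(len(regions))))


class TestClassifyEnhancers:
    def setup_method(self):
        # 12 enhancers: 2 with huge OS, rest tiny; enhancers 0 and 2 inside an SE region
        self.enh = active_set([(i * 10_000, i * 10_000 + 500) for i in range(12)])
        raw = np.ones((12, 4)) * 0.1
        raw[0] = 50.0  # high occupancy inside SE -> dSE
        raw[1] = 50.0  # high occupancy outside SE -> aSE
        self.occ = occupancy_score(mk_matrix(raw))
        self.se = classic_call([(0, 700), (20_000, 20_400)])

    def test_four_way_rules(self):
        classes = classify_enhancers(self.occ, self.enh, self.se)
        assert classes.labels[0] == "dSE"
        assert classes.labels[1] == "aSE"
        assert classes.labels[2] == "cSE"   # low occupancy inside SE
        assert classes.labels[3] == "rEh"   # low occupancy outside

    def test_labels_partition_the_set(self):
        classes = classify_enhancers(self.occ, self.enh, self.se)
        assert len(classes.labels) == 12
        assert sum(classes.counts().values()) == 12

    def test_count_mismatch_rejected(self):
        small = active_set([(0, 10)])
        with pytest.raises(ValueError):
            classify_enhancers(self.occ, small, self.se)
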