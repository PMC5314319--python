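import numpy as np
import pytest

from uvomics.genome import GenomeAnnotation
from uvomics.superenhancers import (
    annotate_se_genes,
    call_superenhancers,
    compare_se_sets,
    exclude_promoter_peaks,
    se_cutoff,
    stitch_enhancers,
)

from .conftest import make_gene, peak


def cutoff_oracle(signals):
    """Exhaustive scan of the scaled below-diagonal depth (independent of
    the vectorized implementation)."""
    s = sorted(signals)
    n = len(s)
    best_i, best_d = 0, -float("inf")
    for i in range(n):
        x = i / (n - 1)
        y = (s[i] - s[0]) / (s[-1] - s[0])
        d = x - y
        if d > best_d:
            best_i, best_d = i, d
    return s[best_i], best_i


class TestPromoterExclusion:
    @pytest.fixture
    def ann(self):
        return GenomeAnnotation(
            {"chr1": 100_000}, [make_gene("g", "chr1", 1_000, 30_000)]
        )

    def test_peak_over_tss_removed(self, ann):
        assert exclude_promoter_peaks([peak("chr1", 900, 1_100, 1.0)], ann) == []

    def test_distal_peak_retained(self, ann):
        p = [peak("chr1", 50_000, 50_500, 1.0)]
        assert exclude_promoter_peaks(p, ann) == p

    def test_window_zero_removes_only_tss_base(self, ann):
        over = peak("chr1", 1_000, 1_001, 1.0)
        near = peak("chr1", 1_001, 1_002, 1.0)
        assert exclude_promoter_peaks([over, near], ann, tss_window=0) == [near]


class TestStitching:
    def test_gap_arithmetic(self):
        peaks = [
            peak("chr1", 100, 200, 1.0),
            peak("chr1", 5_000, 5_100, 2.0),
            peak("chr1", 20_000, 20_100, 4.0),
        ]
        st = stitch_enhancers(peaks)
        assert len(st) == 2
        assert st[0].interval.start == 100 and st[0].interval.end == 5_100
        assert st[0].total_signal == 3.0
        assert st[1].constituent_peaks == [peaks[2]]

    def test_single_peak_identity(self):
        p = peak("chr1", 10, 60, 2.5)
        (st,) = stitch_enhancers([p])
        assert st.interval == p.interval and st.total_signal == 2.5

    def test_full_chain_merges_to_one(self):
        peaks = [peak("chr1", i * 12_000, i * 12_000 + 100, 1.0) for i in range(10)]
        assert len(stitch_enhancers(peaks)) == 1

    def test_signal_conserved(self):
        rng = np.random.default_rng(2)
        peaks = []
        pos = 0
        for i in range(200):
            pos += int(rng.integers(100, 30_000))
            peaks.append(peak("chr1", pos, pos + 200, float(rng.uniform(0, 10))))
            pos += 200
        st = stitch_enhancers(peaks)
        assert sum(e.total_signal for e in st) == pytest.approx(
            sum(p.signal for p in peaks)
        )

    def test_monotone_in_stitch_distance(self):
        rng = np.random.default_rng(3)
        peaks = []
        pos = 0
        for i in range(100):
            pos += int(rng.integers(100, 25_000))
            peaks.append(peak("chr1", pos, pos + 150, 1.0))
            pos += 150
        counts = [len(stitch_enhancers(peaks, d)) for d in (0, 2_000, 10_000, 50_000)]
        assert counts == sorted(counts, reverse=True)


class TestCutoff:
    def test_flat_then_spike(self):
        cut, idx = se_cutoff([1, 1, 1, 1, 1, 1, 10, 20, 40])
        assert (cut, idx) == (1, 5)  # last flat point; SEs are {10, 20, 40}

    def test_linear_curve_warns_and_keeps_all_but_minimum(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            cut, idx = se_cutoff(list(range(1, 11)))
        assert (cut, idx) == (1, 0)

    def test_two_zeros_one_spike(self):
        assert se_cutoff([0, 0, 100]) == (0, 1)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="no transition point"):
            se_cutoff([5, 5, 5, 5])

    def test_too_few_signals_errors(self):
        with pytest.raises(ValueError):
            se_cutoff([1, 2])

    def test_matches_exhaustive_oracle_on_hockey_sticks(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(50, 500))
            flat = rng.lognormal(1.0, 0.5, size=n)
            k = int(rng.integers(1, max(2, n // 20)))
            spike = rng.lognormal(5.0, 0.5, size=k)
            signals = np.concatenate([flat, spike])
            assert se_cutoff(signals) == cutoff_oracle(signals)


class TestCallSuperenhancers:
    def test_planted_recovery_zero_noise(self):
        from uvomics.simulate import (
            SimulationConfig,
            generate_annotation,
            generate_chipseq_pair,
        )

        cfg = SimulationConfig(seed=2, chip_noise_sd=0.0)
        ann = generate_annotation(cfg)
        ctrl, _, truth = generate_chipseq_pair(cfg, ann)
        se_set = call_superenhancers(ctrl, ann)
        called = {(e.interval.chrom, e.interval.start) for e in se_set.superenhancers}
        planted = {(c, a) for c, a, _ in truth.se_cluster_intervals}
        assert called == planted

    def test_no_peaks_errors(self, toy_annotation):
        with pytest.raises(ValueError):
            call_superenhancers([], toy_annotation)

    def test_se_count_matches_cutoff_index_without_ties(self, toy_annotation):
        peaks = [
            peak("chr2", 50_000 + i * 20_000, 50_200 + i * 20_000, float(2**i))
            for i in range(8)
        ]
        se_set = call_superenhancers(peaks, toy_annotation)
        assert len(se_set.superenhancers) == len(se_set.stitched) - se_set.cutoff_index - 1


class TestSEGeneAnnotation:
    def test_distance_window(self):
        genes = [
            make_gene("near", "chr1", 76_000, 80_000),   # 24 kb from SE end
            make_gene("far", "chr1", 78_100, 84_000),    # 26.1 kb
            make_gene("inside", "chr1", 30_000, 34_000),
        ]
        # place genes to the right of an SE spanning [20_000, 52_000)
        genes[0] = make_gene("near", "chr1", 76_000, 80_000)
        genes[1] = make_gene("far", "chr1", 78_200, 84_000)
        ann = GenomeAnnotation({"chr1": 200_000}, genes)
        peaks = [
            # positions avoid every gene's promoter window
            peak("chr1", 20_000, 20_500, 100.0),
            peak("chr1", 33_000, 33_500, 100.0),
            peak("chr1", 41_500, 42_000, 100.0),
            peak("chr1", 51_500, 52_000, 100.0),
            # low-signal distal enhancers so a transition point exists
            peak("chr1", 120_000, 120_500, 1.0),
            peak("chr1", 150_000, 150_500, 1.0),
            peak("chr1", 180_000, 180_500, 1.0),
        ]
        se_set = call_superenhancers(peaks, ann)
        assert len(se_set.superenhancers) == 1
        se = se_set.superenhancers[0]
        assert (se.interval.start, se.interval.end) == (20_000, 52_000)
        genes_map = annotate_se_genes(se_set, ann)
        assert sorted(genes_map[se.rank]) == ["inside", "near"]
        d_far = genes[1].body.start - se.interval.end
        assert d_far > 25_000  # the excluded gene really is beyond the window


class TestCompareSESets:
    def _se_set(self, intervals):
        from uvomics.superenhancers import StitchedEnhancer, SuperEnhancerSet

        stitched = [
            StitchedEnhancer(iv, [peak(iv.chrom, iv.start, iv.end, 10.0)], rank=i)
            for i, iv in enumerate(intervals)
        ]
        return SuperEnhancerSet("s", stitched, 0.0, 0, superenhancers=stitched)

    def test_identical_sets_no_uniques(self):
        from uvomics.genome import Interval

        a = self._se_set([Interval("chr1", 0, 100), Interval("chr1", 500, 900)])
        b = self._se_set([Interval("chr1", 0, 100), Interval("chr1", 500, 900)])
        venn = compare_se_sets(a, b)
        assert venn["unique_a"] == [] and venn["unique_b"] == []
        assert len(venn["common_a"]) == len(venn["common_b"]) == 2

    def test_disjoint_chromosomes_all_unique(self):
        from uvomics.genome import Interval

        a = self._se_set([Interval("chr1", 0, 100)])
        b = self._se_set([Interval("chr2", 0, 100)])
        venn = compare_se_sets(a, b)
        assert len(venn["unique_a"]) == 1 and len(venn["unique_b"]) == 1
        assert venn["common_a"] == [] and venn["common_b"] == []

    def test_one_spanning_two(self):
        from uvomics.genome import Interval

        a = self._se_set([Interval("chr1", 0, 10_000)])
        b = self._se_set([Interval("chr1", 100, 200), Interval("chr1", 5_000, 6_000)])
        venn = compare_se_sets(a, b)
        assert len(venn["common_a"]) == 1
        assert len(venn["common_b"]) == 2
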