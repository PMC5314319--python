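import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uvomics.genome import (
    AnnotationError,
    GenomeAnnotation,
    Interval,
    assign_peaks_to_genes,
    interval_distance,
    read_gene_annotation,
    read_peaks,
    write_gene_annotation,
    write_peaks,
)

from .conftest import make_gene, peak


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestGFF3:
    def test_coordinates_convert_to_half_open(self, tmp_path):
        path = _write(
            tmp_path, "g.gff3",
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n",
        )
        ann = read_gene_annotation(path)
        assert ann.genes[0].body == Interval("chr1", 100, 200)
        assert ann.genes[0].tss == 100

    def test_minus_strand_tss_is_last_base(self, tmp_path):
        path = _write(
            tmp_path, "g.gff3",
            "chr1\tsrc\tgene\t101\t200\t.\t-\t.\tID=g1\n",
        )
        assert read_gene_annotation(path).genes[0].tss == 199

    def test_empty_file_gives_empty_annotation(self, tmp_path):
        ann = read_gene_annotation(_write(tmp_path, "e.gff3", ""))
        assert len(ann) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        path = _write(
            tmp_path, "bad.gff3",
            "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tgene\tnotanumber\t300\t.\t+\t.\tID=g2\n",
        )
        with pytest.raises(AnnotationError, match=":2:"):
            read_gene_annotation(path)

    def test_exon_outside_gene_rejected(self, tmp_path):
        path = _write(
            tmp_path, "bad.gff3",
            "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\texon\t50\t90\t.\t+\t.\tParent=g1\n",
        )
        with pytest.raises(AnnotationError, match="outside gene"):
            read_gene_annotation(path)

    def test_round_trip_is_identity_on_coordinates(self, tmp_path, toy_annotation):
        out = str(tmp_path / "rt.gff3")
        write_gene_annotation(toy_annotation, out)
        back = read_gene_annotation(out)
        orig = {g.gene_id: g for g in toy_annotation.genes}
        assert set(g.gene_id for g in back.genes) == set(orig)
        for g in back.genes:
            o = orig[g.gene_id]
            assert (g.body, g.strand, g.exons, g.utr5, g.utr3) == (
                o.body, o.strand, o.exons, o.utr5, o.utr3
            )


class TestPeakIO:
    def test_basic_line(self, tmp_path):
        p = read_peaks(_write(tmp_path, "p.bed", "chr1\t100\t200\tpeak1\t5.0\n"))
        assert len(p) == 1
        assert p[0].interval == Interval("chr1", 100, 200)
        assert p[0].signal == 5.0

    def test_duplicates_retained(self, tmp_path):
        text = "chr1\t100\t200\tp\t5.0\n" * 2
        assert len(read_peaks(_write(tmp_path, "d.bed", text))) == 2

    def test_non_numeric_signal_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_peaks(_write(tmp_path, "na.bed", "chr1\t100\t200\tp\tNA\n"))

    def test_negative_signal_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_peaks(_write(tmp_path, "neg.bed", "chr1\t100\t200\tp\t-1\n"))

    def test_unsorted_input_sorted(self, tmp_path):
        text = "chr2\t5\t10\ta\t1\nchr1\t500\t600\tb\t1\nchr1\t5\t10\tc\t1\n"
        p = read_peaks(_write(tmp_path, "u.bed", text))
        assert [(q.interval.chrom, q.interval.start) for q in p] == [
            ("chr1", 5), ("chr1", 500), ("chr2", 5)
        ]

    def test_write_read_round_trip(self, tmp_path):
        peaks = [peak("chr1", 10, 20, 3.5, "x"), peak("chr1", 100, 130, 0.0, "y")]
        out = str(tmp_path / "w.bed")
        write_peaks(peaks, out)
        assert read_peaks(out) == peaks


class TestIntervalDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (Interval("chr1", 100, 200), Interval("chr1", 150, 300), 0),
            (Interval("chr1", 100, 200), Interval("chr1", 700, 800), 500),
            (Interval("chr1", 100, 200), Interval("chr1", 200, 300), 0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert interval_distance(a, b) == expected

    def test_different_chromosomes_infinite(self):
        d = interval_distance(Interval("chr1", 0, 10), Interval("chr2", 0, 10))
        assert math.isinf(d)

    @given(st.lists(st.integers(0, 1000), min_size=6, max_size=6))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_symmetry_and_triangle_inequality(self, raw):
        ivs = []
        for i in range(0, 6, 2):
            lo, hi = sorted(raw[i:i + 2])
            ivs.append(Interval("chr1", lo, hi + 1))
        a, b, c = ivs
        assert interval_distance(a, b) == interval_distance(b, a)
        # gap distance satisfies a triangle-type bound once span of the
        # middle interval is accounted for
        assert interval_distance(a, c) <= (
            interval_distance(a, b) + len(b) + interval_distance(b, c)
        )


class TestAssignPeaksToGenes:
    def test_within_window_assigned(self, toy_annotation):
        # gene gA body starts at 10_000; peak ends 9_500 -> gap 500
        got = assign_peaks_to_genes([peak("chr1", 8_500, 9_500, 1.0)], toy_annotation)
        assert list(got) == ["gA"]

    def test_beyond_window_not_assigned(self):
        ann = GenomeAnnotation(
            {"chr1": 100_000}, [make_gene("g", "chr1", 13_000, 20_000)]
        )
        assert assign_peaks_to_genes([peak("chr1", 1_000, 2_000, 1.0)], ann) == {}

    def test_peak_near_two_genes_assigned_to_both(self):
        ann = GenomeAnnotation(
            {"chr1": 100_000},
            [make_gene("g1", "chr1", 1_000, 5_000), make_gene("g2", "chr1", 12_000, 15_000)],
        )
        got = assign_peaks_to_genes([peak("chr1", 6_000, 7_000, 1.0)], ann)
        assert sorted(got) == ["g1", "g2"]

    def test_window_zero_equals_bruteforce_overlap(self):
        import numpy as np

        rng = np.random.default_rng(5)
        genes = []
        pos = 0
        for i in range(20):
            pos += int(rng.integers(100, 2_000))
            length = int(rng.integers(50, 3_000))
            genes.append(make_gene(f"g{i}", "chr1", pos, pos + length))
            pos += length
        ann = GenomeAnnotation({"chr1": pos + 10_000}, genes)
        peaks = []
        for i in range(100):
            s = int(rng.integers(0, pos))
            peaks.append(peak("chr1", s, s + int(rng.integers(1, 500)), 1.0, f"p{i}"))
        got = assign_peaks_to_genes(peaks, ann, window=0)
        expected = {}
        for g in genes:
            hits = [p for p in peaks if p.interval.overlaps(g.body)]
            if hits:
                expected[g.gene_id] = sorted(
                    hits, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
                )
        assert got == expected


class TestInvariants:
    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(AnnotationError):
            GenomeAnnotation(
                {"chr1": 1_000},
                [make_gene("g", "chr1", 0, 10), make_gene("g", "chr1", 100, 200)],
            )

    def test_gene_past_chromosome_end_rejected(self):
        with pytest.raises(AnnotationError):
            GenomeAnnotation({"chr1": 100}, [make_gene("g", "chr1", 50, 200)])

    def test_overlapping_exons_rejected(self):
        with pytest.raises(AnnotationError):
            make_gene("g", "chr1", 0, 100, exons=[(0, 50), (40, 90)])
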