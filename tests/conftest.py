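import pytest

from uvomics.genome import GeneModel, GenomeAnnotation, Interval, Peak


def make_gene(gene_id, chrom, start, end, strand="+", exons=None, utr5=None, utr3=None):
    return GeneModel(
        gene_id,
        chrom,
        strand,
        Interval(chrom, start, end),
        [Interval(chrom, a, b) for a, b in (exons or [])],
        [Interval(chrom, a, b) for a, b in (utr5 or [])],
        [Interval(chrom, a, b) for a, b in (utr3 or [])],
    )


def peak(chrom, start, end, signal, name=""):
    return Peak(Interval(chrom, start, end), signal, name)


@pytest.fixture
def toy_annotation():
    """Two genes on chr1 (one per strand), one on chr2, wide gaps."""
    genes = [
        make_gene("gA", "chr1", 10_000, 20_000, "+",
                  exons=[(10_000, 12_000), (15_000, 20_000)],
                  utr5=[(10_000, 10_500)], utr3=[(19_500, 20_000)]),
        make_gene("gB", "chr1", 60_000, 70_000, "-",
                  exons=[(60_000, 63_000), (68_000, 70_000)],
                  utr5=[(69_500, 70_000)], utr3=[(60_000, 60_500)]),
        make_gene("gC", "chr2", 5_000, 9_000, "+",
                  exons=[(5_000, 9_000)]),
    ]
    return GenomeAnnotation({"chr1": 200_000, "chr2": 100_000}, genes)
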