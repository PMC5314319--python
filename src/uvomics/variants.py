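"""SNV handling: depth filtering, set intersection, genomic-feature
classification and substitution spectrum.

Variants are single-nucleotide only; indels and multi-allelic records in
input files are skipped with a logged count.  Each variant receives
exactly one genomic-feature category under the precedence

    exon > utr5 > utr3 > intron > upstream1kb > downstream1kb > intergenic

where "exon" means protein-coding exonic sequence outside the UTRs, and
the 1 kb flanks are strand-aware (upstream is 5' of the gene body).
Substitutions are collapsed onto the pyrimidine-rooted representation,
so C>T and G>A count as one class — the classical UV-signature class.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .genome import GenomeAnnotation, GeneModel

log = logging.getLogger(__name__)

BASES = {"A", "C", "G", "T"}
CATEGORIES = (
    "exon",
    "utr5",
    "utr3",
    "intron",
    "upstream1kb",
    "downstream1kb",
    "intergenic",
)
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
SPECTRUM_CLASSES = (
    "C>T/G>A",
    "C>A/G>T",
    "C>G/G>C",
    "T>A/A>T",
    "T>C/A>G",
    "T>G/A>C",
)


@dataclass(frozen=True, order=True)
class Variant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    depth: int = 0

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-SNV alleles {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")
        if self.depth < 0:
            raise ValueError("negative depth")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def substitution_class(self) -> str:
        ref, alt = self.ref, self.alt
        if ref in ("G", "A"):  # fold purine-rooted onto the pyrimidine strand
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        for cls in SPECTRUM_CLASSES:
            if cls.startswith(f"{ref}>{alt}"):
                return cls
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class VariantAnnotation:
    variant: Variant
    category: str
    gene_id: str | None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category}")


def read_variants(path: str) -> list[Variant]:
    """Read SNVs from a VCF (1-based, converted to 0-based) or a TSV.

    TSV input needs columns chrom, pos, ref, alt and optionally depth,
    with 0-based positions.  VCF depth comes from INFO DP when present.
    Non-SNV records are skipped and counted.
    """
    if path.endswith((".tsv", ".txt")):
        df = pd.read_csv(path, sep="\t")
        required = {"chrom", "pos", "ref", "alt"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: TSV needs columns {sorted(required)}")
        depth = df["depth"] if "depth" in df.columns else [0] * len(df)
        return [
            Variant(str(c), int(p), str(r).upper(), str(a).upper(), int(d))
            for c, p, r, a, d in zip(df["chrom"], df["pos"], df["ref"], df["alt"], depth)
        ]
    variants: list[Variant] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(f"{path}:{lineno}: VCF record needs >= 8 columns")
            chrom, pos_s, _, ref, alt = cols[0], cols[1], cols[2], cols[3], cols[4]
            try:
                pos1 = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer POS") from exc
            if len(ref) != 1 or len(alt) != 1 or "," in alt or ref == "." or alt == ".":
                n_skipped += 1
                continue
            depth = 0
            for field in cols[7].split(";"):
                if field.startswith("DP="):
                    depth = int(field[3:])
            variants.append(Variant(chrom, pos1 - 1, ref.upper(), alt.upper(), depth))
    if n_skipped:
        log.info("read_variants(%s): skipped %d non-SNV records", path, n_skipped)
    return variants


def write_variants(variants: list[Variant], path: str, chromosomes: dict[str, int] | None = None) -> None:
    """Write SNVs as a minimal VCF with DP in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom, length in sorted((chromosomes or {}).items()):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants):
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tDP={v.depth}\n"
            )


def filter_by_depth(variants: list[Variant], min_depth: int = 10) -> list[Variant]:
    """Keep variants with depth >= min_depth (depth 10 passes at the default)."""
    return [v for v in variants if v.depth >= min_depth]


def intersect_variant_sets(a: list[Variant], b: list[Variant]) -> list[Variant]:
    """Variants present in both sets; identity is (chrom, pos, ref, alt)."""
    keys_b = {v.key for v in b}
    seen: set[tuple] = set()
    common = []
    for v in a:
        if v.key in keys_b and v.key not in seen:
            seen.add(v.key)
            common.append(v)
    return sorted(common)


def _categorize_in_gene(v: Variant, g: GeneModel) -> str | None:
    """Category of the variant with respect to one gene, or None if unrelated."""
    if g.chrom != v.chrom:
        return None
    if g.body.contains(v.chrom, v.pos):
        for iv in g.utr5:
            if iv.contains(v.chrom, v.pos):
                return "utr5"
        for iv in g.utr3:
            if iv.contains(v.chrom, v.pos):
                return "utr3"
        for iv in g.exons:
            if iv.contains(v.chrom, v.pos):
                return "exon"
        return "intron"
    up = g.upstream_flank(1000)
    if up is not None and up.contains(v.chrom, v.pos):
        return "upstream1kb"
    down = g.downstream_flank(1000)
    if down is not None and down.contains(v.chrom, v.pos):
        return "downstream1kb"
    return None


class VariantClassifier:
    """Interval-indexed classifier over a genome annotation.

    The index holds each gene body padded by the 1 kb flanks, so only
    genes that can possibly categorise a position are examined.
    """

    _FLANK = 1000

    def __init__(self, annotation: GenomeAnnotation) -> None:
        from intervaltree import IntervalTree

        self._trees: dict[str, IntervalTree] = {}
        self._precedence = {c: i for i, c in enumerate(CATEGORIES)}
        for g in annotation.genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                max(g.body.start - self._FLANK, 0), g.body.end + self._FLANK, g
            )

    def classify(self, v: Variant) -> VariantAnnotation:
        best: tuple[int, str, str] | None = None
        tree = self._trees.get(v.chrom)
        for hit in tree.at(v.pos) if tree is not None else ():
            cat = _categorize_in_gene(v, hit.data)
            if cat is None:
                continue
            rank = self._precedence[cat]
            if best is None or rank < best[0] or (rank == best[0] and hit.data.gene_id < best[2]):
                best = (rank, cat, hit.data.gene_id)
        if best is None:
            return VariantAnnotation(v, "intergenic", None)
        return VariantAnnotation(v, best[1], best[2])


def classify_variant(v: Variant, annotation: GenomeAnnotation) -> VariantAnnotation:
    """Assign the single genomic-feature category of one variant.

    When a position relates to several genes (e.g. exon of one, intron
    of another) the highest-precedence category wins and carries that
    gene's identifier; precedence ties go to the lexicographically
    smallest gene id.  For many variants against one annotation, build a
    :class:`VariantClassifier` once instead.
    """
    return VariantClassifier(annotation).classify(v)


def classify_variants(
    variants: list[Variant], annotation: GenomeAnnotation
) -> list[VariantAnnotation]:
    clf = VariantClassifier(annotation)
    return [clf.classify(v) for v in variants]


def category_counts(annotations: list[VariantAnnotation]) -> dict[str, int]:
    counts = Counter(a.category for a in annotations)
    return {c: counts.get(c, 0) for c in CATEGORIES}


def mutation_spectrum(variants: list[Variant]) -> dict[str, int]:
    """Counts per strand-collapsed substitution class; sums to |variants|."""
    counts = Counter(v.substitution_class for v in variants)
    return {c: counts.get(c, 0) for c in SPECTRUM_CLASSES}


def annotation_table(annotations: list[VariantAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": a.variant.chrom,
                "pos": a.variant.pos,
                "ref": a.variant.ref,
                "alt": a.variant.alt,
                "depth": a.variant.depth,
                "category": a.category,
                "gene_id": a.gene_id or "",
                "substitution_class": a.variant.substitution_class,
            }
            for a in annotations
        ]
    )
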