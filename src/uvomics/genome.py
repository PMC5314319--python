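"""Genome annotation model and interval algebra.

All coordinates are 0-based half-open internally.  BED input is native;
GFF3 (1-based, inclusive) and VCF (1-based) are converted at the I/O
boundary.  Chromosome names are matched by exact string equality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

INF_DISTANCE = math.inf


class AnnotationError(ValueError):
    """Raised when an annotation file violates the gene-model invariants."""


@dataclass(frozen=True, order=True)
class Interval:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A scored signal interval (e.g. one H3K27ac MACS peak).

    ``signal`` is the tag-count-derived enrichment value from the BED
    score column; it is consumed as given and never re-quantified.
    """

    interval: Interval
    signal: float
    name: str = ""
    sample: str = ""

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak {self.name or self.interval}: negative signal")


@dataclass
class GeneModel:
    """A gene body with strand, TSS and sub-features.

    The TSS equals the body start on the + strand and ``end - 1`` on the
    - strand.  Exons are stored sorted and non-overlapping; ``exons``
    includes UTR sequence, while UTR intervals are tracked separately so
    that coding-exon vs UTR categories can be distinguished.
    """

    gene_id: str
    chrom: str
    strand: str
    body: Interval
    exons: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        for feats, label in ((self.exons, "exon"), (self.utr5, "5'UTR"), (self.utr3, "3'UTR")):
            for iv in feats:
                if iv.start < self.body.start or iv.end > self.body.end:
                    raise AnnotationError(
                        f"gene {self.gene_id}: {label} {iv.start}-{iv.end} "
                        f"outside gene body {self.body.start}-{self.body.end}"
                    )
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(f"gene {self.gene_id}: overlapping exons")

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1

    def upstream_flank(self, width: int = 1000) -> Interval | None:
        """Strand-aware interval immediately 5' of the gene body."""
        if self.strand == "+":
            start, end = self.body.start - width, self.body.start
        else:
            start, end = self.body.end, self.body.end + width
        start = max(start, 0)
        return Interval(self.chrom, start, end) if start < end else None

    def downstream_flank(self, width: int = 1000) -> Interval | None:
        if self.strand == "+":
            start, end = self.body.end, self.body.end + width
        else:
            start, end = self.body.start - width, self.body.start
        start = max(start, 0)
        return Interval(self.chrom, start, end) if start < end else None


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus gene models; backbone for interval assignment."""

    chromosomes: dict[str, int]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene identifier {g.gene_id}")
            seen.add(g.gene_id)
            if g.chrom in self.chromosomes and g.body.end > self.chromosomes[g.chrom]:
                raise AnnotationError(
                    f"gene {g.gene_id} extends past end of {g.chrom}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def genes_by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: g.body.start)
        return out


# ---------------------------------------------------------------------------
# interval algebra


def interval_distance(a: Interval, b: Interval) -> float:
    """Gap in bp between the nearest ends of two intervals.

    Overlapping or abutting intervals have distance 0.  Intervals on
    different chromosomes are infinitely far apart.
    """
    if a.chrom != b.chrom:
        return INF_DISTANCE
    return float(max(a.start - b.end, b.start - a.end, 0))


def assign_peaks_to_genes(
    peaks: list[Peak],
    annotation: GenomeAnnotation,
    window: int = 10_000,
) -> dict[str, list[Peak]]:
    """Map each gene to the peaks lying within ``window`` bp of its body.

    A peak near several genes is assigned to every one of them; peaks
    near no gene are dropped.  Genes with no peak do not appear in the
    result.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    by_id = {g.gene_id: g for g in annotation.genes}
    trees: dict[str, IntervalTree] = {}
    for g in annotation.genes:
        # query interval expanded by the window; +1 so that a gap of
        # exactly `window` still intersects under half-open semantics
        trees.setdefault(g.chrom, IntervalTree()).addi(
            max(g.body.start - window, 0) - 1, g.body.end + window + 1, g.gene_id
        )
    assigned: dict[str, list[Peak]] = {}
    for p in peaks:
        tree = trees.get(p.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(p.interval.start, p.interval.end):
            gene = by_id[hit.data]
            if interval_distance(p.interval, gene.body) <= window:
                assigned.setdefault(hit.data, []).append(p)
    for lst in assigned.values():
        lst.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return assigned


# ---------------------------------------------------------------------------
# readers / writers

_GFF_COLS = 9


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().rstrip(";").split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gene_annotation(path: str) -> GenomeAnnotation:
    """Read gene models from a GFF3 file.

    Recognised feature types: ``gene``, ``exon``, ``five_prime_UTR``,
    ``three_prime_UTR`` (others are ignored).  GFF3 1-based inclusive
    coordinates are converted to 0-based half-open.  Sub-features attach
    to their gene via the ``Parent`` attribute or, failing that, the
    nearest enclosing gene on the same chromosome.
    """
    chroms: dict[str, int] = {}
    genes: dict[str, GeneModel] = {}
    pending: list[tuple[str, str, Interval, str | None]] = []  # type, chrom, iv, parent
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    if len(parts) >= 4:
                        chroms[parts[1]] = int(parts[3])
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise AnnotationError(
                    f"{path}:{lineno}: expected {_GFF_COLS} tab-separated columns, "
                    f"got {len(cols)}"
                )
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise AnnotationError(f"{path}:{lineno}: bad coordinates {start1}-{end1}")
            iv = Interval(chrom, start1 - 1, end1)
            attrs = _parse_gff_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID") or attrs.get("gene_id")
                if gid is None:
                    raise AnnotationError(f"{path}:{lineno}: gene without ID attribute")
                if gid in genes:
                    raise AnnotationError(f"{path}:{lineno}: duplicate gene {gid}")
                genes[gid] = GeneModel(gid, chrom, strand, iv)
            elif ftype in ("exon", "five_prime_UTR", "three_prime_UTR"):
                pending.append((ftype, chrom, iv, attrs.get("Parent")))
    for ftype, chrom, iv, parent in pending:
        gene = genes.get(parent) if parent else None
        if gene is None:
            for g in genes.values():
                if g.chrom == chrom and g.body.start <= iv.start and iv.end <= g.body.end:
                    gene = g
                    break
        if gene is None:
            raise AnnotationError(
                f"{path}: {ftype} {chrom}:{iv.start}-{iv.end} matches no gene"
            )
        if iv.start < gene.body.start or iv.end > gene.body.end:
            raise AnnotationError(
                f"{path}: {ftype} {chrom}:{iv.start}-{iv.end} outside gene {gene.gene_id}"
            )
        {"exon": gene.exons, "five_prime_UTR": gene.utr5, "three_prime_UTR": gene.utr3}[
            ftype
        ].append(iv)
    models = []
    for g in genes.values():
        # re-validate sub-feature ordering through the constructor
        models.append(
            GeneModel(g.gene_id, g.chrom, g.strand, g.body, g.exons, g.utr5, g.utr3)
        )
        chroms.setdefault(g.chrom, g.body.end)
        chroms[g.chrom] = max(chroms[g.chrom], g.body.end)
    return GenomeAnnotation(chroms, models)


def write_gene_annotation(annotation: GenomeAnnotation, path: str) -> None:
    """Write gene models back to GFF3 (inverse of :func:`read_gene_annotation`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in sorted(annotation.chromosomes.items()):
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.body.start)):
            def row(ftype: str, iv: Interval, attrs: str) -> str:
                return (
                    f"{g.chrom}\tuvomics\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )

            fh.write(row("gene", g.body, f"ID={g.gene_id}"))
            for iv in g.exons:
                fh.write(row("exon", iv, f"Parent={g.gene_id}"))
            for iv in g.utr5:
                fh.write(row("five_prime_UTR", iv, f"Parent={g.gene_id}"))
            for iv in g.utr3:
                fh.write(row("three_prime_UTR", iv, f"Parent={g.gene_id}"))


def read_peaks(path: str, sample: str = "") -> list[Peak]:
    """Read scored peaks from BED4+score (chrom start end name signal).

    Input order is not required to be sorted; the result is sorted by
    (chrom, start, end).  Duplicate lines are retained (and logged).
    """
    peaks: list[Peak] = []
    seen: set[tuple] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(
                    f"{path}:{lineno}: need 5 columns (chrom start end name signal)"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
                signal = float(cols[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            if signal < 0 or math.isnan(signal):
                raise ValueError(f"{path}:{lineno}: invalid signal {cols[4]}")
            key = (cols[0], start, end, signal)
            if key in seen:
                n_dup += 1
            seen.add(key)
            peaks.append(Peak(Interval(cols[0], start, end), signal, cols[3], sample))
    if n_dup:
        log.info("read_peaks(%s): %d duplicate peak lines retained", path, n_dup)
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks


def write_peaks(peaks: list[Peak], path: str) -> None:
    """Write peaks as BED with the signal in column 5."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak_{i + 1}"
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{name}\t{p.signal:g}\n"
            )
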