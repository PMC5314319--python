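"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: a gene
annotation tiled on synthetic chromosomes, paired control/UV H3K27ac
peak sets with planted super-enhancer clusters and differential-
acetylation genes, an expression table with planted differential genes
optionally coupled to the acetylation effects, two somatic SNV sets
with a controlled intersection, category composition and substitution
spectrum, and an shRNA depletion screen with planted skin-lineage
essential genes.  All generators are deterministic given the config
(which carries the seed), and each dataset is accompanied by a ground
truth object sufficient to score any downstream caller.

The geometry is deliberately sparse: genes are separated by wide
intergenic gaps so that enhancer units never stitch across units and
the 1 kb flanks of different genes never collide, which keeps the
planted labels exact.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeAnnotation, Interval, Peak
from .variants import SPECTRUM_CLASSES, Variant, VariantClassifier, _COMPLEMENT

# layout constants: margins chosen so distinct peak units can never
# stitch (12.5 kb rule) nor fall within the 10 kb gene-assignment window
_ENH_MARGIN = 13_000
_ENH_WIDTH = 500
_ENH_SPACING = 14_000
_SE_PEAK_STEP = 4_000


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the default conditions.

    Defaults emulate the study design the pipeline targets: a net
    global loss of H3K27ac (multiplier < 1) with regional gains at the
    planted DHA-up genes, SNV sets of 463 and 417 variants sharing 75,
    a common-variant category composition matching the printed summary
    (26 intronic, 15 exonic, 9 5'-UTR, 2 3'-UTR, 2 upstream, 21
    intergenic of 75), a UV-signature-dominated substitution spectrum,
    and a 500-gene screen with 10 planted skin-essential genes.
    """

    seed: int = 0
    # genome
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 7_000_000 for i in range(1, 5)}
    )
    n_genes: int = 400
    gene_length_range: tuple[int, int] = (7_000, 12_000)
    intergenic_gap_range: tuple[int, int] = (45_000, 60_000)
    utr_length: int = 300
    n_exons: int = 3
    # chip-seq
    n_background_enhancers: int = 500
    n_planted_se_clusters: int = 20
    se_cluster_size: int = 8
    se_signal_multiplier: float = 50.0
    enhancer_log_mean: float = 2.0
    enhancer_log_sd: float = 0.3
    gene_peak_signal_mean: float = 8.0
    gene_peak_log_sd: float = 0.15
    peaks_per_gene: int = 2
    global_uv_signal_multiplier: float = 0.7
    n_dha_up: int = 40
    n_dha_down: int = 40
    dha_effect_log2fc: float = 2.0
    n_se_uv_lost: int = 4
    se_uv_loss_factor: float = 0.02
    chip_noise_sd: float = 0.1
    # expression
    n_dge_up: int = 40
    n_dge_down: int = 40
    dge_effect_log2fc: float = 3.0
    dge_dha_coupling: float = 0.5
    coupled_effect_log2fc: float = 2.0
    expr_baseline_log_mean: float = math.log(50.0)
    expr_baseline_log_sd: float = 1.0
    expr_noise_sd: float = 0.25
    # variants
    n_variants_a: int = 463
    n_variants_b: int = 417
    n_common_variants: int = 75
    category_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "intron": 26 / 75,
            "exon": 15 / 75,
            "utr5": 9 / 75,
            "utr3": 2 / 75,
            "upstream1kb": 2 / 75,
            "downstream1kb": 0.0,
            "intergenic": 21 / 75,
        }
    )
    spectrum_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "C>T/G>A": 0.6,
            "C>A/G>T": 0.08,
            "C>G/G>C": 0.08,
            "T>A/A>T": 0.08,
            "T>C/A>G": 0.08,
            "T>G/A>C": 0.08,
        }
    )
    depth_min: int = 10
    depth_extra_mean: float = 40.0
    # screen
    n_screen_genes: int = 500
    shrnas_per_gene: int = 4
    n_control_shrnas: int = 100
    n_skin_lines: int = 4
    n_nonskin_lines: int = 8
    n_planted_essential: int = 10
    essential_ds_shift: float = -3.0
    shrna_noise_sd: float = 0.5
    between_gene_sd: float = 1.0

    def __post_init__(self) -> None:
        for name, props in (
            ("category_proportions", self.category_proportions),
            ("spectrum_proportions", self.spectrum_proportions),
        ):
            total = sum(props.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must sum to 1 (got {total})")
        if self.n_common_variants > min(self.n_variants_a, self.n_variants_b):
            raise ValueError("overlap larger than a variant set")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

def _stream_rng(seed: int, stream_id: int) -> np.random.Generator:
    """Independent deterministic stream per generator."""
    return np.random.default_rng([seed, stream_id])


@dataclass
class GroundTruth:
    """Planted labels per assay; serialized next to every dataset."""

    dha_up: list[str] = field(default_factory=list)
    dha_down: list[str] = field(default_factory=list)
    dge_up: list[str] = field(default_factory=list)
    dge_down: list[str] = field(default_factory=list)
    coupled_genes: list[str] = field(default_factory=list)
    se_cluster_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    se_uv_lost_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    variant_categories: dict[str, int] = field(default_factory=dict)
    spectrum_counts: dict[str, int] = field(default_factory=dict)
    n_common_variants: int = 0
    essential_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        for key in ("se_cluster_intervals", "se_uv_lost_intervals"):
            data[key] = [tuple(x) for x in data.get(key, [])]
        return cls(**data)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        merged = dataclasses.replace(self)
        for f in dataclasses.fields(other):
            val = getattr(other, f.name)
            if val:
                setattr(merged, f.name, val)
        return merged


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Tile non-overlapping gene models with wide intergenic gaps.

    Each gene gets ``n_exons`` exons with the first/last carrying the
    5'/3' UTR (strand-aware).  Raises when the requested genes cannot
    fit on the configured chromosomes.
    """
    rng = _stream_rng(config.seed, 1)
    chroms = list(config.chromosome_lengths.items())
    genes: list[GeneModel] = []
    ci = 0
    cursor = int(rng.integers(*config.intergenic_gap_range))
    lo, hi = config.gene_length_range
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        while ci < len(chroms) and cursor + length + 1000 > chroms[ci][1]:
            ci += 1
            cursor = int(rng.integers(*config.intergenic_gap_range))
        if ci >= len(chroms):
            raise ValueError(
                f"cannot fit {config.n_genes} genes on the configured chromosomes"
            )
        chrom = chroms[ci][0]
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor
        end = start + length
        genes.append(_build_gene(f"G{i + 1:04d}", chrom, strand, start, end, config))
        cursor = end + int(rng.integers(*config.intergenic_gap_range))
    return GenomeAnnotation(dict(config.chromosome_lengths), genes)


def _build_gene(
    gene_id: str, chrom: str, strand: str, start: int, end: int, config: SimulationConfig
) -> GeneModel:
    length = end - start
    n_exons = config.n_exons
    # equal-width exons separated by equal introns
    exon_w = max(length // (2 * n_exons), config.utr_length + 100)
    step = (length - exon_w) // (n_exons - 1) if n_exons > 1 else 0
    exons = []
    for k in range(n_exons):
        s = start + k * step
        exons.append(Interval(chrom, s, min(s + exon_w, end)))
    u = config.utr_length
    if strand == "+":
        utr5 = [Interval(chrom, start, start + u)]
        utr3 = [Interval(chrom, end - u, end)]
    else:
        utr5 = [Interval(chrom, end - u, end)]
        utr3 = [Interval(chrom, start, start + u)]
    return GeneModel(gene_id, chrom, strand, Interval(chrom, start, end), exons, utr5, utr3)


# ---------------------------------------------------------------------------
# chip-seq


def _intergenic_gaps(annotation: GenomeAnnotation) -> list[tuple[str, int, int]]:
    gaps = []
    by_chrom = annotation.genes_by_chrom()
    for chrom, length in sorted(annotation.chromosomes.items()):
        genes = by_chrom.get(chrom, [])
        prev_end = 0
        for g in genes:
            if g.body.start > prev_end:
                gaps.append((chrom, prev_end, g.body.start))
            prev_end = g.body.end
        if prev_end < length:
            gaps.append((chrom, prev_end, length))
    return gaps


def generate_chipseq_pair(
    config: SimulationConfig, annotation: GenomeAnnotation
) -> tuple[list[Peak], list[Peak], GroundTruth]:
    """Paired control/UV peak sets with planted SE clusters and DHA genes.

    Control signal: per-gene peaks inside gene bodies (for the
    gene-level acetylation statistic), heavy-tailed background
    enhancers in the intergenic gaps (the hockey-stick curve), and
    ``n_planted_se_clusters`` dense high-signal peak runs (the planted
    SEs).  UV signal: control times the global multiplier, with the
    peaks of planted DHA genes additionally scaled by 2**(+-effect),
    then multiplicative log-normal noise on every peak.
    """
    rng = _stream_rng(config.seed, 2)
    truth = GroundTruth()
    gene_ids = [g.gene_id for g in annotation.genes]
    n_planted = config.n_dha_up + config.n_dha_down
    if n_planted > len(gene_ids):
        raise ValueError("more planted DHA genes than genes in the annotation")
    planted = rng.choice(gene_ids, size=n_planted, replace=False)
    truth.dha_up = sorted(map(str, planted[: config.n_dha_up]))
    truth.dha_down = sorted(map(str, planted[config.n_dha_up:]))

    control: list[Peak] = []
    uv_scale: list[float] = []  # extra per-peak multiplier on top of the global one

    # gene-body peaks (placed away from both gene ends so promoter
    # exclusion never removes them)
    for g in annotation.genes:
        body = g.body
        inner_lo, inner_hi = body.start + 3000, body.end - 3000 - _ENH_WIDTH
        if inner_hi <= inner_lo:
            inner_lo, inner_hi = body.start + 1000, max(body.start + 1001, body.end - 1000 - _ENH_WIDTH)
        extra = 1.0
        if g.gene_id in truth.dha_up:
            extra = 2.0**config.dha_effect_log2fc
        elif g.gene_id in truth.dha_down:
            extra = 2.0**-config.dha_effect_log2fc
        for k in range(config.peaks_per_gene):
            pos = int(rng.integers(inner_lo, inner_hi + 1))
            signal = config.gene_peak_signal_mean * float(rng.lognormal(0.0, config.gene_peak_log_sd))
            control.append(
                Peak(Interval(g.chrom, pos, pos + _ENH_WIDTH), signal, f"{g.gene_id}_p{k}")
            )
            uv_scale.append(extra)

    # background enhancers and planted SE clusters in the gaps
    gaps = [g for g in _intergenic_gaps(annotation) if g[2] - g[1] >= 2 * _ENH_MARGIN + _ENH_WIDTH]
    rng.shuffle(gaps)
    se_span = (config.se_cluster_size - 1) * _SE_PEAK_STEP + _ENH_WIDTH
    se_gaps = [g for g in gaps if g[2] - g[1] >= 2 * _ENH_MARGIN + se_span]
    if len(se_gaps) < config.n_planted_se_clusters:
        raise ValueError("not enough intergenic space for the requested SE clusters")
    base_signal = math.exp(config.enhancer_log_mean)
    used = set()
    n_lost = min(config.n_se_uv_lost, config.n_planted_se_clusters)
    lost_idx = set(rng.choice(config.n_planted_se_clusters, size=n_lost, replace=False))
    for ci, (chrom, lo, hi) in enumerate(se_gaps[: config.n_planted_se_clusters]):
        used.add((chrom, lo, hi))
        start = lo + _ENH_MARGIN
        # clusters in lost_idx collapse to near-background level in the UV
        # sample: the mechanism behind the net SE loss after irradiation
        uv_extra = config.se_uv_loss_factor if ci in lost_idx else 1.0
        for k in range(config.se_cluster_size):
            s = start + k * _SE_PEAK_STEP
            signal = config.se_signal_multiplier * base_signal * float(rng.lognormal(0.0, 0.1))
            control.append(Peak(Interval(chrom, s, s + _ENH_WIDTH), signal, f"se_{chrom}_{s}"))
            uv_scale.append(uv_extra)
        truth.se_cluster_intervals.append((chrom, start, start + se_span))
        if ci in lost_idx:
            truth.se_uv_lost_intervals.append((chrom, start, start + se_span))

    slots: list[tuple[str, int]] = []
    for chrom, lo, hi in gaps:
        if (chrom, lo, hi) in used:
            continue
        pos = lo + _ENH_MARGIN
        while pos + _ENH_WIDTH + _ENH_MARGIN <= hi:
            slots.append((chrom, pos))
            pos += _ENH_SPACING
    if len(slots) < config.n_background_enhancers:
        raise ValueError(
            f"only {len(slots)} background-enhancer slots for "
            f"{config.n_background_enhancers} requested"
        )
    take = rng.choice(len(slots), size=config.n_background_enhancers, replace=False)
    for idx in sorted(take):
        chrom, pos = slots[idx]
        signal = float(rng.lognormal(config.enhancer_log_mean, config.enhancer_log_sd))
        control.append(Peak(Interval(chrom, pos, pos + _ENH_WIDTH), signal, f"bg_{chrom}_{pos}"))
        uv_scale.append(1.0)

    order = sorted(range(len(control)), key=lambda i: (
        control[i].interval.chrom, control[i].interval.start))
    control = [control[i] for i in order]
    uv_scale = [uv_scale[i] for i in order]

    noise_c = rng.lognormal(0.0, config.chip_noise_sd, size=len(control)) \
        if config.chip_noise_sd > 0 else np.ones(len(control))
    noise_u = rng.lognormal(0.0, config.chip_noise_sd, size=len(control)) \
        if config.chip_noise_sd > 0 else np.ones(len(control))
    ctrl_out = [
        Peak(p.interval, p.signal * float(noise_c[i]), p.name, "control")
        for i, p in enumerate(control)
    ]
    uv_out = [
        Peak(
            p.interval,
            p.signal * config.global_uv_signal_multiplier * uv_scale[i] * float(noise_u[i]),
            p.name,
            "uv",
        )
        for i, p in enumerate(control)
    ]
    return ctrl_out, uv_out, truth


# ---------------------------------------------------------------------------
# expression


def generate_expression_pair(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    chip_truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Expression table with planted DGE genes and optional DHA coupling.

    Baseline expression is log-normal; planted DGE genes get a
    2**(+-effect) shift, and a ``dge_dha_coupling`` fraction of the
    planted DHA genes (when chip ground truth is given) get a coupled
    expression shift in the same direction, which is what makes the
    acetylation-bin group-shift test significant by construction.
    """
    rng = _stream_rng(config.seed, 3)
    truth = GroundTruth()
    gene_ids = [g.gene_id for g in annotation.genes]
    excluded = set()
    if chip_truth is not None:
        excluded = set(chip_truth.dha_up) | set(chip_truth.dha_down)
    free = [g for g in gene_ids if g not in excluded]
    n_planted = config.n_dge_up + config.n_dge_down
    if n_planted > len(free):
        raise ValueError("more planted DGE genes than available genes")
    planted = rng.choice(free, size=n_planted, replace=False)
    truth.dge_up = sorted(map(str, planted[: config.n_dge_up]))
    truth.dge_down = sorted(map(str, planted[config.n_dge_up:]))

    shifts = {g: config.dge_effect_log2fc for g in truth.dge_up}
    shifts.update({g: -config.dge_effect_log2fc for g in truth.dge_down})
    if chip_truth is not None and config.dge_dha_coupling > 0:
        for group, sign in ((chip_truth.dha_up, 1.0), (chip_truth.dha_down, -1.0)):
            k = int(round(config.dge_dha_coupling * len(group)))
            coupled = rng.choice(group, size=k, replace=False) if k else []
            for g in coupled:
                shifts[str(g)] = sign * config.coupled_effect_log2fc
                truth.coupled_genes.append(str(g))
        truth.coupled_genes.sort()

    base = rng.lognormal(config.expr_baseline_log_mean, config.expr_baseline_log_sd,
                         size=len(gene_ids))
    noise = rng.normal(0.0, config.expr_noise_sd, size=len(gene_ids)) \
        if config.expr_noise_sd > 0 else np.zeros(len(gene_ids))
    rows = []
    for i, g in enumerate(gene_ids):
        log2fc = shifts.get(g, 0.0) + noise[i]
        rows.append(
            {"gene_id": g, "expr_control": float(base[i]),
             "expr_uv": float(base[i] * 2.0**log2fc)}
        )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# variants


def _category_pools(annotation: GenomeAnnotation) -> dict[str, list[Interval]]:
    """Candidate intervals per genomic-feature category."""

    def subtract(iv: Interval, cuts: list[Interval]) -> list[Interval]:
        pieces = [iv]
        for cut in cuts:
            nxt = []
            for p in pieces:
                if cut.end <= p.start or cut.start >= p.end:
                    nxt.append(p)
                    continue
                if cut.start > p.start:
                    nxt.append(Interval(p.chrom, p.start, cut.start))
                if cut.end < p.end:
                    nxt.append(Interval(p.chrom, cut.end, p.end))
            pieces = nxt
        return pieces

    pools: dict[str, list[Interval]] = {c: [] for c in
                                        ("exon", "utr5", "utr3", "intron",
                                         "upstream1kb", "downstream1kb", "intergenic")}
    for g in annotation.genes:
        pools["utr5"].extend(g.utr5)
        pools["utr3"].extend(g.utr3)
        for ex in g.exons:
            pools["exon"].extend(subtract(ex, g.utr5 + g.utr3))
        pools["intron"].extend(subtract(g.body, g.exons))
        up = g.upstream_flank(1000)
        if up:
            pools["upstream1kb"].append(up)
        down = g.downstream_flank(1000)
        if down:
            pools["downstream1kb"].append(down)
    padded = sorted(
        (Interval(g.chrom, max(g.body.start - 1001, 0), g.body.end + 1001)
         for g in annotation.genes),
        key=lambda iv: (iv.chrom, iv.start),
    )
    by_chrom: dict[str, list[Interval]] = {}
    for iv in padded:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, length in sorted(annotation.chromosomes.items()):
        prev = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > prev:
                pools["intergenic"].append(Interval(chrom, prev, iv.start))
            prev = max(prev, iv.end)
        if prev < length:
            pools["intergenic"].append(Interval(chrom, prev, length))
    return pools


def _quota(props: dict[str, float], n: int, order: tuple[str, ...]) -> dict[str, int]:
    """Largest-remainder integer quotas summing exactly to n."""
    raw = {c: props.get(c, 0.0) * n for c in order}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    remainder = n - sum(counts.values())
    for c in sorted(order, key=lambda c: raw[c] - counts[c], reverse=True)[:remainder]:
        counts[c] += 1
    return counts


def generate_variant_sets(
    config: SimulationConfig, annotation: GenomeAnnotation
) -> tuple[list[Variant], list[Variant], GroundTruth]:
    """Two SNV sets sharing exactly ``n_common_variants`` variants.

    Genomic-feature categories follow ``category_proportions`` by exact
    largest-remainder quota within each of the three groups (common,
    unique to A, unique to B); every sampled position is verified
    against the classifier so the planted label is never ambiguous.
    Substitution classes are drawn from ``spectrum_proportions`` with a
    random strand orientation; depths are depth_min + Poisson.
    """
    rng = _stream_rng(config.seed, 4)
    pools = _category_pools(annotation)
    clf = VariantClassifier(annotation)
    order = tuple(config.category_proportions.keys())
    used_positions: set[tuple[str, int]] = set()

    def sample_variants(n: int) -> list[Variant]:
        quotas = _quota(config.category_proportions, n, order)
        classes = list(config.spectrum_proportions.keys())
        class_p = np.array([config.spectrum_proportions[c] for c in classes])
        out = []
        for cat, k in quotas.items():
            pool = pools[cat]
            if k > 0 and not pool:
                raise ValueError(f"no genomic regions available for category {cat!r}")
            weights = np.array([len(iv) for iv in pool], dtype=float)
            weights /= weights.sum() if pool else 1.0
            made = 0
            attempts = 0
            while made < k:
                attempts += 1
                if attempts > 1000 * k + 1000:
                    raise ValueError(f"cannot place {k} variants in category {cat!r}")
                iv = pool[int(rng.choice(len(pool), p=weights))]
                pos = int(rng.integers(iv.start, iv.end))
                if (iv.chrom, pos) in used_positions:
                    continue
                cls = classes[int(rng.choice(len(classes), p=class_p))]
                pyr, rest = cls.split("/")[0].split(">")
                ref, alt = (pyr, rest) if rng.random() < 0.5 else (
                    _COMPLEMENT[pyr], _COMPLEMENT[rest])
                v = Variant(iv.chrom, pos, ref, alt,
                            config.depth_min + int(rng.poisson(config.depth_extra_mean)))
                if clf.classify(v).category != cat:
                    continue
                used_positions.add((iv.chrom, pos))
                out.append(v)
                made += 1
        return out

    common = sample_variants(config.n_common_variants)
    only_a = sample_variants(config.n_variants_a - config.n_common_variants)
    only_b = sample_variants(config.n_variants_b - config.n_common_variants)
    set_a = sorted(common + only_a)
    set_b = sorted(common + only_b)
    truth = GroundTruth(
        variant_categories=_quota(config.category_proportions,
                                  config.n_common_variants, order),
        spectrum_counts={c: sum(v.substitution_class == c for v in set_a + only_b)
                         for c in SPECTRUM_CLASSES},
        n_common_variants=config.n_common_variants,
    )
    return set_a, set_b, truth


# ---------------------------------------------------------------------------
# screen


def generate_screen(config: SimulationConfig):
    """shRNA depletion screen with planted skin-essential genes.

    Each gene carries a shared per-gene baseline (between_gene_sd) so
    its shRNAs are mutually consistent, plus per-shRNA noise; planted
    essential genes get ``essential_ds_shift`` added in skin lines
    only; negative-control shRNAs sit at DS ~ 0.  Returns
    (ScreenMatrix, GroundTruth).
    """
    from .essentiality import ScreenMatrix

    rng = _stream_rng(config.seed, 5)
    genes = [f"ACH{i + 1:04d}" for i in range(config.n_screen_genes)]
    essential = sorted(map(str, rng.choice(genes, size=config.n_planted_essential,
                                           replace=False)))
    lines = [f"SKIN{i + 1}" for i in range(config.n_skin_lines)] + [
        f"LINE{i + 1}" for i in range(config.n_nonskin_lines)
    ]
    lineage = {c: ("skin" if c.startswith("SKIN") else "non-skin") for c in lines}

    shrnas, mapping, control_flags = [], {}, {}
    for g in genes:
        for k in range(config.shrnas_per_gene):
            name = f"sh_{g}_{k + 1}"
            shrnas.append(name)
            mapping[name] = g
            control_flags[name] = False
    for k in range(config.n_control_shrnas):
        name = f"ctrl_{k + 1}"
        shrnas.append(name)
        control_flags[name] = True

    n_shrna, n_lines = len(shrnas), len(lines)
    baseline = rng.normal(0.0, config.between_gene_sd, size=config.n_screen_genes)
    ds = np.zeros((n_shrna, n_lines))
    essential_set = set(essential)
    row = 0
    for gi, g in enumerate(genes):
        gene_level = np.full(n_lines, baseline[gi])
        if g in essential_set:
            for li, line in enumerate(lines):
                if lineage[line] == "skin":
                    gene_level[li] += config.essential_ds_shift
        for _ in range(config.shrnas_per_gene):
            ds[row] = gene_level + rng.normal(0.0, config.shrna_noise_sd, size=n_lines)
            row += 1
    for _ in range(config.n_control_shrnas):
        ds[row] = rng.normal(0.0, config.shrna_noise_sd, size=n_lines)
        row += 1

    matrix = pd.DataFrame(ds, index=shrnas, columns=lines)
    screen = ScreenMatrix(matrix, mapping, control_flags, lineage)
    truth = GroundTruth(essential_genes=essential)
    return screen, truth


# ---------------------------------------------------------------------------
# disk output


def write_screen(screen, directory: str) -> None:
    """Write a ScreenMatrix as the three TSVs the readers accept."""
    import os

    os.makedirs(directory, exist_ok=True)
    screen.ds.rename_axis("shrna").to_csv(os.path.join(directory, "ds.tsv"), sep="\t")
    pd.DataFrame(
        {
            "shrna": list(screen.ds.index),
            "gene_id": [screen.shrna_to_gene.get(s, "") for s in screen.ds.index],
            "is_negative_control": [int(screen.is_negative_control.get(s, False))
                                    for s in screen.ds.index],
        }
    ).to_csv(os.path.join(directory, "shrna_map.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {"cell_line": list(screen.ds.columns),
         "lineage": [screen.lineage[c] for c in screen.ds.columns]}
    ).to_csv(os.path.join(directory, "lineage.tsv"), sep="\t", index=False)


def read_screen(directory: str):
    """Read back the screen TSVs written by :func:`write_screen`."""
    import os

    from .essentiality import ScreenMatrix

    ds = pd.read_csv(os.path.join(directory, "ds.tsv"), sep="\t", index_col="shrna")
    smap = pd.read_csv(os.path.join(directory, "shrna_map.tsv"), sep="\t",
                       keep_default_na=False)
    lin = pd.read_csv(os.path.join(directory, "lineage.tsv"), sep="\t")
    mapping = {r.shrna: r.gene_id for r in smap.itertuples() if r.gene_id}
    controls = {r.shrna: bool(r.is_negative_control) for r in smap.itertuples()}
    lineage = {r.cell_line: r.lineage for r in lin.itertuples()}
    return ScreenMatrix(ds, mapping, controls, lineage)


def simulate_all(config: SimulationConfig, out_dir: str) -> GroundTruth:
    """Generate every pipeline input into a directory; returns merged truth."""
    import os

    from .genome import write_gene_annotation, write_peaks
    from .variants import write_variants

    os.makedirs(out_dir, exist_ok=True)
    annotation = generate_annotation(config)
    write_gene_annotation(annotation, os.path.join(out_dir, "genes.gff3"))
    ctrl, uv, chip_truth = generate_chipseq_pair(config, annotation)
    write_peaks(ctrl, os.path.join(out_dir, "control.bed"))
    write_peaks(uv, os.path.join(out_dir, "uv.bed"))
    expr, expr_truth = generate_expression_pair(config, annotation, chip_truth)
    expr.to_csv(os.path.join(out_dir, "expression.tsv"), sep="\t", index=False)
    va, vb, var_truth = generate_variant_sets(config, annotation)
    write_variants(va, os.path.join(out_dir, "variants_4h.vcf"), annotation.chromosomes)
    write_variants(vb, os.path.join(out_dir, "variants_72h.vcf"), annotation.chromosomes)
    screen, screen_truth = generate_screen(config)
    write_screen(screen, os.path.join(out_dir, "screen"))
    truth = chip_truth.merge(expr_truth).merge(var_truth).merge(screen_truth)
    truth.to_json(os.path.join(out_dir, "truth.json"))
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True, default=str)
    return truth
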