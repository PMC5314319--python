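# Methods

This note documents the models and procedures uvomics implements, the
parameters that matter, the design choices made where the design was
genuinely open, what the synthetic-data generators do and do not
emulate, and known limitations.

## Coordinate and interval conventions

All internal coordinates are 0-based half-open. BED input is native;
GFF3 (1-based inclusive) and VCF (1-based) are converted at the I/O
boundary. Distance between intervals is the gap between nearest ends:
overlapping or abutting intervals have distance 0, intervals on
different chromosomes are infinitely distant. Chromosome names match by
exact string equality — no "chr" aliasing. A peak lying within the
assignment window of several genes is assigned to all of them;
duplication is resolved at the gene level, never by picking one gene
per peak.

## Differential H3K27 acetylation

For each gene, the DHA statistic is the fold change of the mean signal
of assigned peaks (window 10 kb from the gene body) between the UV and
control samples, with a pseudocount ε = 1 on both means so the ratio is
defined when a gene has peaks in only one condition. Classes use strict
inequalities (up: FC > 2; down: FC < 0.5); a gene at exactly the cutoff
is unclassified. Peak signal is taken from the BED score column as
given — whether that score is a height or an area is a property of the
upstream peak caller, not re-derived here.

The genome-wide trend statistic is the through-origin least-squares
slope β = Σxy/Σx² of UV tag signal on control tag signal over *merged
peak regions* (the union of both samples' peak intervals, with each
sample's signal summed per merged region). Through-origin regression is
used because the quantity of interest is a global scaling factor; a
slope below 1 is a net loss of the mark. An all-zero control vector is
an error.

## Super-enhancer calling

The procedure is the classical rank-ordering approach on constituent
enhancers:

1. **Promoter exclusion** removes every peak overlapping
   [TSS − w, TSS + w) for any gene, w = 2,500 bp by default. The width
   is configurable; 2.5 kb is the convention of rank-ordering SE
   pipelines.
2. **Stitching** merges consecutive peaks whose gap is ≤ 12,500 bp,
   taken to transitive closure per chromosome; a stitched enhancer's
   signal is the sum over constituents (no input-track subtraction — no
   input chromatin is in scope).
3. **Cutoff.** Signals are sorted ascending; rank and signal are
   min–max scaled to [0, 1]; the cutoff index is argmax(x̂ᵢ − ŷᵢ), the
   point of maximal depth below the diagonal. On a convex curve this is
   exactly where the tangent slope passes 1, but unlike a
   tangent-slope search it is well defined on any curve, exact, and
   checkable against an exhaustive scan. Ties in depth take the
   smallest index; SE membership is *strictly* above the cutoff signal,
   so the transition-point enhancer itself is not an SE. A constant
   signal vector has no transition point (error); an exactly linear
   curve yields zero depth everywhere and is flagged with a
   degenerate-curve warning.

Genes are SE-associated when the gene body lies within 25 kb of the SE
boundary (not its center). Two SE sets are compared by interval
overlap: an SE is "common" when it overlaps ≥ 1 bp of any SE in the
other set (configurable), so common counts may differ between the two
sides when one SE spans several on the other side.

## Expression classification and integration

Expression input is a normalized per-gene table (control, UV); the same
pseudocounted strict fold-change rule classifies DGE. The integration
statistics follow the three-bin design: genes are grouped by
acetylation log₂FC into (> 1), (< −1) and the middle bin, with values
exactly at ±1 falling in the middle bin (strict inequalities,
documented and tested). Each outer bin's expression log₂FC values are
compared with the middle bin by a two-sided two-sample Student t-test
(equal variances pooled; Welch available by flag). Class concordance is
a 3×3 contingency table; (up, up) and (down, down) are positive
couplings, (up, down) and (down, up) inverse ones.

A replicate-based differential-expression model (e.g. negative
binomial) is deliberately out of scope: the two-sample design has no
replicate structure to re-model. An externally computed p-value column
is accepted for additional filtering when available.

## Enrichment statistics

The gene-set score is the classical *unweighted* Kolmogorov–Smirnov
statistic on the ranked list: the maximal deviation between the
empirical CDFs of member and non-member genes, signed positive when the
set concentrates at the top. It depends only on rank positions, so any
monotone transformation of the ranking metric leaves it unchanged. The
permutation null reshuffles gene labels (set size preserved) with a
seeded generator and uses the add-one estimator
p = (1 + #{null ≥ observed}) / (n_perm + 1), bounded below by
1/(n_perm + 1) and above by 1. The one-sided comparison is on the
signed score; to test depletion, rank the list in the opposite
direction (an explicit flag — the direction is never guessed).

Pathway over-representation uses the exact hypergeometric upper tail
P(X ≥ k) with X ~ Hypergeom(|universe|, |pathway|, |query|), multiplied
by the number of pathways tested (Bonferroni, capped at 1). Pathway
collections are user input in GMT format; no database content ships
with the package.

## Essentiality calling

The two-stage caller follows the pooled-screen convention:

1. **Normalization** (when raw counts are supplied):
   DS = log₂(reads/total × 10⁶) + 1 per replicate; zero counts are
   offset by +0.5 reads (logged) so the log is defined.
2. **Control centering** subtracts, per sample, the median DS of the
   negative-control shRNAs; the centered control median is 0 in every
   sample and the operation is idempotent.
3. **Consistency filter.** For each gene with ≥ 2 shRNAs, the pairwise
   absolute DS differences among its shRNAs (per sample, pooled over
   samples) are compared against the pairwise differences of *all*
   shRNAs by a one-sided rank-sum test (within-gene smaller). "Pairwise
   DS" is read as pairwise differences — a dispersion statement, which
   is what "significantly similar" means — rather than pooled raw DS
   values; the alternative reading is exposed as a flag. The null pool
   is subsampled to ≤ 10⁵ pairs with a seeded generator (exact when
   smaller); the depletion matrix is canonically sorted first so
   results are invariant to input row/column order. Genes pass at
   p < 0.1. Because the within-gene pairwise differences are mutually
   correlated (m shRNAs give m(m−1)/2 dependent pairs), the null pass
   rate at the 0.1 threshold runs above nominal (≈ 0.17 in a fully
   exchangeable screen); the filter is a screening heuristic, not a
   calibrated test, and is used here exactly as specified.
4. **Gene collapse:** per-line median DS over the gene's shRNAs, for
   passing genes only.
5. **Skin specificity:** one-sided rank-sum test per gene that DS is
   lower in skin-lineage lines than in the rest, exact null
   distribution for ≤ 30 lines, flagged at p < 0.05. One-sidedness
   means a gene *less* depleted in skin lines can never be flagged.

No multiple-testing adjustment is applied in either stage, matching the
raw 0.1/0.05 thresholds of the procedure; a Benjamini–Hochberg column
can be added downstream by the user.

## Synthetic-data generators

Every generator is deterministic given (config, seed) and writes ground
truth alongside the data. Default scales (4 × 7 Mb chromosomes, 400
genes, 500 background enhancers, 20 planted SE clusters, 500-gene
screen with 12 lines) generate in seconds and keep the full test suite
and the acceptance script within minutes on one CPU.

* **Annotation:** non-overlapping genes (7–12 kb, three exons,
  300 bp UTRs at the transcript ends, random strand) tiled with
  45–60 kb intergenic gaps. The wide gaps are deliberate: they
  guarantee that enhancer units never stitch across units, that 1 kb
  flanks of different genes never collide, and that every planted
  variant category is unambiguous.
* **ChIP-seq pair:** two peaks per gene body (placed ≥ 3 kb from the
  gene ends so promoter exclusion never removes them), log-normal
  background enhancers in the gaps, and planted SE clusters of 8 peaks
  at 4 kb spacing with per-peak signal 50× the background median. The
  UV sample is the control times a global multiplier (default 0.7, the
  net-loss condition), with planted DHA genes' peaks further scaled by
  2^±2 and a subset of planted SE clusters (default 4) collapsed to
  near-background level — the mechanism behind the net SE loss, since
  a uniform multiplier alone cannot change SE counts (the cutoff is
  scale-invariant). Background dispersion (log-sd 0.3; gene peaks
  0.15) is kept moderate on purpose: at desk scale (~900 stitched
  enhancers) a heavy-tailed background throws single-peak outliers
  whose signal is indistinguishable from a planted cluster, which
  would make "planted truth" ill-defined. Real rank curves are smooth
  for a different reason — their n is two orders of magnitude larger.
* **Expression pair:** log-normal baseline, planted DGE genes at
  2^±3, and a configurable fraction (default 0.5) of the planted DHA
  genes receiving coupled expression shifts of 2^±2 in the same
  direction. Coupling 1 makes the bin-shift test extreme by
  construction; coupling 0 is the calibration null.
* **Variant sets:** categories are planted by exact largest-remainder
  quota within each group (shared, unique-to-A, unique-to-B) and every
  sampled position is verified against the classifier, so planted
  labels are exact, not approximate. Default composition mirrors the
  published shared-SNV summary (26 intronic, 15 exonic, 9 5′-UTR, 2
  3′-UTR, 2 upstream, 21 intergenic of 75) and a 60 % C>T/G>A
  spectrum. Depths are 10 + Poisson(40), i.e. post-filter by default.
* **Screen:** each gene carries a shared N(0, 1) baseline so its
  shRNAs are mutually consistent, plus N(0, 0.5) per-shRNA noise;
  planted essential genes get −3 added in skin lines only; 100
  negative-control shRNAs sit at DS ≈ 0. The control count matters:
  centering subtracts a per-sample control median whose sampling noise
  is shared by every gene in that sample, so with few controls the
  null flag rate of the specificity test becomes overdispersed across
  screens. With 100 controls the centering noise (≈ 0.06 per line) is
  small against the per-line gene-DS noise (≈ 0.3).

What the generators do **not** emulate: read-level data (no FASTQ/BAM),
mappability and GC structure, peak-calling artifacts, overlapping or
nested real gene models, copy-number confounding of screen data, and
the correlated biological replicate structure of real cohorts. Passing
tests therefore demonstrate correctness and calibration of the
*computations* under controlled conditions, not robustness to the full
messiness of real sequencing data.

## Numerical choices

* Strict inequalities at every threshold (FC cutoffs, log₂FC bin
  edges, SE cutoff, p-value thresholds); boundary cases are tested.
* Pseudocount ε = 1 for both fold-change statistics; the ε → 0 limit
  restores exact scale equivariance of log₂FC (tested at ε = 10⁻⁹).
* The SE cutoff resolves depth ties to the smallest index.
* Rank-sum tests use the exact null distribution whenever the combined
  sample is ≤ 30 (ties are rare on continuous scores and the exact
  method ignores them); the asymptotic form with tie correction
  otherwise.
* Permutation p-values are add-one estimators and can never be 0.
* Every stochastic routine takes an explicit seed and echoes it in its
  output.

## Known limitations

* SE "identity" across samples is overlap-based; a reciprocal-fraction
  rule is available but no tracking of SE boundaries over time is
  attempted.
* The consistency filter's null is shared across genes and subsampled;
  two screens of very different size can have slightly different
  filter stringency.
* Variant classification precedence (exon first across overlapping
  genes, UTRs before coding exon within a gene) is a convention;
  printed category totals from other pipelines may use another.
* The gene-level acetylation statistic averages peak signal as given;
  no length normalization or input subtraction is performed.
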