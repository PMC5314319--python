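# uvomics

Integrative analysis of how ultraviolet radiation (UVR) dysregulates
the genome, epigenome and transcriptome of human keratinocytes — and of
which UV target genes matter for skin cancer cell survival.

The package re-implements, as a tested and reusable library, the
computational core of a multi-omics UV study design:

* **Differential H3K27 acetylation (DHA).** H3K27ac ChIP-seq peaks are
  assigned to every gene within 10 kb of the gene body; the per-gene
  statistic is the fold change of mean assigned-peak signal,
  FC = (s̄(UV) + ε) / (s̄(ctrl) + ε), classed *up* if FC > 2 and *down*
  if FC < 0.5. The genome-wide trend is the through-origin regression
  slope of UV on control tag signal over merged peak regions (slope < 1
  ⇒ net loss of the mark).
* **Super-enhancer (SE) calling.** Promoter peaks (±2.5 kb of a TSS)
  are excluded, constituent enhancers within 12.5 kb are stitched, and
  stitched enhancers are ranked by total signal. On the min–max-scaled
  rank/signal curve the cutoff is the transition point
  i\* = argmax(x̂ᵢ − ŷᵢ) — the deepest point below the diagonal, where
  the tangent slope passes 1; enhancers above it are SEs. Genes within
  25 kb of an SE are SE-associated; SE sets from two samples are
  compared by interval overlap.
* **DGE × DHA integration.** Expression fold changes use the same
  strict FC > 2 / < 0.5 rule; genes are binned by acetylation log₂FC
  (> 1, < −1, between), the expression log₂FC of the outer bins is
  tested against the middle bin with a two-sample Student t-test, and a
  3×3 DGE-class × DHA-class concordance matrix separates positive from
  inverse couplings.
* **Enrichment statistics.** Unweighted Kolmogorov–Smirnov gene-set
  enrichment, ES = max |F_set − F_complement| (signed), with
  gene-shuffling permutation p-values p = (1 + #{ES_null ≥ ES}) /
  (n_perm + 1); and hypergeometric pathway over-representation,
  p = P(X ≥ k), Bonferroni-adjusted.
* **SNV profiling.** Somatic single-nucleotide variants are
  depth-filtered (≥ 10 reads), intersected across timepoints by
  (chrom, pos, ref, alt), classified into one genomic-feature category
  (exon > 5′UTR > 3′UTR > intron > 1 kb up/downstream > intergenic) and
  folded into the six pyrimidine-rooted substitution classes (C>T/G>A
  is the UV signature).
* **shRNA essentiality.** Depletion scores DS = log₂(CPM) + 1 are
  centered on the per-sample median of negative-control shRNAs; genes
  whose shRNAs score consistently (one-sided rank-sum of within-gene
  pairwise |ΔDS| against the all-shRNA pairwise null, p < 0.1) are
  collapsed to per-line median DS; skin-specific essential genes have
  significantly lower DS in skin-lineage lines (one-sided rank-sum,
  p < 0.05).
* **Synthetic data.** Seeded generators produce every input with
  planted ground truth — SE clusters, acetylation and expression
  effects with tunable coupling, variant sets with controlled overlap,
  category and spectrum composition, and screens with planted
  lineage-specific essential genes — so each caller's sensitivity and
  calibration are measurable without any external download.

## Worked example

```sh
python examples/03_variant_profiling.py
```

```
SNVs at 4 h: 463, at 72 h: 417, common: 75
common SNVs within or near genes: 54
  exon           15
  utr5           9
  utr3           2
  intron         26
  upstream1kb    2
  intergenic     21
substitution spectrum at 4 h (strand-collapsed):
  C>T/G>A    289  (62.4%)
  ...
```

Two simulated timepoint variant sets (463 and 417 SNVs) share exactly
75 variants; of those, 54 fall within or near genes (26 in introns, 15
in exons, 9 in the 5′-UTR, 2 in the 3′-UTR, 2 within 1 kb upstream) and
21 are intergenic, and the spectrum is dominated by the C>T/G>A UV
signature. The other examples cover SE calling
(`01_superenhancer_calling.py`: 5/5 planted SEs recovered from 185
stitched enhancers), acetylation/expression integration
(`02_dha_dge_integration.py`: slope 0.550, bin-shift p ≈ 3 × 10⁻¹⁵),
the essentiality caller (`04_essentiality_screen.py`: 10/10 planted
genes recovered at a 1.6 % false-positive rate) and the end-to-end
pipeline (`05_full_pipeline.py`).

A thin CLI wraps the same functions:

```sh
uvomics simulate --out sim --seed 5
uvomics run-all --input-dir sim --out results --seed 5
uvomics se --peaks sim/control.bed --genes sim/genes.gff3
```

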