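"""shRNA depletion-screen essentiality scoring.

The pipeline mirrors the classical pooled-screen analysis of
genome-wide shRNA depletion data:

1. normalize raw read counts per replicate to log2 counts-per-million
   plus one (the depletion score, DS);
2. center each sample by subtracting the median DS of its
   negative-control shRNAs (non-human targets such as luciferase, GFP,
   RFP, LacZ);
3. keep genes whose shRNAs behave consistently: the pairwise absolute
   DS differences among a gene's shRNAs are compared, one-sided
   rank-sum, against the pairwise differences of all shRNAs (the null),
   and the gene passes when they are significantly smaller (p < 0.1);
4. collapse passing genes to a gene x cell-line DS matrix by the
   per-line median over the gene's shRNAs;
5. flag skin-specific essential genes: one-sided rank-sum test that the
   gene-level DS is lower in skin-lineage lines than in the others
   (p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CONSISTENCY_ALPHA = 0.1
SPECIFICITY_ALPHA = 0.05
MAX_NULL_PAIRS = 100_000


@dataclass
class ScreenMatrix:
    """shRNA x cell-line depletion scores with screen metadata.

    ``ds`` rows are shRNAs, columns cell lines.  Every non-control
    shRNA maps to exactly one gene; each sample must include at least
    one negative-control shRNA.  ``lineage`` labels lines as
    "skin" / "non-skin".
    """

    ds: pd.DataFrame
    shrna_to_gene: dict[str, str]
    is_negative_control: dict[str, bool]
    lineage: dict[str, str]

    def __post_init__(self) -> None:
        for shrna in self.ds.index:
            if self.is_negative_control.get(shrna, False):
                continue
            if shrna not in self.shrna_to_gene:
                raise ValueError(f"shRNA {shrna} has no gene mapping and is not a control")
        if not any(self.is_negative_control.get(s, False) for s in self.ds.index):
            raise ValueError("screen has no negative-control shRNAs")
        for line in self.ds.columns:
            if self.lineage.get(line) not in ("skin", "non-skin"):
                raise ValueError(f"cell line {line} lacks a skin/non-skin lineage label")

    @property
    def control_shrnas(self) -> list[str]:
        return [s for s in self.ds.index if self.is_negative_control.get(s, False)]

    @property
    def gene_shrnas(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.ds.index:
            if not self.is_negative_control.get(s, False):
                out.setdefault(self.shrna_to_gene[s], []).append(s)
        return out


@dataclass
class GeneEssentiality:
    gene_id: str
    consistency_p: float
    gene_ds: pd.Series | None  # per-line median DS, present iff consistency passes
    specificity_p: float = float("nan")
    skin_specific: bool = False
    untestable: bool = False


def normalize_shrna(raw_reads: pd.DataFrame, zero_offset: float = 0.5) -> pd.DataFrame:
    """Depletion score from raw counts: log2(CPM) + 1 per replicate column.

    Zero counts are offset by ``zero_offset`` reads before the CPM so
    the logarithm is defined; affected cells are logged.
    """
    if (raw_reads < 0).any().any():
        raise ValueError("negative raw read count")
    totals = raw_reads.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero total read count in replicate(s) {bad}")
    n_zero = int((raw_reads == 0).sum().sum())
    if n_zero:
        log.info("normalize_shrna: %d zero counts offset by +%g reads", n_zero, zero_offset)
    counts = raw_reads.where(raw_reads > 0, zero_offset)
    cpm = counts.div(totals, axis=1) * 1e6
    return np.log2(cpm) + 1


def center_by_controls(ds: pd.DataFrame, is_negative_control: dict[str, bool]) -> pd.DataFrame:
    """Subtract, per sample, the median DS of the negative-control shRNAs."""
    controls = [s for s in ds.index if is_negative_control.get(s, False)]
    if not controls:
        raise ValueError("no negative-control shRNAs present")
    medians = ds.loc[controls].median(axis=0)
    if medians.isna().any():
        bad = medians.index[medians.isna()].tolist()
        raise ValueError(f"no control values in sample(s) {bad}")
    return ds.sub(medians, axis=1)


def _pairwise_abs_diffs(values: np.ndarray) -> np.ndarray:
    """All |x_i - x_j| for i < j along the first axis, per column, flattened."""
    n = values.shape[0]
    i, j = np.triu_indices(n, k=1)
    return np.abs(values[i] - values[j]).ravel()


def sample_null_pair_diffs(
    ds: pd.DataFrame,
    max_pairs: int = MAX_NULL_PAIRS,
    seed: int = 0,
) -> np.ndarray:
    """Pairwise absolute DS differences over all shRNA pairs, per sample.

    The complete pool has C(n_shRNA, 2) x n_samples values; when that
    exceeds ``max_pairs`` a seeded uniform subsample of pairs is drawn,
    otherwise the pool is exact.
    """
    values = ds.to_numpy(dtype=float)
    n, m = values.shape
    total_pairs = n * (n - 1) // 2
    if total_pairs * m <= max_pairs:
        return _pairwise_abs_diffs(values)
    rng = np.random.default_rng(seed)
    k = max_pairs
    i = rng.integers(0, n, size=2 * k)
    j = rng.integers(0, n, size=2 * k)
    keep = i != j
    i, j = i[keep][:k], j[keep][:k]
    cols = rng.integers(0, m, size=i.size)
    return np.abs(values[i, cols] - values[j, cols])


def gene_consistency_test(
    ds: pd.DataFrame,
    shrna_to_gene: dict[str, str],
    is_negative_control: dict[str, bool] | None = None,
    max_null_pairs: int = MAX_NULL_PAIRS,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene one-sided rank-sum test of within-gene DS similarity.

    Within-gene pairwise absolute differences (pooled over samples) are
    tested against the all-shRNA pairwise-difference null; small
    differences mean the gene's shRNAs score consistently.  Genes with
    a single shRNA are untestable and excluded from downstream calls.
    """
    is_negative_control = is_negative_control or {}
    # canonical ordering so the seeded null subsample — and hence every
    # p-value — is invariant to shRNA / cell-line input order
    ds = ds.sort_index(axis=0).sort_index(axis=1)
    null = sample_null_pair_diffs(ds, max_null_pairs, seed)
    genes: dict[str, list[str]] = {}
    for s in ds.index:
        if not is_negative_control.get(s, False):
            if s in shrna_to_gene:
                genes.setdefault(shrna_to_gene[s], []).append(s)
    rows = []
    for gene, shrnas in sorted(genes.items()):
        if len(shrnas) < 2:
            rows.append({"gene_id": gene, "n_shrna": len(shrnas),
                         "consistency_p": np.nan, "passes": False, "untestable": True})
            continue
        within = _pairwise_abs_diffs(ds.loc[shrnas].to_numpy(dtype=float))
        stat = stats.mannwhitneyu(within, null, alternative="less")
        rows.append({"gene_id": gene, "n_shrna": len(shrnas),
                     "consistency_p": float(stat.pvalue),
                     "passes": bool(stat.pvalue < CONSISTENCY_ALPHA),
                     "untestable": False})
    return pd.DataFrame(rows)


def collapse_to_gene(
    ds: pd.DataFrame,
    shrna_to_gene: dict[str, str],
    passing_genes: list[str],
) -> pd.DataFrame:
    """Gene x line matrix: per-line median DS over each passing gene's shRNAs."""
    shrnas_by_gene: dict[str, list[str]] = {}
    for s in ds.index:
        g = shrna_to_gene.get(s)
        if g is not None:
            shrnas_by_gene.setdefault(g, []).append(s)
    rows = {}
    for gene in sorted(passing_genes):
        shrnas = shrnas_by_gene.get(gene, [])
        if not shrnas:
            raise KeyError(f"gene {gene} has no shRNAs in the matrix")
        rows[gene] = ds.loc[shrnas].median(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=ds.columns)


def skin_specificity_test(
    gene_ds: pd.DataFrame, lineage: dict[str, str]
) -> pd.DataFrame:
    """One-sided rank-sum test per gene: skin DS lower than non-skin DS.

    A gene is skin-specific when p < 0.05; by one-sidedness a gene with
    higher DS in skin lines can never be flagged.
    """
    skin = [c for c in gene_ds.columns if lineage.get(c) == "skin"]
    non_skin = [c for c in gene_ds.columns if lineage.get(c) == "non-skin"]
    if len(skin) < 2 or len(non_skin) < 2:
        raise ValueError(
            f"need >= 2 lines per lineage group (skin={len(skin)}, non-skin={len(non_skin)})"
        )
    # exact null distribution for desk-scale line counts (ties are rare on
    # continuous DS medians, and the exact method ignores them anyway)
    method = "exact" if len(skin) + len(non_skin) <= 30 else "auto"
    rows = []
    for gene in gene_ds.index:
        x = gene_ds.loc[gene, skin].to_numpy(dtype=float)
        y = gene_ds.loc[gene, non_skin].to_numpy(dtype=float)
        p = float(stats.mannwhitneyu(x, y, alternative="less", method=method).pvalue)
        rows.append(
            {
                "gene_id": gene,
                "median_skin_ds": float(np.median(x)),
                "median_non_skin_ds": float(np.median(y)),
                "specificity_p": p,
                "skin_specific": bool(p < SPECIFICITY_ALPHA),
            }
        )
    return pd.DataFrame(rows)


def run_essentiality_pipeline(
    screen: ScreenMatrix,
    raw_counts: bool = False,
    seed: int = 0,
    consistency_alpha: float = CONSISTENCY_ALPHA,
    specificity_alpha: float = SPECIFICITY_ALPHA,
) -> pd.DataFrame:
    """Full two-stage essentiality caller on a screen matrix.

    Returns one row per gene with >= 2 shRNAs: consistency p, and —
    for consistency-passing genes — the specificity p and the
    skin-specific flag.  Deterministic given ``seed``.
    """
    ds = normalize_shrna(screen.ds) if raw_counts else screen.ds
    ds = center_by_controls(ds, screen.is_negative_control)
    consistency = gene_consistency_test(
        ds, screen.shrna_to_gene, screen.is_negative_control, seed=seed
    )
    consistency = consistency[~consistency["untestable"]].copy()
    consistency["passes"] = consistency["consistency_p"] < consistency_alpha
    passing = consistency.loc[consistency["passes"], "gene_id"].tolist()
    result = consistency.set_index("gene_id")[["n_shrna", "consistency_p", "passes"]]
    result["specificity_p"] = np.nan
    result["skin_specific"] = False
    if passing:
        gene_ds = collapse_to_gene(ds, screen.shrna_to_gene, passing)
        spec = skin_specificity_test(gene_ds, screen.lineage).set_index("gene_id")
        result.loc[spec.index, "specificity_p"] = spec["specificity_p"]
        result.loc[spec.index, "skin_specific"] = (
            spec["specificity_p"] < specificity_alpha
        ) & (spec["median_skin_ds"] < spec["median_non_skin_ds"])
    return result.sort_index().reset_index()


def as_records(result: pd.DataFrame, gene_ds: pd.DataFrame | None = None) -> list[GeneEssentiality]:
    """Convert the pipeline's flat table into GeneEssentiality records."""
    records = []
    for row in result.itertuples(index=False):
        ds_row = None
        if gene_ds is not None and row.passes and row.gene_id in gene_ds.index:
            ds_row = gene_ds.loc[row.gene_id]
        records.append(
            GeneEssentiality(
                gene_id=row.gene_id,
                consistency_p=float(row.consistency_p),
                gene_ds=ds_row,
                specificity_p=float(row.specificity_p),
                skin_specific=bool(row.skin_specific),
            )
        )
    return records
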