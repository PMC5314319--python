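"""Gene-set enrichment statistics.

Two tests are provided: an unweighted Kolmogorov–Smirnov enrichment
score on a ranked gene list with a gene-shuffling permutation p-value,
and a hypergeometric overlap test with Bonferroni adjustment for
pathway collections.

The KS enrichment score walks the ranked list and takes the maximal
deviation between the empirical CDF of the member genes and that of the
non-members; the sign is positive when the set concentrates at the top
of the ranking.  The permutation null reshuffles gene labels (set size
preserved) and the p-value uses the add-one estimator
p = (1 + #{null >= observed}) / (n_perm + 1), so it can never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RankedList:
    """Gene identifiers ordered by a ranking metric, best first."""

    genes: tuple[str, ...]
    metric: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate gene ids")
        if self.metric and len(self.metric) != len(self.genes):
            raise ValueError("metric length mismatch")

    @classmethod
    def from_scores(cls, scores: Mapping[str, float], descending: bool = True) -> "RankedList":
        items = sorted(scores.items(), key=lambda kv: kv[1], reverse=descending)
        return cls(tuple(k for k, _ in items), tuple(v for _, v in items))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentResult:
    es: float
    p_perm: float
    n_perm: int
    seed: int
    set_size: int


def _membership(ranked: Sequence[str], gene_set: Iterable[str]) -> np.ndarray:
    gs = set(gene_set)
    unknown = gs - set(ranked)
    if unknown:
        raise ValueError(f"gene set members absent from the ranked list: {sorted(unknown)[:5]}")
    member = np.fromiter((g in gs for g in ranked), dtype=bool, count=len(ranked))
    k = int(member.sum())
    if k == 0 or k == len(ranked):
        raise ValueError("gene set must be a proper non-empty subset of the ranked list")
    return member


def _es_from_membership(member: np.ndarray) -> float:
    # signed maximal deviation between member and non-member CDFs
    n = member.shape[-1]
    k = member.sum(axis=-1, keepdims=True)
    f_set = np.cumsum(member, axis=-1) / k
    f_comp = np.cumsum(~member, axis=-1) / (n - k)
    diff = f_set - f_comp
    d_pos = diff.max(axis=-1)
    d_neg = (-diff).max(axis=-1)
    return np.where(d_pos >= d_neg, d_pos, -d_neg)


def ks_enrichment_score(ranked: RankedList | Sequence[str], gene_set: Iterable[str]) -> float:
    """Unweighted KS enrichment score of ``gene_set`` in the ranked list.

    Returns a value in [-1, 1]; positive when the set concentrates at
    the top of the ranking, negative at the bottom.  Depends only on
    the rank positions, not on the metric values.
    """
    genes = ranked.genes if isinstance(ranked, RankedList) else tuple(ranked)
    member = _membership(genes, gene_set)
    return float(_es_from_membership(member))


def permutation_pvalue(
    ranked: RankedList | Sequence[str],
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation p-value for the KS enrichment score.

    The null distribution recomputes the score on ``n_perm`` uniform
    reshufflings of the gene labels, preserving the set size; the
    comparison is one-sided on the signed score (null >= observed).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = ranked.genes if isinstance(ranked, RankedList) else tuple(ranked)
    member = _membership(genes, gene_set)
    observed = float(_es_from_membership(member))
    rng = np.random.default_rng(seed)
    perms = np.tile(member, (n_perm, 1))
    # shuffle each row independently: equivalent to relabelling the genes
    idx = np.argsort(rng.random(perms.shape), axis=1)
    perms = np.take_along_axis(perms, idx, axis=1)
    null = _es_from_membership(perms)
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return EnrichmentResult(observed, p, n_perm, seed, int(member.sum()))


def hypergeometric_enrichment(
    query_set: Iterable[str],
    pathway_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric overlap test per pathway, Bonferroni-adjusted.

    For each pathway, p = P(X >= k) with X ~ Hypergeom(N=|universe|,
    K=|pathway|, n=|query|) and k the observed overlap; the adjusted
    p-value is min(1, p * number of pathways tested).
    """
    uni = set(universe)
    query = set(query_set)
    if not query <= uni:
        raise ValueError("query set not contained in the universe")
    m = len(pathway_sets)
    rows = []
    for name, members in pathway_sets.items():
        pw = set(members)
        if not pw <= uni:
            raise ValueError(f"pathway {name!r} not contained in the universe")
        k = len(query & pw)
        # sf(k-1) = P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(pw), len(query)))
        rows.append(
            {
                "pathway": name,
                "pathway_size": len(pw),
                "overlap": k,
                "p": p,
                "p_bonferroni": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows, columns=["pathway", "pathway_size", "overlap", "p", "p_bonferroni"])


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 columns")
            sets[cols[0]] = [g for g in cols[2:] if g]
    return sets
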