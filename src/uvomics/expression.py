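"""Differential expression classification and DGE x DHA integration.

Differential gene expression (DGE) uses the same pseudocounted
fold-change rule as the acetylation side: FC = (uv + eps)/(ctrl + eps)
with strict cutoffs (> 2 up, < 0.5 down).  Integration groups genes by
their acetylation log2FC into three bins (> 1, < -1, between), tests
whether the expression log2FC of the outer bins is shifted relative to
the middle bin (two-sample Student t), and tabulates class concordance
in a 3 x 3 contingency matrix where the (up, up)/(down, down) diagonal
cells are positive couplings and (up, down)/(down, up) inverse ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chromatin import DHARecord, _fc_class

DHA_BINS = ("gt1", "lt-1", "mid")
CLASSES = ("up", "down", "none")


@dataclass(frozen=True)
class DGERecord:
    gene_id: str
    expr_control: float
    expr_uv: float
    log2fc: float
    dge_class: str  # up | down | none


@dataclass(frozen=True)
class GeneOmicsRecord:
    """Per-gene integration unit joining expression and acetylation calls."""

    gene_id: str
    dge: DGERecord
    dha: DHARecord
    dha_bin: str  # gt1 | lt-1 | mid
    concordance: str  # positive | inverse | discordant-none


def compute_dge(
    expression: pd.DataFrame,
    epsilon: float = 1.0,
    fc_cutoff: float = 2.0,
) -> list[DGERecord]:
    """Classify genes from a table with gene_id, expr_control, expr_uv.

    Values must be normalized, non-negative expression measures.
    Classes use strict inequalities: FC exactly at the cutoff is "none".
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    required = {"gene_id", "expr_control", "expr_uv"}
    if not required.issubset(expression.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    if (expression["expr_control"] < 0).any() or (expression["expr_uv"] < 0).any():
        raise ValueError("negative expression value")
    records = []
    for row in expression.itertuples(index=False):
        fc = (row.expr_uv + epsilon) / (row.expr_control + epsilon)
        records.append(
            DGERecord(
                str(row.gene_id),
                float(row.expr_control),
                float(row.expr_uv),
                math.log2(fc),
                _fc_class(fc, fc_cutoff),
            )
        )
    return records


def log2fc_bin(log2fc: float, edge: float = 1.0) -> str:
    """Three-way bin with strict edges; values exactly at +-edge are 'mid'."""
    if log2fc > edge:
        return "gt1"
    if log2fc < -edge:
        return "lt-1"
    return "mid"


def bin_by_log2fc(
    log2fcs: dict[str, float], edge: float = 1.0
) -> dict[str, list[str]]:
    """Partition gene_id -> log2fc into the three bins."""
    groups: dict[str, list[str]] = {b: [] for b in DHA_BINS}
    for gene_id, value in log2fcs.items():
        groups[log2fc_bin(value, edge)].append(gene_id)
    return groups


def group_shift_test(
    dge_log2fc_by_dha_bin: dict[str, list[float] | np.ndarray],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Test expression shift of the outer acetylation bins against 'mid'.

    For each of the 'gt1' and 'lt-1' bins, a two-sided two-sample
    Student t-test (Welch with ``equal_var=False``) compares the
    expression log2FC values of that bin against the 'mid' bin.  Bins
    with fewer than two values are flagged untestable (NaN statistics).
    """
    mid = np.asarray(dge_log2fc_by_dha_bin.get("mid", []), dtype=float)
    rows = []
    for bin_name in ("gt1", "lt-1"):
        grp = np.asarray(dge_log2fc_by_dha_bin.get(bin_name, []), dtype=float)
        if grp.size < 2 or mid.size < 2:
            rows.append(
                {"dha_bin": bin_name, "n": grp.size, "n_mid": mid.size,
                 "t": np.nan, "p": np.nan, "testable": False, "significant": False}
            )
            continue
        t, p = stats.ttest_ind(grp, mid, equal_var=equal_var)
        rows.append(
            {"dha_bin": bin_name, "n": grp.size, "n_mid": mid.size,
             "t": float(t), "p": float(p), "testable": True,
             "significant": bool(p < 0.05)}
        )
    return pd.DataFrame(rows)


def _concordance(dge_class: str, dha_class: str) -> str:
    if dge_class == dha_class and dge_class != "none":
        return "positive"
    if {dge_class, dha_class} == {"up", "down"}:
        return "inverse"
    return "discordant-none"


def integrate(
    dge_records: list[DGERecord], dha_records: list[DHARecord]
) -> list[GeneOmicsRecord]:
    """Join DGE and DHA calls on gene_id (inner join)."""
    dha_by_id = {r.gene_id: r for r in dha_records}
    out = []
    for dge in dge_records:
        dha = dha_by_id.get(dge.gene_id)
        if dha is None:
            continue
        out.append(
            GeneOmicsRecord(
                dge.gene_id,
                dge,
                dha,
                log2fc_bin(dha.log2fc),
                _concordance(dge.dge_class, dha.dha_class),
            )
        )
    return out


def concordance_matrix(records: list[GeneOmicsRecord]) -> pd.DataFrame:
    """3 x 3 contingency table of DGE class (rows) by DHA class (columns).

    The table sums to the number of records; (up, up) and (down, down)
    are the positively coupled cells, (up, down) and (down, up) the
    inverse ones.
    """
    table = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for r in records:
        table.loc[r.dge.dge_class, r.dha.dha_class] += 1
    table.index.name = "dge_class"
    table.columns.name = "dha_class"
    return table


def integration_table(records: list[GeneOmicsRecord]) -> pd.DataFrame:
    """Flattened per-gene integration table (the output TSV layout)."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "expr_control": r.dge.expr_control,
                "expr_uv": r.dge.expr_uv,
                "dge_log2fc": r.dge.log2fc,
                "dge_class": r.dge.dge_class,
                "dha_log2fc": r.dha.log2fc,
                "dha_class": r.dha.dha_class,
                "dha_bin": r.dha_bin,
                "concordance": r.concordance,
            }
            for r in records
        ]
    )
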