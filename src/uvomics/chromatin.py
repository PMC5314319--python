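"""Gene-level differential H3K27 acetylation (DHA) and global signal trend.

The DHA statistic for a gene is the fold change between the mean signal
of the H3K27ac peaks assigned to it (within 10 kb of the gene body) in
the UV-exposed sample and in the control sample.  A pseudocount on both
means defines the fold change when a gene carries peaks in only one
condition.  Genes with FC strictly above the cutoff are classed "up",
strictly below its reciprocal "down", otherwise "none".

The global acetylation trend is summarised as the through-origin
least-squares slope of UV tag signal on control tag signal over merged
peak regions; a slope below 1 indicates a net genome-wide loss of the
mark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation, Interval, Peak, assign_peaks_to_genes


@dataclass(frozen=True)
class DHARecord:
    gene_id: str
    mean_signal_control: float
    mean_signal_uv: float
    log2fc: float
    dha_class: str  # up | down | none


def _fc_class(fc: float, fc_cutoff: float) -> str:
    if fc > fc_cutoff:
        return "up"
    if fc < 1.0 / fc_cutoff:
        return "down"
    return "none"


def compute_dha(
    peaks_control: list[Peak],
    peaks_uv: list[Peak],
    annotation: GenomeAnnotation,
    window: int = 10_000,
    fc_cutoff: float = 2.0,
    epsilon: float = 1.0,
) -> list[DHARecord]:
    """Per-gene differential H3K27ac from two assigned peak sets.

    One record is produced per gene holding at least one assigned peak
    in at least one condition.  FC = (mean UV signal + eps) /
    (mean control signal + eps); classes use strict inequalities, so a
    gene at exactly the cutoff is "none".
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if fc_cutoff <= 1:
        raise ValueError("fc_cutoff must be > 1")
    ctrl = assign_peaks_to_genes(peaks_control, annotation, window)
    uv = assign_peaks_to_genes(peaks_uv, annotation, window)
    records = []
    for gene_id in sorted(set(ctrl) | set(uv)):
        mc = float(np.mean([p.signal for p in ctrl[gene_id]])) if gene_id in ctrl else 0.0
        mu = float(np.mean([p.signal for p in uv[gene_id]])) if gene_id in uv else 0.0
        fc = (mu + epsilon) / (mc + epsilon)
        records.append(DHARecord(gene_id, mc, mu, math.log2(fc), _fc_class(fc, fc_cutoff)))
    return records


def global_signal_slope(
    tags_control: Sequence[float], tags_uv: Sequence[float]
) -> float:
    """Through-origin least-squares slope of UV tags on control tags.

    Computed over merged peak regions (see :func:`merged_region_signals`);
    slope < 1 means a net loss of signal in the UV sample.
    """
    x = np.asarray(tags_control, dtype=float)
    y = np.asarray(tags_uv, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need paired 1-D vectors with n >= 2")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("all-zero control vector: slope undefined")
    return float(x @ y) / sxx


def merged_region_signals(
    peaks_control: Iterable[Peak], peaks_uv: Iterable[Peak]
) -> pd.DataFrame:
    """Sum per-sample peak signal over the union of both samples' intervals.

    Overlapping intervals from the two samples are merged; each merged
    region gets one row with the summed control and UV signal falling in
    it.  This defines the paired vectors for :func:`global_signal_slope`.
    """
    ctrl = list(peaks_control)
    uv = list(peaks_uv)
    ivs = sorted(
        (p.interval for p in ctrl + uv), key=lambda iv: (iv.chrom, iv.start, iv.end)
    )
    merged: list[Interval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged.pop()
            merged.append(Interval(last.chrom, last.start, max(last.end, iv.end)))
        else:
            merged.append(iv)
    # each input peak lies inside exactly one merged region; locate it by
    # binary search over per-chromosome region starts
    import bisect

    starts: dict[str, list[int]] = {}
    index: dict[str, list[int]] = {}
    for i, region in enumerate(merged):
        starts.setdefault(region.chrom, []).append(region.start)
        index.setdefault(region.chrom, []).append(i)
    sums = np.zeros((len(merged), 2))
    for col, peaks in ((0, ctrl), (1, uv)):
        for p in peaks:
            pos = bisect.bisect_right(starts[p.interval.chrom], p.interval.start) - 1
            sums[index[p.interval.chrom][pos], col] += p.signal
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in merged],
            "start": [r.start for r in merged],
            "end": [r.end for r in merged],
            "control": sums[:, 0],
            "uv": sums[:, 1],
        }
    )


def dha_table(records: list[DHARecord]) -> pd.DataFrame:
    """Flatten DHA records to the output TSV layout."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "mean_ctrl": r.mean_signal_control,
                "mean_uv": r.mean_signal_uv,
                "log2fc": r.log2fc,
                "dha_class": r.dha_class,
            }
            for r in records
        ],
        columns=["gene_id", "mean_ctrl", "mean_uv", "log2fc", "dha_class"],
    )
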