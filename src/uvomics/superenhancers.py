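"""Super-enhancer identification from H3K27ac constituent peaks.

The procedure follows the classical rank-ordering approach: promoter
peaks are excluded, the remaining constituent enhancers are stitched
when closer than a fixed distance (default 12.5 kb), the stitched
enhancers are ranked by total signal, and super enhancers (SEs) are the
clusters whose signal exceeds the transition point of the min-max-scaled
rank/signal curve — the point of maximal depth below the diagonal, which
on a convex "hockey-stick" curve is where the tangent slope passes 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import (
    GenomeAnnotation,
    Interval,
    Peak,
    interval_distance,
)

log = logging.getLogger(__name__)


@dataclass
class StitchedEnhancer:
    """A chain of constituent peaks mutually within the stitch distance."""

    interval: Interval
    constituent_peaks: list[Peak]
    rank: int = -1  # ascending-signal rank, filled after sorting

    @property
    def total_signal(self) -> float:
        return sum(p.signal for p in self.constituent_peaks)


@dataclass
class SuperEnhancerSet:
    sample: str
    stitched: list[StitchedEnhancer]  # ranked ascending by total signal
    cutoff_signal: float
    cutoff_index: int
    superenhancers: list[StitchedEnhancer] = field(default_factory=list)
    associated_genes: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.superenhancers:
            self.superenhancers = [
                e for e in self.stitched if e.total_signal > self.cutoff_signal
            ]


def exclude_promoter_peaks(
    peaks: list[Peak],
    annotation: GenomeAnnotation,
    tss_window: int = 2500,
) -> list[Peak]:
    """Drop every peak overlapping [TSS - window, TSS + window) of any gene."""
    if tss_window < 0:
        raise ValueError("tss_window must be >= 0")
    promoters: dict[str, list[tuple[int, int]]] = {}
    for g in annotation.genes:
        start = max(g.tss - tss_window, 0)
        promoters.setdefault(g.chrom, []).append((start, g.tss + tss_window + 1))
    for lst in promoters.values():
        lst.sort()
    import bisect

    width = 2 * tss_window + 1  # all promoter windows share this maximal width
    kept = []
    for p in peaks:
        windows = promoters.get(p.interval.chrom, [])
        # overlapping windows start in [peak.start - width, peak.end)
        lo = bisect.bisect_left(windows, (p.interval.start - width, -1))
        hi = bisect.bisect_left(windows, (p.interval.end, -1))
        hit = any(end > p.interval.start for _, end in windows[lo:hi])
        if not hit:
            kept.append(p)
    return kept


def stitch_enhancers(
    peaks: list[Peak], stitch_distance: int = 12_500
) -> list[StitchedEnhancer]:
    """Merge consecutive peaks whose gap is <= stitch_distance (per chromosome).

    Stitching is the transitive closure of the pairwise rule, so a chain
    of peaks each within the distance of its neighbour forms one
    stitched enhancer spanning first start to last end.  Total signal is
    the sum over constituents.
    """
    ordered = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    stitched: list[StitchedEnhancer] = []
    current: list[Peak] = []
    for p in ordered:
        if current and p.interval.chrom == current[-1].interval.chrom:
            gap = max(p.interval.start - max(q.interval.end for q in current), 0)
            if gap <= stitch_distance:
                current.append(p)
                continue
        if current:
            stitched.append(_finish_cluster(current))
        current = [p]
    if current:
        stitched.append(_finish_cluster(current))
    return stitched


def _finish_cluster(peaks: list[Peak]) -> StitchedEnhancer:
    start = min(p.interval.start for p in peaks)
    end = max(p.interval.end for p in peaks)
    return StitchedEnhancer(Interval(peaks[0].interval.chrom, start, end), list(peaks))


def se_cutoff(total_signals: np.ndarray | list[float]) -> tuple[float, int]:
    """Transition-point cutoff on the ranked signal curve.

    Signals are sorted ascending; rank and signal are min-max scaled to
    [0, 1]; the cutoff index is the argmax of (scaled rank - scaled
    signal), the deepest point below the diagonal.  Ties in depth take
    the smallest index.  Returns (cutoff signal, 0-based index into the
    ascending-sorted vector); enhancers with signal strictly above the
    cutoff signal are SEs.
    """
    s = np.sort(np.asarray(total_signals, dtype=float))
    n = s.size
    if n < 3:
        raise ValueError("need at least 3 signals")
    if s[0] == s[-1]:
        raise ValueError("no transition point: constant signal vector")
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    depth = x - y
    i_star = int(np.argmax(depth))
    if depth[i_star] <= 0:
        warnings.warn(
            "degenerate rank/signal curve: no point below the diagonal; "
            "cutoff falls at the minimum signal",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(s[i_star]), i_star


def call_superenhancers(
    peaks: list[Peak],
    annotation: GenomeAnnotation,
    stitch_distance: int = 12_500,
    tss_window: int = 2500,
    sample: str = "",
) -> SuperEnhancerSet:
    """Full SE calling: exclude promoters -> stitch -> rank -> cutoff."""
    if not peaks:
        raise ValueError("no peaks supplied")
    constituents = exclude_promoter_peaks(peaks, annotation, tss_window)
    stitched = stitch_enhancers(constituents, stitch_distance)
    if len(stitched) < 3:
        raise ValueError(
            f"only {len(stitched)} stitched enhancers after promoter exclusion; "
            "need >= 3 to locate a transition point"
        )
    stitched.sort(key=lambda e: e.total_signal)
    for rank, e in enumerate(stitched):
        e.rank = rank
    cutoff_signal, cutoff_index = se_cutoff([e.total_signal for e in stitched])
    return SuperEnhancerSet(sample, stitched, cutoff_signal, cutoff_index)


def annotate_se_genes(
    se_set: SuperEnhancerSet,
    annotation: GenomeAnnotation,
    window: int = 25_000,
) -> dict[int, list[str]]:
    """Associate genes lying within ``window`` bp of each SE interval.

    Keys are SE ranks; a gene may associate with several SEs.  Distance
    is measured from the SE boundary to the gene body.
    """
    result: dict[int, list[str]] = {}
    by_chrom = annotation.genes_by_chrom()
    for se in se_set.superenhancers:
        hits = [
            g.gene_id
            for g in by_chrom.get(se.interval.chrom, [])
            if interval_distance(se.interval, g.body) <= window
        ]
        result[se.rank] = hits
    se_set.associated_genes = result
    return result


def compare_se_sets(
    a: SuperEnhancerSet,
    b: SuperEnhancerSet,
    min_overlap_bp: int = 1,
) -> dict[str, list[StitchedEnhancer]]:
    """Partition two SE sets into common and unique members by overlap.

    An SE of one set is "common" when it overlaps at least
    ``min_overlap_bp`` with any SE of the other set; common counts may
    differ between the sets (one SE can span several on the other side).
    """

    def overlap_bp(u: Interval, v: Interval) -> int:
        if u.chrom != v.chrom:
            return 0
        return max(0, min(u.end, v.end) - max(u.start, v.start))

    def split(xs: list[StitchedEnhancer], ys: list[StitchedEnhancer]):
        common, unique = [], []
        for x in xs:
            if any(overlap_bp(x.interval, y.interval) >= min_overlap_bp for y in ys):
                common.append(x)
            else:
                unique.append(x)
        return common, unique

    common_a, unique_a = split(a.superenhancers, b.superenhancers)
    common_b, unique_b = split(b.superenhancers, a.superenhancers)
    return {
        "common_a": common_a,
        "common_b": common_b,
        "unique_a": unique_a,
        "unique_b": unique_b,
    }
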