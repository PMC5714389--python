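"""Overlap, vicinity, annotation and correlation analytics over peak sets.

All operations treat intervals as 0-based half-open and count each region
of the query set as one trial (a region of A spanning two regions of B is
a single hit).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import GeneModel, InputError, PeakSet, ProbeTrack, Region

__all__ = [
    "OverlapSummary",
    "merge_intervals",
    "overlap_summary",
    "vicinity_fraction",
    "assign_peaks_to_genes",
    "StateAnnotation",
    "annotate_states",
    "top_k_signal_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class OverlapSummary:
    n_a: int
    n_b: int
    n_a_hit: int
    n_b_hit: int

    @property
    def fraction_a_hit(self) -> float:
        return self.n_a_hit / self.n_a if self.n_a else 0.0

    @property
    def fraction_b_hit(self) -> float:
        return self.n_b_hit / self.n_b if self.n_b else 0.0


def merge_intervals(peaks: PeakSet) -> PeakSet:
    """Merge overlapping-or-touching intervals; covered bp is preserved."""
    merged: list[Region] = []
    cur: Region | None = None
    for r in peaks:  # PeakSet iterates sorted; output carries no stats
        if cur is not None and r.chrom == cur.chrom and r.start <= cur.end:
            if r.end > cur.end:
                cur = Region(cur.chrom, cur.start, r.end)
        else:
            if cur is not None:
                merged.append(cur)
            cur = Region(r.chrom, r.start, r.end)
    if cur is not None:
        merged.append(cur)
    return PeakSet(merged)


def _trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in peaks:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return trees


def _hits(a: PeakSet, trees_b: dict[str, IntervalTree], min_overlap_bp: int) -> int:
    n_hit = 0
    for r in a:
        tree = trees_b.get(r.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(r.start, r.end):
            if min(r.end, iv.end) - max(r.start, iv.begin) >= min_overlap_bp:
                n_hit += 1
                break
    return n_hit


def overlap_summary(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1) -> OverlapSummary:
    """Symmetric region-level overlap counts.

    A region hits if it shares at least ``min_overlap_bp`` with any single
    region of the other set.
    """
    if min_overlap_bp < 1:
        raise InputError("min_overlap_bp must be >= 1")
    return OverlapSummary(
        n_a=len(a),
        n_b=len(b),
        n_a_hit=_hits(a, _trees(b), min_overlap_bp),
        n_b_hit=_hits(b, _trees(a), min_overlap_bp),
    )


def vicinity_fraction(a: PeakSet, b: PeakSet, window_bp: int) -> float:
    """Fraction of A regions with any B region within ``window_bp``.

    Each A region is expanded by window_bp on both sides (clipped at 0)
    before testing >= 1 bp overlap with B; window_bp = 0 reduces to
    ``overlap_summary(a, b).fraction_a_hit``.
    """
    if window_bp < 0:
        raise InputError("window_bp must be >= 0")
    if len(a) == 0:
        return 0.0
    if window_bp == 0:
        return overlap_summary(a, b).fraction_a_hit
    by_chrom = b.by_chrom()
    n_hit = 0
    for r in a:
        if r.chrom not in by_chrom:
            continue
        starts, ends, _ = by_chrom[r.chrom]
        gaps = np.maximum(0, np.maximum(starts - r.end, r.start - ends))
        if np.any(gaps <= window_bp):
            n_hit += 1
    return n_hit / len(a)


def assign_peaks_to_genes(
    peaks: PeakSet, genes: list[GeneModel], max_dist_bp: int = 10_000
) -> pd.DataFrame:
    """Many-to-many peak-gene assignment within a distance cut-off.

    A gene maps to a peak iff the gap between the two intervals is
    <= max_dist_bp (0 when they overlap); the bound is inclusive and
    strand-agnostic. Returns a DataFrame with columns peak_index, gene_id,
    distance.
    """
    if max_dist_bp < 0:
        raise InputError("max_dist_bp must be >= 0")
    rows: list[tuple[int, str, int]] = []
    for i, r in enumerate(peaks):
        for g in genes:
            if g.chrom != r.chrom:
                continue
            dist = max(0, r.start - g.end, g.start - r.end)
            if dist <= max_dist_bp:
                rows.append((i, g.gene_id, dist))
    return pd.DataFrame(rows, columns=["peak_index", "gene_id", "distance"])


@dataclass
class StateAnnotation:
    """Per-peak chromatin-state assignment and the label distribution."""

    labels: list[str]  # one entry per peak, in PeakSet order
    counts: dict[str, int]
    fractions: dict[str, float]
    n_ties: int


def annotate_states(peaks: PeakSet, states: list[tuple[str, int, int, str]]) -> StateAnnotation:
    """Assign each peak the chromatin state with maximal bp overlap.

    ``states`` is a labelled segmentation in file order: (chrom, start,
    end, label). Ties go to the label listed first in the segmentation;
    peaks overlapping no segment get "unassigned". Fractions sum to 1 over
    all peaks.
    """
    label_rank: dict[str, int] = {}
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, label in states:
        if start >= end:
            raise InputError(f"malformed state segment {chrom}:{start}-{end}")
        if label not in label_rank:
            label_rank[label] = len(label_rank)
        trees.setdefault(chrom, IntervalTree()).addi(start, end, label)
    labels: list[str] = []
    n_ties = 0
    for r in peaks:
        bp: dict[str, int] = {}
        tree = trees.get(r.chrom)
        if tree is not None:
            for iv in tree.overlap(r.start, r.end):
                ov = min(r.end, iv.end) - max(r.start, iv.begin)
                if ov > 0:
                    bp[iv.data] = bp.get(iv.data, 0) + ov
        if not bp:
            labels.append("unassigned")
            continue
        best = max(bp.values())
        winners = [lab for lab, v in bp.items() if v == best]
        if len(winners) > 1:
            n_ties += 1
        labels.append(min(winners, key=lambda lab: label_rank[lab]))
    if n_ties:
        logger.info("annotate_states: %d ties broken by segmentation order", n_ties)
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    total = len(labels)
    fractions = {lab: c / total for lab, c in counts.items()} if total else {}
    return StateAnnotation(labels=labels, counts=counts, fractions=fractions, n_ties=n_ties)


def _signal_index(track: ProbeTrack) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    y = track.replicate_mean()
    return {chrom: (track.pos[sl], y[sl]) for chrom, sl in track.per_chrom()}


def _mean_signal_over(
    index: dict[str, tuple[np.ndarray, np.ndarray]], region: Region
) -> float:
    """Mean replicate-mean signal over probes inside the region (NaN if none)."""
    if region.chrom not in index:
        return float("nan")
    pos, y = index[region.chrom]
    lo = np.searchsorted(pos, region.start, side="left")
    hi = np.searchsorted(pos, region.end, side="left")
    return float(np.mean(y[lo:hi])) if hi > lo else float("nan")


def top_k_signal_correlation(
    track_a: ProbeTrack,
    track_b: ProbeTrack,
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    k: int = 100,
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of two tracks over their top-k bound enhancers.

    The enhancer universe is the merged union of both peak sets; each
    enhancer is scored with the mean signal of each track over its span.
    Enhancers are ranked by fold enrichment, i.e. max(value_a, value_b),
    descending with genomic-order tie-break, and the correlation is
    computed on the top k. Returns (r, two-sided p, ranked table).
    """
    if k < 3:
        raise InputError("k must be >= 3")
    universe = merge_intervals(PeakSet(list(peaks_a) + list(peaks_b)))
    if len(universe) == 0:
        raise InputError("empty enhancer universe")
    idx_a = _signal_index(track_a)
    idx_b = _signal_index(track_b)
    rows = []
    for i, reg in enumerate(universe):
        va = _mean_signal_over(idx_a, reg)
        vb = _mean_signal_over(idx_b, reg)
        if np.isnan(va) or np.isnan(vb):
            continue
        rows.append((reg.chrom, reg.start, reg.end, va, vb, i))
    if len(rows) < 3:
        raise InputError("fewer than 3 enhancers with probe signal")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value_a", "value_b", "_order"])
    df["rank_value"] = df[["value_a", "value_b"]].max(axis=1)
    df = df.sort_values(["rank_value", "_order"], ascending=[False, True]).drop(
        columns="_order"
    )
    if k > len(df):
        warnings.warn(
            f"k={k} exceeds universe size {len(df)}; using the full universe",
            stacklevel=2,
        )
        k = len(df)
    top = df.head(k).reset_index(drop=True)
    r, p = stats.pearsonr(top["value_a"], top["value_b"])
    return float(r), float(p), top
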