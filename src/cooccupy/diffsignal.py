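"""Sliding-window differential-signal detection with a replicate-noise null.

The test asks, window by window, whether the difference between two
conditions exceeds what replicate noise alone can produce. Probe signal is
averaged per replicate inside sliding windows (2 kb, 1 kb step by
default); the null distribution of |difference| is built empirically from
within-condition replicate pairs over all windows; each window's observed
between-condition |mean difference| is converted to an upper-tail
empirical p-value, BH-corrected, and significant same-direction windows
are merged into maximal differential regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError, InputError, ProbeTrack
from .peaks import bh_adjust

__all__ = [
    "WindowMeans",
    "WindowStat",
    "DifferentialRegion",
    "window_means",
    "replicate_noise_null",
    "window_pvalues",
    "differential_windows",
    "differential_regions",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 2000
DEFAULT_STEP_BP = 1000
DEFAULT_FDR = 0.01


@dataclass
class WindowMeans:
    """Per-window, per-replicate mean signal; windows with no probes are
    dropped (count logged)."""

    chrom: np.ndarray  # str per window
    start: np.ndarray
    end: np.ndarray
    means: np.ndarray  # (n_windows, n_replicates)
    n_probes: np.ndarray

    def __len__(self) -> int:
        return len(self.start)


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    delta: float  # |mean(treated) - mean(control)|
    signed_delta: float
    pvalue: float
    qvalue: float


@dataclass
class DifferentialRegion:
    chrom: str
    start: int
    end: int
    direction: str  # "+" (treated > control) or "-"
    min_qvalue: float
    n_windows: int


def window_means(
    track: ProbeTrack,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
) -> WindowMeans:
    """Mean probe signal per replicate in sliding windows.

    Windows tile each chromosome from 0 at ``step_bp`` intervals and span
    ``window_bp``; a window keeps the mean over the probes it contains and
    is dropped when it contains none.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ConfigurationError("window_bp and step_bp must be positive")
    if track.n_replicates < 1:
        raise InputError("track has no signal replicates")
    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    means: list[np.ndarray] = []
    counts: list[np.ndarray] = []
    n_dropped = 0
    for chrom, sl in track.per_chrom():
        pos = track.pos[sl]
        sig = track.signal[sl]
        last = int(pos[-1])
        w_start = np.arange(0, last + 1, step_bp, dtype=np.int64)
        lo = np.searchsorted(pos, w_start, side="left")
        hi = np.searchsorted(pos, w_start + window_bp, side="left")
        n_in = hi - lo
        keep = n_in > 0
        n_dropped += int((~keep).sum())
        csum = np.vstack([np.zeros((1, sig.shape[1])), np.cumsum(sig, axis=0)])
        m = (csum[hi[keep]] - csum[lo[keep]]) / n_in[keep, None]
        chroms.append(np.repeat(np.array([chrom], dtype=object), keep.sum()))
        starts.append(w_start[keep])
        means.append(m)
        counts.append(n_in[keep])
    if n_dropped:
        logger.info("window_means: dropped %d empty windows", n_dropped)
    if not starts:
        raise InputError("empty track")
    start = np.concatenate(starts)
    return WindowMeans(
        chrom=np.concatenate(chroms),
        start=start,
        end=start + window_bp,
        means=np.vstack(means),
        n_probes=np.concatenate(counts),
    )


def _check_aligned(a: WindowMeans, b: WindowMeans) -> None:
    if len(a) != len(b) or not (
        np.array_equal(a.start, b.start) and np.array_equal(a.chrom, b.chrom)
    ):
        raise InputError(
            "window sets of the two conditions are not aligned; compute them "
            "from tracks on the same probe map"
        )


def replicate_noise_null(
    control: WindowMeans, treated: WindowMeans, scale_to_condition_means: bool = True
) -> np.ndarray:
    """Empirical null sample of |delta| from within-condition replicate pairs.

    Pools |rep_i - rep_j| of window means over all windows and all
    within-condition replicate pairs of both conditions. Size =
    n_windows x (C(r_control, 2) + C(r_treated, 2)).

    The tested statistic is a difference of *condition means*, whose noise
    variance is sigma^2 (1/r_c + 1/r_t), while a raw replicate pair
    difference has variance 2 sigma^2; by default the pooled sample is
    rescaled by sqrt((1/r_c + 1/r_t) / 2) so the null lives on the same
    scale as the statistic and null p-values are uniform. Pass
    ``scale_to_condition_means=False`` for the raw (conservative) pairs.
    """
    _check_aligned(control, treated)
    out: list[np.ndarray] = []
    reps = []
    for wm in (control, treated):
        r = wm.means.shape[1]
        reps.append(r)
        if r < 2:
            raise InputError("each condition needs >= 2 replicates for the noise null")
        for i in range(r):
            for j in range(i + 1, r):
                out.append(np.abs(wm.means[:, i] - wm.means[:, j]))
    null = np.concatenate(out)
    if scale_to_condition_means:
        r_c, r_t = reps
        null = null * np.sqrt((1.0 / r_c + 1.0 / r_t) / 2.0)
    return null


def window_pvalues(deltas: np.ndarray, null_sample: np.ndarray) -> np.ndarray:
    """Empirical upper-tail p-values with add-one continuity.

    p(w) = (1 + #{null >= delta(w)}) / (1 + null size).
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise InputError("empty null sample")
    snull = np.sort(null_sample)
    n_ge = len(snull) - np.searchsorted(snull, np.asarray(deltas, dtype=float), side="left")
    return (1.0 + n_ge) / (1.0 + len(snull))


def differential_windows(
    control: ProbeTrack,
    treated: ProbeTrack,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
) -> list[WindowStat]:
    """Full window pipeline: means, noise null, empirical p, BH q."""
    wm_c = window_means(control, window_bp, step_bp)
    wm_t = window_means(treated, window_bp, step_bp)
    _check_aligned(wm_c, wm_t)
    signed = wm_t.means.mean(axis=1) - wm_c.means.mean(axis=1)
    delta = np.abs(signed)
    null = replicate_noise_null(wm_c, wm_t)
    p = window_pvalues(delta, null)
    q = bh_adjust(p)
    return [
        WindowStat(
            chrom=str(wm_c.chrom[i]),
            start=int(wm_c.start[i]),
            end=int(wm_c.end[i]),
            delta=float(delta[i]),
            signed_delta=float(signed[i]),
            pvalue=float(p[i]),
            qvalue=float(q[i]),
        )
        for i in range(len(wm_c))
    ]


def differential_regions(
    windows: list[WindowStat], fdr: float = DEFAULT_FDR
) -> list[DifferentialRegion]:
    """Merge adjacent/overlapping significant same-direction windows.

    Windows with q <= fdr join a region while they overlap or touch the
    running region and share the sign of (treated - control); regions of
    opposite direction never merge.
    """
    sig = sorted(
        (w for w in windows if w.qvalue <= fdr),
        key=lambda w: (w.chrom, w.start),
    )
    regions: list[DifferentialRegion] = []
    cur: DifferentialRegion | None = None
    for w in sig:
        direction = "+" if w.signed_delta >= 0 else "-"
        if (
            cur is not None
            and w.chrom == cur.chrom
            and w.start <= cur.end
            and direction == cur.direction
        ):
            cur.end = max(cur.end, w.end)
            cur.min_qvalue = min(cur.min_qvalue, w.qvalue)
            cur.n_windows += 1
        else:
            if cur is not None:
                regions.append(cur)
            cur = DifferentialRegion(
                chrom=w.chrom,
                start=w.start,
                end=w.end,
                direction=direction,
                min_qvalue=w.qvalue,
                n_windows=1,
            )
    if cur is not None:
        regions.append(cur)
    return regions
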