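"""Combinatorial co-occupancy null model with a latent unoccupied count.

Three factors A, B, C are scored over an enhancer universe (the merged
union of their peak sets). The null model lets the (A, B) pair be
arbitrarily dependent — their 2x2 joint law is a free parameter — while C
is independent of both:

    P(a, b, c) = q_ab * p^c * (1 - p)^(1 - c)

The (0,0,0) cell is unobservable (an unoccupied candidate enhancer leaves
no peak), so the universe size N = n_observed + n0 with a latent count
n0 searched on an integer grid (0..n_max, default 5000). At each n0 the
remaining parameters have closed-form plug-in maximum-likelihood
estimates, giving a profile likelihood that the grid search maximises
(smallest n0 on ties). The headline statistic is the triple-binding
excess, 100 * (observed(1,1,1) / expected(1,1,1) - 1), with a Fisher
exact test of observed-vs-expected triple counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, xlogy

from .core import InputError, PeakSet
from .intervals import _trees, merge_intervals

__all__ = [
    "PATTERNS",
    "PatternCounts",
    "NullModelFit",
    "build_universe",
    "fit_null_model",
    "triple_excess",
    "fisher_deviation",
    "expected_triple_excess",
    "calibrate_triple_boost",
    "pattern_simulation_power",
]

logger = logging.getLogger(__name__)

Pattern = tuple[int, int, int]
#: the eight binding patterns (a, b, c); (0,0,0) is the unobservable one
PATTERNS: list[Pattern] = [
    (a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)
]
NONNULL = [p for p in PATTERNS if p != (0, 0, 0)]
TRIPLE: Pattern = (1, 1, 1)

DEFAULT_N_MAX = 5000


@dataclass
class PatternCounts:
    """Counts of binding patterns over an enhancer universe.

    ``counts[(a, b, c)]`` for the 7 observable patterns; the (0, 0, 0)
    entry (if any) is the *known* unoccupied count and is only available
    from simulation truth — real universes carry 0 there and the latent
    count is inferred by :func:`fit_null_model`.
    """

    counts: dict[Pattern, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[Pattern, float] = {}
        for pat in PATTERNS:
            v = float(self.counts.get(pat, 0))
            if v < 0:
                raise InputError(f"negative count for pattern {pat}")
            clean[pat] = v
        self.counts = clean

    @property
    def n_observed(self) -> float:
        return sum(self.counts[p] for p in NONNULL)

    @property
    def n_unoccupied(self) -> float:
        return self.counts[(0, 0, 0)]

    @property
    def total(self) -> float:
        return self.n_observed + self.n_unoccupied

    @classmethod
    def from_patterns(cls, patterns: np.ndarray, include_null: bool = False) -> "PatternCounts":
        """Tally an (n, 3) array of 0/1 patterns.

        With ``include_null=False`` (the observable situation) the
        (0,0,0) rows are discarded.
        """
        patterns = np.asarray(patterns, dtype=int)
        counts: dict[Pattern, float] = {}
        keys, tallies = np.unique(patterns, axis=0, return_counts=True)
        for key, n in zip(keys, tallies):
            pat = tuple(int(x) for x in key)
            if pat == (0, 0, 0) and not include_null:
                continue
            counts[pat] = float(n)
        return cls(counts)

    def observed_only(self) -> "PatternCounts":
        return PatternCounts({p: self.counts[p] for p in NONNULL})


@dataclass
class NullModelFit:
    """Best-fitting dependent-(A,B) / independent-C model."""

    joint_ab_hat: np.ndarray  # 2x2, joint_ab_hat[a, b]
    p_c_hat: float
    n_unoccupied_hat: int
    log_likelihood: float
    expected: dict[Pattern, float]
    n_max: int
    at_boundary: bool  # argmax hit n_max: the search bound truncated the fit

    @property
    def n_total(self) -> float:
        return sum(self.expected.values())


def build_universe(peaks_a: PeakSet, peaks_b: PeakSet, peaks_c: PeakSet) -> PatternCounts:
    """Pattern counts over the merged union of three peak sets.

    Each merged enhancer is scored 0/1 per factor for >= 1 bp overlap with
    that factor's peak set; every enhancer therefore has at least one bit
    set and the (0,0,0) count is 0.
    """
    if len(peaks_a) == len(peaks_b) == len(peaks_c) == 0:
        raise InputError("all three peak sets are empty")
    universe = merge_intervals(PeakSet(list(peaks_a) + list(peaks_b) + list(peaks_c)))
    trees = [_trees(p) for p in (peaks_a, peaks_b, peaks_c)]
    patterns = np.zeros((len(universe), 3), dtype=int)
    for i, reg in enumerate(universe):
        for k, tr in enumerate(trees):
            tree = tr.get(reg.chrom)
            if tree is not None and tree.overlap(reg.start, reg.end):
                patterns[i, k] = 1
    return PatternCounts.from_patterns(patterns, include_null=False)


def _profile_loglik(counts: dict[Pattern, float], n0_grid: np.ndarray) -> np.ndarray:
    """Profile log-likelihood over the latent-count grid.

    For each n0: N = n_obs + n0, plug-in q_ab = m_ab / N (with the n0
    added to the (0,0) margin) and p = m_c / N. The full multinomial
    log-likelihood is

        log N! - sum_abc log n_abc! + sum_abc n_abc log P(a,b,c),

    and only the ``log N! - log n0!`` part of the coefficient varies with
    n0. The coefficient is essential: without it the likelihood is
    strictly decreasing in n0 (adding unobserved mass only dilutes the
    observed cells) and the latent count would always be estimated as 0.
    This is the classic capture-recapture likelihood for "how many sites
    did we fail to observe".
    """
    m = {
        (a, b): counts[(a, b, 0)] + counts[(a, b, 1)]
        for a in (0, 1)
        for b in (0, 1)
    }
    n_obs = sum(counts[p] for p in NONNULL)
    m_c = sum(counts[(a, b, 1)] for a in (0, 1) for b in (0, 1))
    n0 = n0_grid.astype(float)
    N = n_obs + n0
    ll = gammaln(N + 1.0) - gammaln(n0 + 1.0)
    for (a, b), m_ab in m.items():
        m_eff = m_ab + n0 if (a, b) == (0, 0) else m_ab
        ll += xlogy(m_eff, m_eff) - xlogy(m_eff, N)
    ll += xlogy(m_c, m_c) - xlogy(m_c, N)
    ll += xlogy(N - m_c, N - m_c) - xlogy(N - m_c, N)
    return ll


def fit_null_model(pc: PatternCounts, n_max: int = DEFAULT_N_MAX) -> NullModelFit:
    """Maximum-likelihood fit of the null model with latent unoccupied count.

    Scans n0 = 0..n_max; at each candidate the (a,b) joint and P(c=1) are
    plug-in estimates, so the profile likelihood is exact and the grid
    argmax is the global optimum (smallest n0 on ties). The fitted
    expected counts reproduce the observed (a,b) margins and the observed
    c count exactly; only the independence of C constrains the fit.
    """
    counts = {p: pc.counts[p] for p in PATTERNS}
    if pc.n_unoccupied > 0:
        raise InputError(
            "input carries a known (0,0,0) count; pass observed_only() — the "
            "latent count is what this fit infers"
        )
    if pc.n_observed <= 0:
        raise InputError("no observed patterns to fit")
    n0_grid = np.arange(0, int(n_max) + 1)
    ll = _profile_loglik(counts, n0_grid)
    if not np.any(np.isfinite(ll)):
        raise InputError("likelihood is -inf over the whole grid")
    best = int(np.flatnonzero(ll == np.nanmax(ll))[0])  # smallest argmax
    n0 = int(n0_grid[best])
    N = pc.n_observed + n0
    joint = np.zeros((2, 2))
    for a in (0, 1):
        for b in (0, 1):
            m_ab = counts[(a, b, 0)] + counts[(a, b, 1)]
            if (a, b) == (0, 0):
                m_ab += n0
            joint[a, b] = m_ab / N
    p_c = sum(counts[(a, b, 1)] for a in (0, 1) for b in (0, 1)) / N
    expected = {
        (a, b, c): N * joint[a, b] * (p_c if c else 1.0 - p_c)
        for (a, b, c) in PATTERNS
    }
    return NullModelFit(
        joint_ab_hat=joint,
        p_c_hat=float(p_c),
        n_unoccupied_hat=n0,
        log_likelihood=float(ll[best]),
        expected=expected,
        n_max=int(n_max),
        at_boundary=(n0 == int(n_max)),
    )


def triple_excess(pc: PatternCounts, fit: NullModelFit) -> float:
    """Percent excess of observed over expected triple-bound enhancers.

    100 * (observed(1,1,1) / expected(1,1,1) - 1); negative when triples
    are depleted.
    """
    exp_triple = fit.expected[TRIPLE]
    if exp_triple <= 0:
        raise InputError("expected triple count is zero; excess undefined")
    return 100.0 * (pc.counts[TRIPLE] / exp_triple - 1.0)


def fisher_deviation(pc: PatternCounts, fit: NullModelFit) -> float:
    """Two-sided Fisher exact p for the observed-vs-expected triple split.

    Table rows: (observed triple, observed non-triple) and (rounded
    expected triple, rounded expected non-triple), both over the fitted
    universe size N.
    """
    n_total = round(fit.n_total)
    obs_triple = int(round(pc.counts[TRIPLE]))
    exp_triple = int(round(fit.expected[TRIPLE]))
    table = [
        [obs_triple, int(round(fit.n_total)) - obs_triple],
        [exp_triple, n_total - exp_triple],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _expected_observable_counts(
    joint_ab: np.ndarray, p_c: float, triple_boost: float, n: float
) -> dict[Pattern, float]:
    """Expected observable (non-null) counts for n law draws with a boost."""
    counts: dict[Pattern, float] = {}
    for a in (0, 1):
        for b in (0, 1):
            pc1 = min(p_c * triple_boost, 1.0) if (a, b) == (1, 1) else p_c
            for c in (0, 1):
                pat = (a, b, c)
                if pat == (0, 0, 0):
                    continue
                counts[pat] = n * joint_ab[a, b] * (pc1 if c else 1.0 - pc1)
    return counts


def expected_triple_excess(
    joint_ab, p_c: float, triple_boost: float, n_enhancers: int,
    n_max: int = DEFAULT_N_MAX,
) -> float:
    """Fitted triple excess on the *expected* counts of the generative law.

    Deterministic: evaluates the whole inference pipeline on the infinite-
    sample (expected-count) version of the simulation, which is how a
    generative boost maps to a measured excess.
    """
    joint_ab = np.asarray(joint_ab, dtype=float)
    counts = _expected_observable_counts(joint_ab, p_c, triple_boost, n_enhancers)
    pc = PatternCounts(counts)
    fit = fit_null_model(pc, n_max=n_max)
    return triple_excess(pc, fit)


def calibrate_triple_boost(
    target_excess_pct: float,
    joint_ab,
    p_c: float,
    n_enhancers: int,
    n_max: int = DEFAULT_N_MAX,
) -> float:
    """Solve for the generative triple_boost whose fitted excess equals
    ``target_excess_pct``.

    The fitted excess is smaller than the raw boost because the plug-in
    P(c=1) estimate absorbs part of the planted enrichment (to first
    order, excess + 1 = boost / (1 + (boost - 1) * q11)); this inverts the
    exact mapping numerically on expected counts.
    """
    joint_ab = np.asarray(joint_ab, dtype=float)
    if joint_ab[1, 1] <= 0 or not 0 < p_c < 1:
        raise InputError("calibration needs joint_ab[1,1] > 0 and 0 < p_c < 1")
    hi = min(0.999 / p_c, 50.0)

    def f(b: float) -> float:
        return (
            expected_triple_excess(joint_ab, p_c, b, n_enhancers, n_max)
            - target_excess_pct
        )

    if f(hi) < 0:
        raise InputError(
            f"target excess {target_excess_pct}% not reachable with p_c={p_c}"
        )
    return float(optimize.brentq(f, 1.0, hi, xtol=1e-6))


def pattern_simulation_power(
    cfg,
    n_seeds: int,
    base_seed: int = 0,
    alpha: float = 0.05,
    n_max: int = DEFAULT_N_MAX,
    use_peak_calling: bool = False,
    genome=None,
) -> pd.DataFrame:
    """End-to-end co-occupancy validation over simulation seeds.

    For each seed: draw patterns under ``cfg`` (with the configured
    triple_boost), count observable patterns, fit the null model, and
    record the excess and Fisher p. With ``use_peak_calling=True`` the
    patterns are realised as planted sites and signal tracks, peaks are
    called per factor, and the universe is built from the called peak
    sets (slower, exercises the full pipeline).

    Returns a DataFrame with one row per seed (seed, n_unoccupied_hat,
    at_boundary, excess, fisher_p, reject) whose ``reject`` rate
    summarises power at level ``alpha``.
    """
    from dataclasses import replace

    from . import simulate
    from .peaks import call_peaks

    rows = []
    for s in range(n_seeds):
        seed = int(base_seed) + s
        cfg_s = replace(cfg, seed=seed)
        if use_peak_calling:
            g = genome if genome is not None else simulate.GenomeSpec()
            truth = simulate.plant_sites(g, cfg_s)
            called = [
                call_peaks(simulate.simulate_chip_track(truth, cfg_s, f))
                for f in ("A", "B", "C")
            ]
            pc = build_universe(*called)
        else:
            pats = simulate.sample_patterns(cfg_s)
            pc = PatternCounts.from_patterns(pats, include_null=False)
        fit = fit_null_model(pc, n_max=n_max)
        excess = triple_excess(pc, fit)
        p = fisher_deviation(pc, fit)
        rows.append(
            {
                "seed": seed,
                "n_unoccupied_hat": fit.n_unoccupied_hat,
                "at_boundary": fit.at_boundary,
                "excess": excess,
                "fisher_p": p,
                "reject": p < alpha,
            }
        )
    return pd.DataFrame(rows)
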