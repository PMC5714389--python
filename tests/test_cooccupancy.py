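"""Co-occupancy null model: universe construction, latent-count likelihood,
triple excess, Fisher deviation, calibration."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from cooccupy import simulate
from cooccupy.cooccupancy import (
    NONNULL,
    PATTERNS,
    PatternCounts,
    build_universe,
    calibrate_triple_boost,
    expected_triple_excess,
    fisher_deviation,
    fit_null_model,
    pattern_simulation_power,
    triple_excess,
    _profile_loglik,
)
from cooccupy.core import InputError, PeakSet, Region

from conftest import random_peakset, regions


# correctly specified generative law: latent nulls arise from the law itself
WELL_SPECIFIED = dict(
    joint_ab=[[1 / 14, (1 - 0.3 - 1 / 14) / 2], [(1 - 0.3 - 1 / 14) / 2, 0.3]],
    p_c=0.3,
)


class TestBuildUniverse:
    def test_disjoint_single_factor_sets(self):
        a = regions((0, 100), (1000, 1100))
        b = regions((5000, 5100))
        c = regions((9000, 9100), (12_000, 12_100), (15_000, 15_100))
        pc = build_universe(a, b, c)
        assert pc.counts[(1, 0, 0)] == 2
        assert pc.counts[(0, 1, 0)] == 1
        assert pc.counts[(0, 0, 1)] == 3
        assert pc.n_observed == 6 and pc.n_unoccupied == 0

    def test_identical_sets_give_one_triple(self):
        a = regions((0, 100))
        pc = build_universe(a, a, a)
        assert pc.counts[(1, 1, 1)] == 1 and pc.n_observed == 1

    def test_all_empty_rejected(self):
        empty = PeakSet()
        with pytest.raises(InputError):
            build_universe(empty, empty, empty)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sets = [random_peakset(rng, n=100, span=20_000) for _ in range(3)]
        pc = build_universe(*sets)
        # oracle: merge by hand, test each enhancer against each raw set
        from conftest import naive_merge

        merged = naive_merge(PeakSet([r for s in sets for r in s]))
        expected: dict = {p: 0 for p in PATTERNS}
        for chrom, start, end in merged:
            bits = []
            for s in sets:
                hit = any(
                    r.chrom == chrom and r.start < end and start < r.end for r in s
                )
                bits.append(int(hit))
            expected[tuple(bits)] += 1
        for p in NONNULL:
            assert pc.counts[p] == expected[p]


def loglik_oracle(counts: dict, n0: int) -> float:
    """Independent evaluation: exact multinomial log-pmf at the plug-in
    parameters (written against scipy, not the package's algebra)."""
    full = dict(counts)
    full[(0, 0, 0)] = n0
    N = sum(full.values())
    q = {
        (a, b): sum(full[(a, b, c)] for c in (0, 1)) / N
        for a in (0, 1)
        for b in (0, 1)
    }
    p_c = sum(full[(a, b, 1)] for a in (0, 1) for b in (0, 1)) / N
    probs, ns = [], []
    for pat in PATTERNS:
        a, b, c = pat
        probs.append(q[(a, b)] * (p_c if c else 1 - p_c))
        ns.append(full[pat])
    return float(stats.multinomial(int(N), probs).logpmf(ns))


class TestFitNullModel:
    TOY = {
        (0, 0, 1): 8, (0, 1, 0): 12, (0, 1, 1): 5, (1, 0, 0): 14,
        (1, 0, 1): 6, (1, 1, 0): 9, (1, 1, 1): 4,
    }

    def test_profile_matches_multinomial_oracle_up_to_constant(self):
        grid = np.arange(0, 41)
        ll = _profile_loglik({**{p: 0.0 for p in PATTERNS}, **self.TOY}, grid)
        oracle = np.array([loglik_oracle(self.TOY, n0) for n0 in grid])
        # observed-cell factorials are constant in n0, so curves differ by a
        # constant shift only
        diffs = ll - oracle
        assert np.allclose(diffs, diffs[0])
        assert np.argmax(ll) == np.argmax(oracle)

    def test_toy_argmax_is_global_on_full_scan(self):
        pc = PatternCounts(dict(self.TOY))
        fit = fit_null_model(pc, n_max=500)
        grid = np.arange(0, 501)
        ll = _profile_loglik(pc.counts, grid)
        assert fit.n_unoccupied_hat == int(np.flatnonzero(ll == ll.max())[0])
        assert fit.log_likelihood == pytest.approx(ll.max())

    def test_perfect_independence_expected_triple(self):
        # q(1,1) = 0.25, p = 0.5 exactly; expected triple = N/8
        counts = {}
        for pat in NONNULL:
            a, b, c = pat
            counts[pat] = 800 * 0.25 * 0.5  # uniform over (a,b) x c
        pc = PatternCounts(counts)
        fit = fit_null_model(pc, n_max=500)
        # consistent completion: ~100 latent nulls restore the product law
        assert fit.n_unoccupied_hat == pytest.approx(100, abs=2)
        assert fit.expected[(1, 1, 1)] == pytest.approx(100.0, rel=5e-3)
        assert fit.p_c_hat == pytest.approx(0.5, abs=5e-3)

    def test_recovery_of_latent_count(self):
        cfg = simulate.FactorSimConfig(
            n_enhancers=20_000, seed=42, triple_boost=1.0, **WELL_SPECIFIED
        )
        pats = simulate.sample_patterns(cfg)
        n_null_true = int((pats.sum(axis=1) == 0).sum())
        fit = fit_null_model(PatternCounts.from_patterns(pats))
        assert n_null_true == pytest.approx(1000, abs=150)
        assert abs(fit.n_unoccupied_hat - n_null_true) / n_null_true < 0.15

    def test_conservation_invariants(self):
        pc = PatternCounts(dict(self.TOY))
        fit = fit_null_model(pc, n_max=200)
        N = pc.n_observed + fit.n_unoccupied_hat
        assert sum(fit.expected.values()) == pytest.approx(N, abs=1e-6)
        for a in (0, 1):
            for b in (0, 1):
                obs_ab = self.TOY.get((a, b, 0), 0) + self.TOY.get((a, b, 1), 0)
                if (a, b) == (0, 0):
                    obs_ab += fit.n_unoccupied_hat
                exp_ab = fit.expected[(a, b, 0)] + fit.expected[(a, b, 1)]
                assert exp_ab == pytest.approx(obs_ab, abs=1e-9)
        obs_c = sum(self.TOY.get((a, b, 1), 0) for a in (0, 1) for b in (0, 1))
        exp_c = sum(fit.expected[(a, b, 1)] for a in (0, 1) for b in (0, 1))
        assert exp_c == pytest.approx(obs_c, abs=1e-9)

    def test_boundary_hit_is_flagged(self):
        cfg = simulate.FactorSimConfig(
            n_enhancers=20_000, seed=7, triple_boost=1.0, **WELL_SPECIFIED
        )
        pc = PatternCounts.from_patterns(simulate.sample_patterns(cfg))
        fit = fit_null_model(pc, n_max=300)  # true latent ~1000 > n_max
        assert fit.at_boundary and fit.n_unoccupied_hat == 300

    def test_known_null_count_rejected(self):
        pc = PatternCounts({(0, 0, 0): 5, (1, 1, 1): 5})
        with pytest.raises(InputError):
            fit_null_model(pc)
        fit_null_model(pc.observed_only(), n_max=10)  # stripped input is fine


class TestTripleExcess:
    def test_zero_when_observed_equals_expected(self):
        pc = PatternCounts({p: 10 for p in NONNULL})
        fit = fit_null_model(pc, n_max=100)
        pc_matched = PatternCounts(
            {p: fit.expected[p] for p in NONNULL}
        )
        assert triple_excess(pc_matched, fit) == pytest.approx(0.0)

    def test_seventy_percent_by_arithmetic(self):
        pc = PatternCounts({**{p: 10 for p in NONNULL}, (1, 1, 1): 170})
        fit = fit_null_model(PatternCounts({**{p: 10 for p in NONNULL}}), n_max=0)
        fit.expected[(1, 1, 1)] = 100.0
        assert triple_excess(pc, fit) == pytest.approx(70.0)

    def test_monotone_in_triple_count_with_refit(self):
        base = {p: 50.0 for p in NONNULL}
        last = -np.inf
        for triple in (10, 30, 50, 80, 120, 200):
            pc = PatternCounts({**base, (1, 1, 1): triple})
            ex = triple_excess(pc, fit_null_model(pc, n_max=500))
            assert ex >= last
            last = ex

    def test_null_simulation_centers_at_zero_and_boost_detected(self):
        cfg = simulate.FactorSimConfig(
            n_enhancers=20_000, seed=0, triple_boost=1.0, **WELL_SPECIFIED
        )
        ex = []
        for s in range(10):
            pc = PatternCounts.from_patterns(
                simulate.sample_patterns(replace(cfg, seed=s))
            )
            ex.append(triple_excess(pc, fit_null_model(pc)))
        se = np.std(ex, ddof=1) / np.sqrt(len(ex))
        assert abs(np.mean(ex)) < 3 * se + 1e-9


def fisher_oracle(table) -> float:
    """Brute-force two-sided Fisher p: enumerate all tables with the same
    margins, sum hypergeometric point masses <= the observed one."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def point(x):
        return np.exp(
            gammaln(row1 + 1) - gammaln(x + 1) - gammaln(row1 - x + 1)
            + gammaln(n - row1 + 1) - gammaln(col1 - x + 1)
            - gammaln(n - row1 - col1 + x + 1)
            - (gammaln(n + 1) - gammaln(col1 + 1) - gammaln(n - col1 + 1))
        )

    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    p_obs = point(a)
    return float(
        sum(point(x) for x in range(lo, hi + 1) if point(x) <= p_obs * (1 + 1e-12))
    )


class TestFisherDeviation:
    def test_observed_equals_expected_p_one(self):
        pc = PatternCounts({p: 10 for p in NONNULL})
        fit = fit_null_model(pc, n_max=100)
        pc_matched = PatternCounts({p: round(fit.expected[p]) for p in NONNULL})
        assert fisher_deviation(pc_matched, fit) > 0.9

    def test_symmetric_table_p_one(self):
        assert stats.fisher_exact([[5, 5], [5, 5]])[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_scipy_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 50, size=(2, 2))
        p_scipy = stats.fisher_exact(table)[1]
        assert p_scipy == pytest.approx(fisher_oracle(table), abs=1e-12)


class TestCalibration:
    def test_boost_one_gives_zero_expected_excess(self):
        ex = expected_triple_excess(WELL_SPECIFIED["joint_ab"], 0.3, 1.0, 20_000)
        assert abs(ex) < 0.5

    def test_calibrated_boost_hits_target(self):
        b = calibrate_triple_boost(70.0, WELL_SPECIFIED["joint_ab"], 0.3, 20_000)
        assert b > 1.0
        ex = expected_triple_excess(WELL_SPECIFIED["joint_ab"], 0.3, b, 20_000)
        assert ex == pytest.approx(70.0, abs=0.01)

    def test_unreachable_target_rejected(self):
        with pytest.raises(InputError):
            calibrate_triple_boost(5000.0, WELL_SPECIFIED["joint_ab"], 0.9, 20_000)


class TestSimulationHarness:
    def test_null_runs_do_not_hit_boundary_and_rarely_reject(self):
        cfg = simulate.FactorSimConfig(
            n_enhancers=5000, seed=0, triple_boost=1.0, **WELL_SPECIFIED
        )
        df = pattern_simulation_power(cfg, n_seeds=10, base_seed=0)
        assert not df.at_boundary.any()
        assert df.reject.mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 10)

    def test_strong_boost_is_detected(self):
        cfg = simulate.FactorSimConfig(
            n_enhancers=3000, seed=0, triple_boost=2.0, **WELL_SPECIFIED
        )
        df = pattern_simulation_power(cfg, n_seeds=10, base_seed=0)
        assert df.reject.mean() >= 0.9
        assert df.excess.mean() > 30

    def test_peak_calling_variant_runs_end_to_end(self):
        g = simulate.GenomeSpec(
            chrom_names=["chr2L"], chrom_lengths=[600_000], probe_spacing=50
        )
        cfg = simulate.FactorSimConfig(
            n_enhancers=120, site_width_bp=1500, min_gap_bp=2000,
            noise_sd=0.3, seed=0, **WELL_SPECIFIED
        )
        df = pattern_simulation_power(
            cfg, n_seeds=2, base_seed=0, use_peak_calling=True, genome=g
        )
        assert len(df) == 2
        assert np.isfinite(df.excess).all()
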