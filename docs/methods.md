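# Methods

`cooccupy` re-implements, as a tested library, the computational core of a
co-repressor genomic-landscape analysis on tiling arrays: probe-level peak
calling for ChIP-chip and DamID tracks, high-confidence profile
intersection, interval overlap and annotation statistics, a sliding-window
differential test for histone-acetylation changes with an empirical
replicate-noise null, and a combinatorial co-occupancy null model that
infers a latent count of unoccupied candidate enhancers. A synthetic-data
module generates tiling-array-like inputs with fully known ground truth so
every stage can be validated end to end.

## Peak calling (`cooccupy.peaks`)

Probe-level log2 enrichment values from replicated hybridisations are
processed in four stages:

1. **Smoothing.** The replicate-mean signal is smoothed with a running
   median over all probes within ±`win_half_size_bp` (default 700 bp) of
   each probe; a score is masked when the window holds fewer than
   `min_probes` (default 10) probes. The median is the robust choice for
   block-shaped enrichment with outlier probes.
2. **Empirical Gaussian null ("normalNull").** Most probes are unbound, so
   the bulk of the smoothed-score distribution is treated as the null. Its
   center is estimated as the mode of a Gaussian kernel density (Scott's
   bandwidth × 2; the oversmoothing suppresses argmax jitter on the flat
   top of the bulk, which would otherwise bias the spread estimate — at
   n = 5000 the mode error drops from ~0.23σ to ~0.1σ). The null sd is
   1.4826 × median(|score − mode|) over scores at or below the mode: only
   the lower half is used, mirrored, so genuine enrichment in the upper
   tail cannot inflate the null. Per-probe p-values are upper-tail
   Gaussian probabilities under this null.
3. **Multiple testing.** Benjamini–Hochberg step-up adjustment (via
   statsmodels), producing per-probe q-values.
4. **Condensation.** Probes with q ≤ FDR (1% default for ChIP, 10% for
   DamID, whose fragment-level signal is noisier and broader) are grouped:
   consecutive significant probes at most `dist_cutoff_bp` (200 bp) apart
   join one region; groups with fewer than `min_probes` significant probes
   are discarded. Probes are points, so a region spans
   `[first_probe, last_probe + 1)`.

`min_probes` is applied both as window support and as region support; the
two uses are separately configurable. A high-confidence profile is the set
of ChIP regions overlapping (≥ 1 bp) any DamID region, keeping ChIP
geometry — the broader DamID profile acts purely as a confirmation filter.

Degenerate inputs are errors by design: fewer than 100 unmasked scores, or
a score distribution with zero spread, make the null unestimable and raise
instead of returning arbitrary p-values. This is why a strictly noiseless
track cannot be peak-called; validation uses small-but-nonzero noise
(e.g. enrichment 40× the noise sd) for round-trip tests and asserts exact
footprints at the simulator level instead.

## Interval analytics (`cooccupy.intervals`)

All coordinates are 0-based half-open. Overlap counting treats each region
of the query set as one trial: a region of A spanning two regions of B is
a single hit. Vicinity queries count a hit when the bp gap between two
intervals is ≤ the window (inclusive; window 0 reduces to plain overlap).
Peak-to-gene assignment is many-to-many within an inclusive,
strand-agnostic 10 kb edge-to-edge distance. Chromatin-state annotation
assigns each peak the state with maximal bp overlap, breaking exact ties
by segmentation file order (tie count logged) and labelling uncovered
peaks "unassigned". The top-k signal correlation builds the enhancer
universe as the merged union of both peak sets, scores each enhancer with
the mean track signal over its span, ranks by fold enrichment
(max of the two values, descending, genomic order on ties) and returns the
Pearson r with its two-sided p over the top k (default 100).

There is deliberately **no default vicinity window**: no principled value
exists independent of the data, so callers must choose one explicitly.

## Differential windows (`cooccupy.diffsignal`)

Windows of `window_bp` (2000) tile each chromosome at `step_bp` (1000, a
half-window step — a reasonable reading of "sliding" that keeps the test
count manageable; configurable). Per window and replicate the probe mean
is taken; empty windows are dropped. The test statistic per window is
|mean(treated) − mean(control)| of the replicate-averaged means.

The null sample pools |rep_i − rep_j| of window means over all windows and
all within-condition replicate pairs, then rescales by
√((1/r_c + 1/r_t)/2): a raw replicate pair difference has noise variance
2σ², while the tested difference of condition means has σ²(1/r_c + 1/r_t),
and matching the two scales is what makes null p-values uniform (verified:
KS ≈ 0.03 against U(0,1) at 2000 windows; unscaled pooling gives a
conservative KS ≈ 0.17 and is available via a flag). P-values are
empirical upper-tail with add-one continuity,
p = (1 + #{null ≥ Δ}) / (1 + |null|), then BH-adjusted with the same
implementation the peak caller uses. Windows with q ≤ 1% merge into
maximal same-direction regions; regions of opposite sign never merge.

Two floors follow from this construction and matter in practice. With r
replicates per condition and W windows the null has W·2·C(r,2) values, so
the smallest attainable p is ~1/(2W) and the smallest attainable BH q for
k significant windows is ~0.5/k: at 1% FDR a signal must light up ≥ ~50
windows genome-wide before *anything* can be called. Validation therefore
plants 20 ten-window regions rather than one.

## Co-occupancy null model (`cooccupy.cooccupancy`)

Three factors A, B, C are scored 0/1 over an enhancer universe (merged
union of their peak sets, ≥ 1 bp overlap per factor). The null model lets
the (A, B) pair be arbitrarily dependent and constrains only C:

    P(a, b, c) = q_ab · p^c (1 − p)^(1−c)

The (0,0,0) cell is unobservable, so the universe size is
N = n_observed + n₀ with n₀ ∈ {0..n_max} (default 5000) a latent count.
For each candidate n₀ the remaining parameters have closed-form plug-in
MLEs (q̂_ab = m_ab/N with n₀ added to the (0,0) margin; p̂ = m_c/N), giving
the profile log-likelihood

    ℓ(n₀) = log N! − log n₀! + Σ_ab m_ab log q̂_ab + m_c log p̂ + (N−m_c) log(1−p̂)

up to constants. The combinatorial coefficient is essential: without it
the profile is strictly decreasing in n₀ (its derivative is
log q̂₀₀ + log(1−p̂) < 0), so the latent count would always be estimated as
zero. This is the classic capture–recapture likelihood for an unobserved
multinomial cell. The integer grid is scanned exhaustively (n_max ≤ 5000
makes this cheap and guarantees the global argmax; smallest n₀ wins ties;
a fit at the n_max boundary is flagged). By the plug-in property the
fitted expected counts reproduce the observed (a,b) margins and the
observed C count exactly — only C-independence is testable.

The headline statistic is the **triple excess**,
100·(observed(1,1,1)/expected(1,1,1) − 1), with a two-sided Fisher exact
test on the 2×2 table [observed triple vs rest; rounded expected triple vs
rest]. Because the expected row is fitted to the same data and Fisher
treats the rows as independent samples, this test is intrinsically
conservative: its null rejection rate is far below the nominal level
(measured ≈ 0 at α = 0.05 over 200 null simulations), while power against
a doubled triple rate at 3000 enhancers is ≈ 1. Validation therefore
checks type-I *control* (rate ≤ α), not equality with α.

### Calibrating a generative boost to a measured excess

The simulator plants deviations from the null by multiplying
P(C=1 | A=1, B=1) by `triple_boost` b. The measured excess is smaller than
b − 1 because the plug-in p̂ absorbs part of the planted enrichment: to
first order excess + 1 = b / (1 + (b−1)·q₁₁). `calibrate_triple_boost`
inverts the exact mapping numerically — it evaluates the whole fit on the
infinite-sample expected counts and solves for b by bracketing — so a
target excess (e.g. 70%) can be planted exactly. Under the reference
configuration (q₁₁ = 0.3, p = 0.3, ~1000 latent nulls among 20,000 sites)
a 70% excess requires b ≈ 2.55; the naive guess b = 1.7 yields only ~39%.

## Synthetic data (`cooccupy.simulate`)

The generator realises exactly the statistical structure the analyses
assume, plus controlled violations:

- **Patterns**: (a,b) ~ a configurable 2×2 joint law; c | (a,b) ~
  Bernoulli(p_c), boosted when a=b=1. `n_unoccupied_true` forced null
  sites can be added on top of the law draws; note the law itself may
  also produce null sites (the realized null count is recorded in the
  truth object, and is the quantity latent-count recovery is scored
  against).
- **Placement**: sites are placed uniformly over all non-overlapping
  configurations with a minimum gap, via the order-statistics transform
  (sorted uniform draws on the gap-deflated interval) — exact, O(n log n),
  and incapable of infinite rejection loops; capacity violations raise
  up front. The default gap (400 bp = 2× the condensation cutoff) keeps
  regions separate at the condensation stage, but configurations meant
  for per-site counting use ≥ 2000 bp so the ±700 bp smoothing window
  cannot bridge neighbouring sites either.
- **ChIP tracks**: baseline 0, plus `enrichment_log2` (default 2.0) on
  probes inside bound sites, plus i.i.d. Gaussian probe noise
  (`noise_sd`, default 0.5) per replicate. These magnitudes are chosen as
  realistic for log2 fold-enrichment tiling data (clear but not trivial
  signal at ~4σ per probe); they are package defaults, not measured
  values.
- **DamID tracks**: GATC sites with geometric (memoryless) inter-site
  gaps, mean 256 bp (the expectation for a random tetramer); enrichment
  is smeared over every GATC fragment touching a bound site, which makes
  DamID footprints systematically broader than ChIP footprints — the
  qualitative bias of methylation-based profiling.
- **Acetylation tracks**: two conditions sharing a probe map; the treated
  mean adds a per-region effect (log2, signed) inside planted
  differential regions; ≥ 2 replicates enforced because the differential
  null needs replicate pairs.
- **Streams**: every draw comes from a stream keyed by (purpose, factor,
  replicate) derived from the master seed, so identical configs are
  bit-reproducible and adding replicates never perturbs earlier ones.

What the generator does **not** model: probe affinity/GC effects,
sequence-level structure, array-edge artefacts, non-Gaussian noise,
spatially correlated background, or partial/graded occupancy. Passing
tests demonstrate internal consistency of the statistics under their own
assumptions, not robustness to those real-data complications.

## Validation problem sizes

Round-trip and calibration checks run on deliberately small instances
chosen so the whole suite stays fast while estimates remain stable: peak
calling on a 200 kb chromosome at 50 bp probe spacing (20 planted 1.5 kb
sites; 20 recovery seeds, 100 pure-noise seeds), differential windows on
a 2 Mb chromosome at 100 bp spacing (2000 windows; 100 null and 100 power
seeds), and pattern-level co-occupancy fits on 20,000-site universes (50
seeds; 200 null seeds at 5000 sites for Fisher calibration). The
acceptance script averages the fitted triple excess over 50 simulated
20,000-site universes.

## Known limitations

- The normalNull estimators (KDE mode, lower-half MAD) follow the
  documented construction above; no claim is made of bit-equivalence with
  any other implementation of the same idea.
- The empirical-null differential test cannot call isolated short effects
  at stringent FDR (p-value floor; see above) — a property of the method,
  not of the implementation.
- The co-occupancy fit assumes every candidate enhancer is exchangeable;
  n₀ is a point estimate without an uncertainty interval, and fits at the
  n_max boundary mean the universe bound, not the data, determined it.
- Fitting is implemented for the 3-factor dependent-pair +
  independent-singleton structure only, although the pattern containers
  admit k factors.
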