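# cooccupy

Tiling-array analytics for co-repressor genomic landscapes: probe-level
ChIP-chip / DamID peak calling, interval overlap and annotation
statistics, sliding-window differential-signal detection, and a
combinatorial transcription-factor co-occupancy null model with a latent
unoccupied-enhancer count.

## Who this is for

Genome-scale studies of transcriptional co-repressors (e.g. Notch-pathway
factors such as Su(H), Hairless and SMRTER in *Drosophila*) ask questions
like: where does each factor bind, which bindings are trustworthy when two
assays disagree, does depleting a factor change histone acetylation
locally, and do three factors co-occur at the same enhancers more often
than chance allows? `cooccupy` provides each of those analyses as tested,
composable library functions plus a thin CLI, together with a simulator
that generates tiling-array-like data with known ground truth so the whole
pipeline can be validated quantitatively.

## The statistical core

**Peak calling.** Replicate-mean probe signal is median-smoothed in
±700 bp windows (≥10 probes), given upper-tail p-values under an
empirically fitted Gaussian null (center = density mode, spread = scaled
lower-half MAD, so enrichment cannot contaminate the null), BH-corrected,
and condensed into regions with a 200 bp gap cutoff (1% FDR for ChIP, 10%
for the broader DamID signal). A high-confidence profile keeps ChIP
regions confirmed by ≥1 bp of DamID overlap.

**Differential windows.** In sliding 2 kb windows (1 kb step), the
between-condition difference of mean signal is compared with an empirical
noise null built from within-condition replicate differences (rescaled to
the variance of a difference of condition means); empirical p-values are
BH-corrected and significant same-direction windows merge into
differential regions at 1% FDR.

**Co-occupancy null model.** Over an enhancer universe (merged peak
union), binding patterns (a,b,c) ∈ {0,1}³ are modelled as

    P(a,b,c) = q_ab · p^c (1−p)^(1−c),

i.e. an arbitrary dependent (A,B) block and an independent C. The
unobservable (0,0,0) count n₀ is inferred by maximising the
capture–recapture profile likelihood on the grid n₀ ∈ {0..5000}. The
headline statistic is the triple excess
100·(obs(1,1,1)/exp(1,1,1) − 1) with a Fisher exact deviation test.

## Worked example

Run the full synthetic pipeline (simulate three factors on a 2 Mb toy
genome, call peaks, intersect ChIP×DamID, fit the co-occupancy model):

```bash
cooccupy pipeline --seed 42 --out-dir demo_out
```

which prints (abridged):

```json
{
  "cooccupancy": {
    "pattern_counts": {"001": 62.0, "010": 32.0, "011": 9.0, "100": 24.0,
                        "101": 17.0, "110": 92.0, "111": 46.0},
    "n_unoccupied_hat": 125,
    "p_c_hat": 0.329,
    "triple_excess_pct": 1.24,
    "fisher_p": 1.0
  }
}
```

Reading this: 282 enhancers were observed bound by at least one factor;
the likelihood fit adds 125 latent unoccupied candidate enhancers and
estimates P(C bound) ≈ 0.33. The observed triple-bound count (46) exceeds
the model expectation (45.4) by only 1.2%, with Fisher p = 1.0 — correct,
because this simulation planted *no* dependence of C on (A,B)
(`triple_boost = 1`). The per-stage region counts land in
`demo_out/report.json` (here: 180/181/134 ChIP regions for A/B/C, 177
DamID regions, 181 high-confidence B regions, A–B overlap fraction 0.77
reflecting the planted dependent (A,B) block).

Each stage is also exposed on its own (`cooccupy callpeaks`,
`hc-intersect`, `overlap`, `vicinity`, `assign-genes`, `annotate-states`,
`topk-cor`, `diffwindows`, `coocc`, `simulate`), and everything the CLI
does is a one-line call into the library.

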