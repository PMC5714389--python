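"""Synthetic tiling-array data with known ground truth.

The generator mirrors the statistical structure the downstream analyses
assume: three factors (A, B, C) occupy candidate enhancer sites, where the
(A, B) pair follows an arbitrary dependent 2x2 joint law and C is Bernoulli
and independent of (A, B) except through an optional ``triple_boost`` that
multiplies P(C=1 | A=1, B=1). ``triple_boost == 1`` reproduces exactly the
null model fitted by :mod:`cooccupy.cooccupancy`; larger values plant the
kind of triple-binding excess the model is meant to detect.

Signal tracks are baseline-0 log2 enrichment plus i.i.d. Gaussian probe
noise per replicate. ChIP tracks gain enrichment only on probes inside a
bound site; DamID tracks smear the enrichment over every GATC restriction
fragment that touches a bound site, which makes DamID footprints
systematically broader than ChIP footprints over the same truth.

Randomness: every draw comes from a stream derived from the master seed by
fixed labelled sub-seeding (``SeedSequence(seed, spawn_key=...)``), so e.g.
adding a replicate never perturbs earlier replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import CapacityError, ConfigurationError, InputError, ProbeTrack

__all__ = [
    "GenomeSpec",
    "FactorSimConfig",
    "TruthSite",
    "TruthSet",
    "make_probe_map",
    "sample_patterns",
    "plant_sites",
    "simulate_chip_track",
    "simulate_damid_track",
    "simulate_two_condition_acetylation",
    "gatc_sites",
]

FACTOR_INDEX = {"A": 0, "B": 1, "C": 2}

# fixed stream labels for sub-seeding
_STREAMS = {
    "pattern": 0,
    "placement": 1,
    "chip_A": 10,
    "chip_B": 11,
    "chip_C": 12,
    "gatc": 20,
    "damid_A": 30,
    "damid_B": 31,
    "damid_C": 32,
    "acetyl_control": 40,
    "acetyl_treated": 41,
}


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[stream], *map(int, extra)))
    )


@dataclass
class GenomeSpec:
    """Layout of a toy tiling-array genome.

    probe_spacing is the distance between consecutive probe centers (the
    real array has ~35-50 bp resolution); gatc_spacing is the mean distance
    between GATC sites, drawn with geometric (memoryless) gaps, roughly the
    4^4 = 256 bp expectation of a random tetramer.
    """

    chrom_names: list[str] = field(default_factory=lambda: ["chr2L"])
    chrom_lengths: list[int] = field(default_factory=lambda: [2_000_000])
    probe_spacing: int = 50
    gatc_spacing: float = 256.0

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ConfigurationError("chrom_names and chrom_lengths length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ConfigurationError("duplicate chromosome names")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ConfigurationError("chromosome lengths must be positive")
        if self.probe_spacing < 1:
            raise ConfigurationError("probe_spacing must be >= 1")
        if self.gatc_spacing <= 1:
            raise ConfigurationError("gatc_spacing must be > 1")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))


@dataclass
class FactorSimConfig:
    """Generative parameters for the three-factor occupancy simulation.

    joint_ab is the 2x2 probability table over (A, B) occupancy, indexed
    ``joint_ab[a][b]``; p_c the marginal probability of C; triple_boost
    multiplies P(C=1 | A=1, B=1) (1.0 = the exact independence null).
    n_unoccupied_true adds that many sites bound by no factor on top of the
    n_enhancers law draws. Enrichment/noise are in log2 units.
    """

    n_enhancers: int = 500
    site_width_bp: int = 1500
    joint_ab: Sequence[Sequence[float]] = field(
        default_factory=lambda: [[0.5, 0.1], [0.1, 0.3]]
    )
    p_c: float = 0.3
    triple_boost: float = 1.0
    n_unoccupied_true: int = 0
    enrichment_log2: float = 2.0
    noise_sd: float = 0.5
    n_replicates: int = 2
    min_gap_bp: int = 400  # 2 x distCutOff: planted sites never merge
    seed: int = 0

    def __post_init__(self) -> None:
        j = np.asarray(self.joint_ab, dtype=float)
        if j.shape != (2, 2) or np.any(j < 0) or not np.isclose(j.sum(), 1.0):
            raise ConfigurationError(
                "joint_ab must be a 2x2 non-negative table summing to 1"
            )
        if not 0.0 <= self.p_c <= 1.0:
            raise ConfigurationError("p_c must lie in [0, 1]")
        if self.triple_boost < 0:
            raise ConfigurationError("triple_boost must be >= 0")
        if self.p_c * self.triple_boost > 1.0 + 1e-12:
            raise ConfigurationError(
                f"P(C=1|A=1,B=1) = p_c * triple_boost = "
                f"{self.p_c * self.triple_boost:.3f} exceeds 1"
            )
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.n_enhancers < 0 or self.n_unoccupied_true < 0:
            raise ConfigurationError("site counts must be non-negative")
        if self.site_width_bp < 1:
            raise ConfigurationError("site_width_bp must be >= 1")

    @property
    def joint(self) -> np.ndarray:
        return np.asarray(self.joint_ab, dtype=float)


@dataclass(frozen=True)
class TruthSite:
    chrom: str
    start: int
    end: int
    pattern: tuple[int, int, int]


@dataclass
class TruthSet:
    """Planted ground truth: sites with binding patterns, differential
    regions, and an echo of the generating configuration."""

    sites: list[TruthSite]
    genome: GenomeSpec
    config_echo: FactorSimConfig | None = None
    differential_regions: list[tuple[str, int, int, float]] = field(default_factory=list)

    def patterns(self) -> np.ndarray:
        return np.array([s.pattern for s in self.sites], dtype=np.int8).reshape(-1, 3)

    def n_null(self) -> int:
        """Realized count of (0,0,0) sites (the true latent unoccupied count)."""
        return int(sum(1 for s in self.sites if s.pattern == (0, 0, 0)))

    def sites_for_factor(self, factor: str) -> list[TruthSite]:
        k = FACTOR_INDEX.get(factor.upper())
        if k is None:
            raise InputError(f"unknown factor {factor!r}; expected A, B or C")
        return [s for s in self.sites if s.pattern[k] == 1]


def make_probe_map(genome: GenomeSpec) -> ProbeTrack:
    """Probe positions at regular spacing per chromosome (no signal)."""
    chroms: list[str] = []
    pos: list[np.ndarray] = []
    for name, length in zip(genome.chrom_names, genome.chrom_lengths):
        p = np.arange(0, length, genome.probe_spacing, dtype=np.int64)
        chroms.extend([name] * len(p))
        pos.append(p)
    allpos = np.concatenate(pos) if pos else np.empty(0, dtype=np.int64)
    return ProbeTrack(np.array(chroms, dtype=object), allpos, None, label="probe_map")


def sample_patterns(cfg: FactorSimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``(n_enhancers + n_unoccupied_true, 3)`` occupancy patterns.

    The first n_enhancers rows are i.i.d. draws from the configured law
    ((a,b) ~ joint_ab; c | a,b ~ Bernoulli(p_c, boosted when a=b=1)); the
    trailing n_unoccupied_true rows are forced (0,0,0).
    """
    if rng is None:
        rng = _rng(cfg.seed, "pattern")
    n = cfg.n_enhancers
    flat = cfg.joint.reshape(-1)  # cells (0,0),(0,1),(1,0),(1,1)
    cell = rng.choice(4, size=n, p=flat)
    a = cell // 2
    b = cell % 2
    p = np.where((a == 1) & (b == 1), min(cfg.p_c * cfg.triple_boost, 1.0), cfg.p_c)
    c = (rng.random(n) < p).astype(np.int8)
    pat = np.column_stack([a.astype(np.int8), b.astype(np.int8), c])
    if cfg.n_unoccupied_true:
        pat = np.vstack([pat, np.zeros((cfg.n_unoccupied_true, 3), dtype=np.int8)])
    return pat


def _place_nonoverlapping(
    genome: GenomeSpec, n_sites: int, width: int, gap: int, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Place n_sites non-overlapping width-bp sites with >= gap bp between
    consecutive sites, uniformly over valid configurations.

    Uses the order-statistics transform: k sorted starts with pairwise
    clearance (width + gap) map one-to-one onto k sorted uniform draws on
    the clearance-deflated interval.
    """
    lengths = np.asarray(genome.chrom_lengths, dtype=float)
    # per-chromosome capacity
    caps = np.floor((lengths - width) / (width + gap)).astype(int) + 1
    caps = np.maximum(caps, 0)
    caps[lengths < width] = 0
    if caps.sum() < n_sites:
        raise CapacityError(
            f"genome capacity {int(caps.sum())} sites < requested {n_sites} "
            f"(width {width} bp, min gap {gap} bp)"
        )
    # allocate counts proportional to free capacity, then fix overflow
    weights = caps / caps.sum()
    counts = rng.multinomial(n_sites, weights)
    while np.any(counts > caps):
        excess = counts - caps
        over = excess > 0
        counts[over] = caps[over]
        short = int(excess[over].sum())
        room = caps - counts
        if room.sum() < short:  # unreachable given the capacity check
            raise CapacityError("could not distribute sites across chromosomes")
        counts += rng.multinomial(short, room / room.sum())
    out: list[tuple[str, int, int]] = []
    for name, length, k in zip(genome.chrom_names, genome.chrom_lengths, counts):
        if k == 0:
            continue
        slack = length - k * width - (k - 1) * gap
        u = np.sort(rng.random(int(k))) * slack
        starts = np.floor(u).astype(np.int64) + np.arange(k) * (width + gap)
        out.extend((name, int(s), int(s) + width) for s in starts)
    return out


def plant_sites(genome: GenomeSpec, cfg: FactorSimConfig) -> TruthSet:
    """Plant candidate enhancer sites with occupancy patterns.

    Patterns are drawn by :func:`sample_patterns`; sites (including the
    unoccupied ones) are placed uniformly without overlap and with a
    minimum gap of ``cfg.min_gap_bp`` so the peak caller can never merge
    two distinct truth sites. Deterministic given ``cfg.seed``.
    """
    pat = sample_patterns(cfg)
    placements = _place_nonoverlapping(
        genome, len(pat), cfg.site_width_bp, cfg.min_gap_bp, _rng(cfg.seed, "placement")
    )
    # shuffle pattern-to-location assignment so forced nulls are not all at
    # the end of the genome
    order = _rng(cfg.seed, "placement", 1).permutation(len(pat))
    sites = [
        TruthSite(chrom, start, end, tuple(int(x) for x in pat[i]))
        for (chrom, start, end), i in zip(sorted(placements), order)
    ]
    return TruthSet(sites=sites, genome=genome, config_echo=cfg)


def _enriched_probe_mask(
    probe_map: ProbeTrack, intervals: list[tuple[str, int, int]]
) -> np.ndarray:
    mask = np.zeros(probe_map.n_probes, dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, sl in probe_map.per_chrom():
        pos = probe_map.pos[sl]
        for start, end in by_chrom.get(chrom, ()):
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")  # half-open
            mask[sl.start + lo : sl.start + hi] = True
    return mask


def simulate_chip_track(
    truth: TruthSet, cfg: FactorSimConfig, factor: str
) -> ProbeTrack:
    """Replicated ChIP-chip log2 enrichment track for one factor.

    Each replicate is baseline 0, plus ``enrichment_log2`` on probes inside
    sites whose pattern bit for ``factor`` is set, plus i.i.d. Gaussian
    noise with sd ``noise_sd``. One RNG stream per (factor, replicate).
    """
    factor = factor.upper()
    if factor not in FACTOR_INDEX:
        raise InputError(f"unknown factor {factor!r}; expected A, B or C")
    probe_map = make_probe_map(truth.genome)
    bound = [(s.chrom, s.start, s.end) for s in truth.sites_for_factor(factor)]
    mask = _enriched_probe_mask(probe_map, bound)
    base = np.where(mask, cfg.enrichment_log2, 0.0)
    sig = np.empty((probe_map.n_probes, cfg.n_replicates))
    for r in range(cfg.n_replicates):
        rng = _rng(cfg.seed, f"chip_{factor}", r)
        sig[:, r] = base + rng.normal(0.0, cfg.noise_sd, size=probe_map.n_probes)
    return probe_map.with_signal(sig, label=f"chip_{factor}")


def gatc_sites(genome: GenomeSpec, seed: int) -> dict[str, np.ndarray]:
    """Seeded GATC site positions per chromosome, geometric inter-site gaps."""
    rng = _rng(seed, "gatc")
    out: dict[str, np.ndarray] = {}
    p = 1.0 / genome.gatc_spacing
    for name, length in zip(genome.chrom_names, genome.chrom_lengths):
        # draw enough gaps to cover the chromosome, then trim
        n_draw = int(length * p * 1.5) + 20
        gaps = rng.geometric(p, size=n_draw)
        while gaps.sum() < length:
            gaps = np.concatenate([gaps, rng.geometric(p, size=n_draw)])
        sites = np.cumsum(gaps)
        out[name] = sites[sites < length].astype(np.int64)
    return out


def _damid_footprint(
    genome: GenomeSpec,
    bound: list[tuple[str, int, int]],
    gatc: dict[str, np.ndarray],
) -> list[tuple[str, int, int]]:
    """Union of GATC fragments intersecting any bound site."""
    out: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in bound:
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, sites in by_chrom.items():
        cuts = gatc.get(chrom, np.empty(0, dtype=np.int64))
        length = genome.lengths[chrom]
        edges = np.concatenate(([0], cuts, [length]))
        for start, end in sites:
            # fragment containing `start` through fragment containing end-1
            i = int(np.searchsorted(edges, start, side="right")) - 1
            j = int(np.searchsorted(edges, end - 1, side="right")) - 1
            out.append((chrom, int(edges[i]), int(edges[j + 1])))
    return out


def simulate_damid_track(
    truth: TruthSet,
    cfg: FactorSimConfig,
    genome: GenomeSpec | None = None,
    factor: str = "B",
) -> ProbeTrack:
    """DamID-like track: enrichment smeared over whole GATC fragments.

    Enrichment is applied to every probe inside any GATC restriction
    fragment that intersects a bound site, so footprints are at least as
    wide as the matching ChIP footprints.
    """
    factor = factor.upper()
    if factor not in FACTOR_INDEX:
        raise InputError(f"unknown factor {factor!r}; expected A, B or C")
    if genome is None:
        genome = truth.genome
    probe_map = make_probe_map(genome)
    gatc = gatc_sites(genome, cfg.seed)
    bound = [(s.chrom, s.start, s.end) for s in truth.sites_for_factor(factor)]
    footprint = _damid_footprint(genome, bound, gatc)
    mask = _enriched_probe_mask(probe_map, footprint)
    base = np.where(mask, cfg.enrichment_log2, 0.0)
    sig = np.empty((probe_map.n_probes, cfg.n_replicates))
    for r in range(cfg.n_replicates):
        rng = _rng(cfg.seed, f"damid_{factor}", r)
        sig[:, r] = base + rng.normal(0.0, cfg.noise_sd, size=probe_map.n_probes)
    return probe_map.with_signal(sig, label=f"damid_{factor}")


def simulate_two_condition_acetylation(
    genome: GenomeSpec,
    n_replicates: int,
    diff_regions: list[tuple[str, int, int, float]],
    noise_sd: float,
    seed: int,
) -> tuple[ProbeTrack, ProbeTrack]:
    """Two-condition histone-acetylation tracks with planted differences.

    The treated condition equals the control mean plus the stated effect
    (log2 units, may be negative) inside each ``(chrom, start, end,
    effect)`` region. Both conditions get ``n_replicates`` independent
    Gaussian noise draws; at least two replicates are required because the
    differential test builds its null from within-condition replicate
    pairs.
    """
    if n_replicates < 2:
        raise ConfigurationError(
            "n_replicates must be >= 2 (the noise null needs replicate pairs)"
        )
    regs = sorted(diff_regions)
    for (c1, s1, e1, _), (c2, s2, e2, _) in zip(regs, regs[1:]):
        if c1 == c2 and s2 < e1:
            raise ConfigurationError("diff_regions must be non-overlapping")
    probe_map = make_probe_map(genome)
    effect = np.zeros(probe_map.n_probes)
    for chrom, start, end, eff in diff_regions:
        m = _enriched_probe_mask(probe_map, [(chrom, start, end)])
        effect[m] = eff
    tracks = []
    for cond, base in (("control", np.zeros_like(effect)), ("treated", effect)):
        sig = np.empty((probe_map.n_probes, n_replicates))
        for r in range(n_replicates):
            rng = _rng(seed, f"acetyl_{cond}", r)
            sig[:, r] = base + rng.normal(0.0, noise_sd, size=probe_map.n_probes)
        tracks.append(probe_map.with_signal(sig, label=f"K56ac_{cond}"))
    control, treated = tracks
    return control, treated
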