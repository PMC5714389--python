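import numpy as np
import pytest

from cooccupy.core import PeakSet, ProbeTrack, Region
from cooccupy.simulate import FactorSimConfig, GenomeSpec


@pytest.fixture
def small_genome() -> GenomeSpec:
    return GenomeSpec(
        chrom_names=["chr2L"], chrom_lengths=[200_000], probe_spacing=50
    )


@pytest.fixture
def bound_all_cfg() -> FactorSimConfig:
    """All sites bound by A only (degenerate law), no C."""
    return FactorSimConfig(
        n_enhancers=20,
        site_width_bp=1500,
        joint_ab=[[0, 0], [1.0, 0]],
        p_c=0.0,
        seed=0,
    )


def make_track(pos, signal, chrom="chr2L", label="t") -> ProbeTrack:
    """Build a single-chromosome track from plain lists/arrays."""
    pos = np.asarray(pos, dtype=np.int64)
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 1:
        signal = signal[:, None]
    return ProbeTrack(np.array([chrom] * len(pos), dtype=object), pos, signal, label)


def regions(*triples) -> PeakSet:
    """PeakSet from (chrom, start, end) triples or (start, end) pairs on chr1."""
    regs = []
    for t in triples:
        if len(t) == 2:
            regs.append(Region("chr1", t[0], t[1]))
        else:
            regs.append(Region(t[0], t[1], t[2]))
    return PeakSet(regs)


def naive_overlap_hits(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1) -> int:
    """O(n*m) oracle: count regions of a sharing >= min_overlap_bp with any
    region of b."""
    n = 0
    for ra in a:
        for rb in b:
            if ra.chrom != rb.chrom:
                continue
            if min(ra.end, rb.end) - max(ra.start, rb.start) >= min_overlap_bp:
                n += 1
                break
    return n


def naive_merge(a: PeakSet) -> list[tuple[str, int, int]]:
    """Quadratic merge oracle: repeatedly fuse any overlapping-or-touching
    pair until a fixed point."""
    items = [(r.chrom, r.start, r.end) for r in a]
    changed = True
    while changed:
        changed = False
        out = []
        while items:
            c, s, e = items.pop()
            fused = False
            for i, (c2, s2, e2) in enumerate(items):
                if c == c2 and s <= e2 and s2 <= e:
                    items[i] = (c, min(s, s2), max(e, e2))
                    fused = changed = True
                    break
            if not fused:
                out.append((c, s, e))
        items = out
    return sorted(items)


def random_peakset(rng, n=60, chroms=("chr1", "chr2"), span=10_000, max_w=400) -> PeakSet:
    regs = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, max_w))
        regs.append(Region(chrom, start, start + width))
    return PeakSet(regs)
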