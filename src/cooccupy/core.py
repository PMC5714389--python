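"""Shared domain types and errors.

Coordinates are 0-based half-open throughout (BED convention). Probe
positions are point coordinates (probe centers); a probe footprint is not
modeled, so a region derived from probes spans
``[first_probe, last_probe + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "CapacityError",
    "InputError",
    "Region",
    "PeakSet",
    "GeneModel",
    "ProbeTrack",
    "SmoothedTrack",
]


class ConfigurationError(ValueError):
    """A configuration value violates its documented constraints."""


class CapacityError(RuntimeError):
    """The genome cannot accommodate the requested planted sites."""


class InputError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class Region:
    """One genomic interval with optional enrichment statistics.

    ``score`` is the maximum smoothed log2 enrichment inside the region and
    ``qvalue`` the minimum BH-adjusted p-value, when the region came out of
    the peak caller; both default to NaN for plain intervals.
    """

    chrom: str
    start: int
    end: int
    score: float = float("nan")
    qvalue: float = float("nan")
    n_probes: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start >= self.end:
            raise InputError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(start must be < end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def copy(self, **changes) -> "Region":
        return replace(self, **changes)


class PeakSet:
    """An ordered collection of :class:`Region`.

    Regions are kept sorted by (chrom, start, end). Chromosome order is
    lexicographic, which is stable and input-order independent.
    """

    def __init__(self, regions: Iterable[Region] = ()):
        self.regions: list[Region] = sorted(
            regions, key=lambda r: (r.chrom, r.start, r.end)
        )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return [(r.chrom, r.start, r.end) for r in self] == [
            (r.chrom, r.start, r.end) for r in other
        ]

    def __repr__(self) -> str:
        return f"PeakSet({len(self)} regions)"

    @property
    def chroms(self) -> list[str]:
        return sorted({r.chrom for r in self.regions})

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome ``(starts, ends, indices)`` arrays, starts sorted."""
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in self.chroms:
            idx = np.array(
                [i for i, r in enumerate(self.regions) if r.chrom == chrom],
                dtype=np.int64,
            )
            starts = np.array([self.regions[i].start for i in idx], dtype=np.int64)
            ends = np.array([self.regions[i].end for i in idx], dtype=np.int64)
            out[chrom] = (starts, ends, idx)
        return out

    def total_bp(self) -> int:
        return sum(r.width for r in self.regions)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "score": [r.score for r in self.regions],
                "qvalue": [r.qvalue for r in self.regions],
                "n_probes": [r.n_probes for r in self.regions],
                "name": [r.name for r in self.regions],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PeakSet":
        return cls(
            Region(
                chrom=str(rec["chrom"]),
                start=int(rec["start"]),
                end=int(rec["end"]),
                score=float(rec.get("score", float("nan"))),
                qvalue=float(rec.get("qvalue", float("nan"))),
                n_probes=int(rec.get("n_probes", 0)),
                name=str(rec.get("name", "")),
            )
            for rec in df.to_dict("records")
        )


@dataclass
class GeneModel:
    """A gene span with strand; strand is carried but distance rules are
    strand-agnostic."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in {"+", "-", "."}:
            raise InputError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class ProbeTrack:
    """Probe-level signal for one factor/condition.

    Parameters
    ----------
    chrom : array of str, one entry per probe.
    pos : array of int probe centers, strictly increasing within chromosome.
    signal : float array of shape ``(n_probes, n_replicates)`` of log2
        enrichment values. May have zero columns for a bare probe map.
    label : free-text factor/condition label.
    """

    def __init__(self, chrom, pos, signal=None, label: str = ""):
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        if signal is None:
            signal = np.empty((len(pos), 0), dtype=float)
        signal = np.atleast_2d(np.asarray(signal, dtype=float))
        if signal.shape[0] != len(pos):
            if signal.shape[1] == len(pos):  # accept (reps, probes)
                signal = signal.T
            else:
                raise InputError("signal rows must match number of probes")
        if len(chrom) != len(pos):
            raise InputError("chrom and pos must have equal length")
        order = np.lexsort((pos, chrom.astype(str)))
        self.chrom = chrom[order]
        self.pos = pos[order]
        self.signal = signal[order]
        self.label = label
        for c, sl in self.per_chrom():
            p = self.pos[sl]
            if np.any(np.diff(p) <= 0):
                raise InputError(f"duplicate or unsorted probe positions on {c}")
        if np.isnan(self.signal).any():
            raise InputError("NaN signal values; drop missing probes on load")

    @property
    def n_probes(self) -> int:
        return len(self.pos)

    @property
    def n_replicates(self) -> int:
        return self.signal.shape[1]

    def per_chrom(self) -> Iterator[tuple[str, slice]]:
        """Yield ``(chrom, slice)`` for each chromosome block (sorted)."""
        if len(self.pos) == 0:
            return
        chroms = self.chrom.astype(str)
        boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        edges = np.concatenate(([0], boundaries, [len(chroms)]))
        for lo, hi in zip(edges[:-1], edges[1:]):
            yield chroms[lo], slice(int(lo), int(hi))

    def replicate_mean(self) -> np.ndarray:
        if self.n_replicates == 0:
            raise InputError("track has no replicate signal")
        return self.signal.mean(axis=1)

    def with_signal(self, signal, label: str | None = None) -> "ProbeTrack":
        return ProbeTrack(
            self.chrom.copy(),
            self.pos.copy(),
            signal,
            self.label if label is None else label,
        )


@dataclass
class SmoothedTrack:
    """Replicate-averaged, window-smoothed score per probe.

    ``score`` is NaN wherever the window held fewer than ``min_probes``
    probes (masked); ``n_support`` records the window occupancy.
    """

    chrom: np.ndarray
    pos: np.ndarray
    score: np.ndarray
    n_support: np.ndarray
    win_half_size_bp: int
    min_probes: int

    def __len__(self) -> int:
        return len(self.pos)

    def per_chrom(self) -> Iterator[tuple[str, slice]]:
        return ProbeTrack.per_chrom(self)  # same layout contract

    @property
    def unmasked(self) -> np.ndarray:
        return ~np.isnan(self.score)
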