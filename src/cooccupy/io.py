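"""Readers, writers and run configuration.

Formats are plain text: BED (0-based half-open) for regions, genes and
chromatin-state segmentations; bedGraph (one file per replicate) or wide
TSV (chrom, position, rep1..repN) for probe tracks; JSON/YAML for run
configuration. Coordinates are preserved exactly; an explicit flag
converts 1-based tables on read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import GeneModel, InputError, PeakSet, ProbeTrack, Region

__all__ = [
    "read_bed",
    "write_bed",
    "read_genes",
    "read_states",
    "read_probe_track",
    "write_probe_track_bedgraph",
    "write_peaks_tsv",
    "RunConfig",
]

logger = logging.getLogger(__name__)


def _parse_bed_line(line: str, lineno: int, path: str) -> tuple[str, int, int, list[str]]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise InputError(f"{path}:{lineno}: expected >= 3 tab-separated BED fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as err:
        raise InputError(f"{path}:{lineno}: non-integer coordinates") from err
    if start >= end:
        raise InputError(f"{path}:{lineno}: start {start} >= end {end}")
    return chrom, start, end, fields[3:]


def _bed_lines(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_bed(path: str | Path) -> PeakSet:
    """Read a BED3+ file into a PeakSet (name and score columns kept)."""
    regions = []
    for lineno, line in _bed_lines(path):
        chrom, start, end, rest = _parse_bed_line(line, lineno, str(path))
        name = rest[0] if rest else ""
        score = float("nan")
        if len(rest) > 1:
            try:
                score = float(rest[1])
            except ValueError:
                pass
        regions.append(Region(chrom, start, end, score=score, name=name))
    return PeakSet(regions)


def write_bed(peaks: PeakSet, path: str | Path, score_scale: float = 1000.0) -> None:
    """Write BED6-ish output sorted by (chrom, start).

    The BED score column is ``min(1000, round(score_scale * -log10(q)))``
    when a q-value is present (capped, browser convention), else 0.
    """
    with open(path, "w") as fh:
        for i, r in enumerate(peaks):
            if np.isnan(r.qvalue):
                bed_score = 0
            else:
                bed_score = int(min(1000, round(score_scale * -np.log10(max(r.qvalue, 1e-300)) / 3)))
            name = r.name or f"region_{i + 1}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{bed_score}\t.\n")


def write_peaks_tsv(peaks: PeakSet, path: str | Path) -> None:
    """Full region table: chrom, start, end, score, qvalue, n_probes."""
    peaks.to_dataframe().to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (name = gene id, strand in column 6)."""
    genes = []
    for lineno, line in _bed_lines(path):
        chrom, start, end, rest = _parse_bed_line(line, lineno, str(path))
        gene_id = rest[0] if rest else f"gene_{lineno}"
        strand = rest[2] if len(rest) > 2 else "."
        genes.append(GeneModel(gene_id, chrom, start, end, strand))
    return genes


def read_states(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a labelled segmentation BED (label in the name column),
    preserving file order (used for tie-breaking)."""
    states = []
    for lineno, line in _bed_lines(path):
        chrom, start, end, rest = _parse_bed_line(line, lineno, str(path))
        if not rest:
            raise InputError(f"{path}:{lineno}: segmentation needs a label column")
        states.append((chrom, start, end, rest[0]))
    return states


def read_probe_track(
    paths: Sequence[str | Path] | str | Path,
    one_based: bool = False,
    label: str = "",
) -> ProbeTrack:
    """Load a replicated probe track.

    ``paths`` is either a list of bedGraph files (one replicate each;
    probe position = interval start) or a single wide TSV with columns
    chrom, position, rep1..repN. Positions present in only some
    replicates are dropped (count logged). ``one_based`` shifts positions
    down by 1 on read.
    """
    if isinstance(paths, (str, Path)):
        df = pd.read_csv(paths, sep="\t")
        if df.shape[1] < 3:
            raise InputError(f"{paths}: wide TSV needs chrom, position, >= 1 replicate")
        chrom = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
        pos = df.iloc[:, 1].to_numpy(dtype=np.int64)
        sig = df.iloc[:, 2:].to_numpy(dtype=float)
        if one_based:
            pos = pos - 1
        keep = ~np.isnan(sig).any(axis=1)
        if (~keep).sum():
            logger.info("read_probe_track: dropped %d probes with missing values", int((~keep).sum()))
        return ProbeTrack(chrom[keep], pos[keep], sig[keep], label=label or str(paths))
    frames = []
    for p in paths:
        rows = []
        for lineno, line in _bed_lines(p):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise InputError(f"{p}:{lineno}: bedGraph needs 4 columns")
            try:
                rows.append((fields[0], int(fields[1]), float(fields[3])))
            except ValueError as err:
                raise InputError(f"{p}:{lineno}: malformed bedGraph line") from err
        frames.append(pd.DataFrame(rows, columns=["chrom", "pos", "value"]))
    if not frames:
        raise InputError("no input files")
    merged = frames[0]
    for i, f in enumerate(frames[1:], start=2):
        merged = merged.merge(f, on=["chrom", "pos"], suffixes=("", f"_{i}"))
    if len(merged) == 0:
        raise InputError("zero probe positions shared across replicates")
    n_union = len(pd.concat(frames)[["chrom", "pos"]].drop_duplicates())
    if n_union > len(merged):
        logger.info(
            "read_probe_track: dropped %d positions absent from some replicates",
            n_union - len(merged),
        )
    pos = merged["pos"].to_numpy(dtype=np.int64)
    if one_based:
        pos = pos - 1
    sig = merged.drop(columns=["chrom", "pos"]).to_numpy(dtype=float)
    return ProbeTrack(
        merged["chrom"].to_numpy(dtype=object), pos, sig, label=label or str(paths[0])
    )


def write_probe_track_bedgraph(
    track: ProbeTrack, prefix: str | Path, span: int = 1
) -> list[Path]:
    """Write one bedGraph per replicate: intervals [pos, pos + span)."""
    out = []
    for r in range(track.n_replicates):
        path = Path(f"{prefix}_rep{r + 1}.bedgraph")
        with open(path, "w") as fh:
            for chrom, p, v in zip(track.chrom, track.pos, track.signal[:, r]):
                fh.write(f"{chrom}\t{p}\t{p + span}\t{v:.6g}\n")
        out.append(path)
    return out


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run; round-trips via JSON/YAML."""

    seed: int = 0
    fdr_chip: float = 0.01
    fdr_damid: float = 0.10
    win_half_size_bp: int = 700
    min_probes: int = 10
    dist_cutoff_bp: int = 200
    window_bp: int = 2000
    step_bp: int = 1000
    fdr_diff: float = 0.01
    n_max: int = 5000
    out_dir: str = "cooccupy_out"
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)  # GenomeSpec/FactorSimConfig overrides

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in {".yaml", ".yml"}:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
            else:
                json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.suffix in {".yaml", ".yml"} else json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
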