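"""GC-depth window profiling and depth-threshold genome coverage.

The assembly is tiled with non-overlapping windows (the last, partial
window is kept), and each window gets a GC percentage over its non-N
bases plus its mean sequencing depth.  Windows that are entirely N carry
no GC value (NaN).  The tiling conserves genome length, so the
size-weighted mean of window depths equals the global mean depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import BlastHit, ConsistencyError, ContigSet

__all__ = [
    "WindowRecord",
    "BinHitSummary",
    "gc_depth_profile",
    "coverage_fractions",
    "bin_hit_summary",
    "gc_depth_histogram",
]


@dataclass(frozen=True)
class WindowRecord:
    chrom: str
    start: int  # 0-based half-open
    end: int
    gc_pct: float  # NaN for all-N windows
    n_pct: float
    mean_depth: float

    @property
    def size(self) -> int:
        return self.end - self.start


def _window_gc(seq: str) -> tuple[float, float]:
    """(gc_pct over non-N bases, n_pct over all bases); soft-masked
    lowercase counts as its uppercase base."""
    up = seq.upper()
    n = up.count("N")
    gc = up.count("G") + up.count("C")
    denom = len(up) - n
    gc_pct = 100.0 * gc / denom if denom else math.nan
    return gc_pct, 100.0 * n / len(up)


def gc_depth_profile(
    genome: ContigSet,
    depth: Mapping[str, np.ndarray],
    window: int = 10_000,
) -> list[WindowRecord]:
    """Tile each chromosome with `window`-bp windows and report GC and
    mean depth per window."""
    if window <= 0:
        raise ValueError("window size must be positive")
    out: list[WindowRecord] = []
    for contig in genome:
        if contig.sequence is None:
            raise ValueError(f"{contig.name}: sequence required for GC profile")
        if contig.name not in depth:
            raise ConsistencyError(f"{contig.name}: no depth vector supplied")
        vec = np.asarray(depth[contig.name])
        if vec.size != contig.length:
            raise ConsistencyError(
                f"{contig.name}: depth vector length {vec.size} != "
                f"sequence length {contig.length}"
            )
        for start in range(0, contig.length, window):
            end = min(start + window, contig.length)
            gc_pct, n_pct = _window_gc(contig.sequence[start:end])
            out.append(WindowRecord(
                chrom=contig.name,
                start=start,
                end=end,
                gc_pct=gc_pct,
                n_pct=n_pct,
                mean_depth=float(vec[start:end].mean()),
            ))
    return out


def coverage_fractions(
    depth: Mapping[str, np.ndarray],
    thresholds: Sequence[int] = (1, 20),
) -> dict[int, float]:
    """Percentage of the assembly covered at depth >= t, per threshold."""
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    total = sum(np.asarray(v).size for v in depth.values())
    out: dict[int, float] = {}
    for t in thresholds:
        covered = sum(int((np.asarray(v) >= t).sum()) for v in depth.values())
        out[int(t)] = 100.0 * covered / total if total else 0.0
    return out


@dataclass(frozen=True)
class BinHitSummary:
    n_bins: int
    n_hit_bins: int
    pct_bins: float
    pct_genome_length: float


def bin_hit_summary(
    assembly: ContigSet,
    hits: Sequence[tuple[str, int, int]],
    bin_bp: int = 1_000_000,
) -> BinHitSummary:
    """Fraction of fixed-size genome bins (and of genome length) touched
    by at least one alignment hit.

    Hit intervals are (chrom, start, end), 1-based inclusive as printed
    by blastn; a bin counts as hit if any interval overlaps it.
    """
    if bin_bp <= 0:
        raise ValueError("bin size must be positive")
    bins: list[tuple[str, int, int]] = []  # internal 0-based half-open
    index: dict[str, list[int]] = {}
    for contig in assembly:
        index[contig.name] = []
        for start in range(0, contig.length, bin_bp):
            index[contig.name].append(len(bins))
            bins.append((contig.name, start, min(start + bin_bp, contig.length)))
    hit_flags = np.zeros(len(bins), dtype=bool)
    lengths = {c.name: c.length for c in assembly}
    for chrom, start1, end1 in hits:
        if chrom not in lengths:
            raise ConsistencyError(f"hit on unknown chromosome {chrom}")
        if start1 < 1 or end1 > lengths[chrom] or end1 < start1:
            raise ConsistencyError(
                f"hit {chrom}:{start1}-{end1} outside assembly"
            )
        s0, e0 = start1 - 1, end1  # to 0-based half-open
        first = s0 // bin_bp
        last = (e0 - 1) // bin_bp
        for b in range(first, last + 1):
            hit_flags[index[chrom][b]] = True
    n_bins = len(bins)
    n_hit = int(hit_flags.sum())
    total_len = assembly.total_length
    hit_len = sum(b[2] - b[1] for b, f in zip(bins, hit_flags) if f)
    return BinHitSummary(
        n_bins=n_bins,
        n_hit_bins=n_hit,
        pct_bins=100.0 * n_hit / n_bins if n_bins else 0.0,
        pct_genome_length=100.0 * hit_len / total_len if total_len else 0.0,
    )


def gc_depth_histogram(
    records: Sequence[WindowRecord],
    gc_bin: float = 1.0,
    depth_bin: float = 1.0,
) -> pd.DataFrame:
    """2-D histogram (GC bin x depth bin -> window count) for plotting
    the GC-depth cloud; all-N windows are dropped."""
    rows = [
        (math.floor(r.gc_pct / gc_bin) * gc_bin,
         math.floor(r.mean_depth / depth_bin) * depth_bin)
        for r in records
        if not math.isnan(r.gc_pct)
    ]
    df = pd.DataFrame(rows, columns=["gc_bin", "depth_bin"])
    return (
        df.groupby(["gc_bin", "depth_bin"]).size().rename("count").reset_index()
    )
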