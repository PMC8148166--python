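"""Contiguity and throughput statistics for assemblies and read sets.

Nxx convention: sort lengths descending; the Nxx length is the length of
the first record at which the cumulative sum reaches at least x% of the
total, and the Nxx count is how many records that takes.  A single
contig is therefore its own N50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NxxRow",
    "NxxTable",
    "ReadSummary",
    "nxx",
    "cumulative_curve",
    "read_summary",
    "coverage_x",
    "mapping_rate_table",
]

DEFAULT_READ_THRESHOLDS = (10_000, 20_000, 40_000)


@dataclass(frozen=True)
class NxxRow:
    level: int   # percent of total, e.g. 50 for N50
    length: int  # bp of the contig reaching the threshold
    count: int   # contigs up to and including it


@dataclass
class NxxTable:
    rows: list[NxxRow]
    longest: tuple[int, int]  # (length, count=1)
    total: tuple[int, int]    # (total length, contig count)

    def to_frame(self) -> pd.DataFrame:
        recs = [(f"N{r.level}", r.length, r.count) for r in self.rows]
        recs.append(("Longest", self.longest[0], self.longest[1]))
        recs.append(("Total", self.total[0], self.total[1]))
        return pd.DataFrame(recs, columns=["Statistic", "Length_bp", "Count"])

    def __getitem__(self, level: int) -> NxxRow:
        for r in self.rows:
            if r.level == level:
                return r
        raise KeyError(level)


@dataclass
class ReadSummary:
    n_reads: int
    n_bases: int
    mean_len: float
    max_len: int
    n50: int
    pct_over: dict[int, float]  # strict > threshold, in percent

    @property
    def mean_len_bp(self) -> int:
        """Mean length rounded to whole base pairs (presentation)."""
        return round(self.mean_len)


def _sorted_desc(lengths: Iterable[int]) -> np.ndarray:
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty length set")
    if (arr <= 0).any():
        raise ValueError("all lengths must be positive")
    return np.sort(arr)[::-1]


def nxx(lengths: Iterable[int], levels: Sequence[int] = (50, 60, 70, 80, 90)) -> NxxTable:
    """Nxx lengths/counts at the requested percentage levels."""
    arr = _sorted_desc(lengths)
    total = int(arr.sum())
    cum = np.cumsum(arr)
    rows = []
    for level in levels:
        if not 0 < level <= 100:
            raise ValueError(f"Nxx level {level} outside (0, 100]")
        threshold = total * level / 100.0
        idx = int(np.searchsorted(cum, threshold, side="left"))
        rows.append(NxxRow(level=level, length=int(arr[idx]), count=idx + 1))
    return NxxTable(
        rows=rows,
        longest=(int(arr[0]), 1),
        total=(total, int(arr.size)),
    )


def cumulative_curve(lengths: Iterable[int]) -> list[tuple[int, int]]:
    """(rank, cumulative bp) after descending sort; ends at the total."""
    arr = _sorted_desc(lengths)
    cum = np.cumsum(arr)
    return [(i + 1, int(c)) for i, c in enumerate(cum)]


def read_summary(
    lengths: Iterable[int],
    thresholds: Sequence[int] = DEFAULT_READ_THRESHOLDS,
) -> ReadSummary:
    """Throughput summary of a read set: totals, mean/max, N50 and the
    percentage of reads strictly longer than each threshold."""
    arr = _sorted_desc(lengths)
    n = int(arr.size)
    total = int(arr.sum())
    pct = {int(t): 100.0 * int((arr > t).sum()) / n for t in thresholds}
    return ReadSummary(
        n_reads=n,
        n_bases=total,
        mean_len=total / n,
        max_len=int(arr[0]),
        n50=nxx(arr, [50])[50].length,
        pct_over=pct,
    )


def coverage_x(total_bases: int, genome_size: int) -> float:
    """Sequencing coverage (X) = total bases / genome size, to 3 decimals."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return round(total_bases / genome_size, 3)


def mapping_rate_table(
    per_tissue: Sequence[tuple[int, int, int]],
    names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-sample mapping statistics with Average and Total rows.

    Each input row is (pairs_total, mapped_unique, mapped_multiple).
    mapped_all = unique + multiple; pct = 100 * mapped_all / pairs_total.
    The Average row is the unweighted mean of the per-sample columns
    (including pct); the Total row is the column sums, with no pct.
    """
    if not per_tissue:
        raise ValueError("no rows supplied")
    if names is None:
        names = [f"sample{i + 1}" for i in range(len(per_tissue))]
    rows = []
    for name, (total, uniq, multi) in zip(names, per_tissue):
        if total <= 0:
            raise ValueError(f"{name}: pairs_total must be positive")
        mapped_all = uniq + multi
        if mapped_all > total:
            raise ValueError(
                f"{name}: mapped reads ({mapped_all}) exceed total ({total})"
            )
        rows.append({
            "sample": name,
            "total_pairs": total,
            "mapped_unique": uniq,
            "mapped_multiple": multi,
            "mapped_all": mapped_all,
            "mapped_pct": 100.0 * mapped_all / total,
        })
    df = pd.DataFrame(rows)
    avg = {
        "sample": "Average",
        "total_pairs": df["total_pairs"].mean(),
        "mapped_unique": df["mapped_unique"].mean(),
        "mapped_multiple": df["mapped_multiple"].mean(),
        "mapped_all": df["mapped_all"].mean(),
        "mapped_pct": df["mapped_pct"].mean(),
    }
    tot = {
        "sample": "Total",
        "total_pairs": df["total_pairs"].sum(),
        "mapped_unique": df["mapped_unique"].sum(),
        "mapped_multiple": df["mapped_multiple"].sum(),
        "mapped_all": df["mapped_all"].sum(),
        "mapped_pct": np.nan,
    }
    return pd.concat([df, pd.DataFrame([avg, tot])], ignore_index=True)
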