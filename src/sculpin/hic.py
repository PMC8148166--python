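"""Hi-C read QC, restriction-site trimming, pair deduplication, contact
binning and cis/trans enrichment.

Chimeric Hi-C reads span the ligation junction of two genomic loci; the
5' prefix up to and including the first restriction-site occurrence
(DpnII: GATC) is the mappable part, so trimming keeps it.  Retained
unique pairs are binned into fixed-size windows per chromosome; the
pair count between two bins is the linkage intensity, shown on log
scale as ln(1 + count) so that empty (mostly trans) bin pairs stay
finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import ConsistencyError, ContigSet, PairRecord, Params, Strand

__all__ = [
    "ReadVerdict",
    "ContactMatrix",
    "qc_filter_read",
    "trim_at_site",
    "dedup_pairs",
    "bin_pairs",
    "log_intensity",
    "cis_trans_summary",
]

LIGATION_JUNCTION = "GATCGATC"  # DpnII re-ligation product


@dataclass(frozen=True)
class ReadVerdict:
    keep: bool
    reason: Optional[str] = None  # low_quality | too_many_N


def _phred_values(quals: str | Sequence[int]) -> np.ndarray:
    if isinstance(quals, str):
        return np.frombuffer(quals.encode(), dtype=np.uint8).astype(float) - 33
    return np.asarray(quals, dtype=float)


def qc_filter_read(
    seq: str, quals: str | Sequence[int], params: Params | None = None
) -> ReadVerdict:
    """Keep a read iff mean Phred > read_min_mean_phred and the number
    of N bases is strictly below read_max_n.

    `quals` may be Phred integers or a FASTQ quality string (offset 33).
    """
    params = params or Params()
    q = _phred_values(quals)
    if q.size != len(seq):
        raise ConsistencyError(
            f"quality length {q.size} != sequence length {len(seq)}"
        )
    if q.size == 0 or q.mean() <= params.read_min_mean_phred:
        return ReadVerdict(False, "low_quality")
    if seq.upper().count("N") >= params.read_max_n:
        return ReadVerdict(False, "too_many_N")
    return ReadVerdict(True)


def trim_at_site(seq: str, site: str = "GATC", *, keep_site: bool = True) -> str:
    """Cut a read at its first restriction-site occurrence.

    Default keeps the prefix up to and including the site (preserves
    mappable bases); keep_site=False cuts just before it.  Reads
    without the site pass through unchanged.  Idempotent in the default
    mode: the trimmed read ends at its first site occurrence.
    """
    if not site:
        raise ValueError("restriction site must be non-empty")
    idx = seq.upper().find(site.upper())
    if idx < 0:
        return seq
    return seq[: idx + (len(site) if keep_site else 0)]


def _canonical(p: PairRecord) -> tuple:
    a = (p.chrom1, p.pos1, p.strand1.value)
    b = (p.chrom2, p.pos2, p.strand2.value)
    return (a, b) if a <= b else (b, a)


def dedup_pairs(pairs: Sequence[PairRecord]) -> list[PairRecord]:
    """Collapse duplicate pairs (mate order ignored) to one record each.

    Output is sorted on the canonical (chrom1, pos1, strand1, chrom2,
    pos2, strand2) key for deterministic downstream binning.
    """
    seen = {}
    for p in pairs:
        key = _canonical(p)
        if key not in seen:
            a, b = key
            seen[key] = PairRecord(
                chrom1=a[0], pos1=a[1], strand1=Strand(a[2]),
                chrom2=b[0], pos2=b[1], strand2=Strand(b[2]),
            )
    return [seen[k] for k in sorted(seen)]


@dataclass
class ContactMatrix:
    """Symmetric binned Hi-C linkage-intensity matrix.

    `bins` tile the assembly at the chosen bin size, in assembly order;
    `counts[i, j]` is the number of retained pairs linking bins i and j
    (the full pair count sits in the upper triangle + diagonal).
    """

    bins: list[tuple[str, int, int]]  # (chrom, start, end), 0-based half-open
    counts: np.ndarray
    transformed: Optional[np.ndarray] = None
    _bin_chroms: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.bins)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match bin count")
        if (self.counts < 0).any():
            raise ValueError("negative contact counts")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("contact matrix must be symmetric")
        self._bin_chroms = np.array([b[0] for b in self.bins])

    @property
    def n_pairs(self) -> int:
        """Total retained pairs (upper triangle + diagonal)."""
        return int(np.triu(self.counts).sum())

    def to_coo(self) -> list[tuple[int, int, int]]:
        ii, jj = np.nonzero(np.triu(self.counts))
        return [(int(i), int(j), int(self.counts[i, j])) for i, j in zip(ii, jj)]

    def write_dense(self, path: str | Path, *, transformed: bool = False) -> None:
        mat = self.transformed if transformed else self.counts
        if mat is None:
            raise ValueError("no transformed matrix present")
        labels = [f"{c}:{s}-{e}" for c, s, e in self.bins]
        with open(path, "w") as fh:
            fh.write("bin\t" + "\t".join(labels) + "\n")
            for lbl, row in zip(labels, mat):
                fh.write(lbl + "\t" + "\t".join(str(v) for v in row) + "\n")

    def write_bins_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, (c, s, e) in enumerate(self.bins):
                fh.write(f"{c}\t{s}\t{e}\tbin{i}\n")


def _make_bins(assembly: ContigSet, bin_bp: int) -> tuple[list, dict[str, int]]:
    bins: list[tuple[str, int, int]] = []
    offset: dict[str, int] = {}
    for contig in assembly:
        offset[contig.name] = len(bins)
        for start in range(0, contig.length, bin_bp):
            bins.append((contig.name, start, min(start + bin_bp, contig.length)))
    return bins, offset


def bin_pairs(
    pairs: Sequence[PairRecord], assembly: ContigSet, bin_bp: int = 100_000
) -> ContactMatrix:
    """Assign each mate to bin floor((pos - 1) / bin_bp) on its
    chromosome and accumulate the symmetric pair-count matrix."""
    if bin_bp <= 0:
        raise ValueError("bin size must be positive")
    bins, offset = _make_bins(assembly, bin_bp)
    lengths = {c.name: c.length for c in assembly}
    counts = np.zeros((len(bins), len(bins)), dtype=np.int64)
    for p in pairs:
        for chrom, pos in ((p.chrom1, p.pos1), (p.chrom2, p.pos2)):
            if chrom not in lengths:
                raise ConsistencyError(f"pair on unknown chromosome {chrom}")
            if pos > lengths[chrom]:
                raise ConsistencyError(
                    f"pair position {chrom}:{pos} beyond chromosome end"
                )
        i = offset[p.chrom1] + (p.pos1 - 1) // bin_bp
        j = offset[p.chrom2] + (p.pos2 - 1) // bin_bp
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    return ContactMatrix(bins=bins, counts=counts)


def log_intensity(m: ContactMatrix) -> ContactMatrix:
    """Natural-log transform of linkage intensity: ln(1 + count)."""
    m.transformed = np.log1p(m.counts.astype(float))
    return m


def cis_trans_summary(m: ContactMatrix) -> tuple[float, dict[str, int]]:
    """(cis fraction of all pairs, per-chromosome cis pair counts)."""
    upper = np.triu(m.counts)
    total = int(upper.sum())
    per_chrom: dict[str, int] = {}
    cis = 0
    for chrom in dict.fromkeys(m._bin_chroms):
        mask = m._bin_chroms == chrom
        c = int(upper[np.ix_(mask, mask)].sum())
        per_chrom[chrom] = c
        cis += c
    frac = cis / total if total else float("nan")
    return frac, per_chrom
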