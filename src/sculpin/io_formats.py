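"""Readers and writers for the standard formats the toolkit consumes.

Every genomic coordinate is 1-based inclusive at file boundaries (FASTA
indexing convention of samtools/VCF/GTF) and converted to 0-based
half-open intervals internally.  This module is the only place where the
conversion happens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils.feature
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("sculpin")

__all__ = [
    "FormatError",
    "ConsistencyError",
    "Params",
    "Contig",
    "ContigSet",
    "PslHit",
    "BlastHit",
    "QuantTable",
    "GeneMap",
    "Genotype",
    "VariantRecord",
    "Strand",
    "PairRecord",
    "read_fasta",
    "write_fasta",
    "read_lengths",
    "read_psl",
    "read_blast_tab",
    "read_quant",
    "read_gene_map",
    "read_vcf_minimal",
    "read_depth",
    "read_pairs",
    "write_pairs",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ConsistencyError(ValueError):
    """Inputs are individually well-formed but mutually inconsistent."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

_DEFAULT_ORGANISMS = ("human", "mouse", "zebrafish", "worm")


@dataclass
class Params:
    """Every named analysis threshold in one configurable record.

    Defaults reproduce the study conditions of the sculpin genome
    project: 10 kb GC-depth windows, 100 kb Hi-C bins, DpnII (GATC)
    restriction trimming, a 5x depth floor for error-proxy variants, the
    0.05 blastn/blastp e-value ceilings, the blat ``-minScore=30
    -minIdentity=60`` retention settings, and the >=50-read expression
    floor of the RNR novelty funnel.
    """

    gc_window_bp: int = 10_000
    hic_bin_bp: int = 100_000
    min_variant_depth: int = 5
    min_novel_reads: float = 50
    blastn_evalue_max: float = 0.05
    blastp_evalue_max: float = 0.05
    psl_min_score: int = 30
    psl_min_identity_pct: float = 60
    restriction_site: str = "GATC"
    read_min_mean_phred: float = 15
    read_max_n: int = 5
    min_orf_aa: int = 100
    depth_thresholds: tuple[int, ...] = (1, 20)
    nxx_levels: tuple[int, ...] = (50, 60, 70, 80, 90)
    # behaviour flags (see docs/methods.md)
    refilter_psl: bool = False      # re-apply score/identity to PSL hits
    round_quant_reads: bool = False  # round read counts before the >=50 filter
    organisms: tuple[str, ...] = _DEFAULT_ORGANISMS

    def __post_init__(self) -> None:
        for f in (
            "gc_window_bp", "hic_bin_bp", "min_variant_depth",
            "min_novel_reads", "blastn_evalue_max", "blastp_evalue_max",
            "psl_min_score", "psl_min_identity_pct", "read_min_mean_phred",
            "read_max_n", "min_orf_aa",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"Params.{f} must be strictly positive")
        if not self.restriction_site or set(self.restriction_site) - set("ACGT"):
            raise ValueError("restriction_site must be a non-empty ACGT string")
        if any(t <= 0 for t in self.depth_thresholds):
            raise ValueError("depth_thresholds must be strictly positive")
        if any(not 0 < x <= 100 for x in self.nxx_levels):
            raise ValueError("nxx_levels must lie in (0, 100]")

    @classmethod
    def from_mapping(cls, overrides: Mapping[str, object]) -> "Params":
        known = {f.name for f in fields(cls)}
        bad = set(overrides) - known
        if bad:
            raise ValueError(f"unknown Params fields: {sorted(bad)}")
        clean = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in overrides.items()
        }
        return cls(**clean)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contig:
    name: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"contig {self.name}: negative length")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.name}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass
class ContigSet:
    """Named sequence lengths (optionally with sequences).

    Models either an assembly (contigs with sequences) or a read set
    (lengths only).  Names must be unique; file order is preserved.
    """

    records: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate record names in ContigSet")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    @property
    def lengths(self) -> list[int]:
        return [r.length for r in self.records]

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)

    def length_of(self, name: str) -> int:
        for r in self.records:
            if r.name == name:
                return r.length
        raise KeyError(name)

    @classmethod
    def from_lengths(cls, items: Iterable[tuple[str, int]]) -> "ContigSet":
        return cls([Contig(n, l) for n, l in items])


@dataclass(frozen=True)
class PslHit:
    """One body line of a blat/pblat PSL alignment."""

    query: str
    target: str
    matches: int
    mismatches: int
    rep_matches: int
    q_num_insert: int
    t_num_insert: int
    q_size: int

    def __post_init__(self) -> None:
        counts = (self.matches, self.mismatches, self.rep_matches,
                  self.q_num_insert, self.t_num_insert, self.q_size)
        if any(c < 0 for c in counts):
            raise ValueError("PSL counts must be non-negative")
        if self.matches + self.mismatches + self.rep_matches > self.q_size:
            raise ValueError(
                f"PSL hit {self.query}: aligned bases exceed query size"
            )

    @property
    def score(self) -> int:
        # blat's simple score: matches + repMatches - misMatches - inserts
        return (self.matches + self.rep_matches - self.mismatches
                - self.q_num_insert - self.t_num_insert)

    @property
    def identity_pct(self) -> float:
        aln = self.matches + self.mismatches
        return 100.0 * self.matches / aln if aln else 0.0


@dataclass(frozen=True)
class BlastHit:
    """One line of BLAST tabular (outfmt 6) output."""

    query: str
    subject: str
    pident: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0 <= self.pident <= 100:
            raise ValueError(f"pident {self.pident} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("negative e-value")


@dataclass
class QuantTable:
    """Per-(transcript, tissue) read counts and abundances.

    The abundance column (TPM) is carried along for reporting but the
    novelty filter operates on read counts only.
    """

    entries: dict[tuple[str, str], tuple[float, float]]

    def __post_init__(self) -> None:
        per_tissue: dict[str, set[str]] = {}
        for (tid, tissue), (reads, _) in self.entries.items():
            if reads < 0:
                raise ValueError(f"negative read count for {tid}/{tissue}")
            per_tissue.setdefault(tissue, set()).add(tid)
        sets = list(per_tissue.values())
        if sets and any(s != sets[0] for s in sets[1:]):
            raise ConsistencyError("transcript sets differ across tissues")

    @property
    def tissues(self) -> list[str]:
        return sorted({t for _, t in self.entries})

    @property
    def transcripts(self) -> list[str]:
        return sorted({tid for tid, _ in self.entries})

    def read_counts(self, transcript_id: str) -> dict[str, float]:
        return {
            tissue: reads
            for (tid, tissue), (reads, _) in self.entries.items()
            if tid == transcript_id
        }

    def max_reads(self, transcript_id: str) -> float:
        counts = self.read_counts(transcript_id)
        if not counts:
            raise KeyError(transcript_id)
        return max(counts.values())


@dataclass
class GeneMap:
    """Total map transcript_id -> gene_id."""

    gene_of: dict[str, str]

    @property
    def transcripts(self) -> list[str]:
        return sorted(self.gene_of)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.gene_of.values()))

    def transcripts_of(self, gene_id: str) -> list[str]:
        return sorted(t for t, g in self.gene_of.items() if g == gene_id)


class Genotype(str, Enum):
    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    other = "other"


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: Genotype
    depth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("VCF positions are 1-based (pos >= 1)")
        if not self.ref or not self.alt:
            raise ValueError("REF and ALT must be non-empty")


class Strand(str, Enum):
    forward = "+"
    reverse = "-"


@dataclass(frozen=True)
class PairRecord:
    """One Hi-C read pair by the 1-based leftmost mapped base of each mate."""

    chrom1: str
    pos1: int
    strand1: Strand
    chrom2: str
    pos2: int
    strand2: Strand

    def __post_init__(self) -> None:
        if self.pos1 < 1 or self.pos2 < 1:
            raise ValueError("pair positions are 1-based (>= 1)")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> ContigSet:
    """Read a FASTA file into a ContigSet (sequences retained)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise FormatError(f"{path}: empty FASTA file")
    if not first.startswith(">"):
        raise FormatError(f"{path}: line 1 is not a FASTA header: {first!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        seq = str(rec.seq)
        records.append(Contig(rec.id, len(seq), seq))
    return ContigSet(records)


def write_fasta(contigs: ContigSet, path: str | Path, width: int = 60) -> None:
    recs = []
    for c in contigs:
        if c.sequence is None:
            raise ValueError(f"contig {c.name} carries no sequence")
        recs.append(SeqRecord(Seq(c.sequence), id=c.name, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_lengths(path: str | Path) -> ContigSet:
    """Read a name<TAB>length (or length-only) list into a ContigSet."""
    items: list[tuple[str, int]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if len(parts) == 1:
                    items.append((f"read{i}", int(parts[0])))
                else:
                    items.append((parts[0], int(parts[1])))
            except ValueError as exc:
                raise FormatError(f"{path}:{i}: bad length line: {line!r}") from exc
    return ContigSet.from_lengths(items)


# ---------------------------------------------------------------------------
# PSL (blat / pblat)
# ---------------------------------------------------------------------------

_PSL_COLUMNS = 21
# column indices in the 21-column PSL body
_PSL_MATCHES, _PSL_MISMATCHES, _PSL_REPMATCHES = 0, 1, 2
_PSL_QNUMINSERT, _PSL_TNUMINSERT = 4, 6
_PSL_QNAME, _PSL_QSIZE, _PSL_TNAME = 9, 10, 13


def _is_psl_header(line: str) -> bool:
    s = line.strip()
    return (
        s.startswith("psLayout")
        or s.startswith("match")
        or s.startswith("-")
        or not s
    )


def read_psl(path: str | Path) -> list[PslHit]:
    """Parse a 21-column PSL body; psLayout header lines are skipped."""
    hits: list[PslHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_psl_header(line):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != _PSL_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_PSL_COLUMNS} PSL columns, "
                    f"got {len(cols)}"
                )
            try:
                hits.append(PslHit(
                    query=cols[_PSL_QNAME],
                    target=cols[_PSL_TNAME],
                    matches=int(cols[_PSL_MATCHES]),
                    mismatches=int(cols[_PSL_MISMATCHES]),
                    rep_matches=int(cols[_PSL_REPMATCHES]),
                    q_num_insert=int(cols[_PSL_QNUMINSERT]),
                    t_num_insert=int(cols[_PSL_TNUMINSERT]),
                    q_size=int(cols[_PSL_QSIZE]),
                ))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

def read_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse 12-column BLAST outfmt-6; only the fields the toolkit uses
    (query, subject, pident, evalue, bitscore) are retained."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                hits.append(BlastHit(
                    query=cols[0],
                    subject=cols[1],
                    pident=float(cols[2]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                ))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


# ---------------------------------------------------------------------------
# salmon-style quantification tables
# ---------------------------------------------------------------------------

def read_quant(paths: Mapping[str, str | Path]) -> QuantTable:
    """Merge per-tissue quant.sf-style tables into one QuantTable.

    Each file must have a header and columns Name / Length /
    EffectiveLength / TPM / NumReads (names case-insensitive; salmon's
    ordering).  All tissues must quantify the same transcript set.
    """
    entries: dict[tuple[str, str], tuple[float, float]] = {}
    seen_sets: dict[str, set[str]] = {}
    for tissue, path in paths.items():
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 5:
            raise FormatError(f"{path}: expected >=5 quant columns")
        name_col, tpm_col, reads_col = df.columns[0], df.columns[3], df.columns[4]
        for _, row in df.iterrows():
            tid = str(row[name_col])
            entries[(tid, tissue)] = (float(row[reads_col]), float(row[tpm_col]))
        seen_sets[tissue] = set(df[name_col].astype(str))
    sets = list(seen_sets.values())
    if sets and any(s != sets[0] for s in sets[1:]):
        raise ConsistencyError(
            "quantification tables disagree on the transcript set across tissues"
        )
    return QuantTable(entries)


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

def read_gene_map(gtf_path: str | Path) -> GeneMap:
    """Extract the transcript_id -> gene_id map from a GTF file."""
    gene_of: dict[str, str] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line, dialect=None)
            except Exception as exc:
                raise FormatError(f"{gtf_path}:{lineno}: {exc}") from exc
            attrs = feat.attributes
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                continue
            tid = attrs["transcript_id"][0]
            gid = attrs["gene_id"][0]
            if tid in gene_of and gene_of[tid] != gid:
                raise ConsistencyError(
                    f"{gtf_path}:{lineno}: transcript {tid} assigned to both "
                    f"{gene_of[tid]} and {gid}"
                )
            gene_of[tid] = gid
    return GeneMap(gene_of)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _classify_gt(alleles: tuple, alt_index: int) -> Genotype:
    if None in alleles or len(alleles) != 2:
        return Genotype.other
    a, b = alleles
    if a == alt_index and b == alt_index:
        return Genotype.hom_alt
    if {a, b} == {0, alt_index}:
        return Genotype.het
    if a == 0 and b == 0:
        return Genotype.hom_ref
    return Genotype.other


def read_vcf_minimal(
    path: str | Path, *, with_stats: bool = False
) -> list[VariantRecord] | tuple[list[VariantRecord], int]:
    """Read GT/DP semantics from a VCF.

    Multi-allelic sites are split into one record per ALT allele, the
    genotype classified against that allele.  Records without a GT call
    are skipped (tallied); records without DP get depth 0, which the
    downstream >= min_variant_depth filter then excludes.
    """
    records: list[VariantRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            sample = rec.samples[0] if rec.samples else None
            if sample is None or sample.get("GT") is None or all(
                a is None for a in sample["GT"]
            ):
                n_skipped += 1
                continue
            try:
                depth = sample.get("DP")
            except (KeyError, ValueError):
                depth = None
            if depth is None:
                try:
                    depth = rec.info.get("DP", 0)
                except (KeyError, ValueError):
                    depth = 0
            depth = int(depth) if depth is not None else 0
            for i, alt in enumerate(rec.alts, start=1):
                records.append(VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=str(alt),
                    genotype=_classify_gt(tuple(sample["GT"]), i),
                    depth=depth,
                ))
    if n_skipped:
        logger.warning("%s: skipped %d records without GT", path, n_skipped)
    if with_stats:
        return records, n_skipped
    return records


# ---------------------------------------------------------------------------
# Depth tables (samtools depth style: chrom <TAB> pos <TAB> depth)
# ---------------------------------------------------------------------------

def read_depth(
    path: str | Path,
    lengths: Optional[Mapping[str, int]] = None,
) -> dict[str, np.ndarray]:
    """Densify a sparse 3-column depth table into per-chromosome vectors.

    Positions are 1-based; positions absent from the file have depth 0.
    Each vector extends to the supplied chromosome length, else to the
    maximum stated position.  Positions must be strictly increasing
    within a chromosome.
    """
    sparse: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(cols)}"
                )
            try:
                chrom, pos, depth = cols[0], int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            rows = sparse.setdefault(chrom, [])
            if rows and pos <= rows[-1][0]:
                raise FormatError(
                    f"{path}:{lineno}: positions not strictly increasing "
                    f"within {chrom}"
                )
            rows.append((pos, depth))

    out: dict[str, np.ndarray] = {}
    chroms = set(sparse) | (set(lengths) if lengths else set())
    for chrom in chroms:
        rows = sparse.get(chrom, [])
        max_pos = rows[-1][0] if rows else 0
        n = lengths[chrom] if lengths and chrom in lengths else max_pos
        if max_pos > n:
            raise ConsistencyError(
                f"{chrom}: depth position {max_pos} beyond declared "
                f"length {n}"
            )
        vec = np.zeros(n, dtype=np.int64)
        for pos, depth in rows:
            vec[pos - 1] = depth
        out[chrom] = vec
    return out


# ---------------------------------------------------------------------------
# Hi-C pair tables (chrom1 pos1 strand1 chrom2 pos2 strand2)
# ---------------------------------------------------------------------------

def read_pairs(path: str | Path) -> list[PairRecord]:
    pairs: list[PairRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 pair columns, got {len(cols)}"
                )
            try:
                pairs.append(PairRecord(
                    chrom1=cols[0], pos1=int(cols[1]), strand1=Strand(cols[2]),
                    chrom2=cols[3], pos2=int(cols[4]), strand2=Strand(cols[5]),
                ))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return pairs


def write_pairs(pairs: Sequence[PairRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                f"{p.chrom1}\t{p.pos1}\t{p.strand1.value}\t"
                f"{p.chrom2}\t{p.pos2}\t{p.strand2.value}\n"
            )
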