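"""Seeded synthetic-fixture generators with planted ground truth.

Every generator is a pure function of its parameters and one integer
seed: the seed feeds a named substream per generator (so adding a
generator never perturbs existing fixtures), and reruns are
byte-identical.  The fixtures emulate the *structure* of the real
inputs — annotated transcripts with per-organism alignment evidence,
a small genome with a depth track, Hi-C pair tables with a planted cis
fraction, VCFs with planted error-proxy variants — not read-level
sequencing realism (no error models or fragment-size distributions).
Default sizes are kept small so a full test run stays fast.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    Contig,
    ContigSet,
    GeneMap,
    PairRecord,
    Strand,
    write_fasta,
    write_pairs,
)

__all__ = [
    "TruthSet",
    "make_transcriptome",
    "make_evidence",
    "make_genome_fixture",
    "make_hic_pairs",
    "make_vcf",
    "simulate_all",
]

# fixed substream tags: one per generator
_STREAMS = {
    "transcriptome": 1,
    "evidence": 2,
    "genome": 3,
    "hic": 4,
    "vcf": 5,
}

ORGANISMS = ("human", "mouse", "zebrafish", "worm")
TISSUES = ("liver", "gallbladder", "stomach", "heart", "kidney", "gill", "skin")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


@dataclass
class TruthSet:
    """Planted ground truth serialized alongside the fixtures."""

    novel_gene_ids: set[str] = field(default_factory=set)
    novel_transcript_ids: set[str] = field(default_factory=set)
    decoy_gene_ids: set[str] = field(default_factory=set)
    refseq_mapped_ids: set[str] = field(default_factory=set)
    nt_only_ids: set[str] = field(default_factory=set)
    unexpressed_candidate_ids: set[str] = field(default_factory=set)
    planted_variant_counts: tuple[int, int, int] = (0, 0, 0)  # hom snp, hom indel, het
    cis_fraction: Optional[float] = None
    n_duplicate_pairs: int = 0
    gc_by_window: dict[str, list[float]] = field(default_factory=dict)
    mean_depth: Optional[float] = None

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, set):
                d[k] = sorted(v)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        for k in (
            "novel_gene_ids", "novel_transcript_ids", "decoy_gene_ids",
            "refseq_mapped_ids", "nt_only_ids", "unexpressed_candidate_ids",
        ):
            d[k] = set(d[k])
        d["planted_variant_counts"] = tuple(d["planted_variant_counts"])
        return cls(**d)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=length, p=p)])


# ---------------------------------------------------------------------------
# Transcriptome with planted novel / decoy genes
# ---------------------------------------------------------------------------

def make_transcriptome(
    n_genes: int = 50,
    isoforms_per_gene: int = 2,
    n_novel_genes: int = 5,
    n_decoy_genes: int = 3,
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
    transcript_len: int = 300,
) -> tuple[str, ContigSet, GeneMap, TruthSet]:
    """Gene models with planted fully-novel and decoy genes.

    Novel genes get no alignment evidence on any isoform and at least
    one expressed isoform; decoy genes get exactly one isoform with
    RefSeq evidence, their remaining isoforms looking novel — the
    gene-level caller must never call them novel.  Returns (GTF text,
    transcript FASTA ContigSet, GeneMap, TruthSet) and writes
    transcripts.gtf / transcripts.fa / truth.json when out_dir is set.
    """
    if n_novel_genes + n_decoy_genes > n_genes:
        raise ValueError("more novel + decoy genes than genes")
    if isoforms_per_gene < 1:
        raise ValueError("isoforms_per_gene must be >= 1")
    rng = _rng(seed, "transcriptome")

    gene_ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    special = rng.choice(n_genes, size=n_novel_genes + n_decoy_genes, replace=False)
    novel_genes = {gene_ids[i] for i in special[:n_novel_genes]}
    decoy_genes = {gene_ids[i] for i in special[n_novel_genes:]}

    truth = TruthSet(novel_gene_ids=set(novel_genes), decoy_gene_ids=set(decoy_genes))
    gene_of: dict[str, str] = {}
    contigs: list[Contig] = []
    gtf_lines: list[str] = []
    pos = 1
    for gid in gene_ids:
        for k in range(isoforms_per_gene):
            tid = f"{gid}.t{k + 1}"
            gene_of[tid] = gid
            seq = _random_seq(rng, transcript_len)
            contigs.append(Contig(tid, len(seq), seq))
            gtf_lines.append(
                "chrS\tsynth\texon\t{}\t{}\t.\t+\t.\t"
                'gene_id "{}"; transcript_id "{}";'.format(
                    pos, pos + transcript_len - 1, gid, tid
                )
            )
            pos += transcript_len + 100
            if gid in novel_genes:
                truth.novel_transcript_ids.add(tid)
            elif gid in decoy_genes and k > 0:
                # decoy gene: isoform 1 keeps RefSeq evidence, the rest
                # are genuinely novel transcripts of a non-novel gene
                truth.novel_transcript_ids.add(tid)
            elif gid in decoy_genes:
                truth.refseq_mapped_ids.add(tid)
        # decoy genes with a single isoform cannot plant a novel one
    known_ids = [
        t for t in gene_of
        if t not in truth.novel_transcript_ids
        and t not in truth.refseq_mapped_ids
    ]
    # split remaining known transcripts: most RefSeq-mapped, some
    # NT-only (exercise stage 2), a few unmapped-but-unexpressed
    # (exercise the expression floor)
    rng.shuffle(known_ids)
    n_nt_only = max(1, len(known_ids) // 10) if known_ids else 0
    n_unexpr = max(1, len(known_ids) // 20) if known_ids else 0
    truth.nt_only_ids = set(known_ids[:n_nt_only])
    truth.unexpressed_candidate_ids = set(known_ids[n_nt_only:n_nt_only + n_unexpr])
    truth.refseq_mapped_ids |= set(known_ids[n_nt_only + n_unexpr:])

    gtf = "\n".join(gtf_lines) + "\n"
    fasta = ContigSet(contigs)
    gene_map = GeneMap(gene_of)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "transcripts.gtf").write_text(gtf)
        write_fasta(fasta, out / "transcripts.fa")
        truth.to_json(out / "truth.json")
    return gtf, fasta, gene_map, truth


# ---------------------------------------------------------------------------
# Alignment / expression evidence
# ---------------------------------------------------------------------------

def _psl_line(query: str, q_size: int, target: str, matches: int,
              mismatches: int) -> str:
    block = f"{matches + mismatches},"
    fields = [
        matches, mismatches, 0, 0, 0, 0, 0, 0, "+",
        query, q_size, 0, matches + mismatches,
        target, q_size * 2, 100, 100 + matches + mismatches,
        1, block, "0,", "100,",
    ]
    return "\t".join(str(f) for f in fields)


def make_evidence(
    truth: TruthSet,
    gene_map: GeneMap,
    transcript_lengths: dict[str, int],
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
    flip_prob: float = 0.0,
    min_reads: float = 50,
) -> tuple[dict[str, str], str, dict[str, str]]:
    """Evidence files consistent with a TruthSet.

    Returns (psl text per organism, NT blast text, quant text per
    tissue).  RefSeq-mapped transcripts get a passing PSL line in 1-4
    organisms; NT-only transcripts get a blastn hit under the e-value
    ceiling; novel transcripts get nothing (or, occasionally, a blastn
    hit failing the ceiling); expression gives every novel transcript
    >= min_reads reads in at least one tissue with a tissue-specific
    pattern, and unexpressed candidates strictly fewer everywhere.
    With flip_prob > 0 each transcript's evidence is flipped with that
    probability (noise knob for robustness tests).
    """
    rng = _rng(seed, "evidence")
    tids = sorted(gene_map.gene_of)

    def flipped(tid: str) -> bool:
        return flip_prob > 0 and rng.random() < flip_prob

    psl: dict[str, list[str]] = {org: [] for org in ORGANISMS}
    nt_lines: list[str] = []
    reads: dict[str, dict[str, float]] = {t: {} for t in TISSUES}

    for tid in tids:
        q_size = transcript_lengths[tid]
        is_refseq = tid in truth.refseq_mapped_ids
        is_nt = tid in truth.nt_only_ids
        is_novel = tid in truth.novel_transcript_ids
        if flipped(tid):
            is_refseq, is_novel = is_novel, is_refseq
        if is_refseq:
            n_org = int(rng.integers(1, len(ORGANISMS) + 1))
            for org in rng.choice(ORGANISMS, size=n_org, replace=False):
                matches = int(q_size * rng.uniform(0.7, 0.95))
                mismatches = min(q_size - matches, max(1, q_size // 50))
                psl[org].append(
                    _psl_line(tid, q_size, f"{org}_ref{rng.integers(1, 999)}",
                              matches, mismatches)
                )
        if is_nt:
            nt_lines.append(
                f"{tid}\tnt_subj{rng.integers(1, 9999)}\t"
                f"{rng.uniform(70, 99):.2f}\t200\t5\t0\t1\t200\t1\t200\t"
                f"{rng.uniform(1e-50, 1e-10):.3e}\t{rng.uniform(100, 400):.1f}"
            )
        elif is_novel and rng.random() < 0.3:
            # weak, non-qualifying NT hit (e-value above the ceiling)
            nt_lines.append(
                f"{tid}\tnt_weak{rng.integers(1, 9999)}\t"
                f"{rng.uniform(30, 60):.2f}\t40\t20\t2\t1\t40\t1\t40\t"
                f"{rng.uniform(0.5, 10):.2f}\t{rng.uniform(20, 35):.1f}"
            )
        # expression
        if is_novel:
            home = TISSUES[int(rng.integers(len(TISSUES)))]
            for tissue in TISSUES:
                base = rng.uniform(0, min_reads * 0.5)
                reads[tissue][tid] = float(round(base, 2))
            reads[home][tid] = float(round(rng.uniform(min_reads, min_reads * 20), 2))
        elif tid in truth.unexpressed_candidate_ids:
            for tissue in TISSUES:
                reads[tissue][tid] = float(round(rng.uniform(0, min_reads - 1), 2))
        else:
            for tissue in TISSUES:
                reads[tissue][tid] = float(round(rng.uniform(0, 5000), 2))

    psl_text = {
        org: ("psLayout version 3\n\nmatch\tmis-\nmatch\n"
              "---------------------------------\n" + "\n".join(lines)
              + ("\n" if lines else ""))
        for org, lines in psl.items()
    }
    nt_text = "\n".join(nt_lines) + ("\n" if nt_lines else "")
    quant_text: dict[str, str] = {}
    for tissue in TISSUES:
        lines = ["Name\tLength\tEffectiveLength\tTPM\tNumReads"]
        for tid in tids:
            length = transcript_lengths[tid]
            n = reads[tissue][tid]
            tpm = round(n / max(length - 150, 1) * 100, 4)
            lines.append(f"{tid}\t{length}\t{max(length - 150, 1)}\t{tpm}\t{n}")
        quant_text[tissue] = "\n".join(lines) + "\n"

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for org, text in psl_text.items():
            (out / f"refseq_{org}.psl").write_text(text)
        (out / "nt_blastn.tsv").write_text(nt_text)
        for tissue, text in quant_text.items():
            (out / f"quant_{tissue}.tsv").write_text(text)
    return psl_text, nt_text, quant_text


# ---------------------------------------------------------------------------
# Genome + depth fixture
# ---------------------------------------------------------------------------

def make_genome_fixture(
    n_chrom: int = 2,
    chrom_len: int = 100_000,
    gc_target: float = 0.5,
    seed: int = 0,
    mean_depth: float = 10.0,
    window: int = 10_000,
    out_dir: Optional[str | Path] = None,
) -> tuple[ContigSet, dict[str, np.ndarray], TruthSet]:
    """Random genome with a Poisson depth track around mean_depth.

    The realized per-window GC of each chromosome is recorded in the
    TruthSet for cross-checking window profiles.
    """
    rng = _rng(seed, "genome")
    contigs: list[Contig] = []
    depth: dict[str, np.ndarray] = {}
    truth = TruthSet(mean_depth=mean_depth)
    for c in range(n_chrom):
        name = f"chr{c + 1}"
        seq = _random_seq(rng, chrom_len, gc=gc_target)
        contigs.append(Contig(name, chrom_len, seq))
        depth[name] = rng.poisson(mean_depth, size=chrom_len).astype(np.int64)
        gcs = []
        for start in range(0, chrom_len, window):
            w = seq[start:start + window]
            gcs.append(round(100.0 * (w.count("G") + w.count("C")) / len(w), 4))
        truth.gc_by_window[name] = gcs
    genome = ContigSet(contigs)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome.fa")
        with open(out / "depth.tsv", "w") as fh:
            for name, vec in depth.items():
                for i, d in enumerate(vec, 1):
                    if d:  # sparse: zero-depth positions omitted
                        fh.write(f"{name}\t{i}\t{d}\n")
        truth.to_json(out / "truth.json")
    return genome, depth, truth


# ---------------------------------------------------------------------------
# Hi-C pairs
# ---------------------------------------------------------------------------

def make_hic_pairs(
    assembly: ContigSet,
    n_pairs: int = 10_000,
    cis_fraction: float = 0.9,
    seed: int = 0,
    duplicate_rate: float = 0.0,
    out_path: Optional[str | Path] = None,
) -> tuple[list[PairRecord], TruthSet]:
    """Pairs intra-chromosomal with probability cis_fraction, positions
    uniform; duplicates of already-emitted pairs appended at
    duplicate_rate (as a fraction of n_pairs)."""
    if not 0 <= cis_fraction <= 1:
        raise ValueError("cis_fraction must lie in [0, 1]")
    if len(assembly) == 0:
        raise ValueError("empty assembly")
    rng = _rng(seed, "hic")
    names = assembly.names
    lengths = dict(zip(names, assembly.lengths))
    weights = np.array([lengths[n] for n in names], dtype=float)
    weights /= weights.sum()
    pairs: list[PairRecord] = []
    for _ in range(n_pairs):
        c1 = names[int(rng.choice(len(names), p=weights))]
        if rng.random() < cis_fraction or len(names) == 1:
            c2 = c1
        else:
            others = [n for n in names if n != c1]
            c2 = others[int(rng.integers(len(others)))]
        pairs.append(PairRecord(
            chrom1=c1, pos1=int(rng.integers(1, lengths[c1] + 1)),
            strand1=Strand("+" if rng.random() < 0.5 else "-"),
            chrom2=c2, pos2=int(rng.integers(1, lengths[c2] + 1)),
            strand2=Strand("+" if rng.random() < 0.5 else "-"),
        ))
    n_dup = int(round(duplicate_rate * n_pairs))
    for idx in rng.integers(0, n_pairs, size=n_dup):
        pairs.append(pairs[int(idx)])
    truth = TruthSet(cis_fraction=cis_fraction, n_duplicate_pairs=n_dup)
    if out_path is not None:
        write_pairs(pairs, out_path)
    return pairs, truth


# ---------------------------------------------------------------------------
# VCF with planted variants
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample
"""


def make_vcf(
    genome_len: int = 1_000_000,
    n_hom_snp: int = 34,
    n_hom_indel: int = 145,
    n_het: int = 50,
    n_lowdepth: int = 10,
    seed: int = 0,
    out_path: Optional[str | Path] = None,
) -> tuple[str, TruthSet]:
    """VCF text with planted hom-alt SNPs/indels at depth >= 5, het
    calls, and low-depth (DP < 5) hom SNPs that the depth floor must
    exclude."""
    total = n_hom_snp + n_hom_indel + n_het + n_lowdepth
    if total > genome_len:
        raise ValueError("more variants than genome positions")
    rng = _rng(seed, "vcf")
    positions = np.sort(rng.choice(genome_len, size=total, replace=False) + 1)
    kinds = (
        ["hom_snp"] * n_hom_snp + ["hom_indel"] * n_hom_indel
        + ["het"] * n_het + ["lowdepth"] * n_lowdepth
    )
    rng.shuffle(kinds)
    bases = "ACGT"
    lines = [_VCF_HEADER.format(length=genome_len).rstrip("\n")]
    for pos, kind in zip(positions, kinds):
        ref = bases[int(rng.integers(4))]
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
        gt, dp = "1/1", int(rng.integers(5, 60))
        if kind == "hom_indel":
            if rng.random() < 0.5:
                ref = ref + bases[int(rng.integers(4))]  # deletion
                alt = ref[0]
            else:
                alt = ref + bases[int(rng.integers(4))]  # insertion
        elif kind == "het":
            gt = "0/1"
        elif kind == "lowdepth":
            dp = int(rng.integers(1, 5))
        lines.append(
            f"chr1\t{pos}\t.\t{ref}\t{alt}\t60\tPASS\t.\tGT:DP\t{gt}:{dp}"
        )
    text = "\n".join(lines) + "\n"
    truth = TruthSet(planted_variant_counts=(n_hom_snp, n_hom_indel, n_het))
    if out_path is not None:
        Path(out_path).write_text(text)
    return text, truth


# ---------------------------------------------------------------------------
# One-shot driver
# ---------------------------------------------------------------------------

def simulate_all(seed: int, out_dir: str | Path) -> None:
    """Write the full fixture bundle (transcriptome + evidence, genome +
    depth, Hi-C pairs, VCF) with their truth files under out_dir."""
    out = Path(out_dir)
    gtf, fasta, gene_map, truth = make_transcriptome(
        seed=seed, out_dir=out / "transcriptome"
    )
    lengths = dict(zip(fasta.names, fasta.lengths))
    make_evidence(truth, gene_map, lengths, seed=seed, out_dir=out / "evidence")
    genome, _, _ = make_genome_fixture(seed=seed, out_dir=out / "genome")
    make_hic_pairs(
        genome, seed=seed, duplicate_rate=0.1, out_path=out / "hic_pairs.tsv"
    )
    make_vcf(seed=seed, out_path=out / "calls.vcf")
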