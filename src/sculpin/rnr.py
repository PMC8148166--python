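"""RNR (RefSeq - NT - RNA-seq) novel gene and transcript selection,
plus ORF-completeness filtering and protein-novelty summarisation.

The RNR funnel removes annotated transcripts with homology evidence in
three stages:

1. transcripts aligning (pblat) to the RefSeq mRNA of any of the model
   organisms (default human, mouse, zebrafish, nematode) are known;
2. survivors aligning (blastn, e-value <= 0.05) to the NCBI nucleotide
   database are known;
3. survivors with at least `min_novel_reads` RNA-seq reads in at least
   one tissue are the novel transcripts; the rest lack expression
   support and stay candidates.

A gene is novel iff every one of its transcripts survived stages 1-2
(no homology evidence on any isoform) and at least one is expressed
above the read floor.  A gene with a novel transcript but also a
homology-supported isoform is only partially novel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import (
    BlastHit,
    ConsistencyError,
    GeneMap,
    Params,
    PslHit,
    QuantTable,
)

__all__ = [
    "TranscriptStatus",
    "GeneStatus",
    "Funnel",
    "EvidenceTable",
    "NoveltyReport",
    "OrfVerdict",
    "ProteinNovelty",
    "step1_refseq",
    "step2_nt",
    "step3_expression",
    "call_novel_genes",
    "orf_filter",
    "protein_novelty",
    "rnr_pipeline",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


class TranscriptStatus(str, Enum):
    mapped_refseq = "mapped_refseq"
    mapped_nt = "mapped_nt"
    candidate_unexpressed = "candidate_unexpressed"
    novel = "novel"


class GeneStatus(str, Enum):
    known = "known"
    partially_novel = "partially_novel"
    novel = "novel"


@dataclass(frozen=True)
class Funnel:
    """Ordered transcript/gene counts through the selection stages."""

    n_total: int
    n_unmapped_refseq: int
    n_nt_mapped: int
    n_unmapped_both: int
    n_novel_transcripts: int
    n_genes_with_novel: int
    n_novel_genes: int

    def __post_init__(self) -> None:
        ok = (
            self.n_total >= self.n_unmapped_refseq
            >= self.n_unmapped_both >= self.n_novel_transcripts
            and self.n_unmapped_refseq == self.n_nt_mapped + self.n_unmapped_both
            and self.n_genes_with_novel >= self.n_novel_genes
        )
        if not ok:
            raise ValueError(f"inconsistent funnel counts: {self}")

    def to_dict(self) -> dict[str, int]:
        return {
            "total_transcripts": self.n_total,
            "unmapped_refseq": self.n_unmapped_refseq,
            "nt_mapped": self.n_nt_mapped,
            "unmapped_both": self.n_unmapped_both,
            "novel_transcripts": self.n_novel_transcripts,
            "genes_with_novel_transcript": self.n_genes_with_novel,
            "novel_genes": self.n_novel_genes,
        }


@dataclass
class EvidenceTable:
    """Per-transcript alignment evidence across the funnel stages."""

    refseq_hits: dict[str, dict[str, int]]  # transcript -> organism -> hits
    nt_hits: dict[str, int]                 # transcript -> qualifying NT hits
    max_reads: dict[str, float]             # transcript -> max reads any tissue
    gene_of: dict[str, str]

    def to_rows(self) -> list[dict]:
        organisms = sorted({o for d in self.refseq_hits.values() for o in d})
        rows = []
        for tid in sorted(self.gene_of):
            row = {"transcript_id": tid, "gene_id": self.gene_of[tid]}
            for org in organisms:
                row[f"refseq_hits_{org}"] = self.refseq_hits.get(tid, {}).get(org, 0)
            row["nt_hits"] = self.nt_hits.get(tid, 0)
            row["max_reads"] = self.max_reads.get(tid, 0.0)
            rows.append(row)
        return rows


@dataclass
class NoveltyReport:
    transcript_status: dict[str, TranscriptStatus]
    gene_status: dict[str, GeneStatus]
    funnel: Funnel
    evidence: Optional[EvidenceTable] = None

    @property
    def novel_transcripts(self) -> set[str]:
        return {
            t for t, s in self.transcript_status.items()
            if s is TranscriptStatus.novel
        }

    @property
    def novel_genes(self) -> set[str]:
        return {g for g, s in self.gene_status.items() if s is GeneStatus.novel}

    def write_tsv(self, out_dir: str | Path) -> None:
        """transcripts.tsv + genes.tsv + funnel.json under out_dir."""
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "transcripts.tsv", "w") as fh:
            fh.write("transcript_id\tgene_id\tstatus\n")
            gene_of = self.evidence.gene_of if self.evidence else {}
            for tid in sorted(self.transcript_status):
                fh.write(
                    f"{tid}\t{gene_of.get(tid, '.')}\t"
                    f"{self.transcript_status[tid].value}\n"
                )
        with open(out / "genes.tsv", "w") as fh:
            fh.write("gene_id\tstatus\n")
            for gid in sorted(self.gene_status):
                fh.write(f"{gid}\t{self.gene_status[gid].value}\n")
        with open(out / "funnel.json", "w") as fh:
            json.dump(self.funnel.to_dict(), fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Funnel stages
# ---------------------------------------------------------------------------

def _retained(hit: PslHit, params: Params) -> bool:
    if not params.refilter_psl:
        return True
    return (
        hit.score >= params.psl_min_score
        and hit.identity_pct >= params.psl_min_identity_pct
    )


def step1_refseq(
    transcript_ids: Iterable[str],
    psl_by_organism: Mapping[str, Sequence[PslHit]],
    params: Params | None = None,
) -> tuple[set[str], set[str]]:
    """Partition transcripts into (mapped, unmapped) by the union of
    retained RefSeq alignments over the model organisms.

    By default any PSL line counts (the aligner's -minScore/-minIdentity
    retention already applied upstream); params.refilter_psl re-applies
    score >= psl_min_score and identity >= psl_min_identity_pct.
    """
    params = params or Params()
    ids = set(transcript_ids)
    mapped: set[str] = set()
    for organism, hits in psl_by_organism.items():
        for hit in hits:
            if hit.query not in ids:
                raise ConsistencyError(
                    f"{organism} PSL hit names unknown transcript {hit.query}"
                )
            if _retained(hit, params):
                mapped.add(hit.query)
    return mapped, ids - mapped


def step2_nt(
    unmapped_ids: Iterable[str],
    nt_hits: Sequence[BlastHit],
    params: Params | None = None,
) -> tuple[set[str], set[str]]:
    """Partition stage-1 survivors into (nt_mapped, candidate) by
    blastn evidence at e-value <= blastn_evalue_max (inclusive)."""
    params = params or Params()
    ids = set(unmapped_ids)
    nt_mapped = {
        h.query for h in nt_hits
        if h.query in ids and h.evalue <= params.blastn_evalue_max
    }
    return nt_mapped, ids - nt_mapped


def step3_expression(
    candidate_ids: Iterable[str],
    quant: QuantTable,
    params: Params | None = None,
) -> tuple[set[str], set[str]]:
    """Partition candidates into (novel, candidate_unexpressed) by the
    read floor: novel iff max read count over tissues >= min_novel_reads
    (optionally rounding counts first, params.round_quant_reads)."""
    params = params or Params()
    novel: set[str] = set()
    unexpressed: set[str] = set()
    for tid in candidate_ids:
        try:
            reads = quant.max_reads(tid)
        except KeyError:
            raise ConsistencyError(
                f"candidate transcript {tid} absent from quantification"
            ) from None
        if params.round_quant_reads:
            reads = round(reads)
        (novel if reads >= params.min_novel_reads else unexpressed).add(tid)
    return novel, unexpressed


def call_novel_genes(
    statuses: Mapping[str, TranscriptStatus],
    gene_map: GeneMap,
) -> NoveltyReport:
    """Lift transcript statuses to gene verdicts and assemble the funnel.

    A gene is novel iff all its transcripts lack homology evidence
    (status candidate_unexpressed or novel) and at least one is novel
    (expressed).  Genes with a novel transcript next to a homology-
    supported isoform are partially novel; everything else is known.
    """
    for tid in statuses:
        if tid not in gene_map.gene_of:
            raise ConsistencyError(f"transcript {tid} missing from gene map")
    for tid in gene_map.gene_of:
        if tid not in statuses:
            raise ConsistencyError(f"transcript {tid} has no status")

    unmapped_states = {TranscriptStatus.candidate_unexpressed, TranscriptStatus.novel}
    gene_status: dict[str, GeneStatus] = {}
    for gid in gene_map.genes:
        tstats = [statuses[t] for t in gene_map.transcripts_of(gid)]
        has_novel = TranscriptStatus.novel in tstats
        all_unmapped = all(s in unmapped_states for s in tstats)
        if has_novel and all_unmapped:
            gene_status[gid] = GeneStatus.novel
        elif has_novel:
            gene_status[gid] = GeneStatus.partially_novel
        else:
            gene_status[gid] = GeneStatus.known

    n_total = len(statuses)
    n_unmapped_refseq = sum(
        1 for s in statuses.values() if s is not TranscriptStatus.mapped_refseq
    )
    n_nt_mapped = sum(
        1 for s in statuses.values() if s is TranscriptStatus.mapped_nt
    )
    n_unmapped_both = n_unmapped_refseq - n_nt_mapped
    n_novel = sum(1 for s in statuses.values() if s is TranscriptStatus.novel)
    genes_with_novel = {
        gene_map.gene_of[t]
        for t, s in statuses.items()
        if s is TranscriptStatus.novel
    }
    n_novel_genes = sum(
        1 for s in gene_status.values() if s is GeneStatus.novel
    )
    funnel = Funnel(
        n_total=n_total,
        n_unmapped_refseq=n_unmapped_refseq,
        n_nt_mapped=n_nt_mapped,
        n_unmapped_both=n_unmapped_both,
        n_novel_transcripts=n_novel,
        n_genes_with_novel=len(genes_with_novel),
        n_novel_genes=n_novel_genes,
    )
    return NoveltyReport(
        transcript_status=dict(statuses),
        gene_status=gene_status,
        funnel=funnel,
    )


# ---------------------------------------------------------------------------
# ORF completeness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrfVerdict:
    transcript_id: str
    reasons: frozenset[str]  # no_start | no_stop | internal_stop | too_short | bad_frame

    @property
    def passed(self) -> bool:
        return not self.reasons


def orf_filter(
    cds: str, params: Params | None = None, *, transcript_id: str = ""
) -> OrfVerdict:
    """Completeness verdict for a coding sequence.

    A complete CDS starts with ATG, ends with a stop codon, has no
    in-frame internal stop, is a whole number of codons, and encodes
    more than `min_orf_aa` amino acids between the initiator and the
    terminal stop.
    """
    params = params or Params()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    cds = cds.upper()
    reasons: set[str] = set()
    if len(cds) % 3 != 0:
        reasons.add("bad_frame")
    if not cds.startswith(START_CODON):
        reasons.add("no_start")
    codons = [cds[i:i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
    if codons[-1] not in STOP_CODONS:
        reasons.add("no_stop")
    if any(c in STOP_CODONS for c in codons[:-1]):
        reasons.add("internal_stop")
    # amino acids strictly between the initiator and the terminal stop
    has_stop = codons[-1] in STOP_CODONS
    n_aa = len(codons) - (1 if has_stop else 0) - 1
    if n_aa <= params.min_orf_aa:
        reasons.add("too_short")
    return OrfVerdict(transcript_id=transcript_id, reasons=frozenset(reasons))


# ---------------------------------------------------------------------------
# Protein novelty
# ---------------------------------------------------------------------------

@dataclass
class ProteinNovelty:
    """Best NR protein hit (or absence of one) per novel transcript."""

    best_hit: dict[str, BlastHit]  # only transcripts with a qualifying hit
    no_hit: set[str]

    @property
    def n_no_hit(self) -> int:
        return len(self.no_hit)

    def pident_of_hits(self) -> list[float]:
        return [h.pident for h in self.best_hit.values()]


def protein_novelty(
    novel_ids: Iterable[str],
    blastp_hits: Sequence[BlastHit],
    params: Params | None = None,
) -> ProteinNovelty:
    """For each novel transcript pick the best qualifying blastp hit
    (minimum e-value; ties by maximum bitscore, then subject name);
    transcripts with no hit at e-value <= blastp_evalue_max are the
    protein-level novelties."""
    params = params or Params()
    ids = set(novel_ids)
    best: dict[str, BlastHit] = {}
    for h in blastp_hits:
        if h.query not in ids or h.evalue > params.blastp_evalue_max:
            continue
        cur = best.get(h.query)
        if cur is None or (h.evalue, -h.bitscore, h.subject) < (
            cur.evalue, -cur.bitscore, cur.subject
        ):
            best[h.query] = h
    return ProteinNovelty(best_hit=best, no_hit=ids - set(best))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def rnr_pipeline(
    gene_map: GeneMap,
    psl_by_organism: Mapping[str, Sequence[PslHit]],
    nt_hits: Sequence[BlastHit],
    quant: QuantTable,
    params: Params | None = None,
) -> NoveltyReport:
    """Run the three-stage funnel and gene-level calling end to end."""
    params = params or Params()
    ids = set(gene_map.gene_of)
    mapped1, unmapped1 = step1_refseq(ids, psl_by_organism, params)
    nt_mapped, candidates = step2_nt(unmapped1, nt_hits, params)
    novel, unexpressed = step3_expression(candidates, quant, params)

    statuses: dict[str, TranscriptStatus] = {}
    for t in mapped1:
        statuses[t] = TranscriptStatus.mapped_refseq
    for t in nt_mapped:
        statuses[t] = TranscriptStatus.mapped_nt
    for t in unexpressed:
        statuses[t] = TranscriptStatus.candidate_unexpressed
    for t in novel:
        statuses[t] = TranscriptStatus.novel

    report = call_novel_genes(statuses, gene_map)
    report.evidence = EvidenceTable(
        refseq_hits={
            tid: {
                org: sum(
                    1 for h in hits
                    if h.query == tid and _retained(h, params)
                )
                for org, hits in psl_by_organism.items()
            }
            for tid in sorted(ids)
        },
        nt_hits={
            tid: sum(
                1 for h in nt_hits
                if h.query == tid and h.evalue <= params.blastn_evalue_max
            )
            for tid in sorted(ids)
        },
        max_reads={
            tid: quant.max_reads(tid)
            for tid in sorted(ids)
            if tid in {t for t, _ in quant.entries}
        },
        gene_of=dict(gene_map.gene_of),
    )
    return report
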