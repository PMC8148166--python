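# Methods

This note documents the statistical conventions, thresholds and design
choices behind each analysis, and what the synthetic fixtures do and do
not demonstrate.

## Coordinates and formats

All genomic positions are 1-based inclusive at file boundaries (VCF,
GTF, depth tables, pair tables, blastn intervals) and converted to
0-based half-open intervals internally; `io_formats` is the only module
that performs the conversion. Standard formats are parsed by the usual
libraries (Biopython for FASTA/FASTQ, pysam for VCF, gffutils for GTF
attributes, pandas for tabular files); the toolkit never re-implements
a format another library already reads.

## Contiguity statistics

**Nxx.** Lengths are sorted descending; the Nxx length is the length of
the first record at which the cumulative sum reaches *at least* x% of
the total, and the Nxx count is the number of records up to and
including it. The ≥ comparison makes a single contig its own N50 and
is verified against a brute-force cumulative-scan oracle at every level
1–100. Nxx at level 100 returns the minimum length and the record
count.

**Read summaries.** "> t" percentages are strictly greater-than,
matching the way read-length thresholds are conventionally labelled.
Coverage X = total bases / genome size. Rounding happens only at the
presentation layer: coverage to 3 decimals, mean lengths to whole base
pairs, percentages to 2 decimals; internal values keep full precision.

**Mapping-rate tables.** mapped_all = unique + multiple;
pct = 100·mapped_all/total. The Average row is the *unweighted* mean of
the per-sample columns (including the percentage — not the pooled
rate), and the Total row is the column sums with no percentage; this is
the convention of the summary tables the toolkit reproduces.

## GC-depth windows

Windows are non-overlapping tilings (step = window size, default
10 kb), with the final partial window kept. Tiling rather than
overlapping sliding guarantees the conservation invariants the tests
rely on: window sizes sum to the assembly length and the size-weighted
mean of window depths equals the global mean depth. At 10 kb scale the
resulting GC-depth cloud is indistinguishable from an overlapped one
for QC purposes. The GC denominator excludes N bases so gap-rich
windows are not deflated; all-N windows carry NaN GC. Soft-masked
lowercase bases count as their uppercase nucleotide. Whether the depth
vector derives from per-base alignment depth or another source is the
caller's choice; the densified 3-column depth table is the contract.

## Single-base accuracy

Homozygous-ALT calls against the assembly, at depth ≥ 5 (configurable),
proxy consensus errors: SNPs (both alleles single bases) mark wrong
bases and indels (length-changing) are counted as *events*, not
affected bases. Heterozygous calls are treated as plausible true
heterozygosity of the diploid individual and excluded from the error
count; by default the homozygosity requirement applies to indels
symmetrically (a flag relaxes it). The denominator is the polished
assembly length. Records lacking DP are assigned depth 0 — permissive
ingestion, conservative exclusion by the depth floor — and records
lacking GT are skipped with a tally. Percentages are reported to 6
decimals and accuracy to 4; at full precision
accuracy + %SNP + %indel = 100 by construction. The method ignores
short-read sequencing error and mapping error (notably in repeats), so
it is an upper bound on the true error rate's confidence, not a
calibrated estimator.

## Hi-C processing

Reads are kept iff mean Phred > 15 (strict) and the N count is
strictly below 5. Chimeric reads are cut at the *first* occurrence of
the restriction site (DpnII, GATC), keeping the 5′ prefix *including*
the site: keeping the site preserves mappable bases, and the operation
is idempotent. A flag offers cutting before the site, and the
re-ligation junction GATCGATC is exposed as a constant for
junction-aware trimming. Duplicate pairs are collapsed after canonical
mate ordering (sorted mate tuples), so mirrored records of the same
fragment dedupe together; output order is sorted, hence deterministic
under input permutation. "Merging" of uniquely mapped pairs is
implemented as this deduplication, with a bypass flag, since uniqueness
filtering itself belongs to the upstream aligner.

Each mate is assigned to bin ⌊(pos−1)/bin⌋ (default 100 kb) by its
5′ mapped coordinate, strand ignored; the symmetric pair-count matrix
conserves the total retained pairs in its upper triangle + diagonal.
Linkage intensity is displayed as ln(1 + count): trans space is
dominated by zero-count bin pairs and ln(0) is undefined, so the +1
offset keeps the transform total and monotone.

## The RNR funnel

Stage 1 (RefSeq): a transcript is known if it has *any* retained pblat
hit in the union over the model organisms (default four: human, mouse,
zebrafish, nematode; configurable). By default every PSL line counts,
since the aligner's own `-minScore=30 -minIdentity=60` retention was
applied upstream; an optional re-filter recomputes
score = matches + repMatches − misMatches − qInserts − tInserts and
identity = 100·matches/(matches + mismatches) — an approximation of
blat's web-BLAT identity, which has no single published formula.

Stage 2 (NT): survivors with a blastn hit at e-value ≤ 0.05
(*inclusive*) are known.

Stage 3 (expression): survivors with ≥ 50 reads (inclusive) in at least
one tissue are novel transcripts; read counts drive the filter, the TPM
column is carried for reporting only. Fractional counts from the
quantifier are compared as-is by default; a flag rounds them first.
The read floor is stated both as "at least 50" and as "> 50" in
different places of the method's description; the inclusive reading is
the default and the boundary is configurable.

Gene calling: a gene is **novel** iff every isoform lacks homology
evidence (stage 1–2 survivor) *and* at least one isoform is novel
(expressed). A gene with a novel transcript next to a
homology-supported isoform is **partially novel** — this is the gap
between "genes with novel transcripts" and "novel genes" in the
funnel. Genes whose isoforms all survive stages 1–2 but none passes
the expression floor are reported as known-with-unexpressed-candidates
rather than silently dropped, keeping the funnel auditable.

**ORF completeness.** A CDS passes iff it starts with ATG, ends with
TAA/TAG/TGA, contains no in-frame internal stop, is a whole number of
codons, and the amino-acid count strictly between the initiator and
the terminal stop exceeds 100 (so a 306 nt CDS — ATG + 100 codons +
stop — fails and 309 nt passes). The internal-stop check is verified
against an independent frame-scan oracle on random sequences.

**Protein novelty.** For each novel transcript the best blastp hit is
the minimum e-value (ties: maximum bitscore, then lexicographic
subject) among hits at e ≤ 0.05; transcripts with no qualifying hit
are the protein-level novelties.

## Synthetic fixtures

Each generator draws from a named substream of one integer seed
(`default_rng([stream_id, seed])`), so fixtures are byte-identical
across reruns and adding a generator never perturbs existing ones.
Defaults are deliberately small — 100 transcripts (50 genes × 2
isoforms, 5 novel + 3 decoy genes), ≤ 1 Mb genomes, 10⁴ Hi-C pairs,
~250 planted variants — sized so the whole suite runs in seconds while
keeping binomial standard errors small enough for 3σ recovery checks.
The fixtures emulate evidence *structure* (which transcript has which
hits, planted cis fractions, planted variant classes), not sequencing
realism: no read error models, no fragment-length distributions, no
homology-by-sequence-similarity. Passing tests therefore demonstrate
that the decision logic is exact given correct upstream alignments —
not that the end-to-end discovery rate on real data matches any
particular study, which depends on the external aligners and
databases.

## Known limitations

- The contiguity statistics of a real assembly (e.g. a published Nxx
  table) can only be reproduced from the actual contig lengths, which
  are not part of this repository; the toolkit verifies the algorithm
  against oracles and published *arithmetic* instead.
- VCF support is deliberately minimal (GT/DP semantics); exotic
  genotypes beyond diploid biallelic calls classify as `other`.
- The Hi-C path stops at the contact matrix and cis/trans summary;
  scaffolding (clustering/ordering/orienting) is an external tool's
  job.
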