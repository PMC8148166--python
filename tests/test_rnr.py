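"""RNR funnel stages, gene-level novelty calling, ORF completeness and
protein novelty."""

import numpy as np
import pytest

from sculpin import BlastHit, GeneMap, Params, PslHit, QuantTable
from sculpin.rnr import (
    GeneStatus,
    TranscriptStatus,
    call_novel_genes,
    orf_filter,
    protein_novelty,
    rnr_pipeline,
    step1_refseq,
    step2_nt,
    step3_expression,
)
from sculpin.synth import ORGANISMS, TISSUES, make_evidence, make_transcriptome


def _psl(query, matches=200, mismatches=5, q_size=300):
    return PslHit(query=query, target="ref", matches=matches,
                  mismatches=mismatches, rep_matches=0,
                  q_num_insert=0, t_num_insert=0, q_size=q_size)


def _blast(query, evalue, pident=80.0, bitscore=100.0, subject="s1"):
    return BlastHit(query=query, subject=subject, pident=pident,
                    evalue=evalue, bitscore=bitscore)


def _quant(counts):
    """counts: {tid: {tissue: reads}} over a single shared tissue set."""
    tissues = sorted({t for d in counts.values() for t in d})
    entries = {}
    for tid, d in counts.items():
        for tissue in tissues:
            entries[(tid, tissue)] = (float(d.get(tissue, 0)), 0.0)
    return QuantTable(entries)


class TestStep1:
    def test_union_over_organisms(self):
        mapped, unmapped = step1_refseq(
            ["t1", "t2"], {"zebrafish": [_psl("t1")], "human": []})
        assert mapped == {"t1"} and unmapped == {"t2"}

    def test_no_hits_anywhere_unmapped(self):
        mapped, unmapped = step1_refseq(
            ["t1"], {org: [] for org in ORGANISMS})
        assert mapped == set() and unmapped == {"t1"}

    def test_unknown_query_raises(self):
        from sculpin import ConsistencyError
        with pytest.raises(ConsistencyError):
            step1_refseq(["t1"], {"human": [_psl("ghost")]})

    def test_refilter_drops_weak_hits(self):
        weak = _psl("t1", matches=20, mismatches=15)  # score 5, identity 57%
        p = Params(refilter_psl=True)
        mapped, unmapped = step1_refseq(["t1"], {"human": [weak]}, p)
        assert mapped == set()
        # without refiltering any line counts
        mapped2, _ = step1_refseq(["t1"], {"human": [weak]})
        assert mapped2 == {"t1"}


class TestStep2:
    @pytest.mark.parametrize("evalue,expect_mapped", [
        (0.04, True),
        (0.05, True),    # ceiling is inclusive
        (0.051, False),
        (0.6, False),
    ])
    def test_evalue_ceiling(self, evalue, expect_mapped):
        nt_mapped, cand = step2_nt(["t1"], [_blast("t1", evalue)])
        assert (("t1" in nt_mapped) is expect_mapped)

    def test_no_hits_is_candidate(self):
        nt_mapped, cand = step2_nt(["t1"], [])
        assert cand == {"t1"}


class TestStep3:
    @pytest.mark.parametrize("reads,expect_novel", [
        (50, True),     # "at least 50" inclusive
        (49, False),
        (0, False),
    ])
    def test_read_floor(self, reads, expect_novel):
        q = _quant({"t1": {"liver": reads}})
        novel, unexpr = step3_expression(["t1"], q)
        assert (("t1" in novel) is expect_novel)

    def test_max_over_tissues(self):
        q = _quant({"t1": {"liver": 50, "skin": 0}})
        novel, _ = step3_expression(["t1"], q)
        assert novel == {"t1"}

    def test_missing_candidate_raises(self):
        from sculpin import ConsistencyError
        with pytest.raises(ConsistencyError):
            step3_expression(["ghost"], _quant({"t1": {"liver": 1}}))

    def test_optional_rounding_flag(self):
        q = _quant({"t1": {"liver": 49.6}})
        novel_default, _ = step3_expression(["t1"], q)
        novel_rounded, _ = step3_expression(
            ["t1"], q, Params(round_quant_reads=True))
        assert novel_default == set() and novel_rounded == {"t1"}


class TestCallNovelGenes:
    GM = GeneMap({"g1.t1": "g1", "g1.t2": "g1", "g2.t1": "g2", "g3.t1": "g3"})

    def test_mixed_gene_is_partially_novel(self):
        statuses = {
            "g1.t1": TranscriptStatus.novel,
            "g1.t2": TranscriptStatus.mapped_refseq,
            "g2.t1": TranscriptStatus.novel,
            "g3.t1": TranscriptStatus.mapped_nt,
        }
        rep = call_novel_genes(statuses, self.GM)
        assert rep.gene_status["g1"] is GeneStatus.partially_novel
        assert rep.gene_status["g2"] is GeneStatus.novel
        assert rep.gene_status["g3"] is GeneStatus.known
        assert rep.funnel.n_genes_with_novel == 2
        assert rep.funnel.n_novel_genes == 1

    def test_all_novel_gene(self):
        statuses = {t: TranscriptStatus.novel for t in self.GM.gene_of}
        rep = call_novel_genes(statuses, self.GM)
        assert set(rep.gene_status.values()) == {GeneStatus.novel}

    def test_unexpressed_gene_not_novel(self):
        # every transcript survives stages 1-2 but none is expressed:
        # no expressed member, so the gene is not novel
        statuses = {t: TranscriptStatus.candidate_unexpressed
                    for t in self.GM.gene_of}
        rep = call_novel_genes(statuses, self.GM)
        assert set(rep.gene_status.values()) == {GeneStatus.known}
        assert rep.funnel.n_novel_genes == 0

    def test_funnel_monotonicity(self):
        statuses = {
            "g1.t1": TranscriptStatus.mapped_refseq,
            "g1.t2": TranscriptStatus.mapped_nt,
            "g2.t1": TranscriptStatus.candidate_unexpressed,
            "g3.t1": TranscriptStatus.novel,
        }
        f = call_novel_genes(statuses, self.GM).funnel
        assert (f.n_total >= f.n_unmapped_refseq >= f.n_unmapped_both
                >= f.n_novel_transcripts)
        assert f.n_genes_with_novel >= f.n_novel_genes


class TestOrfFilter:
    NONSTOP = "GCT"  # alanine

    def _cds(self, n_codons, start="ATG", stop="TAA"):
        return start + self.NONSTOP * n_codons + stop

    def test_exactly_100_aa_fails(self):
        v = orf_filter(self._cds(100))
        assert not v.passed and v.reasons == {"too_short"}

    def test_101_aa_passes(self):
        assert orf_filter(self._cds(101)).passed

    def test_internal_stop(self):
        v = orf_filter("ATG" + "AAA" + "TAG" + "AAA" + "TAA")
        assert "internal_stop" in v.reasons

    def test_missing_start(self):
        v = orf_filter("CCC" + self.NONSTOP * 101 + "TAA")
        assert v.reasons == {"no_start"}

    @pytest.mark.parametrize("stop", ["TAA", "TAG", "TGA"])
    def test_all_stop_codons_accepted(self, stop):
        assert orf_filter(self._cds(101, stop=stop)).passed

    def test_missing_stop(self):
        v = orf_filter("ATG" + self.NONSTOP * 102)
        assert "no_stop" in v.reasons

    def test_out_of_frame_length(self):
        v = orf_filter(self._cds(101) + "A")
        assert "bad_frame" in v.reasons

    def test_internal_stop_agrees_with_frame_scan_oracle(self):
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(200):
            n = int(rng.integers(2, 60)) * 3
            seq = "".join(bases[rng.integers(0, 4, size=n)])
            oracle = any(seq[i:i + 3] in stops for i in range(0, n - 3, 3))
            assert ("internal_stop" in orf_filter(seq).reasons) == oracle


class TestProteinNovelty:
    def test_all_hits_above_threshold_is_no_hit(self):
        res = protein_novelty(["t1"], [_blast("t1", 0.2), _blast("t1", 0.9)])
        assert res.no_hit == {"t1"}

    def test_best_hit_by_min_evalue(self):
        hits = [_blast("t1", 1e-5, pident=55.0), _blast("t1", 1e-3, pident=90.0)]
        res = protein_novelty(["t1"], hits)
        assert res.best_hit["t1"].pident == 55.0

    def test_empty_hit_list(self):
        res = protein_novelty(["t1"], [])
        assert res.no_hit == {"t1"} and res.n_no_hit == 1

    def test_tie_break_bitscore_then_subject(self):
        hits = [
            _blast("t1", 1e-5, bitscore=100.0, subject="b"),
            _blast("t1", 1e-5, bitscore=200.0, subject="z"),
            _blast("t1", 1e-5, bitscore=200.0, subject="a"),
        ]
        res = protein_novelty(["t1"], hits)
        assert res.best_hit["t1"].subject == "a"


class TestPipeline:
    def test_all_mapped_gives_empty_funnel_tail(self):
        gm = GeneMap({"t1": "g1", "t2": "g2"})
        psl = {"human": [_psl("t1"), _psl("t2")]}
        q = _quant({"t1": {"liver": 100}, "t2": {"liver": 100}})
        rep = rnr_pipeline(gm, psl, [], q)
        f = rep.funnel
        assert (f.n_unmapped_refseq, f.n_novel_transcripts, f.n_novel_genes) \
            == (0, 0, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_noiseless_truth_recovery(self, seed, tmp_path):
        _, fasta, gm, truth = make_transcriptome(
            n_genes=50, isoforms_per_gene=2, n_novel_genes=5,
            n_decoy_genes=3, seed=seed)
        lengths = dict(zip(fasta.names, fasta.lengths))
        psl_text, nt_text, quant_text = make_evidence(truth, gm, lengths, seed=seed)
        from sculpin import read_blast_tab, read_psl, read_quant

        for name, text in psl_text.items():
            (tmp_path / f"{name}.psl").write_text(text)
        (tmp_path / "nt.tsv").write_text(nt_text)
        for tissue, text in quant_text.items():
            (tmp_path / f"{tissue}.tsv").write_text(text)
        rep = rnr_pipeline(
            gm,
            {o: read_psl(tmp_path / f"{o}.psl") for o in ORGANISMS},
            read_blast_tab(tmp_path / "nt.tsv"),
            read_quant({t: tmp_path / f"{t}.tsv" for t in TISSUES}),
        )
        assert rep.novel_transcripts == truth.novel_transcript_ids
        assert rep.novel_genes == truth.novel_gene_ids
        assert not (rep.novel_genes & truth.decoy_gene_ids)

    def test_permutation_invariance(self, rnr_inputs):
        rng = np.random.default_rng(3)
        psl = {o: list(h) for o, h in rnr_inputs["psl"].items()}
        for h in psl.values():
            rng.shuffle(h)
        nt = list(rnr_inputs["nt"])
        rng.shuffle(nt)
        a = rnr_pipeline(rnr_inputs["gene_map"], rnr_inputs["psl"],
                         rnr_inputs["nt"], rnr_inputs["quant"])
        b = rnr_pipeline(rnr_inputs["gene_map"], psl, nt, rnr_inputs["quant"])
        assert a.transcript_status == b.transcript_status
        assert a.funnel == b.funnel

    def test_report_tsv_outputs(self, rnr_inputs, tmp_path):
        rep = rnr_pipeline(rnr_inputs["gene_map"], rnr_inputs["psl"],
                           rnr_inputs["nt"], rnr_inputs["quant"])
        rep.write_tsv(tmp_path)
        lines = (tmp_path / "transcripts.tsv").read_text().splitlines()
        assert len(lines) - 1 == rep.funnel.n_total
        assert (tmp_path / "funnel.json").exists()
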