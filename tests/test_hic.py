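"""Hi-C read QC, trimming, dedup, binning and cis/trans enrichment."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sculpin import ConsistencyError, ContigSet, PairRecord, Strand
from sculpin.hic import (
    bin_pairs,
    cis_trans_summary,
    dedup_pairs,
    log_intensity,
    qc_filter_read,
    trim_at_site,
)
from sculpin.synth import make_hic_pairs

dna = st.text(alphabet="ACGTN", min_size=1, max_size=80)


def _pair(c1, p1, c2, p2, s1="+", s2="+"):
    return PairRecord(c1, p1, Strand(s1), c2, p2, Strand(s2))


class TestQcFilter:
    def test_good_read_kept(self):
        v = qc_filter_read("ACGT" * 10, [30] * 40)
        assert v.keep

    def test_low_quality_dropped(self):
        v = qc_filter_read("ACGT" * 10, [10] * 40)
        assert not v.keep and v.reason == "low_quality"

    def test_n_count_boundary(self):
        seq = "N" * 4 + "A" * 36
        assert qc_filter_read(seq, [30] * 40).keep          # 4 Ns < 5: keep
        seq5 = "N" * 5 + "A" * 35
        v = qc_filter_read(seq5, [30] * 40)
        assert not v.keep and v.reason == "too_many_N"      # 5 Ns: drop

    def test_mean_phred_is_strictly_greater(self):
        assert not qc_filter_read("AAAA", [15, 15, 15, 15]).keep
        assert qc_filter_read("AAAA", [16, 16, 16, 16]).keep

    def test_fastq_quality_string_accepted(self):
        # '?' is Phred 30 at offset 33
        assert qc_filter_read("ACGT", "????").keep

    def test_length_mismatch_raises(self):
        with pytest.raises(ConsistencyError):
            qc_filter_read("ACGT", [30, 30])


class TestTrim:
    def test_first_occurrence_kept_inclusive(self):
        assert trim_at_site("AAAGATCTTT", "GATC") == "AAAGATC"

    def test_no_site_unchanged(self):
        assert trim_at_site("AAAA", "GATC") == "AAAA"

    def test_site_at_start(self):
        assert trim_at_site("GATCGG", "GATC") == "GATC"

    def test_cut_before_site_mode(self):
        assert trim_at_site("AAGATCTT", "GATC", keep_site=False) == "AA"

    @given(dna)
    def test_idempotent(self, seq):
        once = trim_at_site(seq, "GATC")
        assert trim_at_site(once, "GATC") == once

    @given(dna)
    def test_output_is_prefix(self, seq):
        assert seq.startswith(trim_at_site(seq, "GATC"))


class TestDedup:
    def test_identical_pairs_collapse(self):
        p = _pair("c1", 10, "c2", 20)
        assert len(dedup_pairs([p, p])) == 1

    def test_mirrored_mates_collapse(self):
        a = _pair("c1", 10, "c2", 20, "+", "-")
        b = _pair("c2", 20, "c1", 10, "-", "+")
        assert len(dedup_pairs([a, b])) == 1

    def test_distinct_pairs_kept(self):
        pairs = [_pair("c1", i, "c1", i + 5) for i in range(1, 11)]
        assert len(dedup_pairs(pairs)) == 10

    def test_output_deterministic_under_shuffle(self):
        rng = np.random.default_rng(0)
        pairs = [_pair("c1", int(p), "c2", int(q))
                 for p, q in rng.integers(1, 100, size=(50, 2))]
        shuffled = list(pairs)
        rng.shuffle(shuffled)
        assert dedup_pairs(pairs) == dedup_pairs(shuffled)

    def test_injected_duplicate_rate_removed(self):
        asm = ContigSet.from_lengths([("c1", 50_000), ("c2", 50_000)])
        pairs, truth = make_hic_pairs(asm, n_pairs=2_000, cis_fraction=0.8,
                                      seed=5, duplicate_rate=0.2)
        deduped = dedup_pairs(pairs)
        # every injected duplicate disappears; a few organic collisions may too
        assert len(pairs) - len(deduped) >= truth.n_duplicate_pairs
        assert len(deduped) <= 2_000


class TestBinPairs:
    @pytest.fixture
    def asm(self):
        return ContigSet.from_lengths([("c1", 300_000), ("c2", 200_000)])

    def test_bin_arithmetic(self, asm):
        m = bin_pairs([_pair("c1", 50_000, "c1", 150_000)], asm, bin_bp=100_000)
        assert m.counts[0, 1] == 1 and m.counts[1, 0] == 1

    def test_empty_pairs_zero_matrix(self, asm):
        m = bin_pairs([], asm, bin_bp=100_000)
        assert m.counts.sum() == 0 and len(m.bins) == 5

    def test_diagonal_conservation(self, asm):
        pairs = [_pair("c1", 10, "c1", 20)] * 10
        m = bin_pairs(pairs, asm, bin_bp=100_000)
        assert m.counts[0, 0] == 10 and m.n_pairs == 10

    def test_bins_tile_assembly(self, asm):
        m = bin_pairs([], asm, bin_bp=100_000)
        assert sum(e - s for _, s, e in m.bins) == asm.total_length

    def test_unknown_chromosome_raises(self, asm):
        with pytest.raises(ConsistencyError):
            bin_pairs([_pair("cX", 1, "c1", 1)], asm, 100_000)

    def test_position_beyond_end_raises(self, asm):
        with pytest.raises(ConsistencyError):
            bin_pairs([_pair("c1", 300_001, "c1", 1)], asm, 100_000)

    def test_symmetry_and_conservation_random(self, asm):
        pairs, _ = make_hic_pairs(asm, n_pairs=3_000, cis_fraction=0.7, seed=8)
        m = bin_pairs(pairs, asm, bin_bp=50_000)
        assert np.array_equal(m.counts, m.counts.T)
        assert m.n_pairs == len(pairs)


class TestLogIntensity:
    def test_values(self):
        asm = ContigSet.from_lengths([("c1", 200_000)])
        m = bin_pairs([_pair("c1", 1, "c1", 150_000)], asm, bin_bp=100_000)
        log_intensity(m)
        assert m.transformed[0, 0] == 0.0                       # ln(1+0)
        assert m.transformed[0, 1] == pytest.approx(math.log(2))  # ln(1+1)

    def test_monotone_in_counts(self):
        asm = ContigSet.from_lengths([("c1", 200_000)])
        pairs = [_pair("c1", 1, "c1", 150_000)] * 3 + [_pair("c1", 1, "c1", 2)]
        m = log_intensity(bin_pairs(pairs, asm, bin_bp=100_000))
        assert m.transformed[0, 1] > m.transformed[0, 0] > 0


class TestCisTrans:
    def test_all_cis(self):
        asm = ContigSet.from_lengths([("c1", 100_000), ("c2", 100_000)])
        m = bin_pairs([_pair("c1", 1, "c1", 2)] * 5, asm, 100_000)
        frac, per_chrom = cis_trans_summary(m)
        assert frac == 1.0 and per_chrom == {"c1": 5, "c2": 0}

    def test_single_trans_pair(self):
        asm = ContigSet.from_lengths([("c1", 100_000), ("c2", 100_000)])
        m = bin_pairs([_pair("c1", 1, "c2", 1)], asm, 100_000)
        assert cis_trans_summary(m)[0] == 0.0

    def test_recovers_generator_cis_fraction(self):
        asm = ContigSet.from_lengths([("c1", 500_000), ("c2", 500_000),
                                      ("c3", 500_000)])
        n, p = 10_000, 0.9
        pairs, _ = make_hic_pairs(asm, n_pairs=n, cis_fraction=p, seed=13)
        m = bin_pairs(pairs, asm, bin_bp=100_000)
        frac, _ = cis_trans_summary(m)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= 3 * se

    def test_block_diagonal_enrichment(self):
        # planted cis excess shows as a hotter block diagonal than
        # off-diagonal space in the log heatmap
        asm = ContigSet.from_lengths([("c1", 500_000), ("c2", 500_000)])
        pairs, _ = make_hic_pairs(asm, n_pairs=8_000, cis_fraction=0.9, seed=21)
        m = log_intensity(bin_pairs(pairs, asm, bin_bp=100_000))
        chroms = np.array([b[0] for b in m.bins])
        same = chroms[:, None] == chroms[None, :]
        assert m.transformed[same].mean() > m.transformed[~same].mean()
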