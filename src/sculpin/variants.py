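"""Single-base accuracy estimation from short-read variant calls.

Homozygous-ALT calls against the assembly are treated as consensus
errors: a hom-alt SNP marks a wrong base, a hom-alt indel a wrong
insertion/deletion event.  Heterozygous calls are read as plausible true
heterozygosity of the diploid individual and excluded.  Accuracy is
100% minus the SNP and indel error percentages of the assembly length.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .io_formats import Genotype, Params, VariantRecord

__all__ = ["VariantClass", "AccuracyReport", "classify_variant", "accuracy_report"]


class VariantClass(str, Enum):
    snp = "snp"
    indel = "indel"
    other = "other"


def classify_variant(v: VariantRecord) -> VariantClass:
    """SNP iff both alleles are single bases; indel iff lengths differ;
    equal-length multi-base substitutions (MNPs) are `other`."""
    if len(v.ref) == 1 and len(v.alt) == 1:
        return VariantClass.snp
    if len(v.ref) != len(v.alt):
        return VariantClass.indel
    return VariantClass.other


@dataclass
class AccuracyReport:
    """Error-proxy variant counts and the derived accuracy percentage.

    Percentages are kept at full precision; `rounded()` applies the
    presentation precision (6 decimals for error percentages, 4 for
    accuracy).  accuracy_pct + snp_pct + indel_pct == 100 exactly.
    """

    n_hom_snp: int
    n_hom_indel: int
    genome_len: int

    @property
    def snp_pct(self) -> float:
        return 100.0 * self.n_hom_snp / self.genome_len

    @property
    def indel_pct(self) -> float:
        return 100.0 * self.n_hom_indel / self.genome_len

    @property
    def accuracy_pct(self) -> float:
        return 100.0 - self.snp_pct - self.indel_pct

    def rounded(self) -> dict[str, float]:
        return {
            "snp_pct": round(self.snp_pct, 6),
            "indel_pct": round(self.indel_pct, 6),
            "accuracy_pct": round(self.accuracy_pct, 4),
        }

    def to_dict(self) -> dict:
        return {
            "n_hom_snp": self.n_hom_snp,
            "n_hom_indel": self.n_hom_indel,
            "genome_len": self.genome_len,
            **self.rounded(),
        }


def accuracy_report(
    variants: Iterable[VariantRecord],
    genome_len: int,
    params: Params | None = None,
    *,
    hom_only_indels: bool = True,
) -> AccuracyReport:
    """Count error-proxy variants and estimate single-base accuracy.

    Only homozygous-ALT records with depth >= params.min_variant_depth
    count.  Indels are counted as events, not affected bases.  Setting
    hom_only_indels=False relaxes the genotype requirement for indels
    (SNPs always require hom-alt).
    """
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    params = params or Params()
    n_snp = n_indel = 0
    for v in variants:
        if v.depth < params.min_variant_depth:
            continue
        cls = classify_variant(v)
        if cls is VariantClass.snp:
            if v.genotype is Genotype.hom_alt:
                n_snp += 1
        elif cls is VariantClass.indel:
            if v.genotype is Genotype.hom_alt or not hom_only_indels:
                n_indel += 1
    return AccuracyReport(n_hom_snp=n_snp, n_hom_indel=n_indel, genome_len=genome_len)
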