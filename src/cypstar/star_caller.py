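"""Star-allele calling and metabolizer-phenotype translation.

Given phased diploid genotypes over the CYP2C19 region, each chromosome copy
(haplotype) is matched against the allele-definition table by *exact set
equality* over table-defining variants: the haplotype's intersection with the
table's variants must equal the defining set of exactly one allele. An empty
intersection yields the reference allele; anything else yields the reserved
``unknown`` token. Variants outside the table never affect the call and are
reported in a side channel.

The diplotype (ordered pair of star calls) is then translated to a CYP2C19
metabolizer phenotype from the unordered pair of allele function labels,
following the PharmGKB-style diplotype-phenotype table: any unknown allele
dominates (Unknown), then any uncertain-function allele (Indeterminate), then
the function-pair map (UM/RM/NM/IM/PM and the "possible" classes).
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

from cyvcf2 import VCF

from .allele_tables import AlleleDefinitionTable, FunctionLabel, UNKNOWN_ALLELE
from .variants import GenomicRegion, VariantKey

logger = logging.getLogger(__name__)


class Phenotype(str, enum.Enum):
    """CYP2C19 metabolizer phenotype (closed vocabulary)."""

    UM = "UM"
    RM = "RM"
    NM = "NM"
    IM = "IM"
    PM = "PM"
    POSSIBLE_IM = "PossibleIM"
    POSSIBLE_PM = "PossiblePM"
    INDETERMINATE = "Indeterminate"
    UNKNOWN = "Unknown"


@dataclass(frozen=True)
class Haplotype:
    """One chromosome copy of one sample: the set of ALT variants it carries."""

    sample_id: str
    phase_index: int  # 0 or 1
    variants: FrozenSet[VariantKey]


@dataclass(frozen=True)
class StarCall:
    """Result of matching one haplotype against the allele table."""

    allele: str  # star-allele name or UNKNOWN_ALLELE
    matched_variants: FrozenSet[VariantKey]
    extra_table_variants: FrozenSet[VariantKey]


@dataclass(frozen=True)
class Diplotype:
    sample_id: str
    calls: Tuple[StarCall, StarCall]

    @property
    def alleles(self) -> Tuple[str, str]:
        return (self.calls[0].allele, self.calls[1].allele)

    def __str__(self) -> str:
        return f"{self.alleles[0]}|{self.alleles[1]}"


@dataclass
class CohortSummary:
    """Per-phenotype counts and percentages (100·count/total, 2 decimals)."""

    counts: Dict[Phenotype, int]
    total: int

    @property
    def percentages(self) -> Dict[Phenotype, float]:
        return {p: round(100.0 * c / self.total, 2) for p, c in self.counts.items()}


# ---------------------------------------------------------------------------
# VCF input


def read_phased_vcf(
    path: Union[str, Path],
    region: GenomicRegion,
    strict_missing: bool = False,
) -> Dict[str, Tuple[Haplotype, Haplotype]]:
    """Read phased genotypes in ``region`` into two Haplotypes per sample.

    A variant belongs to haplotype *k* of a sample iff the allele index at
    phase position *k* is that variant's ALT index. Multi-allelic records are
    split on read. Unphased genotypes raise ``ValueError`` naming the sample
    and site; missing genotypes are treated as reference with a warning, or
    raise when ``strict_missing`` is set.
    """
    vcf = VCF(str(path))
    samples: List[str] = list(vcf.samples)
    hap_vars: Dict[str, Tuple[set, set]] = {s: (set(), set()) for s in samples}
    if not samples:
        return {}
    for rec in vcf:
        chrom = rec.CHROM.removeprefix("chr")
        if not region.contains(chrom, rec.POS):
            continue
        genotypes = rec.genotypes  # [allele0, allele1, phased] per sample
        for alt_index, alt in enumerate(rec.ALT, start=1):
            key = VariantKey(chrom, rec.POS, rec.REF, alt, rsid=rec.ID or None)
            for s, gt in zip(samples, genotypes):
                a0, a1, phased = gt[0], gt[1], gt[-1]
                if a0 < 0 or a1 < 0:
                    if strict_missing:
                        raise ValueError(
                            f"missing genotype for sample {s} at {chrom}:{rec.POS}"
                        )
                    warnings.warn(
                        f"missing genotype for sample {s} at {chrom}:{rec.POS}; "
                        "treated as reference",
                        stacklevel=2,
                    )
                    continue
                if (a0, a1) != (0, 0) and not phased:
                    raise ValueError(
                        f"unphased genotype for sample {s} at {chrom}:{rec.POS}"
                    )
                if a0 == alt_index:
                    hap_vars[s][0].add(key)
                if a1 == alt_index:
                    hap_vars[s][1].add(key)
    return {
        s: (
            Haplotype(s, 0, frozenset(h0)),
            Haplotype(s, 1, frozenset(h1)),
        )
        for s, (h0, h1) in hap_vars.items()
    }


# ---------------------------------------------------------------------------
# Matching and translation


def match_haplotype(hap: Haplotype, table: AlleleDefinitionTable) -> StarCall:
    """Match one haplotype to a star allele by exact set equality.

    Let S be the haplotype's variants restricted to table-defining variants.
    S == the defining set of exactly one allele -> that allele; S empty -> the
    reference allele; otherwise the reserved ``unknown`` token.
    """
    table_variants = table.all_defining_variants
    s = frozenset(hap.variants) & table_variants
    if not s:
        return StarCall(table.reference_allele, frozenset(), frozenset())
    matches = [
        a for a in table.alleles
        if a.name != table.reference_allele and a.defining_variants == s
    ]
    if len(matches) == 1:
        return StarCall(matches[0].name, s, frozenset())
    return StarCall(UNKNOWN_ALLELE, frozenset(), s)


def call_diplotype(
    haps: Tuple[Haplotype, Haplotype], table: AlleleDefinitionTable
) -> Diplotype:
    h0, h1 = haps
    return Diplotype(h0.sample_id, (match_haplotype(h0, table), match_haplotype(h1, table)))


# Unordered function-pair -> phenotype map. Unknown/uncertain precedence is
# handled before this lookup.
_F = FunctionLabel
_PAIR_MAP: Dict[FrozenSet[FunctionLabel], Phenotype] = {
    frozenset({_F.INCREASED}): Phenotype.UM,
    frozenset({_F.NORMAL, _F.INCREASED}): Phenotype.RM,
    frozenset({_F.NORMAL}): Phenotype.NM,
    frozenset({_F.NO_FUNCTION, _F.NORMAL}): Phenotype.IM,
    frozenset({_F.NO_FUNCTION, _F.INCREASED}): Phenotype.IM,
    frozenset({_F.NO_FUNCTION}): Phenotype.PM,
    frozenset({_F.DECREASED, _F.NORMAL}): Phenotype.POSSIBLE_IM,
    frozenset({_F.DECREASED, _F.INCREASED}): Phenotype.POSSIBLE_IM,
    frozenset({_F.DECREASED, _F.NO_FUNCTION}): Phenotype.POSSIBLE_PM,
    frozenset({_F.DECREASED}): Phenotype.POSSIBLE_IM,
}


def phenotype_from_alleles(
    allele_a: str, allele_b: str, table: AlleleDefinitionTable
) -> Phenotype:
    """Translate an allele pair to a metabolizer phenotype (order-invariant)."""
    fa, fb = table.function_of(allele_a), table.function_of(allele_b)
    pair = {fa, fb}
    if _F.UNKNOWN in pair:
        return Phenotype.UNKNOWN
    if _F.UNCERTAIN in pair:
        return Phenotype.INDETERMINATE
    if pair == {_F.DECREASED}:
        # Not listed in the published diplotype-phenotype table; treated as
        # a possible intermediate metabolizer.
        logger.warning(
            "diplotype with two decreased-function alleles (%s/%s) assigned PossibleIM",
            allele_a, allele_b,
        )
    return _PAIR_MAP[frozenset(pair)]


def assign_phenotype(d: Diplotype, table: AlleleDefinitionTable) -> Phenotype:
    return phenotype_from_alleles(d.alleles[0], d.alleles[1], table)


def summarize_cohort(calls: Sequence[Phenotype]) -> CohortSummary:
    """Tally phenotype calls; percentages are 100·count/total to 2 decimals."""
    if not calls:
        raise ValueError("cannot summarize an empty cohort")
    counts = {p: 0 for p in Phenotype}
    for c in calls:
        counts[Phenotype(c)] += 1
    return CohortSummary(counts={p: n for p, n in counts.items()}, total=len(calls))


def call_cohort(
    vcf_path: Union[str, Path],
    table: AlleleDefinitionTable,
    region: Optional[GenomicRegion] = None,
    strict_missing: bool = False,
) -> Tuple[Dict[str, Diplotype], Dict[str, Phenotype], CohortSummary]:
    """End-to-end: phased VCF -> diplotypes -> phenotypes -> cohort summary."""
    region = region or table.region
    haps = read_phased_vcf(vcf_path, region, strict_missing=strict_missing)
    diplotypes = {s: call_diplotype(pair, table) for s, pair in haps.items()}
    phenotypes = {s: assign_phenotype(d, table) for s, d in diplotypes.items()}
    return diplotypes, phenotypes, summarize_cohort(list(phenotypes.values()))
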