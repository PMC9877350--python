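"""In-silico triage of novel missense variants.

Candidate variants for functional assay are selected from a cohort by the
following flow: variants already in the star-allele definition table and
synonymous (or other non-coding) variants are set aside; a remaining
non-synonymous variant is selected outright if any carrier sample is a
normal, rapid or ultra-rapid metabolizer (its carriers' phenotypes show the
variant co-occurs with otherwise-normal alleles), and otherwise only if it
passes a stringent three-score deleteriousness filter
(SIFT = 0 ∩ PolyPhen-2 = 1 ∩ CADD > 20, score equality at the 2-decimal
reporting precision).

Score category conventions follow the algorithms' own rubrics: SIFT < 0.05 is
damaging; PolyPhen-2 in [0, 0.2) benign, [0.2, 0.85) possibly damaging,
[0.85, 1] probably damaging; CADD (phred) > 20 deleterious (top 1%).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .allele_tables import AlleleDefinitionTable
from .star_caller import Phenotype
from .variants import VariantKey

#: Consequences counted as non-synonymous (protein-altering).
NON_SYNONYMOUS = frozenset({"missense", "stop_gained", "start_lost"})

#: |score - target| tolerance for the exact-score filter (2-decimal reporting).
SCORE_PRECISION = 0.005

SIFT_DAMAGING_BELOW = 0.05
POLYPHEN_BENIGN_BELOW = 0.2
POLYPHEN_PROBABLY_FROM = 0.85
CADD_DELETERIOUS_ABOVE = 20.0


class SiftCategory(str, enum.Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"


class PolyphenCategory(str, enum.Enum):
    BENIGN = "benign"
    POSSIBLY_DAMAGING = "possibly_damaging"
    PROBABLY_DAMAGING = "probably_damaging"


class TriageRoute(str, enum.Enum):
    IN_TABLE = "in_table"
    CARRIED_BY_NM_RM_UM = "carried_by_NM_RM_UM"
    DELETERIOUS_FILTER = "deleterious_filter"
    REJECTED = "rejected"


@dataclass(frozen=True)
class AnnotatedVariant:
    """A candidate variant with in-silico scores and cohort carriers."""

    key: VariantKey
    consequence: str
    sift: Optional[float] = None
    polyphen2: Optional[float] = None
    cadd: Optional[float] = None
    allele_frequency: float = 0.0
    carrier_haplotypes: Tuple[Tuple[str, int], ...] = ()
    in_definition_table: bool = False

    def __post_init__(self) -> None:
        for name, score in (("sift", self.sift), ("polyphen2", self.polyphen2)):
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValueError(f"{name} score {score} outside [0, 1]")
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"cadd score {self.cadd} must be >= 0")
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(f"allele frequency {self.allele_frequency} outside [0, 1]")

    @property
    def is_non_synonymous(self) -> bool:
        return self.consequence in NON_SYNONYMOUS


@dataclass(frozen=True)
class TriageDecision:
    key: VariantKey
    selected: bool
    route: TriageRoute
    cooccurrence_clean: bool


def sift_category(score: float) -> SiftCategory:
    """SIFT rubric: scores below 0.05 are damaging, else tolerated."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"SIFT score {score} outside [0, 1]")
    return SiftCategory.DAMAGING if score < SIFT_DAMAGING_BELOW else SiftCategory.TOLERATED


def polyphen_category(score: float) -> PolyphenCategory:
    """PolyPhen-2 rubric: [0,0.2) benign, [0.2,0.85) possibly, [0.85,1] probably."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"PolyPhen-2 score {score} outside [0, 1]")
    if score < POLYPHEN_BENIGN_BELOW:
        return PolyphenCategory.BENIGN
    if score < POLYPHEN_PROBABLY_FROM:
        return PolyphenCategory.POSSIBLY_DAMAGING
    return PolyphenCategory.PROBABLY_DAMAGING


def _require_scores(v: AnnotatedVariant) -> Tuple[float, float, float]:
    if v.sift is None or v.polyphen2 is None or v.cadd is None:
        raise ValueError(f"variant {v.key.label} is missing an in-silico score")
    return v.sift, v.polyphen2, v.cadd


def deleterious_filter(v: AnnotatedVariant) -> bool:
    """Stringent filter: SIFT = 0 ∩ PolyPhen-2 = 1 ∩ CADD > 20.

    Score equality is at the 2-decimal reporting precision; the CADD bound is
    strict.
    """
    sift, polyphen, cadd = _require_scores(v)
    return (
        abs(sift) < SCORE_PRECISION
        and abs(polyphen - 1.0) < SCORE_PRECISION
        and cadd > CADD_DELETERIOUS_ABOVE
    )


def consensus_damaging(v: AnnotatedVariant) -> bool:
    """All three algorithms call the variant damaging.

    SIFT damaging, PolyPhen-2 not benign, and CADD strictly above 20. Implied
    by :func:`deleterious_filter` (which is strictly stronger).
    """
    sift, polyphen, cadd = _require_scores(v)
    return (
        sift_category(sift) is SiftCategory.DAMAGING
        and polyphen_category(polyphen) is not PolyphenCategory.BENIGN
        and cadd > CADD_DELETERIOUS_ABOVE
    )


def cooccurrence_check(
    v: AnnotatedVariant, all_variants: Sequence[AnnotatedVariant]
) -> bool:
    """True iff no carrier haplotype of ``v`` carries another non-synonymous variant."""
    others_by_hap: Dict[Tuple[str, int], Set[VariantKey]] = {}
    for other in all_variants:
        if other.key == v.key or not other.is_non_synonymous:
            continue
        for hap in other.carrier_haplotypes:
            others_by_hap.setdefault(hap, set()).add(other.key)
    return not any(hap in others_by_hap for hap in v.carrier_haplotypes)


def resolve_carriers(
    variants: Sequence[AnnotatedVariant],
    haplotypes: Dict[str, Tuple],
) -> List[AnnotatedVariant]:
    """Fill each variant's carrier haplotypes from per-sample haplotype pairs
    (as returned by ``star_caller.read_phased_vcf``)."""
    from dataclasses import replace

    out: List[AnnotatedVariant] = []
    for v in variants:
        carriers = tuple(
            (sample, phase)
            for sample, pair in haplotypes.items()
            for phase in (0, 1)
            if v.key in pair[phase].variants
        )
        out.append(replace(v, carrier_haplotypes=carriers))
    return out


def select_candidates(
    variants: Sequence[AnnotatedVariant],
    table: AlleleDefinitionTable,
    phenotypes: Dict[str, Phenotype],
) -> List[TriageDecision]:
    """Run the variant-selection flow over a cohort's annotated variants.

    Synonymous/other variants and table variants are not selected (the latter
    routed ``in_table``); each remaining variant is selected via
    ``carried_by_NM_RM_UM`` if any carrier sample's phenotype is NM, RM or UM,
    else via the deleterious filter; otherwise rejected. Raises if a carrier
    sample has no phenotype.
    """
    fast = {Phenotype.NM, Phenotype.RM, Phenotype.UM}
    table_keys = table.all_defining_variants
    decisions: List[TriageDecision] = []
    for v in variants:
        clean = cooccurrence_check(v, variants)
        if v.in_definition_table or v.key in table_keys:
            decisions.append(TriageDecision(v.key, False, TriageRoute.IN_TABLE, clean))
            continue
        if not v.is_non_synonymous:
            decisions.append(TriageDecision(v.key, False, TriageRoute.REJECTED, clean))
            continue
        carrier_samples = {s for s, _ in v.carrier_haplotypes}
        missing = carrier_samples - phenotypes.keys()
        if missing:
            raise ValueError(
                f"carrier sample(s) without phenotype for {v.key.label}: {sorted(missing)}"
            )
        if any(phenotypes[s] in fast for s in carrier_samples):
            decisions.append(
                TriageDecision(v.key, True, TriageRoute.CARRIED_BY_NM_RM_UM, clean)
            )
        elif deleterious_filter(v):
            decisions.append(
                TriageDecision(v.key, True, TriageRoute.DELETERIOUS_FILTER, clean)
            )
        else:
            decisions.append(TriageDecision(v.key, False, TriageRoute.REJECTED, clean))
    return decisions
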