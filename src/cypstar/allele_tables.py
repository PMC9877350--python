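"""Star-allele definition tables.

A star allele is a named haplotype of a pharmacogene defined by a set of
variants in an allele-definition table (PharmVar-style). This module parses,
validates and writes such tables at the *core-allele* level: suballele names
(``*1.001``) are collapsed to their core allele at parse time, and each allele
carries one curated clinical function label used downstream for
diplotype-to-phenotype translation.

TSV dialect: ``allele<TAB>function<TAB><chrom:pos:ref:alt[|cdna[|rsid]]>...``
with cell values ``1`` (defining variant present) / ``0``; ``#`` comments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Union

from .variants import CYP2C19_REGION, GenomicRegion, VariantKey

#: Reserved token for a haplotype matching no defined allele.
UNKNOWN_ALLELE = "unknown"


class FunctionLabel(str, enum.Enum):
    """Curated clinical function of a star allele (closed vocabulary)."""

    INCREASED = "increased"
    NORMAL = "normal"
    DECREASED = "decreased"
    NO_FUNCTION = "no_function"
    UNCERTAIN = "uncertain"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class AlleleDefinition:
    name: str
    defining_variants: FrozenSet[VariantKey]
    function: FunctionLabel


@dataclass
class AlleleDefinitionTable:
    """Validated star-allele definition table for one gene."""

    gene: str
    region: GenomicRegion
    reference_allele: str
    alleles: List[AlleleDefinition] = field(default_factory=list)

    def validate(self) -> List[str]:
        return validate_table(self)

    def check(self) -> "AlleleDefinitionTable":
        """Raise ``ValueError`` if any invariant is violated; else return self."""
        findings = validate_table(self)
        if findings:
            raise ValueError("invalid allele definition table: " + "; ".join(findings))
        return self

    @property
    def allele_names(self) -> List[str]:
        return [a.name for a in self.alleles]

    def allele(self, name: str) -> AlleleDefinition:
        for a in self.alleles:
            if a.name == name:
                return a
        raise KeyError(f"allele {name!r} not in table")

    def function_of(self, name: str) -> FunctionLabel:
        """Function label of a star allele; the unknown token maps to UNKNOWN."""
        if name == UNKNOWN_ALLELE:
            return FunctionLabel.UNKNOWN
        return self.allele(name).function

    @property
    def all_defining_variants(self) -> FrozenSet[VariantKey]:
        out: set = set()
        for a in self.alleles:
            out |= a.defining_variants
        return frozenset(out)


def _core_allele(name: str) -> str:
    """Collapse a suballele name like ``*1.001`` to its core allele ``*1``."""
    return name.split(".")[0]


def validate_table(table: AlleleDefinitionTable) -> List[str]:
    """Check table invariants; returns one finding per violation (never raises).

    Checked: unique allele names, reference allele present with an empty
    defining set, non-empty defining sets for every other allele, no two
    alleles sharing an identical defining set, and every defining variant
    inside the configured region.
    """
    findings: List[str] = []
    names = [a.name for a in table.alleles]
    seen: set = set()
    for n in names:
        if n in seen:
            findings.append(f"duplicate allele name {n!r}")
        seen.add(n)
    if table.reference_allele not in names:
        findings.append(f"reference allele {table.reference_allele!r} not defined")
    sets_seen: Dict[FrozenSet[VariantKey], str] = {}
    for a in table.alleles:
        if a.name == table.reference_allele:
            if a.defining_variants:
                findings.append(
                    f"reference allele {a.name!r} must have no defining variants"
                )
        elif not a.defining_variants:
            findings.append(f"non-reference allele {a.name!r} has no defining variants")
        if a.defining_variants in sets_seen and a.defining_variants:
            findings.append(
                f"alleles {sets_seen[a.defining_variants]!r} and {a.name!r} "
                "share an identical defining variant set"
            )
        else:
            sets_seen[a.defining_variants] = a.name
        for v in a.defining_variants:
            if not table.region.contains(v.chrom, v.pos):
                findings.append(
                    f"variant {v.genomic_id()} of allele {a.name!r} lies outside "
                    f"region {table.region}"
                )
    return findings


def read_allele_definition_table(
    path: Union[str, Path],
    gene: str = "CYP2C19",
    region: GenomicRegion = CYP2C19_REGION,
    reference_allele: str = "*1",
) -> AlleleDefinitionTable:
    """Read a PharmVar-style allele-definition TSV.

    One row per star allele; the header names one variant per column by
    genomic key (``chrom:pos:ref:alt``) with optional ``|cdna|rsid`` labels.
    Suballeles are collapsed to core alleles. Raises ``ValueError`` on
    duplicate allele names, out-of-region variants, or unparseable cells.
    """
    path = Path(path)
    lines = [
        ln.rstrip("\n")
        for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty allele definition table")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "allele" or header[1] != "function":
        raise ValueError(f"{path}: header must start with 'allele<TAB>function'")
    variant_cols: List[VariantKey] = []
    for j, cell in enumerate(header[2:], start=3):
        try:
            key = VariantKey.parse(cell)
        except ValueError as exc:
            raise ValueError(f"{path}: header column {j}: {exc}") from exc
        if not region.contains(key.chrom, key.pos):
            raise ValueError(
                f"{path}: variant {key.genomic_id()} (column {j}) outside region {region}"
            )
        variant_cols.append(key)

    alleles: List[AlleleDefinition] = []
    seen_names: set = set()
    for i, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ValueError(f"{path}: row {i}: expected {len(header)} cells, got {len(cells)}")
        name = _core_allele(cells[0].strip())
        if name in seen_names:
            raise ValueError(f"{path}: row {i}: duplicate allele name {name!r}")
        seen_names.add(name)
        try:
            func = FunctionLabel(cells[1].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: unknown function label {cells[1]!r}") from exc
        variants: set = set()
        for j, cell in enumerate(cells[2:]):
            flag = cell.strip()
            if flag == "1":
                variants.add(variant_cols[j])
            elif flag != "0":
                raise ValueError(
                    f"{path}: row {i}, column {j + 3}: cell must be 0 or 1, got {flag!r}"
                )
        alleles.append(AlleleDefinition(name, frozenset(variants), func))

    return AlleleDefinitionTable(
        gene=gene, region=region, reference_allele=reference_allele, alleles=alleles
    ).check()


def write_allele_definition_table(
    table: AlleleDefinitionTable, path: Union[str, Path]
) -> None:
    """Write a table in the same TSV dialect ``read_allele_definition_table`` reads.

    Round-trip safe: reading the written file reproduces the table
    field-for-field (variant column order is sorted by position).
    """
    cols = sorted(table.all_defining_variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))

    def colname(v: VariantKey) -> str:
        name = v.genomic_id()
        if v.cdna_label or v.rsid:
            name += "|" + (v.cdna_label or "")
        if v.rsid:
            name += "|" + v.rsid
        return name

    lines = ["\t".join(["allele", "function"] + [colname(v) for v in cols])]
    for a in table.alleles:
        flags = ["1" if v in a.defining_variants else "0" for v in cols]
        lines.append("\t".join([a.name, a.function.value] + flags))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
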