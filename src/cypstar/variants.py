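"""Genomic variant keys and region handling.

A :class:`VariantKey` identifies one biallelic SNV by genomic coordinates
(GRCh37, 1-based). Transcript-level (cDNA) labels and rsIDs are carried as
annotations only; equality and hashing use the genomic key alone, so that
haplotype matching is unambiguous at the genomic level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based inclusive genomic interval, e.g. the CYP2C19 gene region."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "GenomicRegion":
        """Parse a ``chrom:start-end`` region string."""
        try:
            chrom, span = text.split(":")
            start, end = span.split("-")
            return cls(chrom, int(start), int(end))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"malformed region string {text!r}") from exc


#: Default CYP2C19 gene region (GRCh37).
CYP2C19_REGION = GenomicRegion("10", 96522438, 96615304)


@dataclass(frozen=True)
class VariantKey:
    """One biallelic SNV; equality is by (chrom, pos, ref, alt) only."""

    chrom: str
    pos: int  # 1-based, GRCh37
    ref: str
    alt: str
    cdna_label: Optional[str] = field(default=None, compare=False)
    rsid: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def label(self) -> str:
        """Human-readable name: cDNA label if present, else genomic key."""
        return self.cdna_label or f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def genomic_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        """Parse ``chrom:pos:ref:alt`` with optional ``|cdna|rsid`` suffixes."""
        parts = text.split("|")
        fields = parts[0].split(":")
        if len(fields) != 4:
            raise ValueError(f"cannot parse variant key {text!r}")
        chrom, pos, ref, alt = fields
        try:
            ipos = int(pos)
        except ValueError as exc:
            raise ValueError(f"unparseable coordinate in {text!r}") from exc
        cdna = parts[1] if len(parts) > 1 and parts[1] else None
        rsid = parts[2] if len(parts) > 2 and parts[2] else None
        return cls(chrom, ipos, ref, alt, cdna_label=cdna, rsid=rsid)
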