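"""Loaders for the packaged in-paper reference tables.

Three small TSVs ship with the package: the CYP2C19 core star-allele
definition table (with function labels), the diplotype-to-phenotype map with
published cohort counts (1000 Genomes phase III, 2,504 subjects), the
in-silico annotations of the 28 assayed variants, and the functional-assay
summary per enzyme preparation. Genomic coordinates in the variant tables are
synthetic placeholders within the gene region (the published tables name
variants at the cDNA level only).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .allele_tables import AlleleDefinitionTable, read_allele_definition_table
from .assay import MEPHENYTOIN, OMEPRAZOLE, EnzymePrep, SubstrateResult
from .star_caller import Phenotype
from .triage import AnnotatedVariant
from .variants import VariantKey


def _data_path(name: str) -> Path:
    return Path(resources.files("cypstar") / "data" / name)


def load_allele_table() -> AlleleDefinitionTable:
    """The packaged CYP2C19 core star-allele definition table (reference *1)."""
    return read_allele_definition_table(_data_path("allele_definitions.tsv"))


@dataclass(frozen=True)
class DiplotypePhenotypeRow:
    phenotype: Phenotype
    count: int
    diplotypes: Tuple[Tuple[str, str], ...]  # allele pairs, "unk" -> "unknown"


def load_diplotype_phenotype_table() -> List[DiplotypePhenotypeRow]:
    """The published diplotype-phenotype map with per-phenotype cohort counts."""
    df = pd.read_csv(_data_path("diplotype_phenotypes.tsv"), sep="\t", comment="#")
    rows: List[DiplotypePhenotypeRow] = []
    for _, rec in df.iterrows():
        pairs = []
        for pattern in str(rec["diplotypes"]).split(","):
            a, b = pattern.strip().split("|")
            pairs.append(
                tuple("unknown" if x == "unk" else x for x in (a, b))
            )
        rows.append(
            DiplotypePhenotypeRow(
                phenotype=Phenotype(rec["phenotype"]),
                count=int(rec["count"]),
                diplotypes=tuple(pairs),
            )
        )
    return rows


def load_variant_annotations(path: Optional[Path] = None) -> List[AnnotatedVariant]:
    """In-silico annotations (SIFT, PolyPhen-2, CADD, AF); defaults to the
    packaged table of the 28 assayed variants."""
    df = pd.read_csv(
        path or _data_path("variant_annotations.tsv"), sep="\t", comment="#",
        dtype={"chrom": str}, na_values=["NA"],
    )
    out: List[AnnotatedVariant] = []
    for _, rec in df.iterrows():
        key = VariantKey(
            chrom=rec["chrom"], pos=int(rec["pos"]), ref=rec["ref"], alt=rec["alt"],
            cdna_label=rec["cdna"], rsid=rec["rsid"],
        )
        out.append(
            AnnotatedVariant(
                key=key,
                consequence=rec["consequence"],
                sift=None if pd.isna(rec["sift"]) else float(rec["sift"]),
                polyphen2=None if pd.isna(rec["polyphen2"]) else float(rec["polyphen2"]),
                cadd=None if pd.isna(rec["cadd"]) else float(rec["cadd"]),
                allele_frequency=float(rec["af"]),
                in_definition_table=bool(int(rec["in_table"])),
            )
        )
    return out


def _opt(value) -> Optional[float]:
    if pd.isna(value) or value in ("ND", "NA"):
        return None
    return float(value)


def load_assay_table(path: Optional[Path] = None) -> List[EnzymePrep]:
    """The functional-assay summary table (one EnzymePrep per row, incl. WT)."""
    df = pd.read_csv(
        path or _data_path("assay_results.tsv"), sep="\t", comment="#",
        dtype=str,
    )
    preps: List[EnzymePrep] = []
    for _, rec in df.iterrows():
        n = int(rec["n"])
        results = {}
        for sub, mcol, scol in (
            (MEPHENYTOIN, "meph_mean", "meph_sd"),
            (OMEPRAZOLE, "omep_mean", "omep_sd"),
        ):
            results[sub] = SubstrateResult(
                substrate=sub, mean_rate=_opt(rec[mcol]), sd_rate=_opt(rec[scol]), n=n
            )
        preps.append(
            EnzymePrep(
                variant_label=rec["variant"],
                star_allele=None if rec["star_allele"] == "NA" else rec["star_allele"],
                expression_detected=bool(int(rec["expression_detected"])),
                spectral_content=_opt(rec["specific_content"]),
                results=results,
                printed_pct_wt={
                    MEPHENYTOIN: _opt(rec["pct_wt_meph"]),
                    OMEPRAZOLE: _opt(rec["pct_wt_omep"]),
                },
                novel=bool(int(rec["novel"])),
            )
        )
    return preps
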