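"""Synthetic cohort and assay generator.

Emulates the statistical structure of the real inputs so that every pipeline
stage is testable without any download:

* phased diplotypes: each of a sample's two haplotypes is drawn independently
  from the configured star-allele frequencies (Hardy-Weinberg at the
  haplotype level) and emitted as phased ALT alleles in a standard VCF;
* novel missense variants: injected per haplotype with a configured Bernoulli
  probability, carrying configured SIFT/PolyPhen-2/CADD scores, onto
  haplotypes that otherwise match a defined allele;
* assay triplicates: replicate formation rates drawn from a normal
  distribution centered at a planted multiple of the wild-type mean with
  SD = CV x mean, truncated at zero, summarized as mean +/- SD.

All randomness comes from one ``numpy.random.default_rng`` stream seeded from
the config, so outputs are byte-identical across runs with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam

from .allele_tables import AlleleDefinitionTable
from .assay import SUBSTRATES, SubstrateResult
from .star_caller import Phenotype, phenotype_from_alleles
from .triage import AnnotatedVariant
from .variants import VariantKey

GRCH37_CHR10_LENGTH = 135_534_747


@dataclass(frozen=True)
class NovelVariantSpec:
    """A variant to inject into the cohort, with its annotation scores."""

    key: VariantKey
    consequence: str = "missense"
    sift: Optional[float] = None
    polyphen2: Optional[float] = None
    cadd: Optional[float] = None
    injection_prob: float = 0.01  # per haplotype

    def __post_init__(self) -> None:
        if not 0.0 <= self.injection_prob <= 1.0:
            raise ValueError(f"injection probability {self.injection_prob} outside [0, 1]")


@dataclass(frozen=True)
class AssaySpec:
    """Planted assay truth for one variant: %WT per substrate plus noise CV."""

    variant_label: str
    true_pct_wt: Dict[str, float]
    cv: float = 0.05

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("coefficient of variation must be >= 0")


@dataclass
class SimulationConfig:
    n_samples: int
    allele_frequencies: Dict[str, float]
    novel_variant_specs: List[NovelVariantSpec] = field(default_factory=list)
    assay_specs: List[AssaySpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        for allele, f in self.allele_frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency of {allele} outside [0, 1]: {f}")
        total = sum(self.allele_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies sum to {total}, not 1")


@dataclass
class Cohort:
    """A simulated cohort plus its generation truth."""

    config: SimulationConfig
    table: AlleleDefinitionTable
    sample_ids: List[str]
    hap_alleles: List[Tuple[str, str]]  # planted star allele per haplotype
    novel_carriers: Dict[VariantKey, List[Tuple[str, int]]]

    def haplotype_variants(self, sample_index: int, phase: int) -> frozenset:
        """All ALT variants on one haplotype (allele-defining + injected)."""
        allele = self.hap_alleles[sample_index][phase]
        variants = set(self.table.allele(allele).defining_variants)
        sid = self.sample_ids[sample_index]
        for key, carriers in self.novel_carriers.items():
            if (sid, phase) in carriers:
                variants.add(key)
        return frozenset(variants)

    def truth_table(self) -> pd.DataFrame:
        """Per-sample planted diplotype and derived phenotype."""
        rows = []
        for i, sid in enumerate(self.sample_ids):
            a, b = self.hap_alleles[i]
            rows.append(
                {
                    "sample": sid,
                    "hap1_allele": a,
                    "hap2_allele": b,
                    "diplotype": f"{a}|{b}",
                    "phenotype": phenotype_from_alleles(a, b, self.table).value,
                }
            )
        return pd.DataFrame(rows, columns=["sample", "hap1_allele", "hap2_allele",
                                           "diplotype", "phenotype"])

    def phenotypes(self) -> Dict[str, Phenotype]:
        return {
            sid: phenotype_from_alleles(a, b, self.table)
            for sid, (a, b) in zip(self.sample_ids, self.hap_alleles)
        }

    def annotated_variants(self) -> List[AnnotatedVariant]:
        """Novel-variant annotations with carriers resolved, plus table variants."""
        n_haps = max(2 * len(self.sample_ids), 1)
        out: List[AnnotatedVariant] = []
        for spec in self.config.novel_variant_specs:
            carriers = tuple(self.novel_carriers.get(spec.key, []))
            out.append(
                AnnotatedVariant(
                    key=spec.key,
                    consequence=spec.consequence,
                    sift=spec.sift,
                    polyphen2=spec.polyphen2,
                    cadd=spec.cadd,
                    allele_frequency=len(carriers) / n_haps,
                    carrier_haplotypes=carriers,
                    in_definition_table=False,
                )
            )
        for key in sorted(self.table.all_defining_variants, key=lambda v: v.pos):
            carriers = []
            for i, sid in enumerate(self.sample_ids):
                for phase in (0, 1):
                    if key in self.table.allele(self.hap_alleles[i][phase]).defining_variants:
                        carriers.append((sid, phase))
            out.append(
                AnnotatedVariant(
                    key=key,
                    consequence="missense",
                    allele_frequency=len(carriers) / n_haps,
                    carrier_haplotypes=tuple(carriers),
                    in_definition_table=True,
                )
            )
        return out


def simulate_cohort(
    cfg: SimulationConfig, table: Optional[AlleleDefinitionTable] = None
) -> Cohort:
    """Draw a phased cohort from star-allele frequencies (deterministic per seed)."""
    if table is None:
        from .fixtures import load_allele_table

        table = load_allele_table()
    rng = np.random.default_rng(cfg.seed)
    alleles = sorted(cfg.allele_frequencies)
    probs = np.asarray([cfg.allele_frequencies[a] for a in alleles], dtype=float)
    probs = probs / probs.sum()
    for a in alleles:
        table.allele(a)  # raises KeyError for undefined alleles

    sample_ids = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    draws = rng.choice(len(alleles), size=(cfg.n_samples, 2), p=probs)
    hap_alleles = [(alleles[i], alleles[j]) for i, j in draws]

    novel_carriers: Dict[VariantKey, List[Tuple[str, int]]] = {}
    for spec in cfg.novel_variant_specs:
        hits = rng.random((cfg.n_samples, 2)) < spec.injection_prob
        novel_carriers[spec.key] = [
            (sample_ids[i], k)
            for i in range(cfg.n_samples)
            for k in (0, 1)
            if hits[i, k]
        ]
    return Cohort(cfg, table, sample_ids, hap_alleles, novel_carriers)


def simulate_assay(
    true_pct_wt: float,
    wt_mean: float,
    cv: float,
    n: int,
    rng: Union[int, np.random.Generator],
    substrate: str = SUBSTRATES[0],
) -> SubstrateResult:
    """Draw ``n`` replicate formation rates and return their summary.

    Replicates are normal around ``wt_mean * true_pct_wt / 100`` with
    SD = ``cv`` times that center, truncated at 0. ``cv=0`` returns the
    planted value exactly with SD 0.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n < 2:
        raise ValueError("need n >= 2 replicates")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    center = wt_mean * true_pct_wt / 100.0
    draws = np.clip(rng.normal(center, cv * center, size=n), 0.0, None)
    return SubstrateResult(
        substrate=substrate,
        mean_rate=float(np.mean(draws)),
        sd_rate=float(np.std(draws, ddof=1)),
        n=n,
    )


# ---------------------------------------------------------------------------
# Output writers


def write_vcf(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write the cohort as a standard phased VCF (one record per SNV site)."""
    sites = sorted(
        set(cohort.table.all_defining_variants)
        | {s.key for s in cohort.config.novel_variant_specs},
        key=lambda v: (v.chrom, v.pos, v.ref, v.alt),
    )
    header = pysam.VariantHeader()
    header.add_meta("source", "cypstar-simulate")
    header.contigs.add("10", length=GRCH37_CHR10_LENGTH)
    header.formats.add("GT", 1, "String", "Genotype")
    for sid in cohort.sample_ids:
        header.add_sample(sid)

    hap_sets = [
        (cohort.haplotype_variants(i, 0), cohort.haplotype_variants(i, 1))
        for i in range(len(cohort.sample_ids))
    ]
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sites:
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=(site.ref, site.alt),
                id=site.rsid,
            )
            for i, sid in enumerate(cohort.sample_ids):
                h0, h1 = hap_sets[i]
                rec.samples[sid]["GT"] = (int(site in h0), int(site in h1))
                rec.samples[sid].phased = True
            out.write(rec)


def write_truth_table(cohort: Cohort, path: Union[str, Path]) -> None:
    cohort.truth_table().to_csv(path, sep="\t", index=False)


def write_annotation_table(cohort: Cohort, path: Union[str, Path]) -> None:
    """Annotation TSV readable by the triage CLI (novel + table variants)."""
    rows = []
    for v in cohort.annotated_variants():
        rows.append(
            {
                "chrom": v.key.chrom,
                "pos": v.key.pos,
                "ref": v.key.ref,
                "alt": v.key.alt,
                "cdna": v.key.cdna_label or "NA",
                "rsid": v.key.rsid or "NA",
                "consequence": v.consequence,
                "sift": "NA" if v.sift is None else v.sift,
                "polyphen2": "NA" if v.polyphen2 is None else v.polyphen2,
                "cadd": "NA" if v.cadd is None else v.cadd,
                "af": v.allele_frequency,
                "acmg": "NA",
                "in_table": int(v.in_definition_table),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_assay_table(
    cohort: Cohort,
    path: Union[str, Path],
    wt_means: Optional[Dict[str, float]] = None,
    n: int = 3,
) -> None:
    """Simulate triplicate assays for the configured specs and write the TSV
    in the same dialect as the packaged assay fixture (includes a WT row)."""
    wt_means = wt_means or {SUBSTRATES[0]: 0.23, SUBSTRATES[1]: 4.23}
    rng = np.random.default_rng(cohort.config.seed + 1)
    rows = []
    specs = list(cohort.config.assay_specs) + [
        AssaySpec("WT", {s: 100.0 for s in SUBSTRATES}, cv=0.02)
    ]
    for spec in specs:
        row: Dict[str, object] = {
            "variant": spec.variant_label,
            "star_allele": "NA" if spec.variant_label != "WT" else "*1",
            "expression_detected": 1,
            "specific_content": round(float(rng.uniform(25.0, 430.0)), 1),
        }
        for sub, mcol, scol, pcol in (
            (SUBSTRATES[0], "meph_mean", "meph_sd", "pct_wt_meph"),
            (SUBSTRATES[1], "omep_mean", "omep_sd", "pct_wt_omep"),
        ):
            res = simulate_assay(spec.true_pct_wt[sub], wt_means[sub], spec.cv, n, rng, sub)
            row[mcol] = round(res.mean_rate, 4)
            row[scol] = round(res.sd_rate, 4)
            row[pcol] = "NA"
        row["n"] = n
        row["novel"] = int(spec.variant_label != "WT")
        rows.append(row)
    cols = ["variant", "star_allele", "expression_detected", "specific_content",
            "meph_mean", "meph_sd", "omep_mean", "omep_sd", "n",
            "pct_wt_meph", "pct_wt_omep", "novel"]
    pd.DataFrame(rows)[cols].to_csv(path, sep="\t", index=False)
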