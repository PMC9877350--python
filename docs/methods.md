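# Methods

## Star-allele model

A star allele is modeled as a named set of defining SNVs inside the
*CYP2C19* gene region (chr10:96522438–96615304, GRCh37, 1-based inclusive).
Matching is by **exact set equality** over table-defining variants: the
haplotype's intersection with the union of all defining variants must equal
one allele's defining set. The alternatives — maximal-subset or scored
matching — would silently promote partial haplotypes to named alleles;
exact matching instead yields an explicit `unknown` class, which the
diplotype–phenotype table propagates. Consequences of the model:

* variants not in the definition table never influence the call (they are
  reported in a side channel and consumed by the triage stage instead);
* a haplotype carrying the defining variants of two different alleles is
  `unknown`, not a best-effort compromise;
* suballele names (`*1.001`) are collapsed to their core allele at parse
  time; the pipeline operates at core-allele resolution throughout.

Coordinates are genomic, 1-based, GRCh37, matching VCF convention. cDNA
labels and rsIDs are annotations only — equality and hashing of a
`VariantKey` use (chrom, pos, ref, alt). The reference allele defaults to
`*1` (configurable, since curation bodies have at times designated other
ancestral haplotypes).

Phase is taken as given: the caller consumes phased GT fields (`|`) and
rejects unphased heterozygotes rather than guessing. Missing genotypes
default to reference with a warning; `strict_missing` turns this into an
error.

### Phenotype translation

Each allele carries one clinical function label (increased / normal /
decreased / no function / uncertain; the `unknown` allele token maps to an
unknown label). Translation works on the **unordered** pair of labels with
the precedence: any unknown → Unknown; else any uncertain → Indeterminate;
else a fixed pair map — {increased, increased} UM; {normal, increased} RM;
{normal, normal} NM; {no function, normal|increased} IM; {no function, no
function} PM; {decreased, normal|increased} possible IM; {decreased, no
function} possible PM. The pair {decreased, decreased} is not covered by the
published map; we assign possible IM and log a warning. Symmetry in allele
order is enforced by construction and tested exhaustively over all allele
pairs.

Cohort summaries report per-phenotype counts and percentages
(100·count/total, rounded to 2 decimals). The packaged diplotype–phenotype
fixture also records published per-phenotype cohort counts; two of its
narrative restatements disagree with the table at the second decimal, and
the fixture carries the table values.

## Variant triage

The selection flow mirrors how assay candidates are chosen from a
population cohort:

1. variants present in the allele-definition table are routed `in_table`
   (characterized via the star-allele system, not as novel variants);
2. synonymous and non-protein-altering variants are dropped;
3. a remaining variant is selected if **any carrier sample is NM, RM or
   UM** — such carriage implies the variant sits on an otherwise-normal
   haplotype, so an activity change is attributable to it;
4. otherwise it must pass the stringent score filter
   **SIFT = 0 ∩ PolyPhen-2 = 1 ∩ CADD > 20**.

Score equality in the filter uses the 2-decimal reporting precision of the
score tables (|SIFT| < 0.005, |PolyPhen-2 − 1| < 0.005): the filter is
defined over reported scores, and bitwise equality over unreported raw
scores would be meaningless. The CADD bound is strict (> 20) in both the
filter and the three-algorithm consensus predicate (SIFT damaging ∧
PolyPhen-2 not benign ∧ CADD > 20); the filter provably implies the
consensus, which the property tests check over random score triples.

Each decision also carries a co-occurrence flag: clean iff no carrier
haplotype of the variant carries another non-synonymous variant (synonymous
co-residents are ignored; the other haplotype of the same sample does not
count).

Scores are consumed as annotations; no SIFT/PolyPhen-2/CADD computation and
no transcript model is embedded.

## Assay analysis

**Spectral quantitation.** Functional P450 from the CO-difference spectrum:
(ΔA450 − ΔA490)/0.091 = nmol P450/mL (the 0.091 divisor is the standard
91 mM⁻¹ cm⁻¹ extinction coefficient of the reduced CO complex); specific
content = that value divided by total protein (mg/mL). Below-baseline
readings are returned as negative values for the caller to treat as
not-detected rather than silently clamped.

**Quantifiability.** A preparation is quantifiable iff immunoblot
expression is detected *and* spectral P450 content is detected. A
non-quantifiable preparation has no %WT values and is classified altered
outright. A quantifiable preparation whose metabolite is below the
quantification limit maps to %WT = 0 (decreased band): the enzyme is
present but effectively inactive for that substrate.

**%WT and bands.** %WT = 100·(variant mean rate)/(WT mean rate). Published
%WT columns derive from unrounded means, so when the input table carries
them they are used for banding and differences; recomputation from rounded
rates is the fallback (and is used for the %WT spot checks against raw
means). Bands: decreased < 50, normal range 50–150 (boundaries inclusive —
the rubric's verbal definitions conflict at exactly 150, and we resolve
both boundaries into the normal range), increased > 150. A variant is
**altered** iff its preparation is not quantifiable or any substrate band
is outside the normal range; it is **discordant** iff both substrates are
quantifiable and their bands differ. The cross-substrate capability
difference is |%WT(mephenytoin) − %WT(omeprazole)| in percentage points,
reported when both sides are defined, with > 25 pp flagged.

**Welch t-test from summary statistics.** t = (m₁ − m₂)/√(s₁²/n₁ + s₂²/n₂)
with fractional Welch–Satterthwaite degrees of freedom and a two-sided p
from the t distribution (the unequal-variance test is the default of
standard statistical software). The cross-substrate comparison is made on
the %WT scale with each arm's SD rescaled by its wild-type mean and without
propagating wild-type uncertainty — the simplest defensible reading for
summary data; the resulting p-values are reported but the altered call
rests on the band rubric alone. Degenerate zero-variance inputs yield
t = 0, p = 1 when means agree and p = 0 (flagged) when they differ, n ≥ 2
per arm is required, and triplicates (n = 3) are the default design.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes:

* **Diplotypes:** each sample's two haplotypes are i.i.d. draws from the
  configured star-allele frequencies — Hardy–Weinberg equilibrium at the
  haplotype level. Phenotype shares therefore follow the closed-form
  multinomial expectation, which the calibration test checks at n = 2000
  within 3 Monte-Carlo standard errors.
* **Novel variants:** injected per haplotype with a Bernoulli probability
  onto haplotypes that otherwise match a defined allele, carrying
  configured annotation scores, so triage-recovery tests have exact truth.
* **Assay replicates:** n replicates drawn from a normal distribution
  centered at a planted multiple of the wild-type mean with SD = CV·mean,
  truncated at 0 (normal, not lognormal, matching mean ± SD reporting; the
  truncation bias is negligible at the CVs used, which the unbiasedness
  test confirms). `simulate_assay` takes the planted %WT directly rather
  than a band token, since a band alone does not pin the center of the
  replicate distribution.

One `numpy.random.default_rng` stream per run, seeded from the config:
outputs are byte-identical across runs with the same seed (the determinism
contract is per generator family; cross-language reproducibility is
statistical, not bitwise). Defaults: injection probability 0.01 per
haplotype (a handful of carriers in a ~100-sample cohort, the regime novel
pharmacogene variants occupy), CV 0.05 (typical replicate scatter for
LC-MS/MS formation-rate assays), n = 3 replicates.

What the generator does **not** emulate: linkage structure beyond
whole-haplotype sampling, indels and structural variants, population
stratification, genotyping or phasing error, and assay batch effects.
Passing recovery tests therefore show correctness of the calling and
classification logic under the model's assumptions, not robustness to real
data pathologies (e.g. phasing switch errors would propagate directly into
calls).

## Problem sizes and runtime

The reference-table computations are desk-scale (29 preparations, 28
variants, a 2,504-subject count table) and run in well under a second. The
Monte-Carlo checks use 2,000-sample cohorts for Hardy–Weinberg convergence,
1,000 draws for band recovery and unbiasedness, and 2,000 paired draws for
the Welch type-I-error check (binomial 99% CI around 0.05); the full suite
runs in a few seconds. The acceptance script's synthetic round trip uses
500 samples.

## Known limitations

* Core-allele resolution only: no suballeles, CNVs, hybrid alleles, indels,
  or multi-row structural definitions.
* No statistical phasing — phased input is a precondition.
* The deleterious filter operates on reported (rounded) scores; variants
  whose true SIFT is nonzero but prints as .00 are indistinguishable from
  exact zeros.
* The altered/discordant rubric is threshold-based; no uncertainty is
  propagated into band assignment, so values near 50/150 flip bands with
  measurement noise.
* Michaelis–Menten kinetics (Km/Vmax) are out of scope; rates are
  single-concentration formation rates.
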