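"""Enzyme-activity quantitation and classification.

Covers the downstream analysis of a recombinant-P450 functional assay:

* CO-difference-spectrum quantitation of functional P450
  ((ΔA450 − ΔA490) / 0.091 = nmol P450/mL; specific content = nmol/mL divided
  by total protein in mg/mL);
* metabolite-formation rates normalized to the wild-type enzyme (%WT) for the
  two probe substrates S-mephenytoin and omeprazole;
* the activity-band rubric (decreased < 50%, normal range 50-150%, increased
  > 150% of WT), substrate-discordance calls, and per-variant Welch t-tests
  computed from summary statistics (mean, SD, n) on the %WT scale.

A preparation whose protein expression or spectral P450 content is not
detected is not quantifiable; a *detected* preparation whose metabolite is not
detected maps to %WT = 0 (decreased band).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from scipy import stats

MEPHENYTOIN = "S_mephenytoin"
OMEPRAZOLE = "omeprazole"
SUBSTRATES = (MEPHENYTOIN, OMEPRAZOLE)

#: Extinction-coefficient divisor of the CO-difference spectrum (per 0.091
#: absorbance units per nmol/mL, i.e. 91 mM^-1 cm^-1).
CO_SPECTRUM_DIVISOR = 0.091

BAND_DECREASED_BELOW = 50.0
BAND_INCREASED_ABOVE = 150.0
DISCORDANCE_DIFF_PP = 25.0


class ActivityBand(str, enum.Enum):
    DECREASED = "decreased"
    NORMAL_RANGE = "normal_range"
    INCREASED = "increased"
    NOT_QUANTIFIABLE = "not_quantifiable"


@dataclass(frozen=True)
class SpectralReading:
    """CO-difference spectrum absorbances and total protein concentration."""

    dA450: float
    dA490: float
    protein_conc: float  # mg/mL

    def __post_init__(self) -> None:
        if self.protein_conc <= 0:
            raise ValueError(f"protein concentration must be > 0, got {self.protein_conc}")


@dataclass(frozen=True)
class SubstrateResult:
    """Metabolite-formation summary for one substrate (None = not detected)."""

    substrate: str
    mean_rate: Optional[float]  # pmol/min/pmol P450
    sd_rate: Optional[float]
    n: int = 3


@dataclass
class EnzymePrep:
    """One recombinant enzyme preparation (a variant or the wild type)."""

    variant_label: str
    star_allele: Optional[str] = None
    expression_detected: bool = True
    spectral_content: Optional[float] = None  # pmol/mg protein; None = N.D.
    results: Dict[str, SubstrateResult] = field(default_factory=dict)
    printed_pct_wt: Dict[str, Optional[float]] = field(default_factory=dict)
    novel: bool = True

    @property
    def quantifiable(self) -> bool:
        return self.expression_detected and self.spectral_content is not None


@dataclass(frozen=True)
class SummaryTTest:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    degenerate: bool = False


@dataclass
class ActivityProfile:
    """Interpreted assay outcome for one variant preparation."""

    variant_label: str
    pct_wt: Dict[str, Optional[float]]
    band: Dict[str, ActivityBand]
    altered: bool
    discordant: bool
    diff_pp: Optional[float]
    welch: Optional[SummaryTTest]
    novel: bool = True


@dataclass
class AssayReport:
    """Cohort-level aggregation of activity profiles."""

    profiles: List[ActivityProfile]
    n_preps: int
    n_quantifiable: int  # including the wild type
    novel_total: int
    novel_altered: int
    novel_discordant: int
    novel_diff_over_threshold: int
    max_diff_pp: Optional[float]
    max_diff_variant: Optional[str]


# ---------------------------------------------------------------------------
# Spectral quantitation


def p450_content(dA450: float, dA490: float) -> float:
    """Functional P450 concentration (nmol/mL) from the CO-difference spectrum.

    (ΔA450 − ΔA490) / 0.091. A below-baseline (negative) reading is returned
    as-is; callers should treat it as not-detected.
    """
    return (dA450 - dA490) / CO_SPECTRUM_DIVISOR


def specific_content(content: float, protein_conc: float) -> float:
    """Specific P450 content (nmol/mg protein) = content / protein concentration."""
    if protein_conc <= 0:
        raise ValueError(f"protein concentration must be > 0, got {protein_conc}")
    return content / protein_conc


def spectral_specific_content(reading: SpectralReading) -> float:
    return specific_content(p450_content(reading.dA450, reading.dA490), reading.protein_conc)


# ---------------------------------------------------------------------------
# %WT normalization and banding


def percent_wt(variant_rate: Optional[float], wt_rate: float) -> float:
    """Variant formation rate as a percentage of the wild-type rate.

    A not-detected metabolite (``None``) on a quantifiable preparation maps
    to 0%.
    """
    if wt_rate <= 0:
        raise ValueError(f"wild-type rate must be > 0, got {wt_rate}")
    if variant_rate is None:
        return 0.0
    return 100.0 * variant_rate / wt_rate


def activity_band(
    pct: Optional[float],
    lower: float = BAND_DECREASED_BELOW,
    upper: float = BAND_INCREASED_ABOVE,
) -> ActivityBand:
    """Band a %WT value: <50 decreased, 50-150 normal range, >150 increased.

    ``None`` (preparation not quantifiable) maps to ``NOT_QUANTIFIABLE``; the
    boundaries 50 and 150 fall in the normal range. ``lower``/``upper`` allow
    a narrower or wider normal range than the default rubric.
    """
    if pct is None:
        return ActivityBand.NOT_QUANTIFIABLE
    if pct < lower:
        return ActivityBand.DECREASED
    if pct > upper:
        return ActivityBand.INCREASED
    return ActivityBand.NORMAL_RANGE


def capability_difference(
    pct_meph: Optional[float], pct_omep: Optional[float]
) -> Optional[float]:
    """Absolute %WT difference between the two substrates (percentage points).

    ``None`` when either side is undefined.
    """
    if pct_meph is None or pct_omep is None:
        return None
    return abs(pct_meph - pct_omep)


# ---------------------------------------------------------------------------
# Summary-statistic Welch t-test


def welch_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> SummaryTTest:
    """Two-sided Welch (unequal-variance) t-test from summary statistics.

    t = (m1 − m2)/sqrt(s1²/n1 + s2²/n2); fractional degrees of freedom by
    Welch-Satterthwaite; p from the t distribution. Degenerate zero-variance
    inputs give t = 0, p = 1 when the means agree, and p → 0 (flagged) when
    they differ.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per arm")
    v1, v2 = s1 * s1 / n1, s2 * s2 / n2
    if v1 + v2 == 0.0:
        if m1 == m2:
            return SummaryTTest(0.0, float(n1 + n2 - 2), 1.0, degenerate=True)
        return SummaryTTest(math.copysign(math.inf, m1 - m2),
                            float(n1 + n2 - 2), 0.0, degenerate=True)
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return SummaryTTest(t, df, p)


# ---------------------------------------------------------------------------
# Classification


def classify_altered(profile: ActivityProfile) -> bool:
    """A variant is altered if its prep is not quantifiable or any band is
    outside the normal range."""
    bands = [profile.band.get(s) for s in SUBSTRATES]
    if all(b is ActivityBand.NOT_QUANTIFIABLE for b in bands):
        return True
    return any(b in (ActivityBand.DECREASED, ActivityBand.INCREASED) for b in bands)


def is_discordant(profile: ActivityProfile) -> bool:
    """Different activity bands for the two substrates (quantifiable preps only)."""
    b_meph = profile.band.get(MEPHENYTOIN)
    b_omep = profile.band.get(OMEPRAZOLE)
    if ActivityBand.NOT_QUANTIFIABLE in (b_meph, b_omep):
        return False
    return b_meph != b_omep


# ---------------------------------------------------------------------------
# Per-prep profile and cohort report


def _pct_for(prep: EnzymePrep, wt: EnzymePrep, substrate: str) -> Optional[float]:
    """%WT for one substrate: printed value if carried, else recomputed.

    ``None`` when the preparation is not quantifiable; 0.0 when quantifiable
    but the metabolite was not detected.
    """
    if not prep.quantifiable:
        return None
    printed = prep.printed_pct_wt.get(substrate)
    if printed is not None:
        return printed
    res = prep.results.get(substrate)
    wt_res = wt.results.get(substrate)
    if wt_res is None or wt_res.mean_rate is None:
        raise ValueError(f"wild-type rate missing for substrate {substrate}")
    if res is None or res.mean_rate is None:
        return 0.0
    return round(percent_wt(res.mean_rate, wt_res.mean_rate), 1)


def build_profile(prep: EnzymePrep, wt: EnzymePrep) -> ActivityProfile:
    """Compute the full interpreted profile of one variant preparation.

    The cross-substrate Welch test compares the two substrates on the %WT
    scale, with each arm's SD rescaled by its wild-type mean; it is computed
    only when both substrates have a detected metabolite with an SD.
    """
    pct = {s: _pct_for(prep, wt, s) for s in SUBSTRATES}
    band = {s: activity_band(pct[s]) for s in SUBSTRATES}
    diff = capability_difference(pct[MEPHENYTOIN], pct[OMEPRAZOLE])

    welch: Optional[SummaryTTest] = None
    if prep.quantifiable:
        arms = []
        for s in SUBSTRATES:
            res = prep.results.get(s)
            wt_res = wt.results.get(s)
            if (
                res is not None and res.mean_rate is not None and res.sd_rate is not None
                and wt_res is not None and wt_res.mean_rate
            ):
                sd_pct = 100.0 * res.sd_rate / wt_res.mean_rate
                arms.append((pct[s], sd_pct, res.n))
        if len(arms) == 2:
            (m1, s1, n1), (m2, s2, n2) = arms
            welch = welch_from_summary(m1, s1, n1, m2, s2, n2)

    profile = ActivityProfile(
        variant_label=prep.variant_label,
        pct_wt=pct,
        band=band,
        altered=False,
        discordant=False,
        diff_pp=diff,
        welch=welch,
        novel=prep.novel,
    )
    profile.altered = classify_altered(profile)
    profile.discordant = is_discordant(profile)
    return profile


def build_report(
    preps: Sequence[EnzymePrep],
    wt_label: str = "WT",
    diff_threshold: float = DISCORDANCE_DIFF_PP,
) -> AssayReport:
    """Aggregate profiles over a panel of preparations.

    Headline counts are computed over the novel (non-table) variants: altered,
    discordant, above-threshold substrate difference, and the maximum
    difference with its variant. Raises if the wild-type prep is missing.
    """
    wt = next((p for p in preps if p.variant_label == wt_label), None)
    if wt is None:
        raise ValueError(f"wild-type preparation {wt_label!r} not found")
    variant_preps = [p for p in preps if p.variant_label != wt_label]
    profiles = [build_profile(p, wt) for p in variant_preps]

    novel = [pr for pr in profiles if pr.novel]
    diffs = [(pr.diff_pp, pr.variant_label) for pr in novel if pr.diff_pp is not None]
    max_diff, max_var = max(diffs, default=(None, None))
    return AssayReport(
        profiles=profiles,
        n_preps=len(preps),
        n_quantifiable=sum(1 for p in preps if p.quantifiable),
        novel_total=len(novel),
        novel_altered=sum(pr.altered for pr in novel),
        novel_discordant=sum(pr.discordant for pr in novel),
        novel_diff_over_threshold=sum(
            1 for pr in novel if pr.diff_pp is not None and pr.diff_pp > diff_threshold
        ),
        max_diff_pp=max_diff,
        max_diff_variant=max_var,
    )
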