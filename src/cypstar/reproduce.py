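"""Recompute the headline results from the packaged reference tables.

Everything here is derived at run time from the shipped fixtures: the assay
report counts come from the assay table, the consensus-damaging count from the
annotation table restricted to the immunoblot-negative novel preparations, the
%WT spot checks from the raw mean rates, and the cohort percentage from the
published diplotype-phenotype counts.
"""

from __future__ import annotations

from typing import Dict

from .assay import OMEPRAZOLE, build_report, percent_wt
from .fixtures import (
    load_assay_table,
    load_diplotype_phenotype_table,
    load_variant_annotations,
)
from .star_caller import Phenotype, summarize_cohort
from .triage import consensus_damaging


def headline_counts() -> Dict[str, float]:
    """All headline quantities of the study, recomputed from the fixtures."""
    preps = load_assay_table()
    report = build_report(preps)

    annotations = {v.key.cdna_label: v for v in load_variant_annotations()}
    expression_negative = [
        p.variant_label for p in preps if p.novel and not p.expression_detected
    ]
    consensus_count = sum(
        consensus_damaging(annotations[label]) for label in expression_negative
    )

    by_label = {p.variant_label: p for p in preps}
    wt_omep = by_label["WT"].results[OMEPRAZOLE].mean_rate
    pct_1465 = round(
        percent_wt(by_label["NM_000769.4:c.1465C>T"].results[OMEPRAZOLE].mean_rate, wt_omep), 1
    )
    pct_394 = round(
        percent_wt(by_label["NM_000769.4:c.394C>T"].results[OMEPRAZOLE].mean_rate, wt_omep), 1
    )

    phen_rows = load_diplotype_phenotype_table()
    calls = [row.phenotype for row in phen_rows for _ in range(row.count)]
    summary = summarize_cohort(calls)

    return {
        "novel_total": report.novel_total,
        "novel_altered_count": report.novel_altered,
        "novel_altered_percent": round(100.0 * report.novel_altered / report.novel_total, 1),
        "discordant_count": report.novel_discordant,
        "diff_over_25pp_count": report.novel_diff_over_threshold,
        "max_diff_pp": None if report.max_diff_pp is None else round(report.max_diff_pp, 1),
        "max_diff_variant": report.max_diff_variant,
        "expression_negative_total": len(expression_negative),
        "expression_negative_consensus_damaging": consensus_count,
        "pct_wt_omeprazole_c1465": pct_1465,
        "pct_wt_omeprazole_c394": pct_394,
        "quantifiable_preps": report.n_quantifiable,
        "total_preps": report.n_preps,
        "nm_percent": summary.percentages[Phenotype.NM],
        "cohort_total": summary.total,
    }
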