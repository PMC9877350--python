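"""Synthetic-cohort generator: determinism, recovery, and calibration."""

import math

import numpy as np
import pytest

from cypstar.assay import ActivityBand, activity_band, welch_from_summary
from cypstar.simulate import (
    AssaySpec,
    NovelVariantSpec,
    SimulationConfig,
    simulate_assay,
    simulate_cohort,
    write_vcf,
)
from cypstar.star_caller import (
    Phenotype,
    assign_phenotype,
    call_diplotype,
    read_phased_vcf,
    summarize_cohort,
)
from cypstar.triage import TriageRoute, select_candidates
from cypstar.variants import VariantKey


def _cfg(**kw):
    defaults = dict(n_samples=20, allele_frequencies={"*1": 1.0}, seed=7)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            _cfg(allele_frequencies={"*1": 0.5, "*2": 0.4})

    def test_frequencies_must_be_probabilities(self):
        with pytest.raises(ValueError, match="outside"):
            _cfg(allele_frequencies={"*1": 1.5, "*2": -0.5})

    def test_undefined_allele_is_rejected(self, allele_table):
        with pytest.raises(KeyError):
            simulate_cohort(_cfg(allele_frequencies={"*99": 1.0}), allele_table)


class TestDegenerateCohorts:
    def test_all_reference_cohort_is_all_nm(self, allele_table):
        cohort = simulate_cohort(_cfg(), allele_table)
        truth = cohort.truth_table()
        assert set(truth["diplotype"]) == {"*1|*1"}
        assert set(truth["phenotype"]) == {"NM"}

    def test_all_increased_cohort_is_all_um(self, allele_table):
        cohort = simulate_cohort(_cfg(allele_frequencies={"*17": 1.0}), allele_table)
        assert set(cohort.truth_table()["phenotype"]) == {"UM"}


class TestVcfRoundTrip:
    def test_written_vcf_reproduces_truth_haplotypes_exactly(self, allele_table, tmp_path):
        cfg = _cfg(
            n_samples=30,
            allele_frequencies={"*1": 0.5, "*2": 0.2, "*17": 0.15, "*9": 0.1, "*27": 0.05},
            seed=11,
        )
        cohort = simulate_cohort(cfg, allele_table)
        path = tmp_path / "c.vcf"
        write_vcf(cohort, path)
        haps = read_phased_vcf(path, allele_table.region)
        for i, sid in enumerate(cohort.sample_ids):
            assert haps[sid][0].variants == cohort.haplotype_variants(i, 0)
            assert haps[sid][1].variants == cohort.haplotype_variants(i, 1)

    def test_diplotype_and_phenotype_recovery_is_total(self, allele_table, tmp_path):
        """With pure table alleles, calling recovers 100% of planted truth."""
        cfg = _cfg(
            n_samples=100,
            allele_frequencies={
                "*1": 0.4, "*2": 0.2, "*3": 0.1, "*17": 0.15, "*9": 0.05,
                "*13": 0.05, "*35": 0.05,
            },
            seed=3,
        )
        cohort = simulate_cohort(cfg, allele_table)
        path = tmp_path / "c.vcf"
        write_vcf(cohort, path)
        haps = read_phased_vcf(path, allele_table.region)
        truth = cohort.truth_table().set_index("sample")
        for sid in cohort.sample_ids:
            d = call_diplotype(haps[sid], allele_table)
            assert d.alleles == (
                truth.loc[sid, "hap1_allele"], truth.loc[sid, "hap2_allele"]
            )
            assert assign_phenotype(d, allele_table).value == truth.loc[sid, "phenotype"]

    def test_same_seed_gives_byte_identical_vcf(self, allele_table, tmp_path):
        cfg = _cfg(n_samples=15, allele_frequencies={"*1": 0.7, "*2": 0.3}, seed=5)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(simulate_cohort(cfg, allele_table), p1)
        write_vcf(simulate_cohort(cfg, allele_table), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_cohort_gives_valid_header_only_vcf(self, allele_table, tmp_path):
        cohort = simulate_cohort(_cfg(n_samples=0), allele_table)
        path = tmp_path / "empty.vcf"
        write_vcf(cohort, path)
        body = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")]
        sites = len(allele_table.all_defining_variants)
        # records are emitted for each site but with no sample columns
        assert len(body) == sites
        assert read_phased_vcf(path, allele_table.region) == {}


class TestHardyWeinberg:
    def test_phenotype_frequencies_converge_to_closed_form(self, allele_table):
        """Haplotypes are i.i.d. draws, so phenotype frequencies follow the
        multinomial expectation from the allele frequencies; with n = 2000
        the observed shares sit within 3 Monte-Carlo standard errors."""
        freqs = {"*1": 0.6, "*2": 0.25, "*17": 0.15}
        n = 2000
        cohort = simulate_cohort(
            _cfg(n_samples=n, allele_frequencies=freqs, seed=17), allele_table
        )
        summary = summarize_cohort(
            [Phenotype(p) for p in cohort.truth_table()["phenotype"]]
        )
        p1, p2, p17 = freqs["*1"], freqs["*2"], freqs["*17"]
        expected = {
            Phenotype.NM: p1 * p1,
            Phenotype.RM: 2 * p1 * p17,
            Phenotype.UM: p17 * p17,
            Phenotype.IM: 2 * p2 * (p1 + p17),
            Phenotype.PM: p2 * p2,
        }
        assert abs(sum(expected.values()) - 1.0) < 1e-12
        for phen, p in expected.items():
            se = math.sqrt(p * (1 - p) / n)
            observed = summary.counts[phen] / n
            assert abs(observed - p) <= 3 * se, (phen, observed, p)


class TestNovelInjectionAndTriage:
    KEY_BENIGN = VariantKey("10", 96522600, "C", "T")
    KEY_DELETERIOUS = VariantKey("10", 96522700, "G", "A")

    def _specs(self):
        return [
            NovelVariantSpec(self.KEY_BENIGN, sift=0.5, polyphen2=0.1, cadd=3.0,
                             injection_prob=0.3),
            NovelVariantSpec(self.KEY_DELETERIOUS, sift=0.0, polyphen2=1.0, cadd=25.0,
                             injection_prob=0.3),
        ]

    def test_triage_recovers_planted_selectable_variants_in_all_pm_cohort(
        self, allele_table
    ):
        """In an all-poor-metabolizer cohort only the planted deleterious
        variant passes the flow; the benign one is rejected, with zero false
        selections."""
        cohort = simulate_cohort(
            _cfg(n_samples=50, allele_frequencies={"*2": 1.0}, seed=23,
                 novel_variant_specs=self._specs()),
            allele_table,
        )
        decisions = {
            d.key: d
            for d in select_candidates(
                cohort.annotated_variants(), allele_table, cohort.phenotypes()
            )
        }
        assert decisions[self.KEY_DELETERIOUS].selected
        assert decisions[self.KEY_DELETERIOUS].route is TriageRoute.DELETERIOUS_FILTER
        assert not decisions[self.KEY_BENIGN].selected
        selected = {k for k, d in decisions.items() if d.selected}
        assert selected == {self.KEY_DELETERIOUS}

    def test_any_missense_in_nm_cohort_is_selected_via_carrier_route(self, allele_table):
        cohort = simulate_cohort(
            _cfg(n_samples=50, allele_frequencies={"*1": 1.0}, seed=23,
                 novel_variant_specs=self._specs()),
            allele_table,
        )
        decisions = {
            d.key: d
            for d in select_candidates(
                cohort.annotated_variants(), allele_table, cohort.phenotypes()
            )
        }
        for key in (self.KEY_BENIGN, self.KEY_DELETERIOUS):
            assert decisions[key].route is TriageRoute.CARRIED_BY_NM_RM_UM

    def test_coinjected_variants_flag_cooccurrence(self, allele_table):
        specs = [
            NovelVariantSpec(self.KEY_BENIGN, sift=0.5, polyphen2=0.1, cadd=3.0,
                             injection_prob=1.0),
            NovelVariantSpec(self.KEY_DELETERIOUS, sift=0.0, polyphen2=1.0, cadd=25.0,
                             injection_prob=1.0),
        ]
        cohort = simulate_cohort(
            _cfg(n_samples=5, novel_variant_specs=specs), allele_table
        )
        decisions = select_candidates(
            cohort.annotated_variants(), allele_table, cohort.phenotypes()
        )
        by_key = {d.key: d for d in decisions}
        assert not by_key[self.KEY_BENIGN].cooccurrence_clean
        assert not by_key[self.KEY_DELETERIOUS].cooccurrence_clean


class TestAssaySimulation:
    WT_MEAN = 4.23

    def test_zero_cv_reproduces_the_planted_value_exactly(self):
        res = simulate_assay(25.0, self.WT_MEAN, 0.0, 3, rng=1)
        assert res.mean_rate == pytest.approx(self.WT_MEAN * 0.25)
        assert res.sd_rate == 0.0

    @pytest.mark.parametrize("pct", [25.0, 100.0, 200.0])
    def test_planted_band_recovered_in_at_least_99pct_of_draws(self, pct):
        rng = np.random.default_rng(101)
        hits = sum(
            activity_band(100 * simulate_assay(pct, self.WT_MEAN, 0.05, 3, rng).mean_rate
                          / self.WT_MEAN)
            is activity_band(pct)
            for _ in range(1000)
        )
        assert hits >= 990

    @pytest.mark.parametrize("pct", [25.0, 100.0, 200.0])
    def test_percent_wt_estimate_is_unbiased_within_mc_error(self, pct):
        rng = np.random.default_rng(202)
        estimates = np.array([
            100 * simulate_assay(pct, self.WT_MEAN, 0.05, 3, rng).mean_rate / self.WT_MEAN
            for _ in range(1000)
        ])
        se = estimates.std(ddof=1) / math.sqrt(len(estimates))
        assert abs(estimates.mean() - pct) < 3 * se

    def test_welch_type_i_error_is_nominal(self):
        """Two identically planted arms rejected at alpha=.05 in ~5% of 2000
        paired draws (within the binomial 99% CI)."""
        rng = np.random.default_rng(2024)
        n_reps = 2000
        rejections = 0
        for _ in range(n_reps):
            a = simulate_assay(100.0, self.WT_MEAN, 0.1, 3, rng)
            b = simulate_assay(100.0, self.WT_MEAN, 0.1, 3, rng)
            t = welch_from_summary(a.mean_rate, a.sd_rate, 3, b.mean_rate, b.sd_rate, 3)
            rejections += t.p_value < 0.05
        rate = rejections / n_reps
        half_width = 2.576 * math.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) <= half_width, rate

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_assay(100.0, 1.0, -0.1, 3, rng=0)
        with pytest.raises(ValueError):
            simulate_assay(100.0, 1.0, 0.1, 1, rng=0)
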