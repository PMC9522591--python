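"""Cohort analyses: stratification, LD, fine-mapping, concordance, funnel."""

import numpy as np
import pandas as pd
import pytest

from gcregulome.hgr_atlas import GRE_CONSENSUS, gre_pwm
from gcregulome.patient_integration import (
    allele_delta_score,
    ld_r2,
    methylation_concordance,
    prioritize_hgrs,
    stratify_resistance,
    variant_phenotype_association,
)
from gcregulome.synthetic_data import SimConfig, simulate_study
from tests.conftest import small_config


class TestStratify:
    def _cohort(self, phenos):
        from gcregulome.diff_counts import CountMatrix
        from gcregulome.patient_integration import Cohort

        ids = [f"p{i}" for i in range(len(phenos))]
        samples = pd.DataFrame(
            {"subtype": "s", "phenotype": phenos, "resistance_class": "sensitive"}, index=ids
        )
        counts = pd.DataFrame({i: [1] for i in ids}, index=["f0"])
        return Cohort(samples=samples, accessibility=CountMatrix(counts, samples[["subtype"]]))

    def test_median_split_balanced(self):
        labels = stratify_resistance(self._cohort(list(range(1, 11))), "median_split")
        assert (labels == "resistant").sum() == 5

    def test_provided_labels_pass_through(self):
        c = self._cohort([1.0, 2.0])
        c.samples["resistance_class"] = ["sensitive", "resistant"]
        labels = stratify_resistance(c, "provided_labels")
        assert labels.tolist() == ["sensitive", "resistant"]

    def test_threshold_outside_range_rejected(self):
        with pytest.raises(ValueError):
            stratify_resistance(self._cohort([1.0, 2.0]), "threshold:99")


class TestLd:
    def test_identical_vectors(self):
        assert ld_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        g1 = np.array([0, 1, 2, 0, 2])
        assert ld_r2(g1, 2 - g1) == pytest.approx(1.0)

    def test_matches_correlation_formula(self):
        rng = np.random.default_rng(0)
        g1 = rng.integers(0, 3, 100).astype(float)
        g2 = rng.integers(0, 3, 100).astype(float)
        want = (
            np.sum((g1 - g1.mean()) * (g2 - g2.mean()))
            / np.sqrt(np.sum((g1 - g1.mean()) ** 2) * np.sum((g2 - g2.mean()) ** 2))
        ) ** 2
        assert ld_r2(g1, g2) == pytest.approx(want)

    def test_zero_variance_is_nan(self):
        assert np.isnan(ld_r2([1, 1, 1, 1], [0, 1, 2, 1]))

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        g1 = rng.integers(0, 3, 50).astype(float)
        g2 = rng.integers(0, 3, 50).astype(float)
        assert ld_r2(g1, g2) == pytest.approx(ld_r2(g2, g1))


class TestAssociation:
    def test_planted_additive_effect_recovered(self):
        rng = np.random.default_rng(2)
        n = 100
        dosage = rng.binomial(2, 0.3, size=(5, n))
        pheno = pd.Series(1.0 * dosage[0] + rng.normal(0, 1, n), index=[f"p{i}" for i in range(n)])
        d = pd.DataFrame(dosage, index=[f"v{i}" for i in range(5)], columns=pheno.index)
        out = variant_phenotype_association(d, pheno)
        assert 0.6 <= out.at["v0", "beta"] <= 1.4
        assert out.at["v0", "q"] < 0.05

    def test_permuted_phenotype_uniform(self):
        rng = np.random.default_rng(3)
        n = 60
        d = pd.DataFrame(
            rng.binomial(2, 0.4, size=(50, n)),
            index=[f"v{i}" for i in range(50)],
            columns=[f"p{i}" for i in range(n)],
        )
        pheno = pd.Series(rng.normal(size=n), index=d.columns)
        out = variant_phenotype_association(d, pheno)
        assert (out["p"] < 0.05).mean() <= 0.12
        assert out["q"].min() > 0.05

    def test_monomorphic_is_nan(self):
        d = pd.DataFrame([[1] * 10], index=["v0"], columns=[f"p{i}" for i in range(10)])
        pheno = pd.Series(np.arange(10.0), index=d.columns)
        assert np.isnan(variant_phenotype_association(d, pheno).at["v0", "beta"])


class TestAlleleScoring:
    def test_core_disruption_negative_delta(self):
        pwm = gre_pwm()
        seq = "T" * 20 + GRE_CONSENSUS.replace("NNN", "ACT") + "T" * 20
        # strike the first consensus base (A -> C)
        delta = allele_delta_score(seq, 20, "A", "C", pwm)
        assert delta < 0 and abs(delta) >= 2.0

    def test_spacer_variant_scores_zero(self):
        pwm = gre_pwm()
        seq = "T" * 20 + GRE_CONSENSUS.replace("NNN", "ACT") + "T" * 20
        delta = allele_delta_score(seq, 20 + 7, "C", "G", pwm)  # middle of spacer
        assert delta == pytest.approx(0.0)

    def test_reference_mismatch_rejected(self):
        pwm = gre_pwm()
        with pytest.raises(ValueError, match="mismatch"):
            allele_delta_score("ACGT" * 10, 0, "G", "T", pwm)


class TestCohortPipeline:
    def test_resistance_sites_recovered_with_direction(self, full_run):
        res = full_run["cohort"]["resistance_sites"]
        truth = full_run["study"].truth
        planted = set(truth.planted_resistance_site_ids)
        recovered = planted & set(res.index)
        assert len(recovered) / len(planted) >= 0.9
        occ = [s for s in recovered if s in set(truth.occluded_site_ids)]
        dirs = res.loc[occ, "direction"]
        assert (dirs == "occluded_in_resistant").mean() >= 0.95

    def test_hgr_enrichment_positive(self, full_run):
        _, odds, p = full_run["cohort"]["hgr_enrichment"]
        assert odds > 1

    def test_methylation_concordance_matches_planted_fraction(self, full_run):
        frac = full_run["cohort"]["methylation_concordance"]
        target = full_run["config"].methylation_anticorr_frac
        assert abs(frac - target) <= 0.15

    def test_fully_anticorrelated_gives_one(self):
        study = simulate_study(small_config(seed=11, methylation_anticorr_frac=1.0))
        from gcregulome.patient_integration import (
            resistance_accessibility,
            stratify_resistance,
        )
        import warnings

        cohort = study.cohort
        labels = stratify_resistance(cohort, "provided_labels")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = resistance_accessibility(cohort, labels)
        _, frac = methylation_concordance(res, study.genome.peaks, cohort, labels)
        assert frac == pytest.approx(1.0)

    def test_independent_methylation_near_half(self):
        study = simulate_study(small_config(seed=12, methylation_anticorr_frac=0.5))
        from gcregulome.patient_integration import (
            resistance_accessibility,
            stratify_resistance,
        )
        import warnings

        cohort = study.cohort
        labels = stratify_resistance(cohort, "provided_labels")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = resistance_accessibility(cohort, labels)
        _, frac = methylation_concordance(res, study.genome.peaks, cohort, labels)
        assert 0.3 <= frac <= 0.7


class TestFineMapping:
    def test_causal_variant_finemapped_with_negative_delta(self):
        import warnings

        from gcregulome.pipeline import run_all

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = run_all(small_config(seed=2, n_patients=100), write_outputs=False)
        fm = r["cohort"]["finemapped"]
        causal = r["study"].truth.causal_variant["variant"]
        assert causal in fm.index
        assert fm.at[causal, "delta_score"] < 0
        assert abs(fm.at[causal, "delta_score"]) >= 2.0
        assert r["cohort"]["association"].at[causal, "q"] < 0.05
        # proxies in high LD with the lead are carried along
        assert (fm["r2_to_lead"] > 0.8).all()


class TestFunnel:
    def test_stage_counts_monotone(self, full_run):
        fc = full_run["funnel_counts"]
        seq = [
            fc["crispri_candidates"],
            fc["gene_associated"],
            fc["deg_linked"],
            fc["resistance_gene_linked"],
        ]
        assert seq == sorted(seq, reverse=True)

    def test_showcase_locus_survives(self, full_run):
        truth = full_run["study"].truth
        out = full_run["prioritized"]
        assert truth.showcase["peak"] in set(out["name"])
        pair = out[out["name"] == truth.showcase["peak"]]
        assert truth.showcase["gene"] in set(pair["gene_id"])

    def test_empty_resistance_list_rejected(self, full_run):
        with pytest.raises(ValueError):
            prioritize_hgrs(
                full_run["screen"]["candidates"],
                full_run["study"].genome.peaks,
                full_run["study"].genome.genes,
                full_run["degs"],
                [],
            )
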