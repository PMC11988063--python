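"""Synthetic-population generator: distributions, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from testday import DefectSpec, SimConfig, inject_defects
from testday.config import SMALLHOLDER_HERD_SIZE_PROBS
from testday.simulate import (
    genic_variance_normalizer,
    simulate_genotypes,
    simulate_herds,
    simulate_phenotypes,
    simulate_population,
    simulate_snp_effects,
)


class TestHerds:
    def test_single_cow_fraction_matches_distribution(self):
        cfg = SimConfig(n_herds=10_000, seed=7)
        herds = simulate_herds(cfg)
        sizes = herds.groupby("herd_id").size()
        single = (sizes == 1).mean()
        assert abs(single - SMALLHOLDER_HERD_SIZE_PROBS[0]) < 0.02

    def test_degenerate_distribution(self):
        cfg = SimConfig(n_herds=50, herd_size_distribution=(1.0,), seed=0)
        herds = simulate_herds(cfg)
        assert herds["herd_id"].nunique() == 50
        assert len(herds) == 50

    def test_determinism(self):
        cfg = SimConfig(n_herds=100, seed=9)
        pd.testing.assert_frame_equal(simulate_herds(cfg), simulate_herds(cfg))

    def test_total_animals_conserved(self):
        cfg = SimConfig(n_herds=500, seed=3)
        herds = simulate_herds(cfg)
        sizes = herds.groupby("herd_id").size()
        assert sizes.sum() == len(herds)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(herd_size_distribution=())


class TestGenotypes:
    def test_symmetric_frequency_mean_dosage(self):
        cfg = SimConfig(n_snps=200, maf_range=(0.5, 0.5), seed=1)
        mat, _ = simulate_genotypes(cfg, 1500)
        assert np.allclose(mat.calls.mean(axis=0), 1.0, atol=0.12)

    def test_reproducible(self):
        cfg = SimConfig(n_snps=5, seed=4)
        m1, f1 = simulate_genotypes(cfg, 3)
        m2, f2 = simulate_genotypes(cfg, 3)
        assert np.array_equal(m1.calls, m2.calls)
        assert np.array_equal(f1, f2)

    def test_observed_maf_within_binomial_error(self):
        cfg = SimConfig(n_snps=500, seed=12)
        n = 2000
        mat, freqs = simulate_genotypes(cfg, n)
        observed = mat.calls.mean(axis=0) / 2.0
        se = np.sqrt(freqs * (1 - freqs) / (2 * n))
        frac_ok = np.mean(np.abs(observed - freqs) <= 3 * se)
        assert frac_ok >= 0.99

    def test_invalid_dimensions(self):
        cfg = SimConfig(n_snps=5, seed=0)
        with pytest.raises(ValueError):
            simulate_genotypes(cfg, 0)


class TestSnpEffects:
    def test_null_mixture_gives_zero_effects(self):
        cfg = SimConfig(
            mixture_proportions=(1.0, 0.0, 0.0, 0.0), n_snps=100, seed=0
        )
        truth = simulate_snp_effects(cfg, 100)
        assert np.all(truth.true_snp_effects == 0.0)

    def test_single_class_effect_variance(self):
        # independent oracle: expected per-effect variance from the config
        cfg = SimConfig(
            mixture_proportions=(0.0, 0.0, 0.0, 1.0),
            n_snps=10_000,
            seed=21,
            standardize_genic_variance=False,
        )
        rng = np.random.default_rng(21)
        freqs = rng.uniform(*cfg.maf_range, size=10_000)
        truth = simulate_snp_effects(cfg, 10_000, allele_freqs=freqs, rng=rng)
        norm = genic_variance_normalizer(cfg, freqs)
        expected = 1e-2 * cfg.variance_components["Va"] / norm
        empirical = float(np.var(truth.true_snp_effects))
        assert abs(empirical - expected) / expected < 0.05

    def test_class_counts_multinomial(self):
        cfg = SimConfig(n_snps=10_000, seed=8)
        truth = simulate_snp_effects(cfg, 10_000)
        counts = np.bincount(truth.true_component_assignments, minlength=4)
        expected = np.asarray(cfg.mixture_proportions) * 10_000
        _, p = stats.chisquare(counts, expected)
        assert p > 0.001

    def test_standardized_genic_variance_exact(self):
        cfg = SimConfig(n_snps=2000, seed=5)
        rng = np.random.default_rng(5)
        freqs = rng.uniform(*cfg.maf_range, size=2000)
        truth = simulate_snp_effects(cfg, 2000, allele_freqs=freqs, rng=rng)
        realized = float(np.sum(2 * freqs * (1 - freqs) * truth.true_snp_effects**2))
        assert abs(realized - cfg.variance_components["Va"]) < 1e-12

    def test_negative_scales_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(mixture_variance_scales=(0.0, -1e-4, 1e-3, 1e-2))


class TestPhenotypes:
    def test_null_variance_gives_zero_records(self):
        cfg = SimConfig(
            n_herds=20,
            n_snps=50,
            seed=2,
            variance_components={"Va": 0.0, "Vpe": 0.0, "Vherd": 0.0, "Ve": 0.0},
            fixed_effect_sd={"lactation": 0.0, "cdc": 0.0, "year_month": 0.0},
            base_fat_pct=0.0,
        )
        records, *_ = simulate_population(cfg)
        assert np.allclose(records["fat_pct"], 0.0)

    def test_between_animal_variance_decomposition(self):
        # ANOVA oracle: var of per-animal means ~= Va + Ve / n_records
        cfg = SimConfig(
            n_herds=2000,
            herd_size_distribution=(1.0,),
            n_snps=400,
            seed=17,
            variance_components={"Va": 0.012, "Vpe": 0.0, "Vherd": 0.0, "Ve": 0.106},
            fixed_effect_sd={"lactation": 0.0, "cdc": 0.0, "year_month": 0.0},
        )
        records, *_ = simulate_population(cfg)
        means = records.groupby("animal_id")["fat_pct"].mean()
        expected = 0.012 + 0.106 / cfg.records_per_lactation
        assert abs(float(means.var()) - expected) / expected < 0.15

    def test_structure(self, small_population):
        records = small_population["records"]
        cfg = small_population["config"]
        per = records.groupby(["animal_id", "lactation_number"]).size()
        assert (per == cfg.records_per_lactation).all()
        assert records["days_in_milk"].between(*cfg.dim_window).all()

    def test_breeding_values_exact_product(self, small_population):
        truth, geno = small_population["truth"], small_population["genotypes"]
        W = geno.calls - 2 * truth.allele_freqs[None, :]
        assert np.allclose(
            truth.true_breeding_values, W @ truth.true_snp_effects, atol=1e-12
        )

    def test_population_determinism(self):
        cfg = SimConfig(n_herds=25, n_snps=60, seed=33)
        r1, g1, t1, _ = simulate_population(cfg)
        r2, g2, t2, _ = simulate_population(cfg)
        pd.testing.assert_frame_equal(r1, r2)
        assert np.array_equal(g1.calls, g2.calls)
        assert np.array_equal(t1.true_snp_effects, t2.true_snp_effects)


class TestInjectDefects:
    def test_empty_spec_is_identity(self, small_population):
        records, geno = small_population["records"], small_population["genotypes"]
        r2, g2, manifest = inject_defects(records, geno, DefectSpec(), seed=1)
        pd.testing.assert_frame_equal(records, r2)
        assert np.array_equal(geno.calls, g2.calls, equal_nan=True)
        assert all(len(v) == 0 for v in manifest.values())

    def test_low_call_rate_animal_flagged(self, small_population):
        records, geno = small_population["records"], small_population["genotypes"]
        spec = DefectSpec(low_call_rate_animals=1, animal_call_rate=0.85)
        _, g2, manifest = inject_defects(records, geno, spec, seed=2)
        [aid] = manifest["animal_call_rate"]
        i = g2.animal_index(aid)
        assert g2.animal_call_rate()[i] <= 0.85 + 1e-9
        assert g2.animal_call_rate()[i] < 0.90

    def test_duplicate_is_exact_copy(self, small_population):
        records, geno = small_population["records"], small_population["genotypes"]
        spec = DefectSpec(duplicate_animals=1)
        _, g2, manifest = inject_defects(records, geno, spec, seed=3)
        [dup] = manifest["duplicates"]
        orig = dup.replace("ZDUP-", "")
        r = np.corrcoef(
            g2.calls[g2.animal_index(orig)], g2.calls[g2.animal_index(dup)]
        )[0, 1]
        assert r == pytest.approx(1.0)

    def test_excess_defects_rejected(self, small_population):
        records, geno = small_population["records"], small_population["genotypes"]
        with pytest.raises(ValueError):
            inject_defects(
                records, geno, DefectSpec(outlier_cows=geno.n_animals + 1), seed=0
            )
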