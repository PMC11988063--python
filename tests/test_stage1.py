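"""Stage-1 repeatability model: design, EM-REML, MME, adjusted records."""

import numpy as np
import pandas as pd
import pytest

from testday import RepeatabilityModel, SimConfig
from testday.simulate import simulate_population
from testday.stage1 import (
    Stage1Design,
    adjust_records,
    build_design,
    estimate_variances_em_reml,
    solve_mme,
)

from conftest import make_records


def _balanced_one_way(n_animals, n_rec, sigma_a, sigma_e, seed):
    """Balanced one-way design (no herd factor) with known components."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, sigma_a, n_animals)
    y = np.repeat(a, n_rec) + rng.normal(0, sigma_e, n_animals * n_rec)
    Z1 = np.kron(np.eye(n_animals), np.ones((n_rec, 1)))
    return Stage1Design(
        y=y,
        X=np.ones((n_animals * n_rec, 1)),
        Z1=Z1,
        Z2=np.zeros((n_animals * n_rec, 0)),
        animal_ids=[f"a{i}" for i in range(n_animals)],
        herd_ids=[],
        fixed_names=["intercept"],
        record_index=np.arange(n_animals * n_rec),
    )


class TestBuildDesign:
    def test_two_lactations_single_everything_else(self):
        rows = [
            ("A", "h1", "c1", 1, 50, "2020-01", 4.0),
            ("A", "h1", "c1", 2, 60, "2020-01", 4.2),
            ("B", "h1", "c1", 1, 70, "2020-01", 3.9),
            ("B", "h1", "c1", 2, 80, "2020-01", 4.1),
        ]
        design = build_design(make_records(rows))
        assert design.X.shape[1] == 2  # intercept + one lactation contrast
        assert design.fixed_names[0] == "intercept"

    def test_single_level_everywhere_intercept_only(self):
        rows = [("A", "h1", "c1", 1, 50, "2020-01", 4.0),
                ("B", "h1", "c1", 1, 60, "2020-01", 4.1)]
        design = build_design(make_records(rows))
        assert design.X.shape[1] == 1

    def test_incidence_rows_sum_to_one(self, small_population):
        design = build_design(small_population["records"])
        assert np.allclose(design.Z1.sum(axis=1), 1.0)
        assert np.allclose(design.Z2.sum(axis=1), 1.0)

    def test_missing_level_rejected(self):
        rows = [("A", "h1", None, 1, 50, "2020-01", 4.0),
                ("B", "h1", "c1", 1, 60, "2020-01", 4.1)]
        with pytest.raises(ValueError, match="cdc_id"):
            build_design(make_records(rows))


class TestEMREML:
    def test_matches_closed_form_anova_reml_balanced(self):
        # closed-form oracle: sigma2_e = MSW, sigma2_a = (MSB - MSW)/k
        n_animals, k = 60, 5
        design = _balanced_one_way(n_animals, k, 0.5, 1.0, seed=11)
        y = design.y.reshape(n_animals, k)
        means = y.mean(axis=1)
        msb = k * np.sum((means - means.mean()) ** 2) / (n_animals - 1)
        msw = np.sum((y - means[:, None]) ** 2) / (n_animals * (k - 1))
        expected_a = (msb - msw) / k
        est = estimate_variances_em_reml(design, tolerance=1e-10, max_iter=2000)
        assert est["sigma2_e"] == pytest.approx(msw, abs=1e-6)
        assert est["sigma2_a"] == pytest.approx(expected_a, abs=1e-6)

    def test_recovers_simulation_truth_within_20pct(self):
        cfg = SimConfig(
            n_herds=100,
            herd_size_distribution=(0, 0, 0, 0, 0, 1.0),  # herds of 6
            n_snps=200,
            seed=19,
            records_per_lactation=8,
            fixed_effect_sd={"lactation": 0.0, "cdc": 0.0, "year_month": 0.0},
        )
        records, _, truth, _ = simulate_population(cfg)
        design = build_design(records)
        est = estimate_variances_em_reml(design)
        realized_va = float(np.var(truth.true_breeding_values))
        assert abs(est["sigma2_a"] - realized_va) / realized_va < 0.20
        assert abs(est["sigma2_e"] - 0.106) / 0.106 < 0.20

    def test_null_component_goes_to_boundary(self):
        design = _balanced_one_way(80, 4, 0.0, 1.0, seed=23)
        est = estimate_variances_em_reml(design)
        assert est["sigma2_a"] < 0.05  # boundary (truth 0, residual 1.0)

    def test_too_few_animals_rejected(self):
        design = _balanced_one_way(1, 4, 0.5, 1.0, seed=0)
        with pytest.raises(ValueError):
            estimate_variances_em_reml(design)


class TestSolveMME:
    def _toy(self):
        rows = [
            ("A", "h1", "c1", 1, 50, "2020-01", 4.3),
            ("A", "h2", "c1", 1, 100, "2020-01", 4.1),
            ("B", "h1", "c1", 1, 60, "2020-01", 3.8),
            ("B", "h2", "c1", 1, 110, "2020-01", 4.0),
        ]
        return build_design(make_records(rows))

    def test_matches_dense_oracle(self):
        design = self._toy()
        vc = {"sigma2_a": 0.4, "sigma2_h": 0.2, "sigma2_e": 1.0}
        fit = solve_mme(design, vc)
        # dense linear-algebra oracle: assemble Henderson's MME directly
        W = np.hstack([design.X, design.Z1, design.Z2])
        p = design.X.shape[1]
        na, nh = design.Z1.shape[1], design.Z2.shape[1]
        C = W.T @ W
        C[p : p + na, p : p + na] += np.eye(na) * (1.0 / 0.4)
        C[p + na :, p + na :] += np.eye(nh) * (1.0 / 0.2)
        sol = np.linalg.solve(C, W.T @ design.y)
        assert np.allclose(np.concatenate([fit.b_hat, fit.a_hat, fit.h_hat]), sol, atol=1e-10)

    def test_infinite_shrinkage_limit(self):
        design = self._toy()
        fit = solve_mme(design, {"sigma2_a": 0.0, "sigma2_h": 0.3, "sigma2_e": 1.0})
        assert np.allclose(fit.a_hat, 0.0, atol=1e-8)

    def test_reconstruction_identity(self, small_population):
        design = build_design(small_population["records"])
        fit = solve_mme(design, {"sigma2_a": 0.01, "sigma2_h": 0.005, "sigma2_e": 0.1})
        recon = (
            design.X @ fit.b_hat
            + design.Z1 @ fit.a_hat
            + design.Z2 @ fit.h_hat
            + fit.e_hat
        )
        assert np.allclose(recon, design.y, atol=1e-8)

    def test_nonpositive_residual_variance_rejected(self):
        with pytest.raises(ValueError):
            solve_mme(self._toy(), {"sigma2_a": 0.1, "sigma2_h": 0.1, "sigma2_e": 0.0})


class TestAdjustedRecords:
    def test_additivity_exact(self, small_population):
        model = RepeatabilityModel(sigma2_a=0.012, sigma2_h=0.001, sigma2_e=0.106)
        model.fit(small_population["records"])
        adj = model.adjust()
        assert np.allclose(adj["afp"], adj["ife"] + adj["are"] + adj["hre"], atol=1e-12)
        # afp also equals y - X b_hat
        design = model.design_
        assert np.allclose(adj["afp"].to_numpy(), design.y - design.X @ model.fit_.b_hat, atol=1e-10)

    def test_location_invariance_of_adjusted_records(self, small_population):
        records = small_population["records"]
        shifted = records.copy()
        shifted["fat_pct"] = shifted["fat_pct"] + 2.5
        kw = dict(sigma2_a=0.012, sigma2_h=0.001, sigma2_e=0.106)
        adj1 = RepeatabilityModel(**kw).fit(records).adjust()
        adj2 = RepeatabilityModel(**kw).fit(shifted).adjust()
        assert np.allclose(adj1["afp"], adj2["afp"], atol=1e-8)

    def test_zero_data_gives_zero_components(self):
        rows = [
            ("A", "h1", "c1", 1, 50, "2020-01", 0.0),
            ("A", "h1", "c1", 1, 100, "2020-01", 0.0),
            ("B", "h1", "c1", 1, 60, "2020-01", 0.0),
            ("B", "h1", "c1", 1, 110, "2020-01", 0.0),
        ]
        model = RepeatabilityModel(sigma2_a=0.1, sigma2_h=0.1, sigma2_e=0.1)
        adj = model.fit(make_records(rows)).adjust()
        assert np.allclose(adj[["ife", "are", "hre", "afp"]], 0.0, atol=1e-12)

    def test_blup_accuracy_grows_with_records(self):
        # over 20 replicates, corr(a_hat, true BV + PE) should be higher
        # with 8 records per cow than with 2
        def mean_corr(n_rec, seeds):
            out = []
            for s in seeds:
                cfg = SimConfig(
                    n_herds=10,
                    herd_size_distribution=(0, 0, 0, 1.0),
                    n_snps=200,
                    mixture_proportions=(0.6, 0.2, 0.1, 0.1),
                    records_per_lactation=n_rec,
                    seed=s,
                    fixed_effect_sd={"lactation": 0.0, "cdc": 0.0, "year_month": 0.0},
                )
                records, geno, truth, herds = simulate_population(cfg)
                m = RepeatabilityModel(sigma2_a=0.012, sigma2_h=1e-4, sigma2_e=0.106)
                m.fit(records)
                a = m.a_.loc[list(herds["animal_id"])].to_numpy()
                out.append(np.corrcoef(a, truth.true_breeding_values)[0, 1])
            return float(np.mean(out))

        seeds = range(100, 120)
        assert mean_corr(8, seeds) > mean_corr(2, seeds)
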