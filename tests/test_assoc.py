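"""SSU gene-based score test, quadratic-form p-values, SMA, Welch contrast."""

import numpy as np
import pytest
from scipy import stats

from genepath import (
    SimulationConfig,
    chi2_quadform_pvalue,
    contrast_genotype_groups,
    project_out_covariates,
    run_gbst,
    run_sma,
    simulate_cohort,
    ssu_permutation_pvalue,
    ssu_test,
)

INTERCEPT4 = np.ones((4, 1))


class TestProjection:
    def test_hand_worked_intercept_projection(self):
        fit = project_out_covariates([1, 2, 3, 4], INTERCEPT4)
        np.testing.assert_allclose(fit.residuals, [-1.5, -0.5, 0.5, 1.5])
        assert fit.sigma2 == pytest.approx(1.25)
        assert fit.rank == 1

    def test_residuals_orthogonal_to_covariates(self, rng):
        Z = rng.standard_normal((60, 4))
        Z[:, 0] = 1.0
        y = rng.standard_normal(60)
        fit = project_out_covariates(y, Z)
        assert np.abs(Z.T @ fit.residuals).max() < 1e-8 * np.linalg.norm(y)

    def test_phenotype_in_covariate_span_rejected(self):
        Z = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="span"):
            project_out_covariates(2.0 + 3.0 * np.arange(5.0), Z)

    def test_ml_scale_divides_by_n(self, rng):
        y = rng.standard_normal(30)
        fit = project_out_covariates(y, np.ones((30, 1)))
        assert fit.sigma2 == pytest.approx(np.sum((y - y.mean()) ** 2) / 30)


class TestSsu:
    def test_hand_worked_single_snp(self):
        """Z = intercept, y = (1,2,3,4), x = (0,1,1,2)."""
        fit = project_out_covariates([1, 2, 3, 4], INTERCEPT4)
        res = ssu_test(fit, np.array([0.0, 1.0, 1.0, 2.0]))
        assert fit.sigma2 == pytest.approx(1.25)
        assert res.u[0] * fit.sigma == pytest.approx(3.0)
        assert res.c_diag[0] == pytest.approx(2.0)
        assert res.ssu == pytest.approx(3.6)
        assert res.c1 == pytest.approx(1.0, abs=1e-6)

    def test_m1_reduces_to_squared_marginal_score(self, rng):
        """For one SNP, SSU is the squared score and p the chi2_1 tail."""
        n = 120
        Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
        x = rng.integers(0, 3, n).astype(float)
        y = rng.standard_normal(n)
        fit = project_out_covariates(y, Z)
        res = ssu_test(fit, x)
        q = fit.basis
        xp = x - q @ (q.T @ x)
        score = (x @ fit.residuals) / fit.sigma
        assert res.ssu == pytest.approx(score**2 / (xp @ xp))
        assert res.p_asymptotic == pytest.approx(
            stats.chi2.sf(res.ssu, 1), abs=1e-10
        )

    def test_orthogonal_equal_diagonal_matches_chi2_m(self, rng):
        """Orthogonal projected columns of equal norm: SSU = U^t C^-1 U."""
        n, m = 64, 4
        # orthogonal columns with equal norms, orthogonal to the intercept
        basis = np.linalg.qr(rng.standard_normal((n, m + 1)))[0]
        ones = np.ones(n) / np.sqrt(n)
        X = basis[:, 1:] - np.outer(ones, ones @ basis[:, 1:])
        X = np.linalg.qr(X)[0] * 3.0
        y = rng.standard_normal(n)
        fit = project_out_covariates(y, np.ones((n, 1)))
        res = ssu_test(fit, X)
        C = X.T @ X  # already projected
        u = (X.T @ fit.residuals) / fit.sigma
        standard = u @ np.linalg.solve(C, u)
        assert res.ssu == pytest.approx(standard)
        assert res.p_asymptotic == pytest.approx(
            stats.chi2.sf(res.ssu, m), rel=1e-6
        )

    def test_scale_invariance(self, rng):
        n = 80
        Z = np.ones((n, 1))
        X = rng.integers(0, 3, (n, 6)).astype(float)
        y = rng.standard_normal(n)
        r1 = ssu_test(project_out_covariates(y, Z), X)
        r2 = ssu_test(project_out_covariates(1000.0 * y, Z), X)
        assert r1.ssu == pytest.approx(r2.ssu)
        assert r1.p_asymptotic == pytest.approx(r2.p_asymptotic)

    def test_degenerate_columns_dropped(self, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.integers(0, 3, n).astype(float)])
        fit = project_out_covariates(rng.standard_normal(n), np.ones((n, 1)))
        res = ssu_test(fit, X)
        assert res.n_dropped == 1 and res.m == 1

    def test_all_degenerate_reports_reason(self, rng):
        n = 50
        fit = project_out_covariates(rng.standard_normal(n), np.ones((n, 1)))
        res = ssu_test(fit, np.ones((n, 2)))
        assert res.p_asymptotic is None
        assert "degenerate" in res.note


class TestQuadformPvalue:
    def test_single_eigenvalue_is_chi2_1(self):
        assert chi2_quadform_pvalue(3.841, [1.0]) == pytest.approx(0.05, abs=5e-4)

    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_unit_eigenvalues_give_chi2_k(self, k):
        q = stats.chi2.ppf(0.9, k)
        assert chi2_quadform_pvalue(q, [1.0] * k) == pytest.approx(0.1, rel=1e-6)

    def test_monte_carlo_oracle(self, rng):
        """Cumulant match vs simulation of sum(lambda_i z_i^2), lam=(2,1,0.5)."""
        lam = np.array([2.0, 1.0, 0.5])
        draws = lam @ rng.standard_normal((3, 200_000)) ** 2
        q95 = np.quantile(draws, 0.95)
        assert chi2_quadform_pvalue(q95, lam) == pytest.approx(0.05, abs=0.005)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            chi2_quadform_pvalue(1.0, [])
        with pytest.raises(ValueError):
            chi2_quadform_pvalue(-1.0, [1.0])


class TestPermutationPvalue:
    def test_bounds_and_determinism(self, rng):
        n = 60
        X = rng.integers(0, 3, (n, 4)).astype(float)
        y = rng.standard_normal(n)
        Z = np.ones((n, 1))
        p1 = ssu_permutation_pvalue(y, X, Z, n_perm=200, seed=9)
        p2 = ssu_permutation_pvalue(y, X, Z, n_perm=200, seed=9)
        assert p1 == p2
        assert 1 / 201 <= p1 <= 1.0

    def test_agrees_with_asymptotic(self, rng):
        """Asymptotic and permutation p within 0.02 in the mid range."""
        n = 300
        diffs = []
        for _ in range(5):
            X = rng.integers(0, 3, (n, 8)).astype(float)
            y = rng.standard_normal(n)
            Z = np.ones((n, 1))
            fit = project_out_covariates(y, Z)
            res = ssu_test(fit, X)
            if not 0.01 <= res.p_asymptotic <= 0.5:
                continue
            p_perm = ssu_permutation_pvalue(y, X, Z, n_perm=2000, seed=3)
            diffs.append(abs(res.p_asymptotic - p_perm))
        assert diffs and max(diffs) <= 0.02


class TestGbstRuns:
    def test_planted_gene_ranks_first(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_samples=300, group_sizes=(225, 75), fst=0.02,
                n_genes=40, snps_per_gene=(8, 15), intergenic_snps=0,
                ld_rho=0.5, causal_genes=((3, 8, 0.25),), n_pathways=0,
                seed=seed,
            )
            cohort = simulate_cohort(cfg)
            from genepath import map_snps_to_genes, build_covariate_matrix

            gene_map = map_snps_to_genes(cohort.genotypes, cohort.genes)
            group = (cohort.phenotypes.frame["group"] == 0).to_numpy()
            Z = build_covariate_matrix(300, group.astype(float))
            y = cohort.phenotypes.frame["nefa_T2"].to_numpy()
            tab = run_gbst(cohort.genotypes.dosage, gene_map, y, Z,
                           genes=cohort.genes)
            best = tab.loc[tab["p_asymptotic"].idxmin(), "gene_id"]
            if best == "GENE0003":
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_permuted_phenotype_destroys_signal(self, small_cohort, rng):
        from genepath import map_snps_to_genes, build_covariate_matrix

        cohort = small_cohort
        gene_map = map_snps_to_genes(cohort.genotypes, cohort.genes)
        group = (cohort.phenotypes.frame["group"] == 0).to_numpy()
        Z = build_covariate_matrix(cohort.genotypes.n_samples, group.astype(float))
        y = cohort.phenotypes.frame["nefa_T2"].to_numpy()
        obs = run_gbst(cohort.genotypes.dosage, gene_map, y, Z).set_index("gene_id")
        assert obs.loc["GENE0007", "p_asymptotic"] < 1e-4
        destroyed = 0
        for _ in range(10):
            yp = rng.permutation(y)
            tab = run_gbst(cohort.genotypes.dosage, gene_map, yp, Z).set_index("gene_id")
            if tab.loc["GENE0007", "p_asymptotic"] > 0.05:
                destroyed += 1
        assert destroyed >= 9

    def test_row_per_mapped_gene_in_genomic_order(self, small_cohort):
        from genepath import map_snps_to_genes, build_covariate_matrix

        cohort = small_cohort
        gene_map = map_snps_to_genes(cohort.genotypes, cohort.genes)
        group = (cohort.phenotypes.frame["group"] == 0).to_numpy()
        Z = build_covariate_matrix(cohort.genotypes.n_samples, group.astype(float))
        y = cohort.phenotypes.frame["glucose_T1"].to_numpy()
        tab = run_gbst(cohort.genotypes.dosage, gene_map, y, Z, genes=cohort.genes)
        assert len(tab) == len(gene_map)
        key = list(zip(tab["chromosome"], tab["start"]))
        assert key == sorted(key)


class TestSma:
    def test_null_p_uniform(self, null_cohort):
        from genepath import build_covariate_matrix

        cohort = null_cohort
        group = (cohort.phenotypes.frame["group"] == 0).to_numpy()
        Z = build_covariate_matrix(cohort.genotypes.n_samples, group.astype(float))
        y = cohort.phenotypes.frame["bhba_T1"].to_numpy()
        tab = run_sma(cohort.genotypes, y, Z)
        p = tab["p"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_large_effect_snp_found(self):
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_samples=300, group_sizes=(225, 75), fst=0.0,
                n_genes=30, snps_per_gene=(5, 10), intergenic_snps=0,
                causal_genes=((4, 1, 0.8),), n_pathways=0, seed=seed,
            )
            cohort = simulate_cohort(cfg)
            from genepath import build_covariate_matrix

            group = (cohort.phenotypes.frame["group"] == 0).to_numpy()
            Z = build_covariate_matrix(300, group.astype(float))
            y = cohort.phenotypes.frame["nefa_T2"].to_numpy()
            tab = run_sma(cohort.genotypes, y, Z)
            best = tab.loc[tab["p"].idxmin(), "snp_id"]
            if best in cohort.truth.causal_snps:
                hits += 1
        assert hits >= 9

    def test_m1_gene_agrees_with_gbst(self, rng):
        """Score test and t test converge for a single SNP at n >= 200."""
        n = 240
        Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
        x = rng.integers(0, 3, (n, 1)).astype(float)
        y = rng.standard_normal(n) + 0.1 * x[:, 0]
        fit = project_out_covariates(y, Z)
        p_gbst = ssu_test(fit, x).p_asymptotic
        p_sma = run_sma(x, y, Z)["p"].iloc[0]
        assert abs(p_gbst - p_sma) < 0.01

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        n = 80
        Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
        x = rng.integers(0, 3, (n, 3)).astype(float)
        y = rng.standard_normal(n)
        tab = run_sma(x, y, Z)
        for j in range(3):
            fit = sm.OLS(y, np.column_stack([Z, x[:, j]])).fit()
            assert tab["t"].iloc[j] == pytest.approx(fit.tvalues[-1], rel=1e-8)
            assert tab["p"].iloc[j] == pytest.approx(fit.pvalues[-1], rel=1e-8)


class TestWelchContrast:
    def test_textbook_example(self):
        a = [1, 2, 3, 4, 5]
        b = [2, 3, 4, 5, 6]
        values = np.array(a + b, dtype=float)
        mask_a = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        t, df, p = contrast_genotype_groups(values, mask_a, ~mask_a)
        # hand evaluation: equal variances 2.5, se = 1, t = -1, df = 8
        assert t == pytest.approx(-1.0)
        assert df == pytest.approx(8.0)
        assert p == pytest.approx(2 * stats.t.sf(1.0, 8.0))

    def test_label_swap_flips_sign(self, rng):
        values = rng.standard_normal(30)
        mask = np.zeros(30, bool)
        mask[:12] = True
        t1, _, p1 = contrast_genotype_groups(values, mask, ~mask)
        t2, _, p2 = contrast_genotype_groups(values, ~mask, mask)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_identical_groups(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        mask = np.array([1, 1, 1, 0, 0, 0], bool)
        t, _, p = contrast_genotype_groups(values, mask, ~mask)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            contrast_genotype_groups(
                np.arange(5.0), np.array([1, 0, 0, 0, 0], bool),
                np.array([0, 1, 1, 1, 1], bool),
            )
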