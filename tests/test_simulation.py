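"""Generators and the study engine: moments, MAR, engine-vs-API equivalence."""

import numpy as np
import pytest
from scipy.stats import kstest

from longkmt.pathway import AnnotationMap
from longkmt.simulate import (
    SimulationConfig,
    StudyModel,
    _draw_arrays,
    _mar_mask,
    _MatrixContext,
    _replicate_pvalue,
    _to_dataset,
    apply_mar,
    draw_subsample,
    gene_level_fisher_comparison,
    make_simulation_network,
    run_study,
    simulate_genotypes,
    simulate_phenotypes,
)


class TestGenotypes:
    def test_independent_model_maf_concentration(self):
        gm = simulate_genotypes(
            10_000, 4, 25, seed=51, genotype_model="independent"
        )
        rng = np.random.default_rng(51)
        drawn = rng.uniform(0.05, 0.5, size=100)
        np.testing.assert_allclose(gm.maf(), drawn, atol=0.02)
        np.testing.assert_allclose(gm.values.mean(axis=0), 2 * drawn, atol=0.04)

    def test_seed_reproducibility(self):
        a = simulate_genotypes(50, 2, 5, seed=3, genotype_model="independent")
        b = simulate_genotypes(50, 2, 5, seed=3, genotype_model="independent")
        np.testing.assert_array_equal(a.values, b.values)

    def test_haplotype_model_common_variants(self):
        gm = simulate_genotypes(300, 2, 10, seed=4, genotype_model="haplotype")
        assert gm.values.shape == (300, 20)
        assert (gm.values >= 0).all() and (gm.values <= 2).all()
        assert (gm.maf() >= 0.02).all()  # drawn common, sampling noise allowed

    def test_subsample_rows_and_maf(self):
        elem = simulate_genotypes(2000, 3, 10, seed=5, genotype_model="independent")
        sub = draw_subsample(elem, 400, seed=6)
        assert sub.values.shape == (400, 30)
        sub2 = draw_subsample(elem, 400, seed=6)
        np.testing.assert_array_equal(sub.values, sub2.values)
        # subsampled MAFs stay within binomial noise of the source
        se = np.sqrt(elem.maf() * (1 - elem.maf()) / (2 * 400))
        assert (np.abs(sub.maf() - elem.maf()) < 5 * se + 0.01).all()

    def test_full_subsample_is_permutation(self):
        elem = simulate_genotypes(100, 2, 5, seed=7, genotype_model="independent")
        sub = draw_subsample(elem, 100, seed=8)
        assert sub.values.sum() == elem.values.sum()


class TestPhenotypes:
    def test_marginal_moments_match_closed_form(self):
        """Var(y_t0) = s2_int + s2_eps = 2; Cov(y_t0, y_t1) = s2_int + s_cov."""
        gm = simulate_genotypes(100_000, 1, 2, seed=9, genotype_model="independent")
        cfg = SimulationConfig(n_subjects=100_000, m=2)
        rng = np.random.default_rng(10)
        X1, X2, Y = _draw_arrays(gm.values, 2, cfg, rng)
        t = np.arange(2)
        fixed = 0.5 * X1[:, None] + 0.25 * X2[:, None] + 0.2 * t[None, :]
        u = Y - fixed  # random effects + residual only
        assert u[:, 0].var() == pytest.approx(2.0, abs=0.05)
        cov01 = np.cov(u[:, 0], u[:, 1])[0, 1]
        assert cov01 == pytest.approx(0.5, abs=0.05)

    def test_zero_beta_reduces_to_null(self):
        gm = simulate_genotypes(200, 2, 5, seed=11, genotype_model="independent")
        a = simulate_phenotypes(
            gm, SimulationConfig(n_subjects=200, m=2, effect="main", beta=0.0), seed=12
        )
        b = simulate_phenotypes(
            gm, SimulationConfig(n_subjects=200, m=2, effect="null"), seed=12
        )
        np.testing.assert_array_equal(a.table["y"], b.table["y"])

    def test_non_psd_variance_config_rejected(self):
        cfg = SimulationConfig(cov_intercept_time=-1.5)
        with pytest.raises(ValueError):
            cfg.random_effect_cov()

    def test_causal_columns_deterministic(self):
        cfg = SimulationConfig(causal_genes=(0, 2), causal_snps_per_gene=2)
        np.testing.assert_array_equal(cfg.causal_columns(10), [0, 1, 20, 21])


class TestMar:
    def test_zero_fraction_unchanged(self, small_dataset):
        assert apply_mar(small_dataset, 0.0, seed=1) is small_dataset

    def test_calibrated_share_and_baseline_retained(self):
        rng = np.random.default_rng(13)
        X1 = rng.binomial(1, 0.5, 10_000).astype(float)
        X2 = rng.normal(50, 5, 10_000)
        mask = _mar_mask(X1, X2, 4, 0.25, rng)
        assert mask[:, 0].all()
        realized = 1 - mask[:, 1:].mean()
        assert realized == pytest.approx(0.25, abs=0.005)

    def test_missingness_is_mar(self):
        """Dropout must not depend on the removed y beyond (X1, X2, t)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(14)
        n = 10_000
        X1 = rng.binomial(1, 0.5, n).astype(float)
        X2 = rng.normal(50, 5, n)
        cfg = SimulationConfig(n_subjects=n, m=2)
        _, _, Y = _draw_arrays(np.zeros((n, 1)), 1, cfg, rng)
        mask = _mar_mask(X1, X2, 2, 0.3, rng)
        miss = (~mask[:, 1]).astype(float)
        # residualize the (removed or not) y(t=1) on the observed covariates
        Z = sm.add_constant(np.column_stack([X1, X2]))
        resid = Y[:, 1] - Z @ np.linalg.lstsq(Z, Y[:, 1], rcond=None)[0]
        fit = sm.Logit(miss, sm.add_constant(np.column_stack([X1, X2, resid]))).fit(
            disp=0
        )
        assert abs(fit.tvalues[-1]) < 3

    def test_invalid_fraction_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            apply_mar(small_dataset, 0.95, seed=1)


class TestStudyEngine:
    def test_alpha_one_rejects_everything(self):
        out = run_study(
            [StudyModel("null", "linear", m=2)],
            n_subjects=60,
            n_matrices=1,
            reps_per_matrix=5,
            n_genes=2,
            snps_per_gene=4,
            elementary_size=200,
            seed=3,
            alphas=(1.0,),
            genotype_model="independent",
        )
        assert out.loc[0, "reject@1"] == 1.0

    def test_fast_paths_match_generic_api(
        self, small_genotypes, small_network, small_annotation
    ):
        """The study engine's optimized routes reproduce test_pathway /
        q_cross_test p-values exactly (complete, MAR, network, ANCOVA)."""
        from longkmt.score_test import q_cross_test, test_pathway

        cfg = SimulationConfig(n_subjects=150, m=3)
        rng = np.random.default_rng(61)
        X1, X2, Y = _draw_arrays(small_genotypes.values, 6, cfg, rng)
        mask = np.ones(Y.shape, bool)
        ctx = _MatrixContext(small_genotypes.values, 6)
        ds = _to_dataset(X1, X2, Y, mask)
        cases = [
            (StudyModel("lin", "linear", m=3), dict(kernel="linear", effect="main")),
            (
                StudyModel("int", "linear", m=3, tested_effect="interaction"),
                dict(kernel="linear", effect="interaction"),
            ),
            (
                StudyModel("net", "network", m=3, network=small_network),
                dict(
                    kernel="network",
                    effect="main",
                    annotation=small_annotation,
                    network=small_network,
                ),
            ),
        ]
        for model, kwargs in cases:
            p_fast = _replicate_pvalue(
                model, ctx, small_annotation, X1, X2, Y, mask
            )
            p_gen = test_pathway(ds, small_genotypes, **kwargs).p_value
            assert p_fast == pytest.approx(p_gen, rel=1e-5)
        # MAR route
        mask2 = _mar_mask(X1, X2, 3, 0.25, np.random.default_rng(62))
        ds2 = _to_dataset(X1, X2, Y, mask2)
        p_fast = _replicate_pvalue(
            StudyModel("lin", "linear", m=3), ctx, None, X1, X2, Y, mask2
        )
        p_gen = test_pathway(ds2, small_genotypes, kernel="linear").p_value
        assert p_fast == pytest.approx(p_gen, rel=1e-6)
        # ANCOVA route
        cfg2 = SimulationConfig(n_subjects=150, m=2)
        X1b, X2b, Yb = _draw_arrays(
            small_genotypes.values, 6, cfg2, np.random.default_rng(63)
        )
        ds3 = _to_dataset(X1b, X2b, Yb, np.ones(Yb.shape, bool))
        p_fast = _replicate_pvalue(
            StudyModel("anc", "linear", m=2, analysis="ancova"),
            ctx, None, X1b, X2b, Yb, np.ones(Yb.shape, bool),
        )
        p_gen = q_cross_test(ds3, small_genotypes, kernel="linear").p_value
        assert p_fast == pytest.approx(p_gen, rel=1e-6)

    def test_kpca_shortcut_matches_observation_level_definition(
        self, small_genotypes
    ):
        """For complete data the subject-level KPCA columns equal the
        observation-level double-centered kernel components."""
        from longkmt.kernels import kpca_components, linear_kernel

        ctx = _MatrixContext(small_genotypes.values, 6)
        fast = ctx.kpca()
        m = 3
        n = small_genotypes.n_subjects
        idx = np.repeat(np.arange(n), m)
        K_obs = linear_kernel(small_genotypes.values[idx]).values
        obs_comps = kpca_components(K_obs, 2)
        # eigenvectors are v (x) 1_m / sqrt(m) with eigenvalue m * mu, so the
        # sqrt(eigenvalue)-scaled components equal the subject components
        # repeated over observations
        np.testing.assert_allclose(
            obs_comps, np.repeat(fast, m, axis=0), atol=1e-6
        )


class TestGeneLevelComparison:
    def test_single_gene_equals_gene_pvalue(self, small_genotypes, small_dataset):
        from longkmt.data import GenotypeMatrix
        from longkmt.score_test import test_pathway

        cols = np.flatnonzero(small_genotypes.gene_index == 0)
        p_combined = gene_level_fisher_comparison(
            small_dataset, small_genotypes, gene_partition=[cols]
        )
        sub = GenotypeMatrix(
            small_genotypes.values[:, cols],
            [small_genotypes.snp_ids[c] for c in cols],
        )
        p_gene = test_pathway(small_dataset, sub).p_value
        assert p_combined == pytest.approx(p_gene, rel=1e-9)

    def test_null_uniformity(self, small_genotypes):
        """Fisher-combined gene-level p-values are uniform under the null."""
        pvals = []
        for rep in range(120):
            ds = simulate_phenotypes(
                small_genotypes,
                SimulationConfig(n_subjects=150, m=2),
                seed=700 + rep,
            )
            pvals.append(gene_level_fisher_comparison(ds, small_genotypes))
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestSimulationNetwork:
    def test_density_and_centrality(self):
        for d in (0.2, 0.46, 0.8):
            net = make_simulation_network(19, density=d, seed=2023)
            assert abs(net.density - d) <= 1 / 171 + 1e-12
            deg = net.degrees()
            med = np.median(deg)
            assert all(deg[i] >= med for i in (0, 1, 2))
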