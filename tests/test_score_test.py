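"""Score statistics, null eigenvalues, and the pathway test orchestration."""

import numpy as np
import pytest

from longkmt.longitudinal import fit_null_lmm
from longkmt.score_test import (
    _eigenvalues_factored,
    mixture_pvalue,
    null_eigenvalues,
    q_cross_test,
    q_long,
)
from longkmt.score_test import test_pathway as pathway_test


class TestQLong:
    def test_identity_cases(self):
        assert q_long([1, 1], np.ones((2, 1)), [0.0], np.eye(2), np.eye(2)) == 1.0
        K = np.ones((2, 2))
        assert q_long([1, -1], np.ones((2, 1)), [0.0], np.eye(2), K) == 0.0

    def test_matches_brute_force_quadratic_form(self):
        rng = np.random.default_rng(0)
        n = 6
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta = rng.standard_normal(2)
        A = rng.standard_normal((n, n))
        Sigma = A @ A.T + n * np.eye(n)
        G = rng.standard_normal((n, 3))
        K = G @ G.T
        Si = np.linalg.inv(Sigma)
        r = y - X @ beta
        expected = 0.5 * r @ Si @ K @ Si @ r  # independent dense evaluation
        assert q_long(y, X, beta, Si, K) == pytest.approx(expected, rel=1e-12)

    def test_nonconformable_errors(self):
        with pytest.raises(ValueError):
            q_long([1, 2, 3], np.ones((2, 1)), [0.0], np.eye(2), np.eye(2))


class TestNullEigenvalues:
    def test_centering_closed_form(self):
        # Sigma = I, X = intercept, K = I: V0 = I - J/n, eigenvalues {1/2 x (n-1), 0}
        n = 3
        lam = null_eigenvalues(np.eye(n), np.ones((n, 1)), np.eye(n))
        np.testing.assert_allclose(lam, [0.5, 0.5], atol=1e-10)

    def test_linear_in_kernel_scale(self):
        rng = np.random.default_rng(1)
        n = 8
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        K = rng.standard_normal((n, 4))
        K = K @ K.T
        lam1 = null_eigenvalues(np.eye(n), X, K)
        lam3 = null_eigenvalues(np.eye(n), X, 3.0 * K)
        np.testing.assert_allclose(lam3, 3.0 * lam1, rtol=1e-10)

    def test_low_rank_path_equals_dense(self, small_dataset, small_genotypes):
        fit = fit_null_lmm(small_dataset)
        subj, t, y, X = small_dataset.design()
        B = small_genotypes.values[subj][:, :12]
        lam_fast = _eigenvalues_factored(fit, B)
        lam_dense = null_eigenvalues(fit.sigma0_dense(), fit.X, B @ B.T)
        assert lam_fast.size == lam_dense.size
        scale = lam_dense.max()
        np.testing.assert_allclose(lam_fast, lam_dense, atol=1e-8 * scale)

    def test_indefinite_sigma_rejected_via_v0(self):
        n = 4
        Sigma = np.diag([1.0, 1.0, 1.0, -0.3])  # invalid marginal covariance
        X = np.eye(n)[:, :1]  # leaves the negative direction untouched
        with pytest.raises(ValueError, match="V0"):
            null_eigenvalues(Sigma, X, np.eye(n))


class TestMixturePvalue:
    def test_chi_square_reference_points(self):
        p, _ = mixture_pvalue(3.841459, [1.0])
        assert p == pytest.approx(0.05, abs=1e-5)
        p, _ = mixture_pvalue(11.9829, [2.0, 2.0])
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_zero_eigenvalues_error(self):
        with pytest.raises(ValueError):
            mixture_pvalue(1.0, [])


class TestTestPathway:
    def test_deterministic(self, small_dataset, small_genotypes):
        r1 = pathway_test(small_dataset, small_genotypes, kernel="linear")
        r2 = pathway_test(small_dataset, small_genotypes, kernel="linear")
        assert r1.Q == r2.Q and r1.p_value == r2.p_value

    def test_pvalue_invariant_to_kernel_scale(self, small_dataset, small_genotypes):
        res1 = pathway_test(small_dataset, small_genotypes, kernel="linear")
        scaled = small_genotypes.values * 0.5  # K scales by 0.25
        from longkmt.data import GenotypeMatrix

        gm2 = GenotypeMatrix(scaled, list(small_genotypes.snp_ids))
        res2 = pathway_test(small_dataset, gm2, kernel="linear")
        assert res2.p_value == pytest.approx(res1.p_value, rel=1e-6)
        assert res2.Q == pytest.approx(res1.Q * 0.25, rel=1e-8)

    def test_network_kernel_matches_linear_for_unit_genes(
        self, small_dataset, small_genotypes
    ):
        # one SNP per gene and N = I collapse the network kernel to the
        # linear kernel on those SNPs
        from longkmt.data import GenotypeMatrix
        from longkmt.pathway import AnnotationMap, PathwayNetwork

        first = [np.flatnonzero(small_genotypes.gene_index == g)[0] for g in range(5)]
        sub = GenotypeMatrix(
            small_genotypes.values[:, first],
            [small_genotypes.snp_ids[c] for c in first],
        )
        genes = [f"g{i + 1}" for i in range(5)]
        iso = PathwayNetwork(genes, set())
        ann = AnnotationMap(list(sub.snp_ids), genes, np.eye(5))
        res_net = pathway_test(
            small_dataset, sub, kernel="network", annotation=ann, network=iso
        )
        res_lin = pathway_test(small_dataset, sub, kernel="linear")
        assert res_net.p_value == pytest.approx(res_lin.p_value, rel=1e-8)
        assert res_net.Q == pytest.approx(res_lin.Q, rel=1e-10)

    def test_interaction_needs_varying_time(self, small_genotypes):
        import pandas as pd

        from longkmt.longitudinal import LongitudinalDataset

        n = small_genotypes.n_subjects
        table = pd.DataFrame(
            {
                "subject_id": np.repeat(np.arange(n), 2),
                "time": 0,
                "y": np.random.default_rng(0).normal(size=2 * n),
            }
        )
        table = table.drop_duplicates(["subject_id", "time"])
        ds = LongitudinalDataset(table)
        with pytest.raises(ValueError):
            pathway_test(ds, small_genotypes, effect="interaction")

    def test_quadratic_kernel_runs(self, small_dataset, small_genotypes):
        res = pathway_test(small_dataset, small_genotypes, kernel="quadratic")
        assert 0 < res.p_value <= 1
        assert res.kernel == "quadratic"

    def test_adjusted_interaction_deflates_main_effect_confounding(
        self, small_genotypes
    ):
        """On data with a pure main genetic effect, KPCA adjustment should
        stochastically enlarge interaction p-values relative to unadjusted."""
        from longkmt.simulate import SimulationConfig, simulate_phenotypes

        cfg = SimulationConfig(
            n_subjects=150, m=2, effect="main", beta=0.25,
            causal_genes=(0, 1, 2), causal_snps_per_gene=3,
        )
        p_unadj, p_adj = [], []
        for rep in range(15):
            ds = simulate_phenotypes(small_genotypes, cfg, seed=100 + rep)
            p_unadj.append(
                pathway_test(ds, small_genotypes, effect="interaction").p_value
            )
            p_adj.append(
                pathway_test(
                    ds, small_genotypes, effect="interaction_adjusted"
                ).p_value
            )
        assert np.median(p_adj) >= np.median(p_unadj)


class TestQCross:
    def test_scale_consistency_of_reported_pair(
        self, small_dataset_m2, small_genotypes
    ):
        res = q_cross_test(small_dataset_m2, small_genotypes, kernel="linear")
        # reported (Q, eigenvalues) must reproduce the reported p-value
        p_check, _ = mixture_pvalue(res.Q, res.eigenvalues)
        assert p_check == pytest.approx(res.p_value, rel=1e-9)

    def test_interaction_label_scale_invariant(
        self, small_dataset_m2, small_genotypes
    ):
        a = q_cross_test(small_dataset_m2, small_genotypes, effect="main")
        b = q_cross_test(small_dataset_m2, small_genotypes, effect="interaction")
        assert b.p_value == pytest.approx(a.p_value, rel=1e-9)
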