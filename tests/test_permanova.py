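"""Gower centering, the pseudo-F statistic, and the permutation engine."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ideas import AnalysisConfig, gower_center, permutation_test, pseudo_F
from ideas import test_gene as run_gene_test


def dense_pseudo_F(G, Z):
    """Independent dense-matrix evaluation of the trace-ratio statistic."""
    H = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
    I = np.eye(len(G))
    return np.trace(H @ G @ H) / np.trace((I - H) @ G @ (I - H))


def euclid_D(x):
    x = np.asarray(x, dtype=float)
    return np.abs(x[:, None] - x[None, :])


class TestGowerCenter:
    def test_two_by_two_closed_form(self):
        d = 3.0
        G = gower_center(np.array([[0.0, d], [d, 0.0]])).G
        np.testing.assert_allclose(G, (d**2 / 4) * np.array([[1, -1], [-1, 1]]), atol=1e-12)

    def test_zero_distances_give_zero_kernel(self):
        G = gower_center(np.zeros((5, 5))).G
        np.testing.assert_allclose(G, 0.0, atol=1e-15)

    def test_line_embedding_is_rank_one_and_psd_before_truncation(self):
        # classical MDS: Euclidean distances from points on a line double-center
        # to a PSD rank-1 kernel even before truncation
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2, 8)
        D = euclid_D(x)
        A = -0.5 * D**2
        C = np.eye(8) - np.ones((8, 8)) / 8
        raw = C @ A @ C
        vals = np.linalg.eigvalsh(raw)
        assert vals.min() > -1e-10
        assert (vals > 1e-8 * vals.max()).sum() == 1
        np.testing.assert_allclose(gower_center(D).G, raw, atol=1e-10)

    def test_contract_centered_and_psd(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(7, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        K = gower_center(D)
        scale = np.abs(K.G).max() * 7
        assert np.abs(K.G.sum(axis=0)).max() < 1e-10 * scale
        assert np.linalg.eigvalsh(K.G).min() >= -1e-10

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            gower_center(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestPseudoF:
    def test_intercept_only_design_gives_zero(self):
        G = gower_center(euclid_D([1.0, 4.0, 2.0, 8.0]))
        F = pseudo_F(G, np.ones((4, 1)))
        assert abs(F) < 1e-12

    def test_separated_pairs_match_dense_oracle(self):
        G = gower_center(euclid_D([0.0, 0.1, 10.0, 10.1]))
        Z = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        F = pseudo_F(G, Z)
        assert F > 10
        np.testing.assert_allclose(F, dense_pseudo_F(G.G, Z), rtol=1e-10)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        G = gower_center(euclid_D(rng.normal(size=9)))
        Z = np.column_stack([np.ones(9), rng.normal(size=9)])
        F = pseudo_F(G, Z)
        perm = rng.permutation(9)
        F_perm = pseudo_F(G.G[np.ix_(perm, perm)], Z[perm])
        np.testing.assert_allclose(F_perm, F, rtol=1e-12)

    def test_saturated_design_is_nan(self):
        # rank-1 Euclidean kernel from x itself is fully explained by a design
        # containing x: the residual trace vanishes and the test is degenerate
        x = np.array([0.0, 1.0, 2.0, 5.0])
        G = gower_center(euclid_D(x))
        Z = np.column_stack([np.ones(4), x])
        assert np.isnan(pseudo_F(G, Z))

    def test_rank_deficient_design_rejected(self):
        G = gower_center(euclid_D([1.0, 2.0, 3.0, 4.0]))
        Z = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="rank"):
            pseudo_F(G, Z)


class TestPermutationEngine:
    def _kernel_and_design(self, rng, n=12, signal=0.0):
        x = np.array([1.0] * (n // 2) + [0.0] * (n // 2))
        values = rng.normal(0, 1, n) + signal * x
        G = gower_center(euclid_D(values))
        Z = pd.DataFrame({"status": x}, index=[f"i{j}" for j in range(n)])
        return G, Z

    def test_exhaustive_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(3)
        x = np.array([1.0, 1.0, 0.0, 0.0])
        G = gower_center(euclid_D([3.0, 2.9, 0.2, 0.0]))
        Z = pd.DataFrame({"status": x}, index=list("abcd"))
        with pytest.warns(UserWarning, match="exhaustive"):
            res = permutation_test(G, Z, "status", n_perm=999, seed=0)
        # brute force: all 6 case assignments via the dense formula
        F_all = []
        for idx in combinations(range(4), 2):
            xb = np.zeros(4)
            xb[list(idx)] = 1.0
            F_all.append(dense_pseudo_F(G.G, np.column_stack([np.ones(4), xb])))
        F_obs = dense_pseudo_F(G.G, np.column_stack([np.ones(4), x]))
        tol = 1e-9 * max(1.0, abs(F_obs))  # same tie convention as the engine
        expected_p = np.mean([f >= F_obs - tol for f in F_all])
        assert res.pvalue == expected_p
        assert res.n_perm_used == 6

    def test_pvalue_floor_when_observed_is_maximal(self):
        rng = np.random.default_rng(4)
        n = 12
        x = rng.normal(size=n)  # continuous X: random-permutation path
        # kernel from x plus slight noise: near-maximal alignment without
        # saturating the design (which would make the statistic degenerate)
        G = gower_center(euclid_D(x + 0.01 * rng.normal(size=n)))
        Z = pd.DataFrame({"x": x}, index=[f"i{j}" for j in range(n)])
        res = permutation_test(G, Z, "x", n_perm=199, seed=1, adaptive=False)
        assert res.pvalue == pytest.approx(1.0 / 200.0)
        assert res.pvalue >= 1.0 / (res.n_perm_used + 1)

    def test_permuting_x_equals_permuting_kernel(self):
        # the efficiency contract: permuting X with G fixed equals relabeling
        # the kernel (and covariates) by the inverse permutation with X fixed
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(6, 15))
            G = gower_center(euclid_D(rng.normal(size=n))).G
            x, c = rng.normal(size=n), rng.normal(size=n)
            perm = rng.permutation(n)
            inv = np.argsort(perm)
            F_x = pseudo_F(G, np.column_stack([np.ones(n), c, x[perm]]))
            F_g = pseudo_F(
                G[np.ix_(inv, inv)], np.column_stack([np.ones(n), c[inv], x])
            )
            np.testing.assert_allclose(F_x, F_g, rtol=1e-12, atol=1e-12)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(300):
            G, Z = self._kernel_and_design(rng, n=14)
            res = permutation_test(G, Z, "status", n_perm=199, seed=int(rng.integers(2**31)),
                                   adaptive=False)
            pvals.append(res.pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_noise_covariate_preserves_null_uniformity(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(200):
            n = 14
            x = np.array([1.0] * 7 + [0.0] * 7)
            G = gower_center(euclid_D(rng.normal(size=n)))
            Z = pd.DataFrame(
                {"status": x, "noise": rng.normal(size=n)},
                index=[f"i{j}" for j in range(n)],
            )
            res = permutation_test(G, Z, "status", n_perm=199,
                                   seed=int(rng.integers(2**31)), adaptive=False)
            pvals.append(res.pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_resample_mode_runs_and_is_valid_under_null(self):
        rng = np.random.default_rng(8)
        rejections = 0
        for _ in range(100):
            G, Z = self._kernel_and_design(rng, n=14)
            res = permutation_test(G, Z, "status", n_perm=99,
                                   seed=int(rng.integers(2**31)), mode="resample")
            rejections += res.pvalue <= 0.05
        assert rejections / 100 <= 0.12

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        G, Z = self._kernel_and_design(rng, n=16)
        a = permutation_test(G, Z, "status", n_perm=199, seed=123)
        b = permutation_test(G, Z, "status", n_perm=199, seed=123)
        assert (a.F_obs, a.pvalue, a.n_perm_used) == (b.F_obs, b.pvalue, b.n_perm_used)


class TestGeneLevel:
    def test_ee_gene_tests_ok_and_deterministic(self, small_sim):
        data, _ = small_sim
        cfg = AnalysisConfig(n_perm=99, seed=5)
        r1 = run_gene_test(data, 0, cfg)
        r2 = run_gene_test(data, 0, cfg)
        assert r1.status in ("ok", "fit_failed")
        assert (r1.F_obs, r1.pvalue, r1.status) == (r2.F_obs, r2.pvalue, r2.status)

    def test_individual_below_min_cells_fails_gene(self, small_sim):
        data, _ = small_sim
        cfg = AnalysisConfig(n_perm=99, seed=5, min_cells=10_000)
        res = run_gene_test(data, 0, cfg)
        assert res.status == "fit_failed"
        assert np.isnan(res.pvalue)

    def test_asymptotic_mode_rejected_by_config(self):
        with pytest.raises(ValueError, match="asymptotic"):
            AnalysisConfig(mode="asymptotic")
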