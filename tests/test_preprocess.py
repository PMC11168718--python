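"""Residualization, rank standardization and cross-product construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata, spearmanr

from latentlink import (CovariateTable, DataBlock, build_cross_products,
                        correlation_matrix, inv_sqrt_psd, rank_standardize,
                        residualize, generate_covariates, generate_study,
                        SynthConfig)


def _block(values, role="brain"):
    values = np.asarray(values, float)
    if values.ndim == 1:
        values = values[:, None]
    n, p = values.shape
    return DataBlock(values, [f"P{i}" for i in range(n)],
                     [f"v{j}" for j in range(p)], role)


def _intercept_only_cov(n):
    return CovariateTable(pd.DataFrame(index=range(n)),
                          [f"P{i}" for i in range(n)])


class TestResidualize:
    def test_intercept_only_centers(self):
        rb = residualize(_block([1.0, 2.0, 3.0]), _intercept_only_cov(3))
        # residuals [-1, 0, 1] have SD 1 already, so Z-scaling is the identity
        np.testing.assert_allclose(rb.values[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_binary_covariate_group_means(self):
        cov = CovariateTable(pd.DataFrame({"g": [0.0, 0.0, 1.0, 1.0]}),
                             [f"P{i}" for i in range(4)])
        rb = residualize(_block([1.0, 2.0, 4.0, 6.0]), cov)
        # group means 1.5 and 5 -> residuals [-0.5, 0.5, -1, 1] up to Z scale
        expected = np.array([-0.5, 0.5, -1.0, 1.0])
        np.testing.assert_allclose(rb.values[:, 0],
                                   expected / expected.std(ddof=1), atol=1e-12)

    def test_residuals_orthogonal_to_design(self):
        cfg = SynthConfig(n_participants=300, n_brain=6, n_behavior=4, seed=3)
        study = generate_study(cfg)
        rb = residualize(study.brain, study.covariates)
        D, names, _ = study.covariates.design_matrix()
        for j, name in enumerate(names):
            col = D[:, j]
            if col.std() == 0:
                continue
            r = np.abs(correlation_matrix(col[:, None], rb.values, "pearson"))
            assert r.max() <= 1e-10, name

    def test_columns_standardized(self):
        cfg = SynthConfig(n_participants=200, n_brain=5, n_behavior=4, seed=9)
        study = generate_study(cfg)
        rb = residualize(study.behavior, study.covariates)
        np.testing.assert_allclose(rb.values.mean(0), 0, atol=1e-8)
        np.testing.assert_allclose(rb.values.std(0, ddof=1), 1, atol=1e-8)

    def test_affine_covariate_rescaling_invariance(self):
        cfg = SynthConfig(n_participants=150, n_brain=4, n_behavior=3, seed=5)
        study = generate_study(cfg)
        rb1 = residualize(study.brain, study.covariates)
        cov2 = CovariateTable(study.covariates.frame.assign(
            age=lambda d: 3.5 * d["age"] - 100.0),
            study.covariates.participant_ids)
        rb2 = residualize(study.brain, cov2)
        np.testing.assert_allclose(rb1.values, rb2.values, atol=1e-8)

    def test_mismatched_ids_rejected(self):
        cov = _intercept_only_cov(3)
        blk = DataBlock(np.eye(3), ["a", "b", "c"], ["v0", "v1", "v2"])
        with pytest.raises(ValueError, match="IDs"):
            residualize(blk, cov)

    def test_collinear_continuous_covariates_named(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                              "b": [2.0, 4.0, 6.0, 8.0]})
        cov = CovariateTable(frame, [f"P{i}" for i in range(4)])
        with pytest.raises(ValueError, match="collinear"):
            residualize(_block([1.0, 3.0, 2.0, 5.0]), cov)

    def test_nested_scanner_dummies_dropped_not_fatal(self):
        # sites nested within scanners alias the scanner dummies; the design
        # drops them instead of failing the whole analysis
        cov = generate_covariates(200, n_sites=10, n_scanners=3, seed=2)
        D, names, dropped = cov.design_matrix()
        assert np.linalg.matrix_rank(D) == D.shape[1]
        assert all(d.startswith("scanner") for d in dropped)


class TestRankStandardize:
    def test_sorted_input_ranks(self):
        rb = residualize(_block([10.0, 20.0, 30.0]), _intercept_only_cov(3))
        rk = rank_standardize(rb)
        expected = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(
            rk.values[:, 0],
            (expected - 2.0) / expected.std(ddof=1), atol=1e-12)

    def test_average_rank_ties(self):
        blk = _block([[5.0, 1.0], [5.0, 2.0], [7.0, 3.0]])
        rb = residualize(blk, _intercept_only_cov(3))
        # residualizing breaks the tie? no: centering preserves equality
        rk = rank_standardize(rb)
        ranks = np.array([1.5, 1.5, 3.0])
        np.testing.assert_allclose(
            rk.values[:, 0], (ranks - ranks.mean()) / ranks.std(ddof=1),
            atol=1e-12)

    def test_monotone_invariance(self):
        x = np.random.default_rng(0).normal(size=20)
        rb1 = residualize(_block(x), _intercept_only_cov(20))
        rb2 = residualize(_block(np.exp(x)), _intercept_only_cov(20))
        np.testing.assert_allclose(rank_standardize(rb1).values,
                                   rank_standardize(rb2).values, atol=1e-10)

    def test_constant_column_rejected(self):
        blk = _block([1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="constant"):
            residualize(blk, _intercept_only_cov(3))


class TestCorrelationMatrix:
    def test_monotone_pair_spearman_one(self):
        r = correlation_matrix(np.array([1.0, 2.0, 3.0]),
                               np.array([1.0, 4.0, 9.0]), "spearman")
        assert r[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("kind", ["pearson", "spearman"])
    def test_reversal_minus_one(self, kind):
        r = correlation_matrix(np.array([1.0, 2.0, 3.0]),
                               np.array([3.0, 2.0, 1.0]), kind)
        assert r[0, 0] == pytest.approx(-1.0)

    def test_spearman_equals_pearson_on_ranks_with_ties(self):
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        ours = correlation_matrix(x, y, "spearman")[0, 0]
        by_hand = correlation_matrix(rankdata(x), rankdata(y), "pearson")[0, 0]
        assert ours == pytest.approx(by_hand, abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_spearman_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        # small integers force ties
        x = rng.integers(0, 4, size=20).astype(float)
        y = rng.integers(0, 4, size=20).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        ours = correlation_matrix(x, y, "spearman")[0, 0]
        ref = spearmanr(x, y).statistic
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_entries_bounded(self):
        rng = np.random.default_rng(1)
        R = correlation_matrix(rng.normal(size=(50, 4)),
                               rng.normal(size=(50, 3)), "spearman")
        assert np.all(np.abs(R) <= 1.0)


class TestInvSqrtPsd:
    def test_identity(self):
        np.testing.assert_allclose(inv_sqrt_psd(np.eye(4)), np.eye(4),
                                   atol=1e-12)

    def test_diagonal(self):
        np.testing.assert_allclose(inv_sqrt_psd(np.diag([4.0, 9.0])),
                                   np.diag([0.5, 1.0 / 3.0]), atol=1e-12)

    def test_roundtrip_spd(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(3, 3))
        M = A @ A.T + 0.5 * np.eye(3)
        K = inv_sqrt_psd(M)
        np.testing.assert_allclose(K @ M @ K, np.eye(3), atol=1e-10)

    def test_not_psd_rejected(self):
        with pytest.raises(ValueError, match="PSD"):
            inv_sqrt_psd(np.diag([1.0, -1.0]))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            inv_sqrt_psd(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestBuildCrossProducts:
    def test_identity_within_block_means_no_adjustment(self):
        rng = np.random.default_rng(3)
        # orthonormalized centered columns -> within-block correlations are
        # exactly identity, so the whitening step is a no-op
        Gx = rng.normal(size=(40, 5))
        Gy = rng.normal(size=(40, 3))
        X, _ = np.linalg.qr(Gx - Gx.mean(0))
        Y, _ = np.linalg.qr(Gy - Gy.mean(0))
        cp = build_cross_products(X, Y, "pearson")
        np.testing.assert_allclose(cp.R_XX, np.eye(5), atol=1e-8)
        np.testing.assert_allclose(cp.Omega, cp.R_XY, atol=1e-7)

    def test_shapes(self):
        cfg = SynthConfig(n_participants=200, n_brain=68, n_behavior=11, seed=1)
        study = generate_study(cfg)
        cp = build_cross_products(residualize(study.brain, study.covariates),
                                  residualize(study.behavior, study.covariates),
                                  "spearman")
        assert cp.R_XY.shape == (68, 11)
        assert cp.Omega.shape == (68, 11)
        assert cp.R_XX.shape == (68, 68)

    def test_low_within_block_correlation_shrinks_adjustment(self):
        # as within-block correlation goes to zero, Omega approaches R_XY
        diffs = []
        for rho in (0.0, 0.5):
            cfg = SynthConfig(n_participants=5000, n_brain=10, n_behavior=6,
                              effect_sizes=(0.2,), within_block_rho_brain=rho,
                              within_block_rho_behavior=rho,
                              behavior_family="gaussian",
                              covariate_effect_scale=0.0, seed=8)
            study = generate_study(cfg)
            cp = build_cross_products(
                residualize(study.brain, study.covariates),
                residualize(study.behavior, study.covariates), "pearson")
            diffs.append(np.abs(cp.Omega - cp.R_XY).max())
        assert diffs[0] <= 0.05
        assert diffs[0] < diffs[1]

    def test_omega_singular_values_bounded_by_one(self):
        rng = np.random.default_rng(4)
        cp = build_cross_products(rng.normal(size=(100, 6)),
                                  rng.normal(size=(100, 4)), "spearman")
        s = np.linalg.svd(cp.Omega, compute_uv=False)
        assert np.all(s <= 1.0 + 1e-8)

    def test_unit_diagonals_and_symmetry(self):
        rng = np.random.default_rng(5)
        cp = build_cross_products(rng.normal(size=(60, 5)),
                                  rng.normal(size=(60, 4)), "spearman")
        np.testing.assert_allclose(np.diag(cp.R_XX), 1.0, atol=1e-12)
        np.testing.assert_allclose(cp.R_YY, cp.R_YY.T, atol=1e-12)
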