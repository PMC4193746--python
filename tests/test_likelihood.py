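"""Covariance assembly and MVN likelihood against dense brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from mvmr import (
    CorrelationSpec,
    ModelParameters,
    SummaryDataset,
    build_covariance,
    log_likelihood,
    unrestricted_log_likelihood,
)
from mvmr.likelihood import stack_means, stack_observations

from conftest import make_dataset


def dense_covariance_oracle(ds: SummaryDataset, corr: CorrelationSpec) -> np.ndarray:
    """Naive four-index assembly: Cov = ld_jk * P_vw * se_vj * se_wk."""
    J, K = ds.n_variants, ds.n_risk_factors
    se = np.column_stack([ds.SE_X, ds.SE_Y])
    ld = ds.ld_matrix()
    n = J * (K + 1)
    out = np.zeros((n, n))
    for j in range(J):
        for k in range(J):
            for v in range(K + 1):
                for w in range(K + 1):
                    out[j * (K + 1) + v, k * (K + 1) + w] = (
                        ld[j, k] * corr.P[v, w] * se[j, v] * se[k, w]
                    )
    return out


class TestBuildCovariance:
    def test_single_variant_identity_corr_is_diagonal(self):
        ds = SummaryDataset(("a",), ("r",), [[0.1]], [[0.03]], [0.05], [0.02])
        cov = build_covariance(ds, CorrelationSpec.identity(1)).dense()
        assert np.allclose(cov, np.diag([0.03**2, 0.02**2]))

    def test_two_variant_ld_expands_as_kronecker(self):
        # J=2, K=1, unit SEs, P=I, ld_12=0.25: pure LD correlation per variable
        ld = np.array([[1.0, 0.25], [0.25, 1.0]])
        ds = SummaryDataset(
            ("a", "b"), ("r",), [[0.1], [0.2]], [[1.0], [1.0]],
            [0.1, 0.2], [1.0, 1.0], ld=ld,
        )
        cov = build_covariance(ds, CorrelationSpec.identity(1)).dense()
        # stacking is (X_a, Y_a, X_b, Y_b)
        assert cov[0, 2] == pytest.approx(0.25)   # Corr(X_a, X_b)
        assert cov[1, 3] == pytest.approx(0.25)   # Corr(Y_a, Y_b)
        assert cov[0, 3] == pytest.approx(0.0)    # no cross-variable term
        assert np.allclose(np.diag(cov), 1.0)

    @pytest.mark.parametrize("with_ld", [False, True])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_oracle(self, seed, with_ld):
        rng = np.random.default_rng(seed)
        ds = make_dataset(rng, J=4, K=2, with_ld=with_ld)
        corr = CorrelationSpec.from_rhos([-0.1, 0.2, -0.1], k=2)
        cov = build_covariance(ds, corr).dense()
        oracle = dense_covariance_oracle(ds, corr)
        assert np.allclose(cov, oracle, rtol=1e-10, atol=0)

    def test_symmetric_with_squared_se_diagonal(self):
        rng = np.random.default_rng(7)
        ds = make_dataset(rng, J=5, K=3, with_ld=True)
        cov = build_covariance(ds, CorrelationSpec.lipid_default()).dense()
        assert np.allclose(cov, cov.T)
        se = np.column_stack([ds.SE_X, ds.SE_Y]).ravel()
        assert np.allclose(np.diag(cov), se**2)

    def test_near_singular_block_is_repaired(self):
        # ld of 0.9999 with strong within-variant correlation drives the
        # Kronecker correlation nearly singular; repair must keep it PD
        ld = np.array([[1.0, 0.9999], [0.9999, 1.0]])
        ds = SummaryDataset(
            ("a", "b"), ("r",), [[0.1], [0.2]], [[0.1], [0.1]],
            [0.1, 0.2], [0.1, 0.1], ld=ld,
        )
        corr = CorrelationSpec.from_rhos([0.99], k=1)
        cov = build_covariance(ds, corr)
        assert all(np.all(np.isfinite(b.chol)) for b in cov.blocks)
        evals = np.linalg.eigvalsh(cov.dense())
        assert evals.min() > 0


class TestLogLikelihood:
    def test_maximized_at_observed_means(self):
        rng = np.random.default_rng(11)
        ds = make_dataset(rng, J=3, K=2)
        corr = CorrelationSpec.identity(2)
        beta = np.array([0.4, -0.1])
        # choose xi so the model means equal the observations exactly
        xi = ds.X.copy()
        y_at_mean = xi @ beta
        ds_exact = SummaryDataset(
            ds.variant_ids, ds.risk_factor_names, ds.X, ds.SE_X,
            y_at_mean, ds.SE_Y,
        )
        ll = log_likelihood(ModelParameters(beta, xi), ds_exact, corr)
        cov = build_covariance(ds_exact, corr)
        norm_const = -0.5 * (
            cov.dim * np.log(2 * np.pi)
            + sum(b.logdet for b in cov.blocks)
        )
        assert ll == pytest.approx(norm_const)
        # perturbing the mean can only lower the density
        xi2 = xi + 0.01
        assert log_likelihood(ModelParameters(beta, xi2), ds_exact, corr) < ll

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_brute_force_dense_mvn(self, seed):
        rng = np.random.default_rng(seed)
        ds = make_dataset(rng, J=2, K=1, with_ld=True)
        corr = CorrelationSpec.from_rhos([0.15], k=1)
        beta = np.array([0.3])
        xi = rng.normal(0, 0.1, (2, 1))
        ll = log_likelihood(ModelParameters(beta, xi), ds, corr)
        oracle_cov = dense_covariance_oracle(ds, corr)
        mean = stack_means(beta, xi)
        obs = stack_observations(ds)
        oracle = stats.multivariate_normal.logpdf(obs, mean=mean, cov=oracle_cov)
        assert ll == pytest.approx(oracle, rel=1e-10)

    def test_independence_factorizes_over_variants(self):
        rng = np.random.default_rng(13)
        ds = make_dataset(rng, J=4, K=2, with_ld=False)
        corr = CorrelationSpec.identity(2)
        beta = np.array([0.2, -0.3])
        xi = rng.normal(0, 0.1, (4, 2))
        total = log_likelihood(ModelParameters(beta, xi), ds, corr)
        per_variant = 0.0
        for j in range(4):
            dj = SummaryDataset(
                (ds.variant_ids[j],), ds.risk_factor_names,
                ds.X[j : j + 1], ds.SE_X[j : j + 1],
                ds.Y[j : j + 1], ds.SE_Y[j : j + 1],
            )
            per_variant += log_likelihood(
                ModelParameters(beta, xi[j : j + 1]), dj, corr
            )
        assert total == pytest.approx(per_variant, rel=1e-12)


class TestUnrestrictedLikelihood:
    def test_nests_restricted_model(self):
        rng = np.random.default_rng(17)
        ds = make_dataset(rng, J=3, K=2, with_ld=True)
        corr = CorrelationSpec.from_rhos([-0.1, 0.2, 0.1], k=2)
        beta = np.array([0.4, -0.1])
        xi = rng.normal(0, 0.1, (3, 2))
        restricted = log_likelihood(ModelParameters(beta, xi), ds, corr)
        same = unrestricted_log_likelihood(xi, xi @ beta, ds, corr)
        assert same == pytest.approx(restricted, rel=1e-12)

    def test_saturated_model_attains_global_maximum(self):
        rng = np.random.default_rng(19)
        ds = make_dataset(rng, J=3, K=2)
        corr = CorrelationSpec.identity(2)
        best = unrestricted_log_likelihood(ds.X, ds.Y, ds, corr)
        for _ in range(10):
            xi = ds.X + rng.normal(0, 0.01, ds.X.shape)
            eta = ds.Y + rng.normal(0, 0.01, ds.Y.shape)
            assert unrestricted_log_likelihood(xi, eta, ds, corr) <= best

    @pytest.mark.parametrize("seed", [23, 29])
    def test_matches_brute_force_dense_mvn(self, seed):
        rng = np.random.default_rng(seed)
        ds = make_dataset(rng, J=3, K=2, with_ld=True)
        corr = CorrelationSpec.from_rhos([-0.1, 0.2, 0.1], k=2)
        xi = rng.normal(0, 0.1, (3, 2))
        eta = rng.normal(0, 0.05, 3)
        ll = unrestricted_log_likelihood(xi, eta, ds, corr)
        mean = np.column_stack([xi, eta]).ravel()
        oracle = stats.multivariate_normal.logpdf(
            stack_observations(ds), mean=mean,
            cov=dense_covariance_oracle(ds, corr),
        )
        assert ll == pytest.approx(oracle, rel=1e-10)
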