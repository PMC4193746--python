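"""Joint multivariate-normal likelihood for multivariable MR.

The observed coefficients for variant j are modelled as draws about latent
true associations:

    X_vj ~ N(xi_vj, sigma_vj^2)          v = 1..K risk factors
    Y_j  ~ N(sum_v beta_v xi_vj, sigma_Yj^2)

with correlation between the (K+1) coefficients of one variant given by a
:class:`~mvmr.data.CorrelationSpec` P, and correlation between coefficients
of variants j and k given by their LD correlation.  The joint covariance is
the separable form

    Cov(coef_vj, coef_wk) = ld_jk * P_vw * sigma_vj * sigma_wk,

the unique choice consistent with both stated marginal structures (j = k
recovers the within-variant block, v = w recovers pure LD correlation).
Because LD is block-diagonal across LD blocks, the likelihood factorizes
over blocks and each block is evaluated from a cached Cholesky factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .data import CorrelationSpec, SummaryDataset

__all__ = [
    "ModelParameters",
    "JointCovariance",
    "build_covariance",
    "log_likelihood",
    "unrestricted_log_likelihood",
    "ld_block_indices",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_MIN_EIG = 1e-8


class CovarianceError(np.linalg.LinAlgError):
    """Joint covariance could not be made positive definite."""


@dataclass(frozen=True)
class ModelParameters:
    """Causal effects ``beta`` (K,) and latent true associations ``xi`` (J, K)."""

    beta: np.ndarray
    xi: np.ndarray

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float).ravel()
        xi = np.atleast_2d(np.asarray(self.xi, dtype=float))
        if xi.shape[1] != beta.shape[0]:
            raise ValueError("xi column count must match beta length")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "xi", xi)


def ld_block_indices(ld: np.ndarray | None, n: int) -> list[np.ndarray]:
    """Connected components of the nonzero-LD graph (exact zero threshold).

    Identity LD yields ``n`` singleton blocks.  Order is by smallest member.
    """
    if ld is None:
        return [np.array([j]) for j in range(n)]
    adj = csr_matrix(ld != 0.0)
    n_comp, labels = connected_components(adj, directed=False)
    blocks = [np.flatnonzero(labels == c) for c in range(n_comp)]
    blocks.sort(key=lambda b: int(b[0]))
    return blocks


def _repair_correlation(C: np.ndarray, context: str) -> np.ndarray:
    """Shrink off-diagonals toward zero just enough to restore eigenvalues.

    LD correlations in practice are modest, so this is a guard against
    ill-conditioned user input, not a routine code path.
    """
    lam = np.linalg.eigvalsh(C)[0]
    if lam >= _MIN_EIG:
        return C
    gamma = (1.0 - _MIN_EIG) / (1.0 - lam)
    out = np.eye(C.shape[0]) + gamma * (C - np.eye(C.shape[0]))
    if np.linalg.eigvalsh(out)[0] < _MIN_EIG * 0.5:
        raise CovarianceError(f"correlation block not repairable: {context}")
    return out


@dataclass(frozen=True)
class _Block:
    """One LD block's slice of the joint covariance, pre-factorized."""

    indices: np.ndarray        # variant indices into the dataset
    cov: np.ndarray            # m(K+1) x m(K+1)
    chol: np.ndarray           # lower Cholesky factor of cov
    prec: np.ndarray           # inverse of cov
    logdet: np.ndarray         # log|cov|

    @property
    def size(self) -> int:
        return len(self.indices)


class JointCovariance:
    """Block-factorized covariance of all (K+1)*J stacked coefficients.

    Coefficients are stacked variant-major: variant j contributes its K
    risk-factor betas followed by its outcome beta.  ``blocks`` holds one
    factorized dense block per LD block.
    """

    def __init__(self, blocks: list[_Block], J: int, K: int):
        self.blocks = blocks
        self.J = J
        self.K = K

    @property
    def dim(self) -> int:
        return self.J * (self.K + 1)

    def dense(self) -> np.ndarray:
        """Full dense covariance (tests and small problems only)."""
        out = np.zeros((self.dim, self.dim))
        w = self.K + 1
        for b in self.blocks:
            rows = np.concatenate([np.arange(j * w, (j + 1) * w) for j in b.indices])
            out[np.ix_(rows, rows)] = b.cov
        return out

    def block_slices(self, b: _Block) -> np.ndarray:
        """Stacked-coefficient indices belonging to block ``b``."""
        w = self.K + 1
        return np.concatenate([np.arange(j * w, (j + 1) * w) for j in b.indices])

    def logpdf(self, resid: np.ndarray) -> float:
        """MVN log-density at mean + ``resid`` (i.e. of the residual)."""
        return float(sum(self._block_logpdf(b, resid) for b in self.blocks))

    def block_logpdfs(self, resid: np.ndarray) -> np.ndarray:
        return np.array([self._block_logpdf(b, resid) for b in self.blocks])

    def _block_logpdf(self, b: _Block, resid: np.ndarray) -> float:
        r = resid[self.block_slices(b)]
        z = np.linalg.solve(b.chol, r)
        return -0.5 * (len(r) * _LOG2PI + b.logdet + z @ z)

    def quad_form(self, resid: np.ndarray) -> float:
        """resid' Cov^-1 resid."""
        return float(
            sum(
                (np.linalg.solve(b.chol, resid[self.block_slices(b)]) ** 2).sum()
                for b in self.blocks
            )
        )


def build_covariance(ds: SummaryDataset, corr: CorrelationSpec) -> JointCovariance:
    """Assemble and factorize the joint covariance of all coefficients.

    Each LD block's correlation matrix is the Kronecker product of the
    block's LD matrix with the within-variant correlation P, scaled by the
    standard errors.  Blocks whose smallest correlation eigenvalue falls
    below 1e-8 have their off-diagonals shrunk minimally toward zero; a
    block that cannot be repaired raises :class:`CovarianceError` naming it.
    """
    J, K = ds.n_variants, ds.n_risk_factors
    if corr.P.shape[0] != K + 1:
        raise ValueError(
            f"correlation spec dimension {corr.P.shape[0]} != K+1 = {K + 1}"
        )
    ld = ds.ld
    se = np.column_stack([ds.SE_X, ds.SE_Y])  # (J, K+1)
    blocks = []
    for idx in ld_block_indices(ld, J):
        m = len(idx)
        ld_b = np.eye(m) if ld is None else ld[np.ix_(idx, idx)]
        C = np.kron(ld_b, corr.P)
        ids = [ds.variant_ids[j] for j in idx]
        C = _repair_correlation(C, context=f"LD block {ids}")
        s = se[idx].ravel()
        cov = C * np.outer(s, s)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise CovarianceError(f"covariance block not PD: LD block {ids}") from exc
        prec = np.linalg.inv(cov)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        blocks.append(_Block(idx, cov, chol, prec, logdet))
    return JointCovariance(blocks, J, K)


def stack_observations(ds: SummaryDataset) -> np.ndarray:
    """Observed coefficients stacked variant-major: (X_j1..X_jK, Y_j) per j."""
    return np.column_stack([ds.X, ds.Y]).ravel()


def stack_means(beta: np.ndarray, xi: np.ndarray) -> np.ndarray:
    """Model means stacked variant-major: (xi_j, beta . xi_j) per variant."""
    return np.column_stack([xi, xi @ beta]).ravel()


def log_likelihood(
    params: ModelParameters,
    ds: SummaryDataset,
    corr: CorrelationSpec,
    cov: JointCovariance | None = None,
) -> float:
    """Log-likelihood of the summarized data under the causal model.

    The stacked observed coefficients are evaluated under the MVN with mean
    (xi_j, sum_v beta_v xi_vj) and covariance :func:`build_covariance`.
    Pass a prebuilt ``cov`` to amortize factorization across evaluations.
    """
    J, K = ds.n_variants, ds.n_risk_factors
    if params.xi.shape != (J, K):
        raise ValueError(f"xi must have shape {(J, K)}, got {params.xi.shape}")
    if cov is None:
        cov = build_covariance(ds, corr)
    resid = stack_observations(ds) - stack_means(params.beta, params.xi)
    return cov.logpdf(resid)


def unrestricted_log_likelihood(
    xi: np.ndarray,
    eta: np.ndarray,
    ds: SummaryDataset,
    corr: CorrelationSpec,
    cov: JointCovariance | None = None,
) -> float:
    """Log-likelihood with free per-variant outcome means.

    ``eta`` replaces the structural outcome mean: Y_j ~ N(eta_j, sigma_Yj^2),
    decoupled from beta and xi.  This is the alternative (saturated-outcome)
    model of the heterogeneity test; its maximized value is never below the
    restricted model's.
    """
    J, K = ds.n_variants, ds.n_risk_factors
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    eta = np.asarray(eta, dtype=float).ravel()
    if xi.shape != (J, K) or eta.shape != (J,):
        raise ValueError("xi must be (J, K) and eta length J")
    if cov is None:
        cov = build_covariance(ds, corr)
    resid = stack_observations(ds) - np.column_stack([xi, eta]).ravel()
    return cov.logpdf(resid)
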