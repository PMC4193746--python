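"""Likelihood-ratio heterogeneity (over-identification) testing.

If every variant affects the outcome only through the modelled risk
factors, the fitted structural means should explain the outcome
associations up to sampling error.  The test compares the restricted model
(outcome mean = sum_v beta_v xi_vj for all j) with the alternative in which
each variant's outcome mean is unrestricted, evaluating both log-likelihoods
at posterior-mean point estimates and referring twice the difference to a
chi-squared distribution with J_active - K degrees of freedom.

Because the covariance is block-diagonal across LD blocks, the statistic
decomposes into per-block contributions; blocks whose contribution exceeds
a chosen percentile of chi-squared(block size) can be pruned as candidate
pleiotropic signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import CorrelationSpec, SummaryDataset, apply_exclusions
from .inference import CausalEstimates, PriorSpec
from .likelihood import (
    JointCovariance,
    build_covariance,
    ld_block_indices,
    stack_observations,
    stack_means,
)

__all__ = [
    "LDBlock",
    "HeterogeneityResult",
    "lr_heterogeneity_test",
    "chisq_upper_tail",
    "decompose_blocks",
    "prune_by_percentile",
]


@dataclass(frozen=True)
class LDBlock:
    """A maximal set of variants mutually connected by nonzero LD."""

    indices: tuple[int, ...]
    variant_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.indices)


@dataclass
class HeterogeneityResult:
    """LR statistic with its chi-squared reference and block decomposition.

    ``per_block`` has one row per LD block: variant ids, the block's
    contribution to the statistic, the block degrees of freedom (the block
    size; the K-parameter adjustment is attributed to the global test only)
    and the block percentile under chi-squared(block df).
    """

    statistic: float
    df: int
    p: float
    per_block: pd.DataFrame

    def blocks_above(self, percentile: float) -> pd.DataFrame:
        return self.per_block[self.per_block["percentile"] > percentile]


def chisq_upper_tail(x: float, df: int) -> float:
    """Upper-tail (survival) probability of chi-squared(df) at x.

    Far-tail accurate: p-values down to the underflow floor of double
    precision are returned as positive numbers, not 0.
    """
    if not x >= 0:
        raise ValueError(f"statistic must be non-negative, got {x}")
    if not df >= 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(stats.chi2.sf(x, df))


def decompose_blocks(ds: SummaryDataset) -> list[LDBlock]:
    """LD blocks of the active variants (connected components of nonzero LD)."""
    act = ds.active()
    ld = act.ld
    return [
        LDBlock(tuple(int(i) for i in idx), tuple(act.variant_ids[i] for i in idx))
        for idx in ld_block_indices(ld, act.n_variants)
    ]


def _h1_point_estimates(
    act: SummaryDataset, cov: JointCovariance, prior: PriorSpec
) -> np.ndarray:
    """Posterior mean of the saturated (unrestricted-outcome) model.

    Every stacked coefficient mean is a free parameter with the vague prior,
    so the posterior is Gaussian in closed form:
    mu = (Cov^-1 + tau^-2 I)^-1 Cov^-1 d.  Under a flat prior this is the
    observed data itself (the saturated maximum).
    """
    d = stack_observations(act)
    if prior.kind == "uniform":
        return d
    tau2inv = prior.precision
    mu = np.empty_like(d)
    for b in cov.blocks:
        sl = cov.block_slices(b)
        A = b.prec + tau2inv * np.eye(len(sl))
        mu[sl] = np.linalg.solve(A, b.prec @ d[sl])
    return mu


def lr_heterogeneity_test(
    ds: SummaryDataset,
    corr: CorrelationSpec,
    estimates: CausalEstimates,
    prior: PriorSpec | None = None,
) -> HeterogeneityResult:
    """Likelihood-ratio test of outcome-mean homogeneity at point estimates.

    Both log-likelihoods are evaluated at posterior means: the restricted
    model at (beta_hat, xi_hat) from ``estimates``, the unrestricted model
    at its closed-form Gaussian posterior mean.  The statistic is twice the
    difference, referred to chi-squared(J_active - K).  Small negative
    values (numerical round-off) are clamped to zero; anything below -1e-6
    raises, since the unrestricted model nests the restricted one.
    """
    act = ds.active()
    J, K = act.n_variants, act.n_risk_factors
    if tuple(estimates.variant_ids) != tuple(act.variant_ids):
        raise ValueError(
            "estimates were fitted on a different active variant set"
        )
    prior = prior if prior is not None else estimates.prior
    cov = build_covariance(act, corr)
    d = stack_observations(act)
    mu0 = stack_means(estimates.estimate, estimates.xi_mean)
    mu1 = _h1_point_estimates(act, cov, prior)
    ll0 = cov.block_logpdfs(d - mu0)
    ll1 = cov.block_logpdfs(d - mu1)
    contrib = 2.0 * (ll1 - ll0)
    statistic = float(contrib.sum())
    if statistic < -1e-6:
        raise FloatingPointError(
            f"negative LR statistic {statistic}: unrestricted model must nest "
            "the restricted model"
        )
    statistic = max(statistic, 0.0)
    contrib = np.maximum(contrib, 0.0)
    df = J - K
    if df < 1:
        raise ValueError(f"no residual degrees of freedom: J={J}, K={K}")
    blocks = decompose_blocks(act)
    per_block = pd.DataFrame(
        {
            "block": range(len(blocks)),
            "variant_ids": [",".join(b.variant_ids) for b in blocks],
            "statistic": contrib,
            "df": [b.size for b in blocks],
            "percentile": [
                float(stats.chi2.cdf(c, b.size)) for c, b in zip(contrib, blocks)
            ],
        }
    )
    return HeterogeneityResult(
        statistic=statistic,
        df=df,
        p=chisq_upper_tail(statistic, df),
        per_block=per_block,
    )


def prune_by_percentile(
    ds: SummaryDataset,
    corr: CorrelationSpec,
    percentile: float,
    estimates: CausalEstimates,
) -> tuple[SummaryDataset, pd.DataFrame]:
    """Exclude every LD block contributing beyond a chi-squared percentile.

    A block is removed wholesale (contributions are defined per block) when
    its statistic exceeds the ``percentile`` quantile of chi-squared(block
    df).  Returns the reduced dataset plus a report of all blocks with a
    ``removed`` flag.  Single pass: the caller refits explicitly if pruning
    is to be iterated, mirroring the published sequence of analyses.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError(f"percentile must lie in (0, 1), got {percentile}")
    het = lr_heterogeneity_test(ds, corr, estimates)
    report = het.per_block.copy()
    report["threshold"] = stats.chi2.ppf(percentile, report["df"])
    report["removed"] = report["statistic"] > report["threshold"]
    report["pruning_percentile"] = percentile
    removed_ids = [
        vid
        for ids in report.loc[report["removed"], "variant_ids"]
        for vid in ids.split(",")
    ]
    pruned = apply_exclusions(
        ds, removed_ids, reason=f"heterogeneity above {percentile:.0%} percentile"
    )
    return pruned, report
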