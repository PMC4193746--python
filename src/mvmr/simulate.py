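"""Synthetic summary datasets with the structure the model assumes.

The generator emulates a GWAS-scale multivariable MR setting: J variants
with latent true associations xi for K risk factors, outcome associations
equal to the causal combination sum_v beta_v xi_vj plus optional pleiotropy
offsets, observed coefficients drawn from the joint multivariate normal
with within-variant correlation P and AR(1)-style LD inside declared
blocks.  Defaults mirror a large lipid consortium setting: 185 variants,
3 risk factors, risk-factor associations estimated in 188,578 participants
and outcome associations in 22,233 cases and 64,762 controls, with LD
correlations below 0.25.

Standard errors follow large-sample scaling: for a variant with allele
frequency f (genotype variance 2f(1-f)),

    SE_X = c / sqrt(n_exposure * 2f(1-f))
    SE_Y = c / sqrt(N * phi * (1-phi) * 2f(1-f)),  phi = n_cases / N,

which lands the SEs on the magnitudes seen in published coefficient tables
(exposure SEs around 0.004, outcome SEs around 0.015).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import CorrelationSpec, SummaryDataset
from .likelihood import build_covariance

__all__ = ["SyntheticTruth", "generate_dataset"]

_LIPID_NAMES = ("LDL", "HDL", "TG")


@dataclass(frozen=True)
class SyntheticTruth:
    """The generating parameters behind one synthetic dataset."""

    beta: np.ndarray                  # (K,) true causal log odds ratios
    xi: np.ndarray                    # (J, K) true genetic associations
    alpha: np.ndarray                 # (J,) pleiotropy offsets on outcome means
    pleiotropic_ids: tuple[str, ...]  # variants with nonzero alpha
    ld_block_sizes: tuple[int, ...]
    n_exposure: int
    n_cases: int
    n_controls: int
    seed: int


def generate_dataset(
    J: int = 185,
    K: int = 3,
    beta: Sequence[float] | None = None,
    pleiotropy_fraction: float = 0.0,
    pleiotropy_scale: float = 5.0,
    ld_block_sizes: Sequence[int] = (),
    max_ld: float = 0.25,
    corr: CorrelationSpec | None = None,
    n_exposure: int = 188_578,
    n_cases: int = 22_233,
    n_controls: int = 64_762,
    seed: int = 0,
    xi_scale: float = 0.05,
    xi_zero_weight: float = 0.3,
    balanced_pleiotropy: bool = True,
    se_scale: float = 1.0,
) -> tuple[SummaryDataset, SyntheticTruth]:
    """Draw one synthetic summary dataset and return it with its truth.

    Parameters
    ----------
    beta : true causal effects; default (0.4, -0.1, 0.3) for K = 3 — the
        magnitude of published multivariable lipid estimates — otherwise
        alternating +/-0.3.
    pleiotropy_fraction, pleiotropy_scale : a random fraction of variants
        receives an outcome-mean offset of ``pleiotropy_scale`` times that
        variant's outcome SE (sign-balanced unless
        ``balanced_pleiotropy=False``, then all risk-increasing).
    ld_block_sizes : sizes of LD blocks (remaining variants independent);
        within a block correlations decay geometrically from a per-block
        value drawn in [max_ld/2, max_ld), so all entries stay below
        ``max_ld`` and the matrix is positive definite by construction.
    xi_scale, xi_zero_weight : latent associations are 0 with probability
        ``xi_zero_weight`` per (variant, factor) — not every variant is
        associated with every risk factor — else N(0, xi_scale^2).
    se_scale : multiplies all SEs; drive toward 0 for noiseless limits.

    The returned dataset is fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    if beta is None:
        beta = (
            np.array([0.4, -0.1, 0.3])
            if K == 3
            else 0.3 * (-1.0) ** np.arange(K)
        )
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (K,):
        raise ValueError(f"beta must have length K={K}")
    if not 0.0 <= pleiotropy_fraction <= 1.0:
        raise ValueError("pleiotropy_fraction must lie in [0, 1]")
    if sum(ld_block_sizes) > J:
        raise ValueError(
            f"LD block sizes sum to {sum(ld_block_sizes)} > J = {J}"
        )
    if any(m < 1 for m in ld_block_sizes):
        raise ValueError("LD block sizes must be positive")
    if not 0.0 <= max_ld < 1.0:
        raise ValueError("max_ld must lie in [0, 1)")
    if corr is None:
        corr = (
            CorrelationSpec.lipid_default()
            if K == 3
            else CorrelationSpec.identity(K)
        )

    names = _LIPID_NAMES if K == 3 else tuple(f"rf{v + 1}" for v in range(K))
    ids = tuple(f"rs{j + 1}" for j in range(J))

    # allele frequencies set the per-variant information content
    freq = rng.uniform(0.05, 0.5, size=J)
    gvar = 2.0 * freq * (1.0 - freq)
    N = n_cases + n_controls
    phi = n_cases / N
    SE_X = se_scale / np.sqrt(n_exposure * gvar)[:, None] * np.ones((1, K))
    SE_Y = se_scale / np.sqrt(N * phi * (1.0 - phi) * gvar)

    xi = rng.normal(0.0, xi_scale, size=(J, K))
    xi[rng.uniform(size=(J, K)) < xi_zero_weight] = 0.0

    alpha = np.zeros(J)
    n_pleio = int(round(pleiotropy_fraction * J))
    pleio_idx = rng.choice(J, size=n_pleio, replace=False) if n_pleio else np.array([], int)
    if n_pleio:
        signs = (
            rng.choice([-1.0, 1.0], size=n_pleio)
            if balanced_pleiotropy
            else np.ones(n_pleio)
        )
        alpha[pleio_idx] = pleiotropy_scale * SE_Y[pleio_idx] * signs

    ld = np.eye(J)
    start = 0
    for m in ld_block_sizes:
        r = rng.uniform(max_ld / 2.0, max_ld) if max_ld > 0 else 0.0
        block = r ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        ld[start : start + m, start : start + m] = block
        start += m

    means = np.column_stack([xi, xi @ beta + alpha])  # (J, K+1)
    # draw observed coefficients through the same separable covariance the
    # likelihood assumes, block by block
    shell = SummaryDataset(
        variant_ids=ids,
        risk_factor_names=names,
        X=means[:, :K],
        SE_X=SE_X,
        Y=means[:, K],
        SE_Y=SE_Y,
        ld=None if not len(ld_block_sizes) else ld,
    )
    cov = build_covariance(shell, corr)
    flat = means.ravel().copy()
    for b in cov.blocks:
        sl = cov.block_slices(b)
        flat[sl] += b.chol @ rng.standard_normal(len(sl))
    observed = flat.reshape(J, K + 1)

    ds = SummaryDataset(
        variant_ids=ids,
        risk_factor_names=names,
        X=observed[:, :K],
        SE_X=SE_X,
        Y=observed[:, K],
        SE_Y=SE_Y,
        ld=None if not len(ld_block_sizes) else ld,
    )
    truth = SyntheticTruth(
        beta=beta,
        xi=xi,
        alpha=alpha,
        pleiotropic_ids=tuple(ids[j] for j in sorted(pleio_idx.tolist())),
        ld_block_sizes=tuple(ld_block_sizes),
        n_exposure=n_exposure,
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
    )
    return ds, truth
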