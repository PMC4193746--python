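"""Bayesian fitting of the causal parameters from summarized data.

The model is conditionally linear-Gaussian in both directions: given the
causal effects ``beta`` the latent associations ``xi`` have a multivariate
normal full conditional, and given ``xi`` so does ``beta``.  The sampler is
therefore a blocked Gibbs scheme drawing each in turn from its exact
conditional — no tuning, fast convergence, and bit-for-bit reproducibility
from a seed.  Vague normal priors (mean 0, SD 1000) are the default for
every unknown, so the posterior effectively reproduces the likelihood;
uniform priors on a finite box are available and give indistinguishable
results for well-identified data.

The posterior mean and SD are reported as the estimate and its standard
error, the 95% credible interval is equal-tailed, and the two-sided p-value
is twice the posterior tail probability on the opposite side of zero from
the point estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CorrelationSpec, SummaryDataset
from .likelihood import JointCovariance, build_covariance

__all__ = [
    "PriorSpec",
    "CausalEstimates",
    "WLSEstimate",
    "SensitivityScan",
    "fit_mcmc",
    "two_sided_p",
    "p_value_label",
    "fit_wls_oracle",
    "sensitivity_scan",
]


@dataclass(frozen=True)
class PriorSpec:
    """Prior on every unknown parameter (the causal effects and the xi).

    ``kind="vague-normal"``: independent N(0, scale^2), default scale 1000 —
    vague enough that the posterior approximates the likelihood.
    ``kind="uniform"``: flat on [bounds[0], bounds[1]] per parameter.
    """

    kind: str = "vague-normal"
    scale: float = 1000.0
    bounds: tuple[float, float] = (-3.0, 3.0)

    def __post_init__(self) -> None:
        if self.kind not in ("vague-normal", "uniform"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "vague-normal" and not self.scale > 0:
            raise ValueError("normal prior scale must be positive")
        lo, hi = self.bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("uniform bounds must be finite and ordered")

    @property
    def precision(self) -> float:
        """Gaussian prior precision; a tiny ridge under the uniform prior
        keeps conditionals proper in degenerate (under-identified) corners."""
        return 1.0 / self.scale**2 if self.kind == "vague-normal" else 1e-10


@dataclass
class CausalEstimates:
    """Posterior summaries of the causal log odds ratios per risk factor.

    ``estimate`` is the posterior mean, ``se`` the posterior SD, the
    credible interval is equal-tailed, and ``p`` is the two-sided posterior
    tail probability (floored at 2/n_draws when no draw crosses zero;
    ``p_is_floor`` marks those).  ``xi_mean`` holds the posterior mean of
    the latent associations for the active variants, used downstream by the
    heterogeneity test.
    """

    risk_factor_names: tuple[str, ...]
    estimate: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray
    p_is_floor: np.ndarray
    rhat: np.ndarray
    ess: np.ndarray
    mcse: np.ndarray
    converged: bool
    beta_draws: np.ndarray                 # (chains, draws, K)
    xi_mean: np.ndarray                    # (J_active, K)
    variant_ids: tuple[str, ...]
    prior: PriorSpec
    settings: dict
    messages: list[str] = field(default_factory=list)

    @property
    def odds_ratio(self) -> np.ndarray:
        return np.exp(self.estimate)

    @property
    def or_ci_lower(self) -> np.ndarray:
        with np.errstate(over="ignore"):  # degenerate fits can overflow exp
            return np.exp(self.ci_lower)

    @property
    def or_ci_upper(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.ci_upper)

    def p_labels(self) -> list[str]:
        n = self.beta_draws.shape[0] * self.beta_draws.shape[1]
        return [
            f"< {2.0 / n:.0e}" if floor else f"{p:.3g}"
            for p, floor in zip(self.p, self.p_is_floor)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "risk_factor": list(self.risk_factor_names),
                "estimate": self.estimate,
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p,
                "p_label": self.p_labels(),
                "odds_ratio": self.odds_ratio,
                "or_ci_lower": self.or_ci_lower,
                "or_ci_upper": self.or_ci_upper,
                "rhat": self.rhat,
                "ess": self.ess,
            }
        )


def two_sided_p(sample: np.ndarray) -> float:
    """Two-sided p-value from posterior draws of one parameter.

    Twice the fraction of draws on the opposite side of zero from the
    sample mean, capped at 1.  Zero opposite-sign draws are floored at
    2/n_draws — the resolution of the sample — never reported as 0.
    """
    s = np.asarray(sample, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("empty posterior sample")
    m = s.mean()
    if m == 0:
        return 1.0
    opposite = np.mean(s < 0 if m > 0 else s > 0)
    if opposite == 0:
        return 2.0 / s.size
    return float(min(1.0, 2.0 * opposite))


def p_value_label(sample: np.ndarray) -> str:
    """Rendering of :func:`two_sided_p` with the "< 2/n" floor made explicit."""
    s = np.asarray(sample, dtype=float).ravel()
    m = s.mean()
    opposite = np.mean(s < 0 if m > 0 else s > 0) if m != 0 else 0.5
    if opposite == 0:
        return f"< {2.0 / s.size:.0e}"
    return f"{min(1.0, 2.0 * float(opposite)):.3g}"


# ---------------------------------------------------------------------------
# Closed-form oracle


@dataclass(frozen=True)
class WLSEstimate:
    """Inverse-variance weighted multivariable estimate (no intercept).

    The limiting form of the likelihood when uncertainty in the risk-factor
    associations is negligible and variants are independent: weighted least
    squares of Y on the K columns of X with weights 1/SE_Y^2.
    """

    beta: np.ndarray
    cov: np.ndarray
    risk_factor_names: tuple[str, ...]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def fit_wls_oracle(ds: SummaryDataset) -> WLSEstimate:
    """Closed-form weighted-regression estimate on the active variants.

    Exact under identity LD and negligible SE_X; otherwise an approximation
    used for validation and as a sampler starting point.
    """
    act = ds.active()
    J, K = act.n_variants, act.n_risk_factors
    if J < K:
        raise np.linalg.LinAlgError(
            f"under-identified: {J} active variants for {K} risk factors"
        )
    w = 1.0 / act.SE_Y**2
    A = (act.X * w[:, None]).T @ act.X
    svals = np.linalg.svd(A, compute_uv=False)
    if svals[-1] <= svals[0] * 1e-12:
        _, _, vt = np.linalg.svd(A)
        worst = np.argsort(-np.abs(vt[-1]))[:2]
        names = [act.risk_factor_names[i] for i in worst]
        raise np.linalg.LinAlgError(
            f"rank-deficient design: risk factors {names} are collinear"
        )
    b = np.linalg.solve(A, (act.X * w[:, None]).T @ act.Y)
    return WLSEstimate(b, np.linalg.inv(A), act.risk_factor_names)


# ---------------------------------------------------------------------------
# Gibbs sampler internals


class _GibbsEngine:
    """Precomputed quantities for the two exact Gaussian conditionals.

    The precision of each LD block is sliced once into its risk-factor /
    outcome parts, so assembling the xi conditional for a new beta is pure
    broadcasting; blocks of equal size and all chains are batched through
    one set of batched-Cholesky calls per sweep.
    """

    def __init__(self, ds: SummaryDataset, cov: JointCovariance):
        self.J, self.K = ds.n_variants, ds.n_risk_factors
        K = self.K
        obs = np.column_stack([ds.X, ds.Y])  # (J, K+1)
        groups: dict[int, list] = {}
        for b in cov.blocks:
            groups.setdefault(b.size, []).append(b)
        self.groups = []
        for m, bs in sorted(groups.items()):
            nb = len(bs)
            idx = np.array([b.indices for b in bs])            # (nb, m)
            prec = np.array([b.prec for b in bs])              # (nb, D, D)
            d = obs[idx].reshape(nb, m * (K + 1))              # (nb, D)
            p4 = prec.reshape(nb, m, K + 1, m, K + 1)
            # slices of the precision: X = risk-factor rows, Y = outcome rows
            pXX = np.ascontiguousarray(p4[:, :, :K, :, :K]).reshape(
                nb, m * K, m * K
            )
            pXY = np.ascontiguousarray(p4[:, :, :K, :, K]).reshape(nb, m * K, m)
            pYY = np.ascontiguousarray(p4[:, :, K, :, K])      # (nb, m, m)
            pd_ = np.einsum("npq,nq->np", prec, d).reshape(nb, m, K + 1)
            pdX = np.ascontiguousarray(pd_[:, :, :K]).reshape(nb, m * K)
            pdY = np.ascontiguousarray(pd_[:, :, K])           # (nb, m)
            self.groups.append(
                {"m": m, "idx": idx, "pXX": pXX, "pXY": pXY, "pYY": pYY,
                 "pdX": pdX, "pdY": pdY}
            )

    def sample_xi(
        self, beta: np.ndarray, prior_prec: float, rng: np.random.Generator
    ) -> np.ndarray:
        """One exact draw of all latent xi for every chain given beta (C, K)."""
        K = self.K
        C = beta.shape[0]
        bb = beta[:, :, None] * beta[:, None, :]               # (C, K, K)
        xi = np.empty((C, self.J, K))
        for g in self.groups:
            m, nb = g["m"], g["idx"].shape[0]
            mk = m * K
            # Q = pXX + pXY (x) beta' + beta (x) pYX + pYY (x) beta beta'
            t2 = (g["pXY"][None, :, :, :, None] * beta[:, None, None, None, :]
                  ).reshape(C, nb, mk, mk)
            t4 = (g["pYY"][None, :, :, None, :, None]
                  * bb[:, None, None, :, None, :]).reshape(C, nb, mk, mk)
            Q = g["pXX"][None] + t2 + np.swapaxes(t2, -1, -2) + t4
            Q[..., np.arange(mk), np.arange(mk)] += prior_prec
            h = (g["pdX"].reshape(1, nb, m, K)
                 + g["pdY"][None, :, :, None] * beta[:, None, None, :]
                 ).reshape(C, nb, mk)
            L = np.linalg.cholesky(Q)
            Lt = np.swapaxes(L, -1, -2)
            mu = np.linalg.solve(Lt, np.linalg.solve(L, h[..., None]))[..., 0]
            z = rng.standard_normal((C, nb, mk))
            draw = mu + np.linalg.solve(Lt, z[..., None])[..., 0]
            xi[:, g["idx"].ravel(), :] = draw.reshape(C, nb * m, K)
        return xi

    def beta_moments(self, xi: np.ndarray, prior_prec: float):
        """Precision and linear term of the beta conditional, per chain."""
        K = self.K
        C = xi.shape[0]
        P = np.tile(prior_prec * np.eye(K), (C, 1, 1))
        lin = np.zeros((C, K))
        for g in self.groups:
            m = g["m"]
            xg = xi[:, g["idx"].ravel(), :].reshape(C, -1, m, K)  # (C, nb, m, K)
            P += np.einsum("cnak,nab,cnbl->ckl", xg, g["pYY"], xg)
            xflat = xg.reshape(C, -1, m * K)
            pc_Y = np.einsum("nam,cnm->cna", np.swapaxes(g["pXY"], 1, 2), xflat)
            rY = g["pdY"][None] - pc_Y                            # (C, nb, m)
            lin += np.einsum("cnak,cna->ck", xg, rY)
        return P, lin


def _draw_beta(
    P: np.ndarray, lin: np.ndarray, prior: PriorSpec, rng: np.random.Generator
) -> np.ndarray:
    """Exact draw from each chain's Gaussian (or box-truncated) conditional."""
    C, K = lin.shape
    L = np.linalg.cholesky(P)
    Lt = np.swapaxes(L, -1, -2)
    mu = np.linalg.solve(Lt, np.linalg.solve(L, lin[..., None]))[..., 0]
    draw = mu + np.linalg.solve(Lt, rng.standard_normal((C, K, 1)))[..., 0]
    if prior.kind != "uniform":
        return draw
    lo, hi = prior.bounds
    for _ in range(100):
        bad = ~np.all((draw >= lo) & (draw <= hi), axis=1)
        if not bad.any():
            return draw
        redraw = mu[bad] + np.linalg.solve(
            Lt[bad], rng.standard_normal((int(bad.sum()), K, 1))
        )[..., 0]
        draw[bad] = redraw
    # conditional mass almost entirely outside the box: clip (and the
    # caller's diagnostics will show the pathology)
    return np.clip(draw, lo, hi)


def fit_mcmc(
    ds: SummaryDataset,
    corr: CorrelationSpec | None = None,
    prior: PriorSpec | None = None,
    chains: int = 4,
    iterations: int = 25_000,
    warmup: int = 2_000,
    seed: int = 0,
    rhat_threshold: float = 1.01,
) -> CausalEstimates:
    """Posterior sampling of the causal effects by blocked Gibbs.

    ``iterations`` counts retained draws per chain after ``warmup`` sweeps
    are discarded; the documented minimum for publication-grade summaries is
    the default 4 chains x 25,000 draws.  The full random stream is fixed by
    ``seed``, so identical settings reproduce identical output.  Convergence
    is monitored by split-chain R-hat on each causal effect; values above
    ``rhat_threshold`` attach a warning (never silently dropped).  Posterior
    SDs comparable to the prior scale flag non-identifiability.
    """
    if chains < 2:
        raise ValueError("at least 2 chains are required for the diagnostics")
    if iterations < 100:
        raise ValueError("iterations must be at least 100")
    act = ds.active()
    J, K = act.n_variants, act.n_risk_factors
    corr = corr if corr is not None else CorrelationSpec.identity(K)
    prior = prior if prior is not None else PriorSpec()
    cov = build_covariance(act, corr)
    engine = _GibbsEngine(act, cov)

    try:
        start = fit_wls_oracle(act).beta
    except np.linalg.LinAlgError:
        start = np.zeros(K)
    messages: list[str] = []

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    beta_draws = np.empty((chains, iterations, K))
    xi_sum = np.zeros((J, K))
    pp = prior.precision
    beta = start[None, :] + 0.05 * rng.standard_normal((chains, K))
    if prior.kind == "uniform":
        beta = np.clip(beta, *prior.bounds)
    for it in range(-warmup, iterations):
        xi = engine.sample_xi(beta, pp, rng)
        if prior.kind == "uniform":
            lo, hi = prior.bounds
            for _ in range(50):
                bad = (xi < lo) | (xi > hi)
                if not bad.any():
                    break
                xi = np.where(bad, engine.sample_xi(beta, pp, rng), xi)
        P, lin = engine.beta_moments(xi, pp)
        beta = _draw_beta(P, lin, prior, rng)
        if it >= 0:
            beta_draws[:, it] = beta
            xi_sum += xi.sum(axis=0)
    xi_mean = xi_sum / (chains * iterations)

    import arviz as az

    rhat = np.array([float(az.rhat(beta_draws[:, :, v])) for v in range(K)])
    ess = np.array([float(az.ess(beta_draws[:, :, v])) for v in range(K)])
    pooled = beta_draws.reshape(-1, K)
    est = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    lo, hi = np.quantile(pooled, [0.025, 0.975], axis=0)
    pvals = np.array([two_sided_p(pooled[:, v]) for v in range(K)])
    floors = np.array(
        [
            (np.sign(pooled[:, v]) != np.sign(est[v])).sum() == 0 and est[v] != 0
            for v in range(K)
        ]
    )
    converged = bool(np.all(rhat < rhat_threshold))
    if not converged:
        messages.append(
            f"convergence warning: max split R-hat {rhat.max():.4f} >= {rhat_threshold}"
        )
        warnings.warn(messages[-1], stacklevel=2)
    ident_scale = prior.scale if prior.kind == "vague-normal" else (
        (prior.bounds[1] - prior.bounds[0]) / np.sqrt(12.0)
    )
    if np.any(sd > 0.1 * ident_scale):
        which = [act.risk_factor_names[v] for v in np.where(sd > 0.1 * ident_scale)[0]]
        messages.append(
            f"non-identifiability warning: posterior SD comparable to prior scale "
            f"for {which}"
        )
        warnings.warn(messages[-1], stacklevel=2)

    return CausalEstimates(
        risk_factor_names=act.risk_factor_names,
        estimate=est,
        se=sd,
        ci_lower=lo,
        ci_upper=hi,
        p=pvals,
        p_is_floor=floors,
        rhat=rhat,
        ess=ess,
        mcse=sd / np.sqrt(np.maximum(ess, 1.0)),
        converged=converged,
        beta_draws=beta_draws,
        xi_mean=xi_mean,
        variant_ids=act.variant_ids,
        prior=prior,
        settings={
            "chains": chains,
            "iterations": iterations,
            "warmup": warmup,
            "seed": seed,
            "rhat_threshold": rhat_threshold,
        },
        messages=messages,
    )


# ---------------------------------------------------------------------------
# Sensitivity to the within-variant correlations


@dataclass
class SensitivityScan:
    """Per-multiplier refits of the model with scaled correlation parameters."""

    table: pd.DataFrame
    fits: dict[float, CausalEstimates]
    errors: dict[float, str]


def sensitivity_scan(
    ds: SummaryDataset,
    corr: CorrelationSpec,
    multipliers: Sequence[float] = (2.0, 1.5, 1.0, 0.5, 0.0, -0.5, -1.0),
    **fit_kwargs,
) -> SensitivityScan:
    """Refit with every off-diagonal correlation scaled by each multiplier.

    Mirrors the published sensitivity analysis: one row per multiplier, the
    rho values followed by each causal estimate with its SE.  A multiplier
    whose scaled matrix is invalid is recorded as an error and skipped; the
    scan continues.
    """
    K = corr.k
    names = None
    rows, fits, errors = [], {}, {}
    iu = np.triu_indices(K + 1, 1)
    for mult in multipliers:
        row: dict = {"multiplier": mult}
        try:
            scaled = corr.scaled(mult)
            fit = fit_mcmc(ds, scaled, **fit_kwargs)
            names = fit.risk_factor_names
            labels = list(names) + ["outcome"]
            for a, b_ in zip(*iu):
                row[f"rho_{labels[a]}_{labels[b_]}"] = scaled.P[a, b_]
            for v, name in enumerate(names):
                row[f"{name}_estimate"] = fit.estimate[v]
                row[f"{name}_se"] = fit.se[v]
            fits[mult] = fit
        except Exception as exc:  # noqa: BLE001 - per-row failures recorded
            row["error"] = str(exc)
            errors[mult] = str(exc)
        rows.append(row)
    return SensitivityScan(pd.DataFrame(rows), fits, errors)
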