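"""Lipid-score diagnostics and study-design calculations.

The lipid score of a variant is its expected outcome association under the
fitted causal model — the causal-estimate-weighted sum of its risk-factor
associations.  Plotting observed outcome associations against the score is
the visual counterpart of the heterogeneity test: without pleiotropy the
points scatter about the identity line through the origin.

The design helpers cover the two standard single-instrument calculations:
the variance in a risk factor explained by a variant, and the power of a
case-control Mendelian randomization study under a normal approximation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data import SummaryDataset
from .heterogeneity import HeterogeneityResult
from .inference import CausalEstimates

__all__ = ["lipid_score", "variance_explained", "power_case_control"]


def lipid_score(
    estimates: CausalEstimates,
    ds: SummaryDataset,
    het: HeterogeneityResult | None = None,
) -> pd.DataFrame:
    """Per-variant expected outcome association s_j = sum_v beta_hat_v X_vj.

    Returns one row per active variant with the score, the observed outcome
    association and its SE, and (when a heterogeneity result is supplied)
    the variant's block percentile with a display bin matching the usual
    plot shading (>=98th, 95-98th, 90-95th, <90th).
    """
    act = ds.active()
    if tuple(estimates.variant_ids) != tuple(act.variant_ids):
        raise ValueError("estimates were fitted on a different active variant set")
    score = act.X @ estimates.estimate
    out = pd.DataFrame(
        {
            "id": list(act.variant_ids),
            "score": score,
            "observed": act.Y,
            "se": act.SE_Y,
        }
    )
    if het is not None:
        pct = {}
        for _, row in het.per_block.iterrows():
            for vid in row["variant_ids"].split(","):
                pct[vid] = row["percentile"]
        out["block_percentile"] = [pct.get(v, np.nan) for v in out["id"]]
        out["percentile_bin"] = pd.cut(
            out["block_percentile"],
            bins=[-np.inf, 0.90, 0.95, 0.98, np.inf],
            labels=["<90th", "90-95th", "95-98th", ">=98th"],
        )
    return out


def variance_explained(
    beta_per_sd: float, freq: float, convention: str = "single-dose"
) -> float:
    """Proportion of a risk factor's variance explained by one variant.

    With effect ``beta_per_sd`` (in SD units of the risk factor) and
    frequency ``freq``, the default "single-dose" convention returns
    f(1-f) beta^2 — the variance of a Bernoulli carrier indicator times the
    squared effect, the convention under which the published worked example
    (beta 0.29 SD at frequency 2.6% -> R^2 = 0.002) reproduces.  The
    additive-genotype convention 2 f(1-f) beta^2, standard when beta is a
    per-allele effect on a diploid genotype, is available with
    ``convention="additive"``.
    """
    if not 0.0 < freq < 1.0:
        raise ValueError(f"frequency must lie in (0, 1), got {freq}")
    if not np.isfinite(beta_per_sd):
        raise ValueError("beta must be finite")
    base = freq * (1.0 - freq) * beta_per_sd**2
    if convention == "single-dose":
        return float(base)
    if convention == "additive":
        return float(2.0 * base)
    raise ValueError(f"unknown convention {convention!r}")


def power_case_control(
    or_per_sd: float,
    r2: float,
    n_cases: int,
    n_controls: int,
    alpha: float = 0.05,
) -> float:
    """Power of a summarized-data MR test for a binary outcome.

    Normal approximation: with N = n_cases + n_controls and case fraction
    phi, the test statistic for a causal odds ratio ``or_per_sd`` per SD of
    a risk factor, instrumented by variants explaining proportion ``r2`` of
    its variance, is approximately normal with mean

        z = |ln OR| * sqrt(N * r2 * phi * (1 - phi)),

    giving two-sided power Phi(z - z_{1-a/2}) + Phi(-z - z_{1-a/2}).
    """
    if or_per_sd <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must lie in [0, 1], got {r2}")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if r2 == 0.0:
        warnings.warn("r2 = 0: no instrument strength, power equals alpha",
                      stacklevel=2)
        return float(alpha)
    N = n_cases + n_controls
    phi = n_cases / N
    z = abs(np.log(or_per_sd)) * np.sqrt(N * r2 * phi * (1.0 - phi))
    zcrit = stats.norm.isf(alpha / 2.0)
    return float(stats.norm.cdf(z - zcrit) + stats.norm.cdf(-z - zcrit))
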