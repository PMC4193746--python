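"""Data model and I/O for summarized genetic association data.

The central object is :class:`SummaryDataset`: per-variant regression
coefficients (betas) and standard errors for K risk factors (per 1 SD of
each risk factor) and for a binary outcome (log odds ratios), together with
an optional variant-by-variant LD correlation matrix.  Standard errors that
are published only as p-values are reconstructed by inverting the two-sided
normal (Wald) test, with an extended-precision path for p-values below the
double-precision floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryDataset",
    "CorrelationSpec",
    "VariantRecord",
    "read_summary_table",
    "write_summary_table",
    "read_ld_matrix",
    "write_ld_matrix",
    "se_from_pvalue",
    "pvalue_from_se",
    "orient_risk_increasing",
    "apply_exclusions",
]


class SummaryDataError(ValueError):
    """Raised when a summary table or LD matrix violates its contract."""


@dataclass(frozen=True)
class CorrelationSpec:
    """Within-variant correlation of the (K+1) association estimates.

    ``P`` is the (K+1)x(K+1) symmetric correlation matrix of the estimation
    errors of one variant's coefficients, ordered as the K risk factors
    followed by the outcome.  For the three-lipid analysis the off-diagonal
    entries are (rho_LH, rho_LT, rho_LY, rho_HT, rho_HY, rho_TY); the
    defaults used throughout are (-0.1, 0.2, 0.1, -0.1, -0.1, 0.1) — rough
    phenotypic correlations of the lipid fractions and log disease risk,
    which stand in for the correlations of the coefficient errors.
    """

    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise SummaryDataError("correlation matrix must be square")
        if not np.allclose(P, P.T, atol=1e-12):
            raise SummaryDataError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(P), 1.0, atol=1e-12):
            raise SummaryDataError("correlation matrix must have unit diagonal")
        off = P[~np.eye(P.shape[0], dtype=bool)]
        if off.size and (np.abs(off) >= 1.0).any():
            raise SummaryDataError("off-diagonal correlations must lie in (-1, 1)")
        if np.linalg.eigvalsh(P).min() < -1e-10:
            raise SummaryDataError("correlation matrix must be positive semi-definite")
        object.__setattr__(self, "P", P)

    @property
    def k(self) -> int:
        """Number of risk factors (matrix dimension minus the outcome)."""
        return self.P.shape[0] - 1

    @classmethod
    def identity(cls, k: int) -> "CorrelationSpec":
        return cls(np.eye(k + 1))

    @classmethod
    def lipid_default(cls) -> "CorrelationSpec":
        """Default three-lipid spec: rho = (-0.1, 0.2, 0.1, -0.1, -0.1, 0.1)."""
        return cls.from_rhos([-0.1, 0.2, 0.1, -0.1, -0.1, 0.1], k=3)

    @classmethod
    def from_rhos(cls, rhos: Sequence[float], k: int) -> "CorrelationSpec":
        """Build from the upper-triangle entries in row-major order."""
        P = np.eye(k + 1)
        iu = np.triu_indices(k + 1, 1)
        if len(rhos) != len(iu[0]):
            raise SummaryDataError(
                f"expected {len(iu[0])} correlations for {k} risk factors, got {len(rhos)}"
            )
        P[iu] = rhos
        P[(iu[1], iu[0])] = rhos
        return cls(P)

    def scaled(self, multiplier: float) -> "CorrelationSpec":
        """All off-diagonal correlations multiplied by ``multiplier``."""
        P = self.P * multiplier
        np.fill_diagonal(P, 1.0)
        return CorrelationSpec(P)


@dataclass(frozen=True)
class VariantRecord:
    """One variant's row: betas and SEs per variable, with optional p-values
    and allele labels (carried as labels only, never harmonized)."""

    id: str
    beta: Mapping[str, float]
    se: Mapping[str, float]
    pvalue: Mapping[str, float] = field(default_factory=dict)
    risk_allele: str | None = None
    other_allele: str | None = None

    def __post_init__(self) -> None:
        for var, p in self.pvalue.items():
            se = self.se.get(var)
            b = self.beta.get(var)
            if se is None or b is None or not (0 < p < 1) or b == 0:
                continue
            implied = abs(b) / stats.norm.isf(p / 2.0)
            if abs(implied - se) > 0.10 * se:
                warnings.warn(
                    f"variant {self.id}, variable {var}: supplied SE {se:.4g} and "
                    f"p-value {p:.3g} disagree by more than 10% (p implies {implied:.4g})",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class SummaryDataset:
    """Per-variant summary associations for K risk factors and one outcome.

    Attributes
    ----------
    variant_ids : list of str, length J
    risk_factor_names : list of str, length K
    X, SE_X : (J, K) arrays
        Associations with each risk factor, per 1 SD of the risk factor,
        and their (strictly positive) standard errors.
    Y, SE_Y : (J,) arrays
        Log odds ratios with the outcome and their standard errors.
    ld : (J, J) array
        Signed correlation between allele counts of the variants; identity
        when variants are independent.
    excluded : dict mapping variant id -> free-text reason
        Non-destructive exclusion flags; excluded variants are dropped from
        all downstream fitting but remain in the object.
    """

    variant_ids: tuple[str, ...]
    risk_factor_names: tuple[str, ...]
    X: np.ndarray
    SE_X: np.ndarray
    Y: np.ndarray
    SE_Y: np.ndarray
    ld: np.ndarray | None = None
    excluded: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        SE_X = np.atleast_2d(np.asarray(self.SE_X, dtype=float))
        Y = np.asarray(self.Y, dtype=float).ravel()
        SE_Y = np.asarray(self.SE_Y, dtype=float).ravel()
        ids = tuple(str(v) for v in self.variant_ids)
        names = tuple(str(v) for v in self.risk_factor_names)
        J, K = X.shape
        if len(ids) != J or len(names) != K:
            raise SummaryDataError("dimension mismatch between ids/names and matrices")
        if SE_X.shape != (J, K) or Y.shape != (J,) or SE_Y.shape != (J,):
            raise SummaryDataError("dimension mismatch among X, SE_X, Y, SE_Y")
        if len(set(ids)) != J:
            raise SummaryDataError("variant ids must be unique")
        if not (np.all(SE_X > 0) and np.all(SE_Y > 0)):
            raise SummaryDataError("all standard errors must be strictly positive")
        ld = self.ld
        if ld is not None:
            ld = np.asarray(ld, dtype=float)
            if ld.shape != (J, J):
                raise SummaryDataError("LD matrix dimension must match variant count")
            if not np.allclose(ld, ld.T, atol=1e-10):
                raise SummaryDataError("LD matrix must be symmetric")
            if not np.allclose(np.diag(ld), 1.0, atol=1e-10):
                raise SummaryDataError("LD matrix must have unit diagonal")
            if np.abs(ld).max() > 1 + 1e-10:
                raise SummaryDataError("LD entries must lie in [-1, 1]")
            ld = (ld + ld.T) / 2.0
        unknown = set(self.excluded) - set(ids)
        if unknown:
            warnings.warn(
                f"exclusion flags for unknown variant ids ignored: {sorted(unknown)}",
                stacklevel=2,
            )
        object.__setattr__(self, "variant_ids", ids)
        object.__setattr__(self, "risk_factor_names", names)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "SE_X", SE_X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "SE_Y", SE_Y)
        object.__setattr__(self, "ld", ld)
        object.__setattr__(
            self, "excluded", {k: v for k, v in self.excluded.items() if k in set(ids)}
        )

    # -- basic shape ------------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_risk_factors(self) -> int:
        return len(self.risk_factor_names)

    @property
    def active_mask(self) -> np.ndarray:
        return np.array([v not in self.excluded for v in self.variant_ids])

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    def ld_matrix(self) -> np.ndarray:
        """The LD matrix, identity when none was supplied."""
        return np.eye(self.n_variants) if self.ld is None else self.ld

    def active(self) -> "SummaryDataset":
        """A copy restricted to the non-excluded variants."""
        mask = self.active_mask
        if mask.all():
            return self
        ld = None if self.ld is None else self.ld[np.ix_(mask, mask)]
        return SummaryDataset(
            variant_ids=tuple(np.array(self.variant_ids)[mask]),
            risk_factor_names=self.risk_factor_names,
            X=self.X[mask],
            SE_X=self.SE_X[mask],
            Y=self.Y[mask],
            SE_Y=self.SE_Y[mask],
            ld=ld,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-variant table (one row per variant)."""
        out = {"id": list(self.variant_ids)}
        for v, name in enumerate(self.risk_factor_names):
            out[f"{name}_beta"] = self.X[:, v]
            out[f"{name}_se"] = self.SE_X[:, v]
        out["outcome_beta"] = self.Y
        out["outcome_se"] = self.SE_Y
        out["excluded"] = [self.excluded.get(v, "") for v in self.variant_ids]
        return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Standard errors from p-values


def se_from_pvalue(
    beta: float,
    p: float | str,
    fallback_ses: Sequence[float] | None = None,
) -> float:
    """Standard error implied by a beta-coefficient and a two-sided p-value.

    Inverts the two-sided normal Wald test: SE = |beta| / Phi^-1(1 - p/2).
    Two published conventions need special handling:

    * ``p == 1`` (reported when beta is exactly 0): the SE is not identified,
      so the mean of ``fallback_ses`` — in practice the SEs of the same
      variable across the other variants — is returned.
    * p-values below the double-precision floor (roughly 2e-308, sometimes
      quoted only as a decimal string): the normal quantile is evaluated in
      extended precision with mpmath, so the result is finite and accurate
      instead of underflowing.

    ``p`` may be a float or a decimal string such as ``"3e-320"``.
    """
    p_str = None
    if isinstance(p, str):
        p_str = p.strip()
        p = float.fromhex(p_str) if p_str.startswith("0x") else _safe_float(p_str)
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if p > 1:
        raise ValueError(f"p-value must lie in (0, 1], got {p}")
    if p == 1.0:
        if not fallback_ses:
            raise ValueError("p = 1 requires fallback SEs (beta is unidentified)")
        return float(np.mean(np.asarray(fallback_ses, dtype=float)))
    if p <= 0 and p_str is None:
        raise ValueError(f"p-value must lie in (0, 1], got {p}")
    if beta == 0.0:
        raise ValueError("p < 1 with beta = 0 is inconsistent")
    if p_str is not None and (p == 0.0 or p < 1e-305):
        z = _extended_precision_quantile(p_str)
    elif p < 1e-305:
        z = _extended_precision_quantile(repr(p))
    else:
        z = float(stats.norm.isf(p / 2.0))
    return abs(beta) / z


def _safe_float(s: str) -> float:
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"cannot parse p-value {s!r}") from exc


def _extended_precision_quantile(p_str: str) -> float:
    """Upper-tail standard normal quantile of p/2 at extended precision."""
    import mpmath

    with mpmath.workdps(40):
        p = mpmath.mpf(p_str)
        if p <= 0:
            raise ValueError(f"p-value must be positive, got {p_str}")
        # digits needed to resolve 1 - p before erfinv
        mpmath.mp.dps = max(40, int(-mpmath.log10(p)) + 25)
        z = mpmath.sqrt(2) * mpmath.erfinv(1 - p)
        return float(z)


def pvalue_from_se(beta: float, se: float) -> float:
    """Two-sided normal Wald p-value; inverse of :func:`se_from_pvalue`."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(2.0 * stats.norm.sf(abs(beta) / se))


# ---------------------------------------------------------------------------
# Orientation and exclusions


def orient_risk_increasing(ds: SummaryDataset) -> SummaryDataset:
    """Re-orient every variant to its risk-increasing allele.

    Variants with a negative outcome association have the signs of the
    outcome beta and all risk-factor betas flipped (equivalent to swapping
    the effect allele).  SEs and LD magnitudes are unchanged; flipping a
    variant also flips the sign of its LD correlations with unflipped
    variants, since the allele count is negated.  Idempotent.
    """
    flip = np.where(ds.Y < 0, -1.0, 1.0)
    ld = None if ds.ld is None else ds.ld * np.outer(flip, flip)
    return replace(ds, X=ds.X * flip[:, None], Y=ds.Y * flip, ld=ld)


def apply_exclusions(
    ds: SummaryDataset, ids: Sequence[str], reason: str = "excluded"
) -> SummaryDataset:
    """Flag ``ids`` as excluded (non-destructive; unknown ids warn)."""
    known = set(ds.variant_ids)
    unknown = [i for i in ids if i not in known]
    if unknown:
        warnings.warn(
            f"{len(unknown)} exclusion ids not present in dataset: "
            f"{unknown[:5]}{'...' if len(unknown) > 5 else ''}",
            stacklevel=2,
        )
    excluded = dict(ds.excluded)
    for i in ids:
        if i in known and i not in excluded:
            excluded[i] = reason
    return replace(ds, excluded=excluded)


def clear_exclusions(ds: SummaryDataset) -> SummaryDataset:
    """Drop all exclusion flags (exclusion is reversible)."""
    return replace(ds, excluded={})


# ---------------------------------------------------------------------------
# Delimited-text I/O


def read_summary_table(
    path,
    risk_factor_names: Sequence[str],
    column_map: Mapping[str, str] | None = None,
    id_column: str = "id",
    outcome: str = "outcome",
    sep: str | None = None,
) -> SummaryDataset:
    """Read a delimited summary table into a :class:`SummaryDataset`.

    One row per variant.  For each variable ``v`` in ``risk_factor_names``
    plus the outcome, the table must carry ``{v}_beta`` and either ``{v}_se``
    or ``{v}_p`` (SEs reconstructed from p-values where the SE column is
    absent or blank).  ``column_map`` renames table columns to this scheme,
    e.g. ``{"rsid": "id", "ldl_b": "ldl_beta"}``.  Rows with a missing
    outcome beta are rejected.
    """
    if sep is None:
        import csv

        with open(path) as fh:
            sep = csv.Sniffer().sniff(fh.readline(), delimiters="\t,;").delimiter
    # round_trip parsing: written tables reproduce to full precision
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    if id_column not in df.columns:
        raise SummaryDataError(f"missing required id column {id_column!r}")

    variables = list(risk_factor_names) + [outcome]
    beta_cols = {}
    for v in variables:
        col = f"{v}_beta"
        if col not in df.columns:
            raise SummaryDataError(f"missing required column {col!r}")
        beta_cols[v] = col
    if df[beta_cols[outcome]].isna().any():
        bad = df.loc[df[beta_cols[outcome]].isna(), id_column].tolist()
        raise SummaryDataError(f"missing outcome beta for variants {bad}")

    def numeric(col: str) -> np.ndarray:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = df.loc[bad, id_column].iloc[0]
            raise SummaryDataError(f"non-numeric value in column {col!r}, row {row!r}")
        return vals.to_numpy(dtype=float)

    betas, ses = {}, {}
    for v in variables:
        b = numeric(beta_cols[v])
        se_col, p_col = f"{v}_se", f"{v}_p"
        se = numeric(se_col) if se_col in df.columns else np.full(len(df), np.nan)
        if p_col in df.columns:
            pvals = numeric(p_col)
            need = np.isnan(se) & ~np.isnan(pvals)
            # p < 1 rows first; p = 1 rows then fall back to the mean SE of
            # the same variable across the other variants
            for j in np.where(need & (pvals < 1.0))[0]:
                se[j] = se_from_pvalue(b[j], pvals[j])
            for j in np.where(need & (pvals == 1.0))[0]:
                others = se[~np.isnan(se) & (np.arange(len(se)) != j)]
                se[j] = se_from_pvalue(b[j], 1.0, fallback_ses=others.tolist())
        if np.isnan(se).any():
            raise SummaryDataError(
                f"variable {v!r}: neither SE nor p-value available for some rows"
            )
        betas[v], ses[v] = b, se

    excluded = {}
    if "excluded" in df.columns:
        for vid, reason in zip(df[id_column], df["excluded"].fillna("")):
            if str(reason):
                excluded[str(vid)] = str(reason)

    return SummaryDataset(
        variant_ids=tuple(str(v) for v in df[id_column]),
        risk_factor_names=tuple(risk_factor_names),
        X=np.column_stack([betas[v] for v in risk_factor_names]),
        SE_X=np.column_stack([ses[v] for v in risk_factor_names]),
        Y=betas[outcome],
        SE_Y=ses[outcome],
        excluded=excluded,
    )


def write_summary_table(ds: SummaryDataset, path, sep: str = "\t") -> None:
    """Write a dataset in the layout :func:`read_summary_table` consumes.

    Numeric fields are written with full round-trip precision.
    """
    ds.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_ld_matrix(path, sep: str = "\t") -> tuple[np.ndarray, list[str]]:
    """Square LD matrix from delimited text with a header row of variant ids."""
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    ids = [str(c) for c in df.columns]
    return df.to_numpy(dtype=float), ids


def write_ld_matrix(ld: np.ndarray, ids: Sequence[str], path, sep: str = "\t") -> None:
    pd.DataFrame(ld, index=list(ids), columns=list(ids)).to_csv(
        path, sep=sep, float_format="%.17g"
    )


def attach_ld(ds: SummaryDataset, ld: np.ndarray, ids: Sequence[str]) -> SummaryDataset:
    """Attach an LD matrix, aligning its rows/columns to the dataset by id.

    Variants absent from ``ids`` are treated as independent (identity rows).
    """
    ld = np.asarray(ld, dtype=float)
    idx = {str(v): i for i, v in enumerate(ids)}
    J = ds.n_variants
    out = np.eye(J)
    pos = [(j, idx[v]) for j, v in enumerate(ds.variant_ids) if v in idx]
    for j, a in pos:
        for k, b in pos:
            out[j, k] = ld[a, b]
    return replace(ds, ld=out)
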