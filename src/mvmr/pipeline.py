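"""End-to-end analysis runner tying the stages into one reproducible run.

A :class:`RunConfig` (serializable to/from JSON) fully determines a run:
inputs, correlation parameters, prior, sampler settings, pruning
percentiles and seed.  :func:`run_analysis` executes the standard sequence
— fit, heterogeneity test, percentile pruning with refits, lipid-score
table — writing each stage's outputs as delimited text plus JSON twins and
a run log.  No computation lives here; every number comes from the library
modules.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .data import (
    CorrelationSpec,
    SummaryDataset,
    apply_exclusions,
    attach_ld,
    read_ld_matrix,
    read_summary_table,
)
from .design import lipid_score
from .heterogeneity import lr_heterogeneity_test, prune_by_percentile
from .inference import CausalEstimates, PriorSpec, fit_mcmc

__all__ = ["RunConfig", "StageError", "run_analysis", "run_analysis_on_dataset"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    summary_path: str
    risk_factor_names: Sequence[str]
    output_dir: str
    ld_path: str | None = None
    column_map: dict | None = None
    exclusion_lists: Sequence[str] = ()          # paths of id-per-line files
    rho: Sequence[float] | None = None           # upper-triangle correlations
    prior_kind: str = "vague-normal"
    prior_scale: float = 1000.0
    prior_bounds: tuple[float, float] = (-3.0, 3.0)
    chains: int = 4
    iterations: int = 25_000
    warmup: int = 2_000
    seed: int = 0
    pruning_percentiles: Sequence[float] = (0.98, 0.95, 0.90)

    def prior(self) -> PriorSpec:
        return PriorSpec(self.prior_kind, self.prior_scale, tuple(self.prior_bounds))

    def correlation(self) -> CorrelationSpec:
        k = len(self.risk_factor_names)
        if self.rho is not None:
            return CorrelationSpec.from_rhos(list(self.rho), k=k)
        return (
            CorrelationSpec.lipid_default() if k == 3 else CorrelationSpec.identity(k)
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _write_estimates(fit: CausalEstimates, outdir: Path, tag: str) -> None:
    table = fit.to_frame()
    table.to_csv(outdir / f"estimates_{tag}.tsv", sep="\t", index=False)
    payload = table.to_dict(orient="records")
    (outdir / f"estimates_{tag}.json").write_text(
        json.dumps(payload, indent=2, default=float)
    )


def load_inputs(config: RunConfig) -> SummaryDataset:
    """Read the summary table, attach LD, and apply exclusion lists."""
    ds = read_summary_table(
        config.summary_path,
        risk_factor_names=config.risk_factor_names,
        column_map=config.column_map,
    )
    if config.ld_path:
        ld, ids = read_ld_matrix(config.ld_path)
        ds = attach_ld(ds, ld, ids)
    for path in config.exclusion_lists:
        ids = [
            ln.strip()
            for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        ds = apply_exclusions(ds, ids, reason=f"listed in {Path(path).name}")
    return ds


def run_analysis(config: RunConfig) -> dict:
    """Run the full sequence from files on disk; see
    :func:`run_analysis_on_dataset` for the in-memory equivalent."""
    try:
        ds = load_inputs(config)
    except Exception as exc:
        raise StageError("load", exc) from exc
    return run_analysis_on_dataset(ds, config)


def run_analysis_on_dataset(ds: SummaryDataset, config: RunConfig) -> dict:
    """Fit, test heterogeneity, prune at each percentile with refits, and
    tabulate lipid scores, writing every table to ``config.output_dir``.

    Pruning percentiles are each applied to the *initial* fit (the per-block
    contributions are computed once), so the pruned sets are nested; each
    pruned dataset is then refitted.  The run log records the seed, package
    versions, all thresholds, and the heterogeneity statistic before and
    after each exclusion so the sequence is auditable.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    corr = config.correlation()
    prior = config.prior()
    log: dict = {
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "n_variants": ds.n_variants,
        "n_active": ds.n_active,
        "pruning_percentiles": list(config.pruning_percentiles),
        "stages": [],
    }
    results: dict = {"dataset": ds, "config": config}

    def fit_stage(data: SummaryDataset, tag: str) -> CausalEstimates:
        fit = fit_mcmc(
            data,
            corr,
            prior=prior,
            chains=config.chains,
            iterations=config.iterations,
            warmup=config.warmup,
            seed=config.seed,
        )
        _write_estimates(fit, outdir, tag)
        log["stages"].append(
            {
                "stage": f"fit_{tag}",
                "n_active": data.n_active,
                "estimates": fit.estimate.tolist(),
                "se": fit.se.tolist(),
                "rhat": fit.rhat.tolist(),
                "converged": fit.converged,
            }
        )
        return fit

    try:
        fit = fit_stage(ds, "full")
        results["fit"] = fit
    except Exception as exc:
        raise StageError("fit", exc) from exc

    try:
        het = lr_heterogeneity_test(ds, corr, fit)
        het.per_block.to_csv(outdir / "heterogeneity_blocks.tsv", sep="\t", index=False)
        (outdir / "heterogeneity.json").write_text(
            json.dumps(
                {"statistic": het.statistic, "df": het.df, "p": het.p}, indent=2
            )
        )
        log["stages"].append(
            {"stage": "heterogeneity", "statistic": het.statistic,
             "df": het.df, "p": het.p}
        )
        results["heterogeneity"] = het
    except Exception as exc:
        raise StageError("heterogeneity", exc) from exc

    results["pruned"] = {}
    for pct in config.pruning_percentiles:
        tag = f"pruned_{int(round(pct * 100))}"
        try:
            pruned_ds, report = prune_by_percentile(ds, corr, pct, fit)
            report.to_csv(outdir / f"{tag}_report.tsv", sep="\t", index=False)
            refit = fit_stage(pruned_ds, tag)
            het_after = lr_heterogeneity_test(pruned_ds, corr, refit)
            log["stages"].append(
                {
                    "stage": f"heterogeneity_{tag}",
                    "statistic": het_after.statistic,
                    "df": het_after.df,
                    "p": het_after.p,
                    "n_removed": int(report["removed"].sum()),
                }
            )
            results["pruned"][pct] = {
                "dataset": pruned_ds,
                "report": report,
                "fit": refit,
                "heterogeneity": het_after,
            }
        except Exception as exc:
            raise StageError(tag, exc) from exc

    try:
        scores = lipid_score(fit, ds, het)
        scores.to_csv(outdir / "lipid_scores.tsv", sep="\t", index=False)
        results["scores"] = scores
    except Exception as exc:
        raise StageError("score", exc) from exc

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    results["log"] = log
    return results
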