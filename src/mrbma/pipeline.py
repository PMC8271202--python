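"""End-to-end orchestration: read -> harmonize -> filter -> MR-BMA ->
diagnostics -> rerun -> permutation inference -> report.

A run emits both the all-variants result and the post-diagnostics (primary)
result, each with models and factors tables, plus a machine-readable
manifest recording every threshold, prior, seed and removed variant — the
manifest alone suffices to reproduce the run.  Sensitivity analyses
(alternative outcome datasets, alternative instrument sets, leave-one-factor-
out) are expressed purely as alternative configurations, never code paths.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .bma_core import (
    BMAResult,
    PriorConfig,
    factors_table,
    models_table,
    score_models,
    standardize,
)
from .data_model import (
    ConfigurationError,
    ExposurePanel,
    HarmonizedDataset,
    TableSpec,
    harmonize,
    read_exposure_table,
    read_outcome_table,
    write_harmonized,
)
from .diagnostics import DiagnosticsConfig, run_diagnostics, scatter_table
from .inference import PermutationConfig, permutation_null, summarize_factors
from .preprocessing import (
    FactorFilterConfig,
    InstrumentFilterConfig,
    LDTable,
    select_instruments,
)

logger = logging.getLogger("mrbma")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run (serialized to the manifest)."""

    exposure_path: str
    outcome_path: str
    output_dir: str
    seed: int
    ld_path: Optional[str] = None
    drop_palindromic: bool = False
    exposure_table: TableSpec = field(default_factory=TableSpec)
    outcome_table: TableSpec = field(default_factory=TableSpec)
    instrument_filter: InstrumentFilterConfig = field(default_factory=InstrumentFilterConfig)
    factor_filter: FactorFilterConfig = field(default_factory=FactorFilterConfig)
    prior: PriorConfig = field(default_factory=PriorConfig)
    diagnostics: DiagnosticsConfig = field(default_factory=DiagnosticsConfig)
    n_perm: int = 1000
    search_mode: str = "exhaustive"
    search_budget: Optional[int] = None
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.search_mode == "stochastic" and self.seed is None:
            raise ConfigurationError("seed is mandatory with stochastic search")

    def to_manifest_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        sd = raw["prior"]["effect_sd"]
        if isinstance(sd, np.ndarray):
            raw["prior"]["effect_sd"] = sd.tolist()
        return raw

    @classmethod
    def from_manifest(cls, manifest: dict | str | Path) -> "RunConfig":
        if not isinstance(manifest, dict):
            manifest = json.loads(Path(manifest).read_text())
        cfg = dict(manifest["config"] if "config" in manifest else manifest)
        cfg["exposure_table"] = TableSpec(**cfg["exposure_table"])
        cfg["outcome_table"] = TableSpec(**cfg["outcome_table"])
        cfg["instrument_filter"] = InstrumentFilterConfig(**cfg["instrument_filter"])
        ff = dict(cfg["factor_filter"])
        ff["keep_list"] = tuple(ff.get("keep_list", ()))
        ff["drop_list"] = tuple(ff.get("drop_list", ()))
        cfg["factor_filter"] = FactorFilterConfig(**ff)
        prior = dict(cfg["prior"])
        if isinstance(prior.get("effect_sd"), list):
            prior["effect_sd"] = np.asarray(prior["effect_sd"])
        cfg["prior"] = PriorConfig(**prior)
        cfg["diagnostics"] = DiagnosticsConfig(**cfg["diagnostics"])
        return cls(**cfg)


def _subset_exposure(panel: ExposurePanel, keep_ids: set[str]) -> ExposurePanel:
    idx = [i for i, v in enumerate(panel.variants) if v.identifier in keep_ids]
    return ExposurePanel(
        variants=[panel.variants[i] for i in idx],
        factors=list(panel.factors),
        beta_x=panel.beta_x[idx],
        se_x=None if panel.se_x is None else panel.se_x[idx],
        pval_x=None if panel.pval_x is None else panel.pval_x[idx],
    )


def _write_result_tables(
    outdir: Path,
    name: str,
    result: BMAResult,
    X: np.ndarray,
    y: np.ndarray,
    prior: PriorConfig,
    n_perm: int,
    perm_seed: int,
    top_k: int,
    search_mode: str,
    search_budget: Optional[int],
) -> dict:
    subdir = outdir / name
    subdir.mkdir(parents=True, exist_ok=True)
    emp_p, _ = permutation_null(
        X, y, prior, result,
        PermutationConfig(n_perm=n_perm, seed=perm_seed),
        mode=search_mode, budget=search_budget)
    factors = summarize_factors(result, emp_p, m=len(result.factors or result.mip))
    models_table(result, top_k=top_k).to_csv(subdir / "models.tsv", sep="\t", index=False)
    factors.to_csv(subdir / "factors.tsv", sep="\t", index=False)
    top_factor = str(factors.iloc[0]["factor"])
    return {"top_factor": top_factor, "n_models_scored": result.models_visited}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory of artifacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_manifest_dict(), "status": "incomplete", "stages": {}}
    stage = "setup"
    try:
        stage = "read"
        logger.info("[read] exposure=%s outcome=%s", config.exposure_path, config.outcome_path)
        exposure = read_exposure_table(config.exposure_path, config.exposure_table)
        outcome = read_outcome_table(config.outcome_path, config.outcome_table)
        manifest["stages"]["read"] = {
            "n_exposure_variants": exposure.n_variants, "n_factors": len(exposure.factors)}

        stage = "select_instruments"
        if config.ld_path is not None:
            if exposure.pval_x is None:
                raise ConfigurationError("instrument selection needs exposure p-values")
            ld = LDTable.from_tsv(config.ld_path)
            pmin = np.nanmin(exposure.pval_x, axis=1)
            candidates = list(zip(exposure.variants, pmin))
            retained = select_instruments(candidates, ld, config.instrument_filter)
            exposure = _subset_exposure(exposure, {v.identifier for v in retained})
            logger.info("[select_instruments] retained %d variants", exposure.n_variants)
            manifest["stages"]["select_instruments"] = {"n_retained": exposure.n_variants}
        else:
            logger.info("[select_instruments] skipped (no LD table supplied)")
            manifest["stages"]["select_instruments"] = {"skipped": True}

        stage = "harmonize"
        dataset = harmonize(exposure, outcome, drop_palindromic=config.drop_palindromic)
        write_harmonized(dataset, outdir / "harmonized.tsv", outdir / "provenance.tsv")
        manifest["stages"]["harmonize"] = {
            "n_variants": dataset.n_variants,
            "n_dropped": len(dataset.provenance)}

        stage = "prune_factors"
        from .preprocessing import prune_factors

        dataset, corr, decisions = prune_factors(dataset, config.factor_filter)
        corr.to_csv(outdir / "factor_correlation.tsv", sep="\t")
        decisions.to_csv(outdir / "factor_decisions.tsv", sep="\t", index=False)
        manifest["stages"]["prune_factors"] = {
            "n_factors": dataset.n_factors,
            "dropped": decisions["item"].tolist() if len(decisions) else []}

        stage = "mr_bma_all_variants"
        X, y = standardize(dataset)
        all_result = score_models(X, y, config.prior, mode=config.search_mode,
                                  budget=config.search_budget, seed=config.seed,
                                  factors=list(dataset.factors))
        manifest["stages"]["mr_bma_all_variants"] = _write_result_tables(
            outdir, "all_variants", all_result, X, y, config.prior, config.n_perm,
            perm_seed=config.seed + 1, top_k=config.top_k,
            search_mode=config.search_mode, search_budget=config.search_budget)

        stage = "diagnostics"
        cleaned, report = run_diagnostics(
            dataset, all_result, config.diagnostics, config.prior,
            mode=config.search_mode, budget=config.search_budget, seed=config.seed)
        report.table.to_csv(outdir / "diagnostics.tsv", sep="\t", index=False)
        report.removed.to_csv(outdir / "removed_variants.tsv", sep="\t", index=False)
        removed_ids = report.removed["variant"].unique().tolist() if len(report.removed) else []
        manifest["stages"]["diagnostics"] = {
            "rounds": report.rounds_run,
            "exhausted": report.exhausted,
            "thresholds": report.thresholds,
            "removed_variants": removed_ids,
            "n_variants_primary": cleaned.n_variants}

        stage = "mr_bma_primary"
        Xc, yc = standardize(cleaned)
        primary = report.final_result
        if primary is None or primary is all_result and removed_ids:
            primary = score_models(Xc, yc, config.prior, mode=config.search_mode,
                                   budget=config.search_budget, seed=config.seed,
                                   factors=list(cleaned.factors))
        info = _write_result_tables(
            outdir, "primary", primary, Xc, yc, config.prior, config.n_perm,
            perm_seed=config.seed + 2, top_k=config.top_k,
            search_mode=config.search_mode, search_budget=config.search_budget)
        manifest["stages"]["mr_bma_primary"] = info

        stage = "scatter_table"
        scatter = scatter_table(dataset, info["top_factor"], removed_ids=removed_ids)
        scatter.to_csv(outdir / "top_factor_scatter.tsv", sep="\t", index=False)

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "incomplete"
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return outdir


def render_report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run: ranked model and factor tables.

    Effects are shown to 3 decimals (display only; the TSVs keep full
    precision).  Factor labels containing commas are quoted so the models
    column stays parseable.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError(f"stage 'report' failed: missing artifact {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("status") != "complete":
        raise PipelineError(
            f"stage 'report' failed: run is {manifest.get('status')} "
            f"(failed stage: {manifest.get('failed_stage')})")

    def _quote(label: str) -> str:
        return f'"{label}"' if "," in label else label

    lines: list[str] = []
    for name, title in (("primary", "Primary analysis (after model diagnostics)"),
                        ("all_variants", "All-variants analysis")):
        mpath = run_dir / name / "models.tsv"
        fpath = run_dir / name / "factors.tsv"
        if not mpath.exists() or not fpath.exists():
            raise PipelineError(f"stage 'report' failed: missing artifacts under {run_dir / name}")
        models = pd.read_csv(mpath, sep="\t")
        factors = pd.read_csv(fpath, sep="\t")
        lines.append(title)
        lines.append("=" * len(title))
        lines.append("")
        lines.append("Top models by posterior probability:")
        lines.append(f"{'rank':>4}  {'model':<40} {'posterior':>9}  causal effects")
        for r in models.itertuples():
            effects = ", ".join(f"{float(v):.3f}" for v in str(r.causal_effects).split(","))
            lines.append(f"{r.rank:>4}  {str(r.model):<40} {r.posterior_prob:>9.3f}  {effects}")
        lines.append("")
        lines.append("Top risk factors by marginal inclusion probability:")
        lines.append(f"{'factor':<24} {'mip':>7} {'mace':>8} {'empirical_p':>12} {'fdr':>7}")
        for r in factors.head(10).itertuples():
            lines.append(f"{_quote(str(r.factor)):<24} {r.mip:>7.3f} {r.mace:>8.3f} "
                         f"{r.empirical_p:>12.4g} {r.fdr:>7.3f}")
        lines.append("")

    removed = manifest["stages"].get("diagnostics", {}).get("removed_variants", [])
    lines.append(f"Variants removed by diagnostics: {len(removed)}"
                 + (f" ({', '.join(removed)})" if removed else ""))
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
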