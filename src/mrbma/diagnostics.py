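"""Per-variant influence and outlier diagnostics for the best models, and
the iterative variant-removal workflow run before the primary analysis.

Two statistics are computed for every (model, variant) pair on the
standardized (IVW) scale:

* **Cook's distance** — the shift in all fitted values when the variant is
  deleted, ``D_i = r_i^2 h_i / (k s^2 (1 - h_i)^2)`` with leverage ``h_i``,
  raw residual ``r_i`` and residual mean square ``s^2``; large values mark
  instruments that single-handedly steer the causal-effect estimates.
* **Q contribution** — the variant's squared standardized residual
  ``q_i = (y_i - x_i' theta_hat)^2``, its share of the heterogeneity Q
  statistic; large values mark outlying (potentially pleiotropic) variants.

Variants flagged by either rule in any model above the posterior-probability
floor are removed as a union, MR-BMA is rerun on the cleaned dataset, and
the cycle repeats until no flags remain or the round cap is hit.  Removal is
permanent across rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bma_core import BMAResult, PriorConfig, fit_subset, score_models, standardize
from .data_model import ConfigurationError, HarmonizedDataset

logger = logging.getLogger("mrbma")


@dataclass
class DiagnosticsConfig:
    """Thresholds for the influence/outlier workflow.

    cooks_threshold_rule
        Quantile of the F(k, n-k) reference distribution above which a
        Cook's distance flags a variant (default 0.5, the median-F rule).
    q_alpha
        Per-dataset error rate for the outlier cutoff: q_i is compared with
        the 1 - q_alpha/n quantile of chi-square(1) (Bonferroni-style).
    """

    model_prob_floor: float = 0.02
    cooks_threshold_rule: float = 0.5
    q_alpha: float = 0.05
    max_rounds: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.model_prob_floor < 1.0):
            raise ConfigurationError(f"model_prob_floor must be in (0,1), got {self.model_prob_floor}")
        if not (0.0 < self.cooks_threshold_rule < 1.0):
            raise ConfigurationError(f"cooks_threshold_rule must be in (0,1)")
        if not (0.0 < self.q_alpha < 1.0):
            raise ConfigurationError(f"q_alpha must be in (0,1)")
        if self.max_rounds < 1:
            raise ConfigurationError(f"max_rounds must be >= 1, got {self.max_rounds}")


@dataclass
class DiagnosticsReport:
    """Per-(model, variant) statistics, removal decisions, and the final rerun."""

    table: pd.DataFrame                      # variant, model, cooks_distance, q_contribution, flag, round
    removed: pd.DataFrame                    # variant, round, model, statistic, value, threshold
    thresholds: dict
    rounds_run: int
    exhausted: bool
    final_result: Optional[BMAResult] = None


def cooks_distance(X: np.ndarray, y: np.ndarray, subset: Sequence[int]) -> np.ndarray:
    """Closed-form Cook's distance per variant for the interceptless subset fit.

    Equivalent to literal leave-one-out refitting:
    ``D_i = sum_j (yhat_j - yhat_j^(-i))^2 / (k s^2)``.  A leverage of 1
    yields an infinite distance (the fit is fully determined by that point).
    """
    subset = tuple(subset)
    k = len(subset)
    n = X.shape[0]
    if n <= k + 1:
        raise ValueError(f"need n > |subset| + 1: n={n}, k={k}")
    Xs = X[:, list(subset)]
    theta, _ = fit_subset(X, y, subset)
    resid = y - Xs @ theta
    Ginv_Xt = np.linalg.solve(Xs.T @ Xs, Xs.T)
    h = np.einsum("ij,ji->i", Xs, Ginv_Xt)
    s2 = float(resid @ resid) / (n - k)
    if s2 == 0.0:
        return np.where(h >= 1.0 - 1e-12, np.inf, 0.0)
    d = np.empty(n)
    near_one = h >= 1.0 - 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        d = resid**2 * h / (k * s2 * (1.0 - h) ** 2)
    d[near_one] = np.inf
    return d


def q_contributions(X: np.ndarray, y: np.ndarray, subset: Sequence[int]) -> np.ndarray:
    """Per-variant contribution to heterogeneity Q: squared standardized residual."""
    subset = tuple(subset)
    theta, _ = fit_subset(X, y, subset)
    resid = y - X[:, list(subset)] @ theta
    return resid**2


def diagnose_models(
    X: np.ndarray,
    y: np.ndarray,
    models: Sequence[tuple[tuple[int, ...], float]],
    config: DiagnosticsConfig,
    factors: Optional[Sequence[str]] = None,
    variant_ids: Optional[Sequence[str]] = None,
    round_no: int = 1,
) -> tuple[pd.DataFrame, list[dict]]:
    """Compute D and q for each (model, variant); return the table and flag records."""
    n = X.shape[0]
    q_cut = float(stats.chi2.ppf(1.0 - config.q_alpha / n, df=1))
    ids = list(variant_ids) if variant_ids is not None else [str(i) for i in range(n)]
    rows = []
    flags: list[dict] = []
    for subset, prob in models:
        k = len(subset)
        labels = ",".join(factors[j] for j in subset) if factors else ",".join(map(str, subset))
        d_cut = float(stats.f.ppf(config.cooks_threshold_rule, k, n - k))
        D = cooks_distance(X, y, subset)
        q = q_contributions(X, y, subset)
        for i in range(n):
            influential = bool(D[i] > d_cut)
            outlier = bool(q[i] > q_cut)
            flag = "influential" if influential else ("outlier" if outlier else "clean")
            if influential and outlier:
                flag = "influential+outlier"
            rows.append({"variant": ids[i], "model": labels, "model_prob": prob,
                         "cooks_distance": D[i], "q_contribution": q[i],
                         "flag": flag, "round": round_no})
            if influential:
                flags.append({"variant": ids[i], "round": round_no, "model": labels,
                              "statistic": "cooks_distance", "value": float(D[i]), "threshold": d_cut})
            if outlier:
                flags.append({"variant": ids[i], "round": round_no, "model": labels,
                              "statistic": "q_contribution", "value": float(q[i]), "threshold": q_cut})
    return pd.DataFrame(rows), flags


def run_diagnostics(
    dataset: HarmonizedDataset,
    bma_result: BMAResult,
    config: DiagnosticsConfig,
    prior: PriorConfig,
    mode: str = "exhaustive",
    budget: Optional[int] = None,
    seed: Optional[int] = None,
) -> tuple[HarmonizedDataset, DiagnosticsReport]:
    """Iterative influence/outlier removal followed by an MR-BMA rerun.

    Every model in ``bma_result`` with posterior probability at or above
    ``model_prob_floor`` is diagnosed; the union of flagged variants is
    removed, MR-BMA is rerun on the cleaned dataset, and the loop repeats
    until no flags remain or ``max_rounds`` is reached.  If a removal would
    leave fewer than ``max_model_size + 2`` variants the workflow stops with
    a diagnostics-exhausted warning and returns the current state.
    """
    diagnosed = [(m.subset, m.posterior_prob) for m in bma_result.models
                 if m.posterior_prob >= config.model_prob_floor and not m.degenerate]
    if not diagnosed:
        raise ValueError(
            f"no model reaches model_prob_floor={config.model_prob_floor}; nothing to diagnose")

    current = dataset
    result = bma_result
    all_rows: list[pd.DataFrame] = []
    removed_records: list[dict] = []
    exhausted = False
    rounds_run = 0
    n0 = dataset.n_variants
    thresholds = {
        "model_prob_floor": config.model_prob_floor,
        "cooks_threshold_rule": f"F(k, n-k) quantile {config.cooks_threshold_rule}",
        "q_threshold_rule": f"chi2(1) quantile 1 - {config.q_alpha}/n",
        "max_rounds": config.max_rounds,
    }

    for round_no in range(1, config.max_rounds + 1):
        rounds_run = round_no
        X, y = standardize(current)
        table, flags = diagnose_models(
            X, y, diagnosed, config, factors=current.factors,
            variant_ids=[v.identifier for v in current.variants], round_no=round_no)
        all_rows.append(table)
        flagged_ids = sorted({f["variant"] for f in flags})
        if not flagged_ids:
            break
        n_after = current.n_variants - len(flagged_ids)
        if n_after <= prior.max_model_size + 2:
            logger.warning(
                "diagnostics exhausted: removing %d variants would leave n=%d <= max_model_size+2=%d",
                len(flagged_ids), n_after, prior.max_model_size + 2)
            exhausted = True
            break
        removed_records.extend(flags)
        keep = np.array([v.identifier not in set(flagged_ids) for v in current.variants])
        current = current.subset_variants(keep)
        result = score_models(*standardize(current), prior, mode=mode, budget=budget,
                              seed=seed, factors=list(current.factors))
        diagnosed = [(m.subset, m.posterior_prob) for m in result.models
                     if m.posterior_prob >= config.model_prob_floor and not m.degenerate]
        if not diagnosed:
            logger.warning("no model above floor after round %d; stopping diagnostics", round_no)
            break

    removed = pd.DataFrame(removed_records,
                           columns=["variant", "round", "model", "statistic", "value", "threshold"])
    n_removed = removed["variant"].nunique() if len(removed) else 0
    assert n_removed + current.n_variants == n0
    report = DiagnosticsReport(
        table=pd.concat(all_rows, ignore_index=True),
        removed=removed, thresholds=thresholds,
        rounds_run=rounds_run, exhausted=exhausted, final_result=result)
    return current, report


def scatter_table(
    dataset: HarmonizedDataset,
    factor: str,
    removed_ids: Sequence[str] = (),
    gene_map: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Per-variant table behind the outcome-vs-exposure diagnostic scatterplot.

    One row per pre-removal variant: genetic association with the chosen
    factor, association with the outcome, and whether the variant was
    removed by diagnostics.  ``gene_map`` optionally annotates variants with
    gene-region labels (pass-through only).
    """
    j = dataset.factors.index(factor)
    removed_set = set(removed_ids)
    df = pd.DataFrame({
        "variant": [v.identifier for v in dataset.variants],
        f"beta_{factor}": dataset.beta_x[:, j],
        "beta_y": dataset.beta_y,
        "se_y": dataset.se_y,
        "flag": ["removed" if v.identifier in removed_set else "retained" for v in dataset.variants],
    })
    if gene_map:
        df["gene_region"] = [gene_map.get(v.identifier, "") for v in dataset.variants]
    return df
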