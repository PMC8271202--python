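"""Permutation-based empirical p-values for marginal inclusion probabilities
and Benjamini-Hochberg false-discovery-rate adjustment.

The permutation null severs the variant-outcome linkage by randomly
permuting the standardized response across variants while keeping the
exposure design (and hence the factor-factor correlation structure) intact.
MR-BMA is rerun on each permuted response and the per-factor marginal
inclusion probability recorded; the add-one estimator

    p_j = (1 + #{permutations with permuted MIP_j >= observed MIP_j}) / (1 + N)

avoids zero p-values.  FDR adjustment follows the step-up BH rule, with the
family size ``m`` allowed to exceed the number of supplied p-values (the
convention when only the top of a larger family is in hand: unsupplied
p-values are assumed larger than all supplied ones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .bma_core import BMAResult, PriorConfig, _SubsetScorer, score_models
from .data_model import ConfigurationError

logger = logging.getLogger("mrbma")


@dataclass
class PermutationConfig:
    """Settings for the permutation null (statistic: marginal inclusion probability)."""

    n_perm: int = 1000
    seed: int = 0
    store_null: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigurationError(f"n_perm must be >= 1, got {self.n_perm}")


@dataclass
class FactorSummary:
    """Per-factor evidence summary (one row of the ranked risk-factor table)."""

    factor: str
    mip: float
    mace: float
    empirical_p: float
    fdr_adjusted_p: float


def permutation_null(
    X: np.ndarray,
    y: np.ndarray,
    prior: PriorConfig,
    observed: BMAResult,
    config: PermutationConfig,
    mode: str = "exhaustive",
    budget: Optional[int] = None,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Empirical per-factor p-values for the observed MIPs under permuted responses.

    Returns ``(empirical_p, null_mips)`` where ``null_mips`` is the
    (n_perm x d) matrix of permuted MIPs when ``config.store_null`` and
    ``None`` otherwise (streaming exceedance counters are used regardless).
    Bit-reproducible given ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    d = X.shape[1]
    observed_mip = np.asarray(observed.mip, dtype=float)
    rng = np.random.default_rng(config.seed)
    exceed = np.zeros(d, dtype=np.int64)
    stored = np.empty((config.n_perm, d)) if config.store_null else None

    if mode == "exhaustive":
        # reuse one scorer across permutations: the Gram matrix never changes,
        # and only MIPs are needed, so theta fits are skipped
        from scipy.special import logsumexp

        scorer = _SubsetScorer(X, y, prior)
        max_size = min(prior.max_model_size, d, X.shape[0] - 2)
        from .bma_core import _enumerate_subsets

        subsets = list(_enumerate_subsets(d, max_size))
        membership = np.zeros((len(subsets), d), dtype=bool)
        for i, s in enumerate(subsets):
            membership[i, list(s)] = True
        for t in range(config.n_perm):
            scorer.set_response(rng.permutation(y))
            lw = np.array([scorer.log_weight(s) for s in subsets])
            post = np.exp(lw - logsumexp(lw))
            mip = post @ membership
            exceed += mip >= observed_mip
            if stored is not None:
                stored[t] = mip
    else:
        for t in range(config.n_perm):
            perm_seed = int(rng.integers(0, 2**31 - 1))
            res = score_models(X, rng.permutation(y), prior, mode=mode,
                               budget=budget, seed=perm_seed)
            exceed += res.mip >= observed_mip
            if stored is not None:
                stored[t] = res.mip

    empirical_p = (1.0 + exceed) / (1.0 + config.n_perm)
    return empirical_p, stored


def bh_adjust(pvalues: np.ndarray, m: Optional[int] = None) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, with family size ``m >= len(pvalues)``.

    ``adjusted_(r) = min_{j >= r, j supplied} p_(j) * m / j``, capped at 1,
    returned in the input order.  With ``m`` larger than the supplied vector
    the unsupplied members of the family are treated as having p-values
    larger than every supplied one (so they occupy the top ranks and never
    lower an adjusted value).
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    if m is None:
        m = k
    if m < k:
        raise ConfigurationError(f"family size m={m} < number of supplied p-values {k}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(k)
    out[order] = adjusted_sorted
    return out


def summarize_factors(
    result: BMAResult,
    empirical_p: np.ndarray,
    m: Optional[int] = None,
) -> pd.DataFrame:
    """Ranked per-factor table: factor, mip, mace, empirical_p, fdr.

    ``m`` defaults to the number of analyzed factors (the full test family),
    not the number of rows reported.
    """
    labels = result.factors or [str(j) for j in range(len(result.mip))]
    fdr = bh_adjust(np.asarray(empirical_p, dtype=float), m=m if m is not None else len(labels))
    df = pd.DataFrame({
        "factor": labels,
        "mip": result.mip,
        "mace": result.mace,
        "empirical_p": empirical_p,
        "fdr": fdr,
    })
    return df.sort_values(["mip", "factor"], ascending=[False, True], kind="stable").reset_index(drop=True)
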