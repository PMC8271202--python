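"""Instrument selection (significance + LD + distance pruning) and
risk-factor pruning against near-collinearity.

Instruments are selected greedily in ascending p-value order, mirroring
standard LD-clumping practice: a candidate is kept iff it is genome-wide
significant, has r^2 below threshold with every already-kept variant, and is
at least ``min_distance`` base pairs from every kept variant on the same
chromosome.  Risk factors whose genetic-association profiles are almost
perfectly correlated cannot be distinguished by multivariable MR; pairs
exceeding the |r| threshold are broken by removing one member at a time
until none remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import ConfigurationError, HarmonizedDataset, InputError, VariantKey

logger = logging.getLogger("mrbma")


@dataclass
class InstrumentFilterConfig:
    """Thresholds for instrument selection (defaults: P<5e-8, r2<0.05, 1 Mb)."""

    gwas_sig_threshold: float = 5e-8
    ld_r2_threshold: float = 0.05
    min_distance: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("gwas_sig_threshold", "ld_r2_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must be in (0,1), got {v}")
        if self.min_distance < 0:
            raise ConfigurationError(f"min_distance must be >= 0, got {self.min_distance}")


@dataclass
class FactorFilterConfig:
    """Risk-factor pruning: collinearity threshold and strong-instrument rule."""

    max_abs_correlation: float = 0.99
    require_strong_instrument: bool = True
    gwas_sig_threshold: float = 5e-8
    keep_list: tuple[str, ...] = ()
    drop_list: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.max_abs_correlation <= 1.0):
            raise ConfigurationError(
                f"max_abs_correlation must be in (0,1], got {self.max_abs_correlation}")
        self.keep_list = tuple(self.keep_list)
        self.drop_list = tuple(self.drop_list)
        overlap = set(self.keep_list) & set(self.drop_list)
        if overlap:
            raise ConfigurationError(f"factors in both keep_list and drop_list: {sorted(overlap)}")


class LDTable:
    """Symmetric pairwise r^2 lookup keyed by variant identifier."""

    def __init__(self, entries: Optional[dict[tuple[str, str], float]] = None):
        self._r2: dict[frozenset, float] = {}
        for (a, b), r2 in (entries or {}).items():
            self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        self._r2[frozenset((a, b))] = float(r2)

    def get(self, a: str, b: str) -> Optional[float]:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDTable":
        df = pd.read_csv(path, sep="\t")
        needed = ["variant_a", "variant_b", "r2"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ConfigurationError(f"{path}: missing LD columns {missing}")
        table = cls()
        for r in df.itertuples():
            table.set(str(r.variant_a), str(r.variant_b), float(r.r2))
        return table


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (int(chrom), "") if chrom.isdigit() else (10**6, chrom)


def select_instruments(
    candidates: Sequence[tuple[VariantKey, float]],
    ld: LDTable,
    config: InstrumentFilterConfig,
) -> list[VariantKey]:
    """Greedy ascending-p instrument selection with LD and distance pruning.

    ``candidates`` are (variant, selection p-value) pairs.  Ties in p are
    broken by identifier so the output is invariant to input order.
    Cross-chromosome pairs are implicitly r^2 = 0; a missing LD entry
    between two same-chromosome variants is an input error.  The retained
    list is sorted by (chromosome, position).
    """
    ordered = sorted(candidates, key=lambda c: (c[1], c[0].identifier))
    kept: list[VariantKey] = []
    for variant, pval in ordered:
        if not pval < config.gwas_sig_threshold:
            continue
        admissible = True
        for other in kept:
            if variant.chromosome != other.chromosome:
                continue
            if abs(variant.position - other.position) < config.min_distance:
                admissible = False
                break
            r2 = ld.get(variant.identifier, other.identifier)
            if r2 is None:
                raise InputError(
                    f"missing LD entry for same-chromosome pair "
                    f"({variant.identifier}, {other.identifier})")
            if not r2 < config.ld_r2_threshold:
                admissible = False
                break
        if admissible:
            kept.append(variant)
    return sorted(kept, key=lambda v: (_chrom_sort_key(v.chromosome), v.position))


def genetic_correlation_matrix(dataset: HarmonizedDataset) -> pd.DataFrame:
    """Pearson correlation of the per-factor genetic-association columns."""
    df = pd.DataFrame(dataset.beta_x, columns=dataset.factors)
    return df.corr()


def prune_factors(
    dataset: HarmonizedDataset,
    config: FactorFilterConfig,
) -> tuple[HarmonizedDataset, pd.DataFrame, pd.DataFrame]:
    """Remove risk factors until no pair exceeds the |r| threshold.

    Steps, in order: (1) drop ``drop_list`` members; (2) when
    ``require_strong_instrument`` and exposure p-values are available, drop
    factors with no instrument at ``p < gwas_sig_threshold``; (3) while any
    retained pair's genetic-association correlation exceeds
    ``max_abs_correlation`` in absolute value, remove the member of the
    worst pair with the larger mean |correlation| to all other retained
    factors (``keep_list`` members are never removed; a too-correlated pair
    entirely inside ``keep_list`` is a configuration error).

    Returns (reduced dataset, full input correlation matrix, decisions log).
    """
    if dataset.n_variants < 3:
        raise InputError(f"need >= 3 variants to estimate factor correlations, got {dataset.n_variants}")
    corr_full = genetic_correlation_matrix(dataset)
    decisions: list[dict] = []
    retained = list(dataset.factors)
    keep_set = set(config.keep_list)

    for f in config.drop_list:
        if f in retained:
            retained.remove(f)
            decisions.append({"item": f, "action": "drop", "reason": "drop_list"})

    if config.require_strong_instrument and dataset.pval_x is not None:
        for j, f in enumerate(dataset.factors):
            if f not in retained or f in keep_set:
                continue
            pvals = dataset.pval_x[:, j]
            if not np.any(pvals[np.isfinite(pvals)] < config.gwas_sig_threshold):
                retained.remove(f)
                decisions.append({"item": f, "action": "drop",
                                  "reason": f"no instrument with p < {config.gwas_sig_threshold:g}"})

    while True:
        sub = corr_full.loc[retained, retained].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        worst = float(sub.max(initial=0.0))
        # the retained set must end strictly below the threshold
        if worst < config.max_abs_correlation:
            break
        i, j = np.unravel_index(int(sub.argmax()), sub.shape)
        fa, fb = retained[i], retained[j]
        if fa in keep_set and fb in keep_set:
            raise ConfigurationError(
                f"keep_list factors {fa!r} and {fb!r} are correlated at |r|={worst:.4f} "
                f"> {config.max_abs_correlation}; resolve by curation")
        if fa in keep_set:
            victim = fb
        elif fb in keep_set:
            victim = fa
        else:
            # drop the member with larger mean |r| to the other retained factors
            mean_a = (sub[i].sum() - sub[i, j]) / max(len(retained) - 2, 1)
            mean_b = (sub[j].sum() - sub[i, j]) / max(len(retained) - 2, 1)
            victim = max((mean_a, fa), (mean_b, fb))[1]
        retained.remove(victim)
        other = fb if victim == fa else fa
        decisions.append({"item": victim, "action": "drop",
                          "reason": f"|r|={worst:.4f} with {other} > {config.max_abs_correlation}"})

    reduced = dataset.subset_factors(retained)
    log = pd.DataFrame(decisions, columns=["item", "action", "reason"])
    return reduced, corr_full, log
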