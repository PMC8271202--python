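"""Core data types, summary-statistics IO, and allele-aware harmonization.

Two-sample multivariable Mendelian randomization works entirely on GWAS
summary statistics: per-variant association estimates (betas) and standard
errors for a panel of exposures (here, metabolomic risk factors in SD units)
and for a binary disease outcome (log odds ratios).  Before any modelling,
the exposure and outcome tables must be aligned so that every retained
variant's effect alleles agree; where the outcome reports the opposite
allele the sign of its beta is flipped.  Variants that cannot be reconciled,
or that are missing any value, are dropped with an explicit provenance
record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mrbma")


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigurationError(ValueError):
    """Invalid configuration (column mappings, thresholds, list conflicts)."""


VALID_ALLELES = frozenset({"A", "C", "G", "T"})
_PALINDROMIC_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))


@dataclass(frozen=True)
class VariantKey:
    """Identity of a genetic variant: identifier, locus, and allele pair.

    ``effect_allele`` is the allele whose dosage the association betas refer
    to; ``other_allele`` is the reference allele.  Positions are 1-based.
    """

    identifier: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise InputError(f"{self.identifier}: position must be >= 1, got {self.position}")
        for allele in (self.effect_allele, self.other_allele):
            if allele not in VALID_ALLELES:
                raise InputError(f"{self.identifier}: invalid allele {allele!r}")
        if self.effect_allele == self.other_allele:
            raise InputError(f"{self.identifier}: effect and other allele are both {self.effect_allele}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand cannot be resolved from alleles alone."""
        return frozenset({self.effect_allele, self.other_allele}) in _PALINDROMIC_PAIRS

    def alleles_match(self, other: "VariantKey") -> Optional[bool]:
        """Compare allele pairs: True = same orientation, False = swapped, None = irreconcilable."""
        if (self.effect_allele, self.other_allele) == (other.effect_allele, other.other_allele):
            return True
        if (self.effect_allele, self.other_allele) == (other.other_allele, other.effect_allele):
            return False
        return None


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise InputError(f"duplicate {what}: {dups}")


@dataclass
class ExposurePanel:
    """Per-variant genetic associations with each candidate risk factor.

    ``beta_x`` is variants x factors, in SD units of each factor.  Standard
    errors and p-values are optional; p-values are needed only for the
    strong-instrument factor filter.
    """

    variants: list[VariantKey]
    factors: list[str]
    beta_x: np.ndarray
    se_x: Optional[np.ndarray] = None
    pval_x: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        shape = (len(self.variants), len(self.factors))
        if self.beta_x.shape != shape:
            raise InputError(f"beta_x shape {self.beta_x.shape} != (variants, factors) {shape}")
        for name in ("se_x", "pval_x"):
            mat = getattr(self, name)
            if mat is not None:
                mat = np.asarray(mat, dtype=float)
                if mat.shape != shape:
                    raise InputError(f"{name} shape {mat.shape} != {shape}")
                setattr(self, name, mat)
        if self.se_x is not None and np.any(self.se_x[np.isfinite(self.se_x)] <= 0):
            raise InputError("se_x entries must be > 0 where present")
        _check_unique([v.identifier for v in self.variants], "variant identifiers")
        _check_unique(self.factors, "factor labels")

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class OutcomePanel:
    """Per-variant log-odds associations with the binary disease outcome."""

    variants: list[VariantKey]
    beta_y: np.ndarray
    se_y: np.ndarray

    def __post_init__(self) -> None:
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        n = len(self.variants)
        if self.beta_y.shape != (n,) or self.se_y.shape != (n,):
            raise InputError(f"beta_y/se_y must have length {n}")
        if np.any(self.se_y[np.isfinite(self.se_y)] <= 0):
            raise InputError("se_y entries must be > 0")
        _check_unique([v.identifier for v in self.variants], "variant identifiers")


@dataclass
class HarmonizedDataset:
    """Analysis-ready aligned dataset: no missing values, alleles reconciled.

    ``provenance`` records every variant dropped on the way here, as
    (identifier, reason) pairs.  Exposure standard errors / p-values are
    carried along when available because the downstream strong-instrument
    factor filter needs them.
    """

    variants: list[VariantKey]
    factors: list[str]
    beta_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    provenance: list[tuple[str, str]] = field(default_factory=list)
    se_x: Optional[np.ndarray] = None
    pval_x: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        n, d = len(self.variants), len(self.factors)
        if self.beta_x.shape != (n, d):
            raise InputError(f"beta_x shape {self.beta_x.shape} != ({n}, {d})")
        if self.beta_y.shape != (n,) or self.se_y.shape != (n,):
            raise InputError(f"beta_y/se_y must have length {n}")
        if not (np.all(np.isfinite(self.beta_x)) and np.all(np.isfinite(self.beta_y)) and np.all(np.isfinite(self.se_y))):
            raise InputError("harmonized dataset must contain no missing values")
        if np.any(self.se_y <= 0):
            raise InputError("se_y entries must be > 0")
        if n < d + 2:
            logger.warning("harmonized dataset has n=%d < d+2=%d; model fits will be refused", n, d + 2)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def subset_variants(self, keep: np.ndarray) -> "HarmonizedDataset":
        """Row-subset by a boolean mask or index array, preserving provenance."""
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HarmonizedDataset(
            variants=[self.variants[i] for i in idx],
            factors=list(self.factors),
            beta_x=self.beta_x[idx],
            beta_y=self.beta_y[idx],
            se_y=self.se_y[idx],
            provenance=list(self.provenance),
            se_x=None if self.se_x is None else self.se_x[idx],
            pval_x=None if self.pval_x is None else self.pval_x[idx],
        )

    def subset_factors(self, keep_labels: Sequence[str]) -> "HarmonizedDataset":
        """Column-subset to the given factor labels (input order of this dataset kept)."""
        keep = [j for j, f in enumerate(self.factors) if f in set(keep_labels)]
        return HarmonizedDataset(
            variants=list(self.variants),
            factors=[self.factors[j] for j in keep],
            beta_x=self.beta_x[:, keep],
            beta_y=self.beta_y,
            se_y=self.se_y,
            provenance=list(self.provenance),
            se_x=None if self.se_x is None else self.se_x[:, keep],
            pval_x=None if self.pval_x is None else self.pval_x[:, keep],
        )

    def to_panels(self) -> tuple[ExposurePanel, OutcomePanel]:
        """Split back into exposure and outcome panels (e.g. to re-harmonize)."""
        exposure = ExposurePanel(
            variants=list(self.variants), factors=list(self.factors),
            beta_x=self.beta_x.copy(), se_x=None if self.se_x is None else self.se_x.copy(),
            pval_x=None if self.pval_x is None else self.pval_x.copy(),
        )
        outcome = OutcomePanel(variants=list(self.variants), beta_y=self.beta_y.copy(), se_y=self.se_y.copy())
        return exposure, outcome


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

@dataclass
class TableSpec:
    """Column-name mapping for delimited summary-statistics tables.

    ``layout`` is "wide" (one beta/se/pval column per factor, named by the
    ``*_template`` patterns with a ``{factor}`` placeholder) or "long"
    (one row per (variant, factor) with a ``factor`` column).
    """

    layout: str = "wide"
    variant: str = "variant"
    chromosome: str = "chrom"
    position: str = "pos"
    effect_allele: str = "ea"
    other_allele: str = "oa"
    beta: str = "beta"
    se: str = "se"
    pval: str = "pval"
    factor: str = "factor"
    beta_template: str = "beta_{factor}"
    se_template: str = "se_{factor}"
    pval_template: str = "pval_{factor}"

    def __post_init__(self) -> None:
        if self.layout not in ("wide", "long"):
            raise ConfigurationError(f"layout must be 'wide' or 'long', got {self.layout!r}")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory columns {missing}")


def _to_numeric(series: pd.Series, column: str, path: Path) -> np.ndarray:
    """Parse a string column to float; a non-numeric non-empty cell is an input error naming the row."""
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna() & (series.str.strip() != "") & (series.str.upper() != "NA")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise InputError(
            f"{path}: non-numeric value {series.iloc[row]!r} in column {column!r} at data row {row + 1}"
        )
    return out.to_numpy(dtype=float)


def _parse_variants(df: pd.DataFrame, spec: TableSpec, path: Path) -> list[VariantKey]:
    pos = _to_numeric(df[spec.position], spec.position, path)
    return [
        VariantKey(
            identifier=str(r[spec.variant]),
            chromosome=str(r[spec.chromosome]),
            position=int(p),
            effect_allele=str(r[spec.effect_allele]).upper(),
            other_allele=str(r[spec.other_allele]).upper(),
        )
        for (_, r), p in zip(df.iterrows(), pos)
    ]


def read_exposure_table(path: str | Path, spec: TableSpec | None = None) -> ExposurePanel:
    """Read an exposure summary-statistics table (wide or long layout) into an ExposurePanel."""
    spec = spec or TableSpec()
    path = Path(path)
    df = _read_delimited(path)
    key_cols = [spec.variant, spec.chromosome, spec.position, spec.effect_allele, spec.other_allele]

    if spec.layout == "long":
        _require_columns(df, key_cols + [spec.factor, spec.beta], path)
        pairs = df[[spec.variant, spec.factor]]
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].iloc[0]
            raise InputError(f"{path}: duplicate (variant, factor) pair ({dup.iloc[0]}, {dup.iloc[1]})")
        first = df.drop_duplicates(subset=spec.variant, keep="first").reset_index(drop=True)
        variants = _parse_variants(first, spec, path)
        var_ids = [v.identifier for v in variants]
        factors = list(dict.fromkeys(df[spec.factor].astype(str)))
        vi = {v: i for i, v in enumerate(var_ids)}
        fi = {f: j for j, f in enumerate(factors)}
        beta = np.full((len(variants), len(factors)), np.nan)
        se = np.full_like(beta, np.nan) if spec.se in df.columns else None
        pv = np.full_like(beta, np.nan) if spec.pval in df.columns else None
        bvals = _to_numeric(df[spec.beta], spec.beta, path)
        svals = _to_numeric(df[spec.se], spec.se, path) if se is not None else None
        pvals = _to_numeric(df[spec.pval], spec.pval, path) if pv is not None else None
        for row, (v, f) in enumerate(zip(df[spec.variant].astype(str), df[spec.factor].astype(str))):
            i, j = vi[v], fi[f]
            beta[i, j] = bvals[row]
            if svals is not None:
                se[i, j] = svals[row]
            if pvals is not None:
                pv[i, j] = pvals[row]
        return ExposurePanel(variants=variants, factors=factors, beta_x=beta, se_x=se, pval_x=pv)

    # wide layout: factors discovered from beta-template columns, file order kept
    _require_columns(df, key_cols, path)
    prefix, suffix = spec.beta_template.split("{factor}")
    factors = [
        c[len(prefix): len(c) - len(suffix) if suffix else None]
        for c in df.columns
        if c.startswith(prefix) and c.endswith(suffix) and len(c) > len(prefix) + len(suffix)
    ]
    if not factors:
        raise ConfigurationError(f"{path}: no columns match beta template {spec.beta_template!r}")
    variants = _parse_variants(df, spec, path)
    beta = np.column_stack([_to_numeric(df[spec.beta_template.format(factor=f)], f, path) for f in factors])

    def _optional(template: str) -> Optional[np.ndarray]:
        cols = [template.format(factor=f) for f in factors]
        if not all(c in df.columns for c in cols):
            return None
        return np.column_stack([_to_numeric(df[c], c, path) for c in cols])

    return ExposurePanel(variants=variants, factors=factors, beta_x=beta,
                         se_x=_optional(spec.se_template), pval_x=_optional(spec.pval_template))


def read_outcome_table(path: str | Path, spec: TableSpec | None = None) -> OutcomePanel:
    """Read an outcome summary-statistics table (one trait) into an OutcomePanel."""
    spec = spec or TableSpec()
    path = Path(path)
    df = _read_delimited(path)
    needed = [spec.variant, spec.chromosome, spec.position, spec.effect_allele, spec.other_allele,
              spec.beta, spec.se]
    _require_columns(df, needed, path)
    extra = [c for c in df.columns if c not in needed]
    if extra:
        logger.info("outcome table %s: ignoring extra columns %s", path, extra)
    variants = _parse_variants(df, spec, path)
    beta = _to_numeric(df[spec.beta], spec.beta, path)
    se = _to_numeric(df[spec.se], spec.se, path)
    if np.any(se[np.isfinite(se)] <= 0):
        row = int(np.flatnonzero(np.isfinite(se) & (se <= 0))[0])
        raise InputError(f"{path}: non-positive standard error at data row {row + 1}")
    return OutcomePanel(variants=variants, beta_y=beta, se_y=se)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

#: provenance reason for a variant in the exposure panel with no outcome record
ABSENT_IN_OUTCOME = "absent_in_outcome"


def harmonize(
    exposure: ExposurePanel,
    outcome: OutcomePanel,
    drop_palindromic: bool = False,
) -> HarmonizedDataset:
    """Align exposure and outcome panels into one analysis-ready dataset.

    Variants are matched by identifier.  Where the outcome's effect allele
    equals the exposure's other allele, the outcome beta sign is flipped (and
    the alleles swapped); irreconcilable allele pairs are dropped.  Variants
    missing any exposure or outcome value are dropped.  A/T and C/G
    (palindromic) variants are kept with a warning unless ``drop_palindromic``.
    Every drop is recorded in ``provenance`` with its reason.
    """
    out_by_id = {v.identifier: i for i, v in enumerate(outcome.variants)}
    provenance: list[tuple[str, str]] = []
    keep_rows: list[int] = []
    betas_y: list[float] = []
    ses_y: list[float] = []
    n_palindromic = 0

    for i, v in enumerate(exposure.variants):
        j = out_by_id.get(v.identifier)
        if j is None:
            provenance.append((v.identifier, ABSENT_IN_OUTCOME))
            continue
        match = v.alleles_match(outcome.variants[j])
        if match is None:
            provenance.append((v.identifier, "allele_mismatch"))
            continue
        by = outcome.beta_y[j] if match else -outcome.beta_y[j]
        sy = outcome.se_y[j]
        if v.is_palindromic:
            if drop_palindromic:
                provenance.append((v.identifier, "palindromic"))
                continue
            n_palindromic += 1
        if not np.all(np.isfinite(exposure.beta_x[i])) or not (np.isfinite(by) and np.isfinite(sy)):
            provenance.append((v.identifier, "missing_value"))
            continue
        keep_rows.append(i)
        betas_y.append(float(by))
        ses_y.append(float(sy))

    if n_palindromic:
        logger.warning("retaining %d palindromic (A/T or C/G) variant(s); pass drop_palindromic=True to remove",
                       n_palindromic)
    if not keep_rows:
        raise InputError("harmonization left no variants (empty intersection or all dropped)")

    idx = np.asarray(keep_rows)
    return HarmonizedDataset(
        variants=[exposure.variants[i] for i in keep_rows],
        factors=list(exposure.factors),
        beta_x=exposure.beta_x[idx],
        beta_y=np.asarray(betas_y),
        se_y=np.asarray(ses_y),
        provenance=provenance,
        se_x=None if exposure.se_x is None else exposure.se_x[idx],
        pval_x=None if exposure.pval_x is None else exposure.pval_x[idx],
    )


def write_harmonized(dataset: HarmonizedDataset, path: str | Path, provenance_path: str | Path | None = None) -> None:
    """Write a harmonized dataset as TSV (key columns, beta_y, se_y, one beta column per factor)."""
    df = pd.DataFrame({
        "variant": [v.identifier for v in dataset.variants],
        "chrom": [v.chromosome for v in dataset.variants],
        "pos": [v.position for v in dataset.variants],
        "ea": [v.effect_allele for v in dataset.variants],
        "oa": [v.other_allele for v in dataset.variants],
        "beta_y": dataset.beta_y,
        "se_y": dataset.se_y,
    })
    for j, f in enumerate(dataset.factors):
        df[f"beta_{f}"] = dataset.beta_x[:, j]
    if dataset.pval_x is not None:
        for j, f in enumerate(dataset.factors):
            df[f"pval_{f}"] = dataset.pval_x[:, j]
    df.to_csv(path, sep="\t", index=False)
    if provenance_path is not None:
        pd.DataFrame(dataset.provenance, columns=["variant", "reason"]).to_csv(
            provenance_path, sep="\t", index=False)


def read_harmonized(path: str | Path) -> HarmonizedDataset:
    """Read back a harmonized dataset written by :func:`write_harmonized`."""
    df = pd.read_csv(path, sep="\t")
    factors = [c[len("beta_"):] for c in df.columns if c.startswith("beta_") and c != "beta_y"]
    pv_cols = [f"pval_{f}" for f in factors]
    has_pv = all(c in df.columns for c in pv_cols)
    variants = [
        VariantKey(str(r.variant), str(r.chrom), int(r.pos), str(r.ea), str(r.oa))
        for r in df.itertuples()
    ]
    return HarmonizedDataset(
        variants=variants,
        factors=factors,
        beta_x=df[[f"beta_{f}" for f in factors]].to_numpy(float),
        beta_y=df["beta_y"].to_numpy(float),
        se_y=df["se_y"].to_numpy(float),
        pval_x=df[pv_cols].to_numpy(float) if has_pv else None,
    )
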