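"""MR-BMA engine: weighted multivariable regression per risk-factor subset,
closed-form Bayesian model scoring, model search, and model averaging.

The model
---------
With n genetic instruments and d candidate risk factors, let ``beta_x`` be
the n x d matrix of genetic associations with the risk factors (SD units)
and ``beta_y``, ``se_y`` the associations with the disease outcome (log odds
ratios).  Dividing each row by ``se_y[i]`` gives a standardized design X and
response y on which ordinary least squares without intercept is the
fixed-effect inverse-variance-weighted (IVW) multivariable MR estimator.

For a subset s of risk factors the Bayesian model is

    y = X_s theta + eps,   eps ~ N(0, I),   theta_j ~ N(0, sigma_j^2),

whose marginal likelihood N(y | 0, X_s D X_s' + I), D = diag(sigma^2), has a
closed form evaluated through the |s|-dimensional inner matrix
A = I + D^{1/2} X_s' X_s D^{1/2} (matrix determinant lemma + Woodbury), so a
model's score costs one small solve against the cached Gram matrix.

Each subset's posterior probability combines this marginal likelihood with an
independent-inclusion prior p^|s| (1-p)^(d-|s|), normalized over the scored
model space.  A factor's marginal inclusion probability (MIP) is the sum of
posterior probabilities of models containing it; its model-averaged causal
effect (MACE) is the posterior-weighted sum of its estimates across those
models.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .data_model import ConfigurationError, HarmonizedDataset

logger = logging.getLogger("mrbma")

_LOG_2PI = math.log(2.0 * math.pi)


class DegenerateModelError(np.linalg.LinAlgError):
    """Raised when a subset's design columns are rank deficient."""


@dataclass
class PriorConfig:
    """Priors for MR-BMA model scoring.

    inclusion_prob
        Prior probability that any one risk factor is causal (default 0.1,
        i.e. three expected causal factors among thirty candidates).
    effect_sd
        Prior standard deviation of each causal effect on the standardized
        (log odds per SD) scale; a scalar or a per-factor vector.
    max_model_size
        Cap on the cardinality of scored subsets.
    """

    inclusion_prob: float = 0.1
    effect_sd: Union[float, np.ndarray] = 0.5
    max_model_size: int = 12

    def __post_init__(self) -> None:
        if not (0.0 < self.inclusion_prob < 1.0):
            raise ConfigurationError(f"inclusion_prob must be in (0,1), got {self.inclusion_prob}")
        sd = np.asarray(self.effect_sd, dtype=float)
        if np.any(sd <= 0):
            raise ConfigurationError("effect_sd must be > 0")
        if self.max_model_size < 1:
            raise ConfigurationError(f"max_model_size must be >= 1, got {self.max_model_size}")

    def effect_sd_vector(self, d: int) -> np.ndarray:
        sd = np.asarray(self.effect_sd, dtype=float)
        if sd.ndim == 0:
            return np.full(d, float(sd))
        if sd.shape != (d,):
            raise ConfigurationError(f"effect_sd vector has length {sd.shape}, expected {d}")
        return sd


@dataclass
class ModelScore:
    """One scored risk-factor subset."""

    subset: tuple[int, ...]
    theta_hat: np.ndarray
    se_theta: np.ndarray
    log_marginal_likelihood: float
    posterior_prob: float
    degenerate: bool = False


@dataclass
class BMAResult:
    """Outcome of a model search: scored models plus per-factor summaries."""

    models: list[ModelScore]
    mip: np.ndarray
    mace: np.ndarray
    factors: Optional[list[str]]
    mode: str
    models_visited: int
    seed: Optional[int]
    log_marginal_empty: float

    def top_models(self, k: int = 10) -> list[ModelScore]:
        return self.models[:k]


# ---------------------------------------------------------------------------
# Standardization and per-subset fitting
# ---------------------------------------------------------------------------

def standardize(dataset: HarmonizedDataset) -> tuple[np.ndarray, np.ndarray]:
    """Scale rows by 1/se_y so that interceptless OLS equals fixed-effect IVW regression."""
    se = dataset.se_y
    if np.any(se <= 0):
        raise ValueError("se_y must be strictly positive")
    return dataset.beta_x / se[:, None], dataset.beta_y / se


def _gram_subset(G: np.ndarray, b: np.ndarray, subset: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    idx = np.asarray(subset, dtype=int)
    return G[np.ix_(idx, idx)], b[idx]


def _solve_theta(G_ss: np.ndarray, b_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares coefficients and fixed-effect SEs from the subset Gram system."""
    k = len(b_s)
    try:
        c, lower = _cho_factor(G_ss)
    except np.linalg.LinAlgError as exc:
        raise DegenerateModelError(f"rank-deficient subset (k={k})") from exc
    theta = _cho_solve(c, b_s)
    inv = _cho_solve(c, np.eye(k))
    return theta, np.sqrt(np.diag(inv))


def _cho_factor(a: np.ndarray) -> tuple[np.ndarray, bool]:
    return np.linalg.cholesky(a), True


def _cho_solve(c: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    z = solve_triangular(c, b, lower=True)
    return solve_triangular(c.T, z, lower=False)


def fit_subset(X: np.ndarray, y: np.ndarray, subset: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Interceptless least squares restricted to ``subset`` columns.

    Returns (theta_hat, se_theta).  Standard errors use the unscaled inverse
    Gram matrix (residual variance fixed at 1: the fixed-effect IVW
    convention on the standardized scale).  Raises
    :class:`DegenerateModelError` if the selected columns are rank deficient.
    """
    subset = tuple(subset)
    if len(subset) < 1:
        raise ValueError("subset must contain at least one factor")
    n = X.shape[0]
    if n <= len(subset):
        raise ValueError(f"need n > |subset|: n={n}, |subset|={len(subset)}")
    Xs = X[:, list(subset)]
    G_ss = Xs.T @ Xs
    # guard against numerically near-singular Gram matrices Cholesky may still pass
    if len(subset) > 1:
        diag = np.sqrt(np.diag(G_ss))
        corr = G_ss / np.outer(diag, diag)
        if np.linalg.matrix_rank(corr, tol=1e-10) < len(subset):
            raise DegenerateModelError(f"rank-deficient subset {subset}")
    return _solve_theta(G_ss, Xs.T @ y)


# ---------------------------------------------------------------------------
# Closed-form marginal likelihood
# ---------------------------------------------------------------------------

def _log_marginal_from_gram(
    G_ss: np.ndarray, b_s: np.ndarray, yy: float, n: int, sd_s: np.ndarray
) -> float:
    """log N(y | 0, X_s diag(sd_s^2) X_s' + I) via the k-dimensional inner matrix."""
    k = len(b_s)
    if k == 0:
        return -0.5 * (n * _LOG_2PI + yy)
    if k == 1:
        v = sd_s[0] * sd_s[0]
        a = 1.0 + v * G_ss[0, 0]
        quad = yy - v * b_s[0] * b_s[0] / a
        logdet = math.log(a)
    elif k == 2:
        c0, c1 = sd_s[0] * b_s[0], sd_s[1] * b_s[1]
        a00 = 1.0 + sd_s[0] * sd_s[0] * G_ss[0, 0]
        a11 = 1.0 + sd_s[1] * sd_s[1] * G_ss[1, 1]
        a01 = sd_s[0] * sd_s[1] * G_ss[0, 1]
        det = a00 * a11 - a01 * a01
        quad = yy - (c0 * c0 * a11 - 2.0 * c0 * c1 * a01 + c1 * c1 * a00) / det
        logdet = math.log(det)
    else:
        c = sd_s * b_s
        A = np.eye(k) + (sd_s[:, None] * G_ss) * sd_s[None, :]
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:
            raise FloatingPointError(f"non-positive-definite inner matrix for subset of size {k}")
        quad = yy - c @ np.linalg.solve(A, c)
    value = -0.5 * (n * _LOG_2PI + logdet + quad)
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite log marginal likelihood (k={k})")
    return value


def log_marginal(
    X: np.ndarray, y: np.ndarray, subset: Sequence[int], prior: PriorConfig
) -> float:
    """Closed-form log marginal likelihood of ``y`` under the subset's Gaussian model.

    The empty subset scores ``log N(y | 0, I)``.  Non-finite results raise,
    reporting the offending subset.
    """
    subset = tuple(subset)
    sd = prior.effect_sd_vector(X.shape[1])
    Xs = X[:, list(subset)]
    G_ss = Xs.T @ Xs
    try:
        return _log_marginal_from_gram(G_ss, Xs.T @ y, float(y @ y), X.shape[0], sd[list(subset)])
    except FloatingPointError as exc:
        raise FloatingPointError(f"subset {subset}: {exc}") from exc


# ---------------------------------------------------------------------------
# Model search
# ---------------------------------------------------------------------------

class _SubsetScorer:
    """Caches the Gram matrix so each subset costs one k x k solve.

    The response can be swapped (``set_response``) without recomputing the
    Gram matrix — the permutation null re-scores thousands of responses
    against the same design.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, prior: PriorConfig):
        self.X = np.asarray(X, dtype=float)
        self.n, self.d = self.X.shape
        self.G = self.X.T @ self.X
        self.sd = prior.effect_sd_vector(self.d)
        self.log_p = math.log(prior.inclusion_prob)
        self.log_q = math.log1p(-prior.inclusion_prob)
        self.set_response(y)

    def set_response(self, y: np.ndarray) -> None:
        self.y = np.asarray(y, dtype=float)
        self.b = self.X.T @ self.y
        self.yy = float(self.y @ self.y)
        self._cache: dict[tuple[int, ...], float] = {}

    def log_marginal(self, subset: tuple[int, ...]) -> float:
        got = self._cache.get(subset)
        if got is None:
            G_ss, b_s = _gram_subset(self.G, self.b, subset)
            got = _log_marginal_from_gram(G_ss, b_s, self.yy, self.n, self.sd[list(subset)])
            self._cache[subset] = got
        return got

    def log_weight(self, subset: tuple[int, ...]) -> float:
        """Unnormalized log posterior weight: log prior + log marginal likelihood."""
        k = len(subset)
        return k * self.log_p + (self.d - k) * self.log_q + self.log_marginal(subset)

    def fit(self, subset: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
        G_ss, b_s = _gram_subset(self.G, self.b, subset)
        return _solve_theta(G_ss, b_s)


def _enumerate_subsets(d: int, max_size: int) -> Iterable[tuple[int, ...]]:
    for k in range(1, min(max_size, d) + 1):
        yield from itertools.combinations(range(d), k)


def _sss_neighbours(subset: tuple[int, ...], d: int, max_size: int) -> list[tuple[int, ...]]:
    """Addition / deletion / swap moves of shotgun stochastic search."""
    inside = set(subset)
    outside = [j for j in range(d) if j not in inside]
    moves: list[tuple[int, ...]] = []
    if len(subset) < max_size:
        moves.extend(tuple(sorted(subset + (j,))) for j in outside)
    if len(subset) > 1:
        moves.extend(tuple(s for s in subset if s != i) for i in subset)
    for i in subset:
        rest = tuple(s for s in subset if s != i)
        moves.extend(tuple(sorted(rest + (j,))) for j in outside)
    return moves


def _assemble_result(
    scorer: _SubsetScorer,
    subsets: list[tuple[int, ...]],
    factors: Optional[list[str]],
    mode: str,
    seed: Optional[int],
) -> BMAResult:
    from scipy.special import logsumexp

    d = scorer.d
    weights = np.empty(len(subsets))
    fits: list[Optional[tuple[np.ndarray, np.ndarray]]] = []
    degenerate = np.zeros(len(subsets), dtype=bool)
    for i, s in enumerate(subsets):
        try:
            fits.append(scorer.fit(s))
            weights[i] = scorer.log_weight(s)
        except DegenerateModelError:
            logger.info("degenerate model %s assigned zero score", s)
            fits.append(None)
            weights[i] = -np.inf
            degenerate[i] = True

    if not np.any(np.isfinite(weights)):
        raise ValueError("every scored model is degenerate; cannot normalize")
    post = np.exp(weights - logsumexp(weights[np.isfinite(weights)]))
    post[degenerate] = 0.0

    mip = np.zeros(d)
    mace = np.zeros(d)
    models = []
    for s, fit, w, p, bad in zip(subsets, fits, weights, post, degenerate):
        theta, se = (np.array([]), np.array([])) if fit is None else fit
        models.append(ModelScore(subset=s, theta_hat=theta, se_theta=se,
                                 log_marginal_likelihood=float(scorer.log_marginal(s)) if not bad else -np.inf,
                                 posterior_prob=float(p), degenerate=bool(bad)))
        if not bad:
            for pos, j in enumerate(s):
                mip[j] += p
                mace[j] += p * theta[pos]

    def _labels(s: tuple[int, ...]) -> tuple[str, ...]:
        return tuple(factors[j] for j in s) if factors else tuple(str(j) for j in s)

    # rank: posterior desc; ties -> smaller model, then lexicographic labels
    models.sort(key=lambda m: (-m.posterior_prob, len(m.subset), _labels(m.subset)))
    return BMAResult(
        models=models, mip=mip, mace=mace, factors=factors, mode=mode,
        models_visited=len(subsets), seed=seed,
        log_marginal_empty=scorer.log_marginal(()),
    )


def score_models(
    X: np.ndarray,
    y: np.ndarray,
    prior: PriorConfig,
    mode: str = "exhaustive",
    budget: Optional[int] = None,
    seed: Optional[int] = None,
    factors: Optional[list[str]] = None,
) -> BMAResult:
    """Score risk-factor subsets and aggregate into MIP / MACE summaries.

    ``mode="exhaustive"`` enumerates every subset of size 1..max_model_size.
    ``mode="stochastic"`` runs a shotgun stochastic search: starting from a
    random admissible subset, all one-factor additions, deletions and swaps
    of the current model are scored, a neighbour is chosen with probability
    proportional to its posterior weight, and the walk continues for
    ``budget`` iterations; posteriors are normalized over the union of
    visited models.  The empty model is excluded from the normalized space
    but its marginal likelihood is recorded for reference.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if d < 1:
        raise ValueError("need at least one factor")
    max_size = min(prior.max_model_size, d, n - 2)
    if max_size < 1:
        raise ValueError(f"n={n} too small to fit any model with d={d}")
    scorer = _SubsetScorer(X, y, prior)

    if mode == "exhaustive":
        subsets = list(_enumerate_subsets(d, max_size))
        return _assemble_result(scorer, subsets, factors, mode, seed)

    if mode != "stochastic":
        raise ConfigurationError(f"unknown search mode {mode!r}")
    if budget is None or budget < d:
        raise ConfigurationError(f"stochastic mode requires budget >= d ({d}), got {budget}")
    rng = np.random.default_rng(seed)

    def _safe_weight(s: tuple[int, ...]) -> float:
        try:
            return scorer.log_weight(s)
        except (DegenerateModelError, FloatingPointError, np.linalg.LinAlgError):
            return -np.inf

    size0 = int(rng.integers(1, max_size + 1))
    current = tuple(sorted(rng.choice(d, size=size0, replace=False).tolist()))
    visited: dict[tuple[int, ...], float] = {current: _safe_weight(current)}
    for _ in range(budget):
        neigh = _sss_neighbours(current, d, max_size)
        lw = np.array([_safe_weight(s) for s in neigh])
        for s, w in zip(neigh, lw):
            if s not in visited:
                visited[s] = w
        finite = np.isfinite(lw)
        if not finite.any():
            break
        probs = np.zeros(len(neigh))
        probs[finite] = np.exp(lw[finite] - lw[finite].max())
        probs /= probs.sum()
        current = neigh[int(rng.choice(len(neigh), p=probs))]
    subsets = sorted(visited)
    return _assemble_result(scorer, subsets, factors, mode, seed)


def run_bma(
    dataset: HarmonizedDataset,
    prior: PriorConfig,
    mode: str = "exhaustive",
    budget: Optional[int] = None,
    seed: Optional[int] = None,
) -> BMAResult:
    """Convenience wrapper: standardize a harmonized dataset and score models."""
    X, y = standardize(dataset)
    return score_models(X, y, prior, mode=mode, budget=budget, seed=seed, factors=list(dataset.factors))


# ---------------------------------------------------------------------------
# Tabular output (ranked models table and ranked factors table)
# ---------------------------------------------------------------------------

def models_table(result: BMAResult, top_k: Optional[int] = None):
    """Ranked models as a DataFrame: rank, comma-joined labels, posterior, effects.

    Labels containing commas are double-quoted so the joined column stays
    parseable.
    """
    import pandas as pd

    def _quote(label: str) -> str:
        return f'"{label}"' if "," in label else label

    rows = []
    models = result.models if top_k is None else result.models[:top_k]
    for rank, m in enumerate(models, start=1):
        labels = [result.factors[j] if result.factors else str(j) for j in m.subset]
        rows.append({
            "rank": rank,
            "model": ",".join(_quote(lb) for lb in labels),
            "posterior_prob": m.posterior_prob,
            "causal_effects": ",".join(f"{t:.6g}" for t in m.theta_hat),
        })
    return pd.DataFrame(rows)


def factors_table(result: BMAResult):
    """Per-factor summary as a DataFrame ranked by MIP: factor, mip, mace."""
    import pandas as pd

    labels = result.factors or [str(j) for j in range(len(result.mip))]
    df = pd.DataFrame({"factor": labels, "mip": result.mip, "mace": result.mace})
    return df.sort_values(["mip", "factor"], ascending=[False, True], kind="stable").reset_index(drop=True)
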