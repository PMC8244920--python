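"""Sparse structure inference: glasso / neighborhood-selection solution paths.

Zeros of the latent precision matrix encode conditional independence, so
the association network is the support of a sparse precision estimate.
Two estimators are exposed, both consuming the reconstructed latent matrix:

* graphical lasso — l1-penalized Gaussian likelihood on the empirical
  correlation matrix;
* neighborhood selection (Meinshausen-Buhlmann) — a lasso regression per
  node, with an edge wherever a coefficient is nonzero (under an "or" or
  "and" symmetrization); equivalent to penalized pseudo-likelihood
  maximization.

Rather than selecting a single graph, both estimators return the full
solution path over a decreasing penalty grid.  Edges are ranked by the
largest penalty at which they first enter a support — early entries are
more reliable — with magnitude tie-breaks; evaluation consumes the ranking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.linear_model import lasso_path as _sk_lasso_path

from .estimate import LatentMatrix, fit_marginals, posterior_mean
from .simulate import CountMatrix
from .transform import zclr

__all__ = [
    "SolutionPath",
    "RankedEdges",
    "lambda_grid",
    "glasso_path",
    "mb_path",
    "rank_edges",
    "infer_network",
]

logger = logging.getLogger(__name__)

Pair = tuple[int, int]


@dataclass
class SolutionPath:
    """Per-penalty edge supports along a decreasing penalty grid.

    ``scores[l]`` maps each pair in ``supports[l]`` to a magnitude used for
    tie-breaking (absolute partial correlation for glasso, max absolute
    regression coefficient for MB).
    """

    lambdas: np.ndarray
    supports: list[frozenset[Pair]]
    scores: list[dict[Pair, float]]
    method: str
    p: int
    symmetrization: str | None = None

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        if len(lam) != len(self.supports):
            raise ValueError("lambdas and supports length mismatch")
        if np.any(np.diff(lam) >= 0):
            raise ValueError("lambdas must be strictly decreasing")
        self.lambdas = lam


@dataclass
class RankedEdges:
    """A total ordering of all candidate pairs.

    Pairs are ordered by decreasing first-entry penalty, then decreasing
    tie-break score, then index order; pairs never selected sit at the end
    with zero scores.
    """

    pairs: list[Pair]
    first_entry_lambda: np.ndarray
    score: np.ndarray

    def tie_keys(self) -> list[tuple[float, float]]:
        """Per-pair (first_entry_lambda, score) keys; equal keys form a tie block."""
        return list(zip(self.first_entry_lambda.tolist(), self.score.tolist()))


def lambda_grid(corr: np.ndarray, n_lambda: int = 50, min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced decreasing penalty grid from the maximal absolute correlation.

    lambda_max is the largest absolute off-diagonal of the correlation
    matrix (at which both estimators return the empty graph); the grid
    descends to lambda_max * min_ratio.
    """
    corr = np.asarray(corr)
    off = np.abs(corr - np.diag(np.diag(corr)))
    lam_max = float(off.max())
    if lam_max == 0:
        raise ValueError("nothing to infer: all off-diagonal correlations are zero")
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _standardize(values: np.ndarray) -> np.ndarray:
    x = values - values.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def _latent_values(latent) -> np.ndarray:
    if isinstance(latent, LatentMatrix):
        return latent.values
    return np.asarray(latent, dtype=float)


def glasso_path(latent, grid: np.ndarray) -> SolutionPath:
    """Graphical-lasso supports along the grid.

    At each penalty the support is the set of nonzero off-diagonals of the
    l1-penalized precision estimate computed from the empirical correlation
    matrix; tie-break scores are absolute partial correlations.  Grid points
    where the solver fails to converge are skipped with a warning.
    """
    x = _latent_values(latent)
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    corr = np.corrcoef(x, rowvar=False)
    lambdas, supports, scores = [], [], []
    for lam in np.asarray(grid, dtype=float):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, prec = _sk_graphical_lasso(corr, alpha=float(lam), max_iter=100, tol=1e-3)
        except Exception as exc:  # pragma: no cover - solver-dependent
            logger.warning("glasso did not converge at lambda=%.4g: %s", lam, exc)
            continue
        d = np.sqrt(np.diag(prec))
        pcorr = np.abs(prec / np.outer(d, d))
        jj, kk = np.nonzero(np.triu(np.abs(prec) > 1e-10, k=1))
        pairs = frozenset(zip(jj.tolist(), kk.tolist()))
        lambdas.append(lam)
        supports.append(pairs)
        scores.append({pr: float(pcorr[pr]) for pr in pairs})
    return SolutionPath(
        lambdas=np.asarray(lambdas), supports=supports, scores=scores, method="glasso", p=p
    )


def mb_path(latent, grid: np.ndarray, symmetrization: str = "or") -> SolutionPath:
    """Neighborhood-selection supports along the grid.

    Each node's column is lasso-regressed on all others (columns are
    standardized first, so penalties are comparable across variables); edge
    (j, k) is in the support when either (``or``) or both (``and``) of the
    two directional coefficients are nonzero.  The lasso objective is
    (1/2n)||y - Xw||^2 + lambda * ||w||_1, under which the grid's
    lambda_max yields all-empty neighborhoods.
    """
    if symmetrization not in ("or", "and"):
        raise ValueError("symmetrization must be 'or' or 'and'")
    x = _standardize(_latent_values(latent))
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    grid = np.asarray(grid, dtype=float)
    L = len(grid)
    # beta[l, j, k]: coefficient of predictor k in the regression of node j.
    beta = np.zeros((L, p, p))
    others = np.arange(p)
    with warnings.catch_warnings():
        # coordinate descent grumbles at the smallest penalties; supports at
        # those grid points are already dense and insensitive to the gap
        warnings.simplefilter("ignore")
        for j in range(p):
            cols = np.delete(others, j)
            _, coefs, _ = _sk_lasso_path(x[:, cols], x[:, j], alphas=grid)
            beta[:, j, cols] = coefs.T
    lambdas, supports, scores = [], [], []
    for l, lam in enumerate(grid):
        b = beta[l]
        nz, nz_t = b != 0, b.T != 0
        sel = (nz | nz_t) if symmetrization == "or" else (nz & nz_t)
        mag = np.maximum(np.abs(b), np.abs(b.T))
        jj, kk = np.nonzero(np.triu(sel, k=1))
        pairs = frozenset(zip(jj.tolist(), kk.tolist()))
        lambdas.append(lam)
        supports.append(pairs)
        scores.append({pr: float(mag[pr]) for pr in pairs})
    return SolutionPath(
        lambdas=np.asarray(lambdas),
        supports=supports,
        scores=scores,
        method="mb",
        p=p,
        symmetrization=symmetrization,
    )


def rank_edges(path: SolutionPath) -> RankedEdges:
    """Total edge ordering from first-entry penalties.

    Each pair is scored by the largest penalty at which it first appears in
    a support (even if it later drops out), with magnitude tie-breaks at
    that penalty; never-selected pairs follow in index order with zero
    scores, so the ranking covers all p(p-1)/2 candidate pairs and recall
    can reach 1.
    """
    p = path.p
    first_lam: dict[Pair, float] = {}
    first_score: dict[Pair, float] = {}
    for lam, support, score in zip(path.lambdas, path.supports, path.scores):
        for pair in support:
            if pair not in first_lam:
                first_lam[pair] = float(lam)
                first_score[pair] = score[pair]
    all_pairs = [(j, k) for j in range(p) for k in range(j + 1, p)]
    ordered = sorted(
        all_pairs,
        key=lambda pr: (-first_lam.get(pr, 0.0), -first_score.get(pr, 0.0), pr),
    )
    return RankedEdges(
        pairs=ordered,
        first_entry_lambda=np.array([first_lam.get(pr, 0.0) for pr in ordered]),
        score=np.array([first_score.get(pr, 0.0) for pr in ordered]),
    )


def infer_network(
    counts: CountMatrix,
    method: str = "mb",
    transform_mode: str = "ziln",
    n_lambda: int = 50,
    min_ratio: float = 0.01,
    symmetrization: str = "or",
) -> tuple[SolutionPath, RankedEdges]:
    """End-to-end network inference from a count matrix.

    ``ziln`` mode runs the full pipeline — zero-preserving clr, marginal
    zero-inflated normal fits, posterior-mean reconstruction of the latent
    layer — before structure inference; ``none`` mode feeds the transformed
    matrix to the estimators directly (the no-imputation baseline).  On
    zero-free data the two modes coincide.

    Taxa observed in no sample carry no information and are dropped before
    inference; their pairs re-enter the returned ranking in the
    never-selected tail, so the ranking always covers all p(p-1)/2 pairs
    of the input.
    """
    if method not in ("mb", "glasso"):
        raise ValueError("method must be 'mb' or 'glasso'")
    if transform_mode not in ("ziln", "none"):
        raise ValueError("transform_mode must be 'ziln' or 'none'")
    p_full = counts.p
    y = np.asarray(counts.counts)
    kept = np.nonzero(y.any(axis=0))[0]
    if len(kept) < 2:
        raise ValueError("fewer than 2 observed taxa")
    if len(kept) < p_full:
        logger.warning("dropping %d all-zero taxa before inference", p_full - len(kept))
        counts = CountMatrix(
            counts=y[:, kept],
            sample_ids=counts.sample_ids,
            taxon_ids=[counts.taxon_ids[j] for j in kept],
            library_sizes=counts.library_sizes,
        )
    transformed = zclr(counts)
    if transform_mode == "ziln":
        fit = fit_marginals(transformed)
        latent = posterior_mean(transformed, fit)
    else:
        latent = LatentMatrix(values=transformed.values.copy())
    corr = np.corrcoef(_standardize(latent.values), rowvar=False)
    grid = lambda_grid(corr, n_lambda=n_lambda, min_ratio=min_ratio)
    if method == "glasso":
        path = glasso_path(latent, grid)
    else:
        path = mb_path(latent, grid, symmetrization=symmetrization)
    ranked = rank_edges(path)
    if len(kept) < p_full:
        ranked = _embed_ranking(ranked, kept, p_full)
    return path, ranked


def _embed_ranking(ranked: RankedEdges, kept: np.ndarray, p_full: int) -> RankedEdges:
    """Map a ranking over kept taxa back to the full pair universe."""
    mapped = [tuple(sorted((int(kept[a]), int(kept[b])))) for a, b in ranked.pairs]
    seen = set(mapped)
    tail = [
        (j, k)
        for j in range(p_full)
        for k in range(j + 1, p_full)
        if (j, k) not in seen
    ]
    return RankedEdges(
        pairs=mapped + tail,
        first_entry_lambda=np.concatenate([ranked.first_entry_lambda, np.zeros(len(tail))]),
        score=np.concatenate([ranked.score, np.zeros(len(tail))]),
    )
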