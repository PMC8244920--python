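"""Seeded generative simulators for ground-truth graphs and synthetic counts.

Two generators are provided.  The native one draws a latent multivariate
normal vector z_i ~ N(mu, Sigma) per sample, thresholds each coordinate at a
per-taxon level delta_j to produce abundances

    a_ij = exp(z_ij) if z_ij > delta_j else 0,

normalizes abundances to proportions and draws counts multinomially with
the sample's library size.  Zeros below the threshold are *structural*
(biological absence); additional *sampling* zeros arise from the finite
multinomial draw.  The comparator generator is a NorTA (Normal-to-Anything)
copula scheme pushing N(0, Sigma) draws through zero-inflated
negative-binomial marginal inverse cdfs; it is intentionally not
compositional (no multinomial step).

Ground-truth graphs come in three topologies (band, Erdos-Renyi,
scale-free); a precision matrix is built on a graph's support with signed
random edge weights and a diagonal shift chosen in closed form so that its
condition number hits a requested kappa exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import optimize, stats

__all__ = [
    "GraphTruth",
    "CovariancePair",
    "ZiLNConfig",
    "NortaZinbConfig",
    "CountMatrix",
    "make_graph",
    "graph_to_precision",
    "sparsity_to_delta",
    "sim2_sparsity_profile",
    "sample_library_sizes",
    "generate_counts",
    "generate_norta_zinb",
    "simulation1_dataset",
    "simulation2_dataset",
]

TOPOLOGIES = ("band", "erdos_renyi", "scale_free")

# Cap for per-taxon sparsity levels: s_j = 1 would make a taxon structurally
# absent from every sample, which the estimators cannot see.
MAX_SPARSITY = 0.99


@dataclass(frozen=True)
class GraphTruth:
    """A ground-truth association graph: symmetric 0/1 adjacency, no self-loops."""

    adjacency: np.ndarray
    topology: str
    edge_count: int

    def __post_init__(self):
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if int(adj.sum()) != 2 * self.edge_count:
            raise ValueError("edge_count inconsistent with adjacency")

    @property
    def p(self) -> int:
        return self.adjacency.shape[0]

    def edges(self) -> list[tuple[int, int]]:
        """Sorted list of (j, k) index pairs with j < k."""
        jj, kk = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(jj.tolist(), kk.tolist()))


@dataclass(frozen=True)
class CovariancePair:
    """A precision matrix, its inverse and the precision's condition number."""

    precision: np.ndarray
    covariance: np.ndarray
    condition_number: float


@dataclass
class ZiLNConfig:
    """Parameters of the native generator.

    mu and delta are the latent normal means and the structural-zero
    thresholds (delta_j = -inf disables zero inflation for taxon j);
    library sizes N_i are negative binomial with the given mean and
    dispersion `size` (variance = mean + mean**2 / size).
    """

    mu: np.ndarray
    delta: np.ndarray
    n: int
    libsize_mean: float = 1.5e6
    libsize_size: float = 5.0
    seed: int = 0

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.mu.shape != self.delta.shape:
            raise ValueError("mu and delta must have the same length")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.libsize_mean <= 0 or self.libsize_size <= 0:
            raise ValueError("library-size parameters must be positive")


@dataclass
class NortaZinbConfig:
    """Parameters of the NorTA / zero-inflated-negative-binomial comparator."""

    covariance: np.ndarray
    marginal_mean: np.ndarray
    size: float = 10.0
    zero_prob: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.covariance = np.asarray(self.covariance, dtype=float)
        self.marginal_mean = np.asarray(self.marginal_mean, dtype=float)
        p = self.covariance.shape[0]
        if self.zero_prob is None:
            self.zero_prob = np.zeros(p)
        self.zero_prob = np.asarray(self.zero_prob, dtype=float)
        if self.size <= 0:
            raise ValueError("size must be positive")
        if np.any(self.zero_prob < 0) or np.any(self.zero_prob >= 1):
            raise ValueError("zero_prob entries must lie in [0, 1)")


@dataclass
class CountMatrix:
    """An n x p observed count table with sample/taxon ids and library sizes."""

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    library_sizes: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.library_sizes = np.asarray(self.library_sizes)

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def p(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_array(cls, counts: np.ndarray) -> "CountMatrix":
        counts = np.asarray(counts)
        n, p = counts.shape
        return cls(
            counts=counts,
            sample_ids=[f"S{i}" for i in range(n)],
            taxon_ids=[f"T{j}" for j in range(p)],
            library_sizes=counts.sum(axis=1),
        )


def _pair_from_index(idx: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Map flat indices of the strict upper triangle back to (row, col)."""
    rows, cols = np.triu_indices(p, k=1)
    return rows[idx], cols[idx]


def make_graph(topology: str, p: int, e: int, seed: int = 0) -> GraphTruth:
    """Draw a ground-truth graph with exactly ``e`` edges.

    band
        each node is linked to its nearest index-neighbors, using the
        smallest bandwidth reaching at least ``e`` edges, then trimming the
        widest-offset edges down to ``e``;
    erdos_renyi
        ``e`` distinct pairs drawn uniformly without replacement;
    scale_free
        Barabasi-Albert preferential attachment (m=1, giving p-1 edges),
        then uniformly random extra non-edges (or random removals) to
        reach ``e`` exactly.
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; expected one of {TOPOLOGIES}")
    if p < 3:
        raise ValueError("p must be >= 3")
    max_e = p * (p - 1) // 2
    if e < 1:
        raise ValueError("e must be >= 1")
    if e > max_e:
        raise ValueError(f"too many edges: e={e} > p(p-1)/2={max_e}")

    rng = np.random.default_rng(seed)
    adj = np.zeros((p, p), dtype=int)

    if topology == "band":
        edges: list[tuple[int, int]] = []
        offset = 1
        while len(edges) < e:
            edges.extend((j, j + offset) for j in range(p - offset))
            offset += 1
        edges = edges[:e]
    elif topology == "erdos_renyi":
        idx = rng.choice(max_e, size=e, replace=False)
        rr, cc = _pair_from_index(idx, p)
        edges = list(zip(rr.tolist(), cc.tolist()))
    else:  # scale_free
        g = nx.barabasi_albert_graph(p, 1, seed=int(rng.integers(2**31)))
        edges = [tuple(sorted(uv)) for uv in g.edges()]
        if len(edges) > e:
            keep = rng.choice(len(edges), size=e, replace=False)
            edges = [edges[i] for i in sorted(keep)]
        elif len(edges) < e:
            have = set(edges)
            all_pairs = [(j, k) for j in range(p) for k in range(j + 1, p)]
            candidates = [pair for pair in all_pairs if pair not in have]
            extra = rng.choice(len(candidates), size=e - len(edges), replace=False)
            edges.extend(candidates[i] for i in np.atleast_1d(extra))

    for j, k in edges:
        adj[j, k] = adj[k, j] = 1
    return GraphTruth(adjacency=adj, topology=topology, edge_count=e)


def graph_to_precision(graph: GraphTruth, kappa: float = 100.0, seed: int = 0) -> CovariancePair:
    """Build a precision matrix supported on ``graph`` with condition number ``kappa``.

    Off-diagonal entries on edges get magnitude uniform on [0.3, 0.7] with a
    random sign (symmetric assignment).  The diagonal is the scalar c solving

        (lambda_max + c) / (lambda_min + c) = kappa

    for the extreme eigenvalues of the off-diagonal skeleton, which makes the
    precision positive definite with condition number exactly kappa.
    """
    if kappa <= 1:
        raise ValueError("kappa must be > 1")
    p = graph.p
    edges = graph.edges()
    if not edges:
        warnings.warn("graph has no edges; returning identity precision (condition number 1)")
        eye = np.eye(p)
        return CovariancePair(precision=eye, covariance=eye.copy(), condition_number=1.0)

    rng = np.random.default_rng(seed)
    skeleton = np.zeros((p, p))
    for j, k in edges:
        w = rng.uniform(0.3, 0.7) * rng.choice([-1.0, 1.0])
        skeleton[j, k] = skeleton[k, j] = w

    eigvals = np.linalg.eigvalsh(skeleton)
    lam_min, lam_max = eigvals[0], eigvals[-1]
    c = (lam_max - kappa * lam_min) / (kappa - 1)
    precision = skeleton + c * np.eye(p)
    covariance = np.linalg.inv(precision)
    ev = np.linalg.eigvalsh(precision)
    return CovariancePair(
        precision=precision,
        covariance=covariance,
        condition_number=float(ev[-1] / ev[0]),
    )


def sparsity_to_delta(s, mu, sigma2):
    """Threshold delta_j giving structural-zero probability s_j.

    delta_j is the s_j-quantile of N(mu_j, sigma2_j), so that
    P(z_j <= delta_j) = s_j; s_j = 0 maps to -inf (no structural zeros).
    Accepts scalars or arrays.
    """
    s = np.asarray(s, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(s < 0) or np.any(s >= 1):
        raise ValueError("sparsity s must lie in [0, 1)")
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be positive")
    out = stats.norm.ppf(s, loc=mu, scale=np.sqrt(sigma2))
    return out if out.ndim else float(out)


def sim2_sparsity_profile(p: int, target_zero_fraction: float) -> np.ndarray:
    """Deterministic per-taxon sparsity profile s_j = min((j/p)^t, cap).

    The exponent t > 0 is solved numerically so that mean(s_j) equals the
    target global proportion of structural zeros to within 1e-6.  s is
    capped at 0.99 so no taxon is structurally absent everywhere; the cap
    keeps every target in [0, 0.99] reachable (without it s_p = 1 always).
    A target of 0 returns the all-zero vector.
    """
    if not 0 <= target_zero_fraction < 1:
        raise ValueError("target zero fraction must lie in [0, 1)")
    if target_zero_fraction == 0:
        return np.zeros(p)

    j = np.arange(1, p + 1)
    base = j / p

    def mean_s(t: float) -> float:
        return float(np.mean(np.minimum(base**t, MAX_SPARSITY)))

    max_mean = mean_s(1e-12)  # ~ cap for every taxon
    if target_zero_fraction > max_mean:
        raise ValueError(
            f"target {target_zero_fraction} unreachable; max mean sparsity is {max_mean:.4f}"
        )
    t = optimize.brentq(
        lambda t: mean_s(t) - target_zero_fraction, 1e-12, 1e4, xtol=1e-12, rtol=1e-14
    )
    s = np.minimum(base**t, MAX_SPARSITY)
    return s


def sample_library_sizes(n: int, mean: float = 1.5e6, size: float = 5.0, seed: int = 0) -> np.ndarray:
    """Negative-binomial library sizes with the (mean, size) parameterization.

    Variance is mean + mean**2 / size; size -> inf recovers the Poisson limit.
    """
    if mean <= 0 or size <= 0:
        raise ValueError("mean and size must be positive")
    rng = np.random.default_rng(seed)
    prob = size / (size + mean)
    return rng.negative_binomial(size, prob, size=n)


def generate_counts(
    graph: GraphTruth | None,
    cov_pair: CovariancePair,
    config: ZiLNConfig,
) -> CountMatrix:
    """Draw an n x p count matrix under the zero-inflated log-normal model.

    Per sample: z_i ~ N(mu, Sigma); abundances a_ij = exp(z_ij) where
    z_ij > delta_j, else 0 (structural zero); proportions pi_i = a_i / sum(a_i);
    counts ~ Multinomial(N_i, pi_i).  Row sums equal library sizes exactly.
    A sample whose abundances are all zero is redrawn once, then rejected as
    a degenerate configuration.

    The ``graph`` argument is carried for provenance only; the covariance
    pair determines the dependence structure.
    """
    sigma = np.asarray(cov_pair.covariance, dtype=float)
    p = sigma.shape[0]
    if config.mu.shape[0] != p:
        raise ValueError("mu length does not match covariance dimension")
    np.linalg.cholesky(sigma)  # raises if not positive definite

    rng = np.random.default_rng(config.seed)
    n = config.n
    lib = sample_library_sizes(
        n, config.libsize_mean, config.libsize_size, seed=int(rng.integers(2**31))
    )
    chol = np.linalg.cholesky(sigma)
    z = config.mu + rng.standard_normal((n, p)) @ chol.T
    alive = z > config.delta

    dead = ~alive.any(axis=1)
    if dead.any():
        z_new = config.mu + rng.standard_normal((int(dead.sum()), p)) @ chol.T
        z[dead] = z_new
        alive[dead] = z_new > config.delta
        if (~alive.any(axis=1)).any():
            raise RuntimeError(
                "sample with all-zero abundances after one resample; "
                "degenerate (mu, delta) configuration"
            )

    a = np.where(alive, np.exp(z), 0.0)
    pi = a / a.sum(axis=1, keepdims=True)
    counts = np.empty((n, p), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(lib[i], pi[i])

    return CountMatrix(
        counts=counts,
        sample_ids=[f"S{i}" for i in range(n)],
        taxon_ids=[f"T{j}" for j in range(p)],
        library_sizes=lib,
    )


def simulation1_dataset(
    topology: str,
    p: int,
    n: int,
    seed: int,
    kappa: float = 100.0,
    sparsity_range: tuple[float, float] = (0.0, 0.9),
    mu_range: tuple[float, float] = (0.0, 3.0),
    libsize_mean: float = 1.5e6,
    libsize_size: float = 5.0,
) -> tuple[GraphTruth, CovariancePair, CountMatrix]:
    """Full varying-sparsity benchmark draw: graph, covariance and counts.

    Graph with e = p edges; precision condition number ``kappa``; per-taxon
    sparsity s_j ~ unif(sparsity_range) converted to thresholds through the
    marginal normal quantile; mu_j ~ unif(mu_range); negative-binomial
    library sizes.  All randomness is split from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_graph, s_prec, s_par, s_counts = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4))
    graph = make_graph(topology, p=p, e=p, seed=s_graph)
    cov = graph_to_precision(graph, kappa=kappa, seed=s_prec)
    rng = np.random.default_rng(s_par)
    mu = rng.uniform(*mu_range, size=p)
    s = rng.uniform(*sparsity_range, size=p)
    delta = sparsity_to_delta(s, mu, np.diag(cov.covariance))
    cfg = ZiLNConfig(
        mu=mu, delta=delta, n=n, libsize_mean=libsize_mean,
        libsize_size=libsize_size, seed=s_counts,
    )
    return graph, cov, generate_counts(graph, cov, cfg)


def simulation2_dataset(
    target_zero_fraction: float,
    seed: int,
    p: int = 300,
    n: int = 100,
    topology: str = "erdos_renyi",
    kappa: float = 100.0,
    generator: str = "ziln",
    norta_size: float = 10.0,
) -> tuple[GraphTruth, CovariancePair, CountMatrix]:
    """Controlled-sparsity benchmark draw with the deterministic s profile.

    s_j follows the (j/p)^t profile tuned to the target global zero
    fraction; mu_j ~ unif(0, 3) and library sizes as in the varying-
    sparsity protocol.  ``generator`` selects the native latent-Gaussian
    generator or the NorTA zero-inflated-negative-binomial comparator
    (whose marginal means are e^{mu_j} and dispersion ``norta_size``).
    """
    if generator not in ("ziln", "norta"):
        raise ValueError("generator must be 'ziln' or 'norta'")
    ss = np.random.SeedSequence(seed)
    s_graph, s_prec, s_par, s_counts = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4))
    graph = make_graph(topology, p=p, e=p, seed=s_graph)
    cov = graph_to_precision(graph, kappa=kappa, seed=s_prec)
    rng = np.random.default_rng(s_par)
    mu = rng.uniform(0.0, 3.0, size=p)
    s = sim2_sparsity_profile(p, target_zero_fraction)
    # taxa are index-ordered by the profile; shuffle so sparsity is not
    # correlated with graph position
    rng.shuffle(s)
    if generator == "ziln":
        delta = sparsity_to_delta(s, mu, np.diag(cov.covariance))
        cfg = ZiLNConfig(mu=mu, delta=delta, n=n, seed=s_counts)
        counts = generate_counts(graph, cov, cfg)
    else:
        norta_cfg = NortaZinbConfig(
            covariance=cov.covariance,
            marginal_mean=np.exp(mu),
            size=norta_size,
            zero_prob=s,
        )
        counts = generate_norta_zinb(norta_cfg, n=n, seed=s_counts)
    return graph, cov, counts


def generate_norta_zinb(config: NortaZinbConfig, n: int, seed: int = 0) -> CountMatrix:
    """Draw counts via the NorTA copula with zero-inflated NB marginals.

    z ~ N(0, Sigma); each coordinate is mapped through its own marginal
    normal cdf Phi_{0, Sigma_jj} and then through the inverse cdf of a
    zero-inflated negative binomial with mean marginal_mean_j, dispersion
    ``size`` and zero-inflation probability zero_prob_j.  Unlike the native
    generator there is no multinomial step: counts are not compositional.
    """
    sigma = config.covariance
    p = sigma.shape[0]
    np.linalg.cholesky(sigma)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n, p)) @ chol.T
    u = stats.norm.cdf(z / np.sqrt(np.diag(sigma)))

    nu = config.size
    mean = config.marginal_mean
    s = config.zero_prob
    # ZINB cdf: F(y) = s + (1-s) F_NB(y); invert by rescaling u past the
    # zero-inflation mass (u <= s gives q <= 0, which nbinom.ppf maps to 0).
    q = (u - s) / (1.0 - s)
    nb_p = nu / (nu + mean)
    counts = stats.nbinom.ppf(np.clip(q, 0.0, 1.0 - 1e-16), nu, nb_p)
    # draws inside the zero-inflation mass (q <= 0) are structural zeros;
    # scipy's discrete ppf maps q = 0 to -1
    counts = np.maximum(counts, 0.0).astype(np.int64)

    return CountMatrix(
        counts=counts,
        sample_ids=[f"S{i}" for i in range(n)],
        taxon_ids=[f"T{j}" for j in range(p)],
        library_sizes=counts.sum(axis=1),
    )
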