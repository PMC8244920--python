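"""Generators: graphs, condition-number-targeted precisions, count simulation."""

import numpy as np
import pytest
from scipy import stats
from statistics import NormalDist

from ziln import (
    GraphTruth,
    NortaZinbConfig,
    ZiLNConfig,
    generate_counts,
    generate_norta_zinb,
    graph_to_precision,
    make_graph,
    sample_library_sizes,
    sim2_sparsity_profile,
    sparsity_to_delta,
)


class TestMakeGraph:
    @pytest.mark.parametrize("topology", ["band", "erdos_renyi", "scale_free"])
    @pytest.mark.parametrize("p,e", [(100, 100), (20, 35), (10, 9)])
    def test_exact_edge_count_and_shape(self, topology, p, e):
        g = make_graph(topology, p=p, e=e, seed=4)
        assert g.edge_count == e
        assert g.adjacency.sum() == 2 * e
        assert np.array_equal(g.adjacency, g.adjacency.T)
        assert np.all(np.diag(g.adjacency) == 0)

    def test_band_bandwidth_one_is_path_graph(self):
        g = make_graph("band", p=4, e=3, seed=0)
        assert g.edges() == [(0, 1), (1, 2), (2, 3)]

    def test_band_widens_when_needed(self):
        g = make_graph("band", p=5, e=7, seed=0)
        # 4 offset-1 edges, then 3 of the offset-2 edges
        assert set(g.edges()) == {(0, 1), (1, 2), (2, 3), (3, 4), (0, 2), (1, 3), (2, 4)}

    def test_too_many_edges_rejected(self):
        with pytest.raises(ValueError, match="too many edges"):
            make_graph("erdos_renyi", p=4, e=7, seed=0)

    def test_unknown_topology_rejected(self):
        with pytest.raises(ValueError, match="unknown topology"):
            make_graph("smallworld", p=10, e=10, seed=0)

    def test_scale_free_has_heavier_degree_tail_than_er(self):
        """Preferential attachment concentrates degree on hubs."""
        max_deg = {"scale_free": [], "erdos_renyi": []}
        for seed in range(100):
            for topo in max_deg:
                g = make_graph(topo, p=50, e=50, seed=seed)
                max_deg[topo].append(g.adjacency.sum(axis=0).max())
        assert np.mean(max_deg["scale_free"]) > np.mean(max_deg["erdos_renyi"]) + 1


class TestGraphToPrecision:
    @pytest.mark.parametrize("topology", ["band", "erdos_renyi", "scale_free"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_condition_number_hits_target(self, topology, seed):
        g = make_graph(topology, p=40, e=40, seed=seed)
        pair = graph_to_precision(g, kappa=100.0, seed=seed)
        ev = np.linalg.eigvalsh(pair.precision)
        assert ev[0] > 0
        assert abs(ev[-1] / ev[0] - 100.0) < 1e-6
        assert abs(pair.condition_number - 100.0) < 1e-6

    def test_support_matches_adjacency(self, er_graph):
        pair = graph_to_precision(er_graph, kappa=100.0, seed=5)
        support = (np.abs(pair.precision) > 1e-12).astype(int) - np.eye(er_graph.p, dtype=int)
        assert np.array_equal(support, er_graph.adjacency)

    def test_precision_inverts_covariance(self, er_graph):
        pair = graph_to_precision(er_graph, kappa=50.0, seed=5)
        np.testing.assert_allclose(
            pair.precision @ pair.covariance, np.eye(er_graph.p), atol=1e-8
        )

    def test_two_node_closed_form(self):
        """For a single edge of weight w the shifted eigenvalues are c +/- |w|."""
        adj = np.array([[0, 1], [1, 0]])
        g = GraphTruth(adjacency=adj, topology="band", edge_count=1)
        pair = graph_to_precision(g, kappa=10.0, seed=2)
        w = abs(pair.precision[0, 1])
        c = pair.precision[0, 0]
        ev = np.linalg.eigvalsh(pair.precision)
        np.testing.assert_allclose(sorted(ev), [c - w, c + w], rtol=1e-12)
        np.testing.assert_allclose((c + w) / (c - w), 10.0, atol=1e-9)

    def test_empty_graph_returns_identity(self):
        g = GraphTruth(adjacency=np.zeros((5, 5), dtype=int), topology="band", edge_count=0)
        with pytest.warns(UserWarning, match="no edges"):
            pair = graph_to_precision(g, kappa=100.0, seed=0)
        np.testing.assert_array_equal(pair.precision, np.eye(5))
        assert pair.condition_number == 1.0

    def test_kappa_must_exceed_one(self, er_graph):
        with pytest.raises(ValueError):
            graph_to_precision(er_graph, kappa=1.0, seed=0)


class TestSparsityToDelta:
    def test_median_sparsity_gives_mean(self):
        assert sparsity_to_delta(0.5, 2.0, 4.0) == pytest.approx(2.0)

    def test_zero_sparsity_gives_minus_infinity(self):
        assert np.isneginf(sparsity_to_delta(0.0, 1.0, 1.0))

    def test_standard_normal_quantile(self):
        # independent quantile routine (stdlib NormalDist)
        assert sparsity_to_delta(0.9, 0.0, 1.0) == pytest.approx(
            NormalDist().inv_cdf(0.9), abs=1e-9
        )

    def test_full_sparsity_rejected(self):
        with pytest.raises(ValueError):
            sparsity_to_delta(1.0, 0.0, 1.0)

    def test_threshold_reproduces_zero_probability(self):
        """P(z <= delta) equals s by construction, checked by simulation."""
        rng = np.random.default_rng(0)
        z = rng.normal(1.5, 2.0, size=200_000)
        d = sparsity_to_delta(0.3, 1.5, 4.0)
        assert np.mean(z <= d) == pytest.approx(0.3, abs=0.01)


class TestSim2Profile:
    def test_target_zero_is_all_zero(self):
        assert np.all(sim2_sparsity_profile(300, 0.0) == 0)

    @pytest.mark.parametrize("target", [0.1, 0.5, 0.7, 0.9])
    def test_mean_hits_target(self, target):
        s = sim2_sparsity_profile(300, target)
        assert np.mean(s) == pytest.approx(target, abs=1e-6)
        assert np.all(s < 1)

    def test_two_taxa_boundary_uses_cap(self):
        s = sim2_sparsity_profile(2, 0.5)
        assert s[1] == pytest.approx(0.99)
        assert np.mean(s) == pytest.approx(0.5, abs=1e-6)

    def test_target_one_rejected(self):
        with pytest.raises(ValueError):
            sim2_sparsity_profile(10, 1.0)


class TestLibrarySizes:
    def test_mean_parameterization(self):
        lib = sample_library_sizes(100_000, mean=1.5e6, size=5, seed=3)
        assert lib.mean() == pytest.approx(1.5e6, rel=0.01)

    def test_variance_identity(self):
        lib = sample_library_sizes(200_000, mean=10, size=5, seed=1)
        assert lib.var() == pytest.approx(10 + 100 / 5, rel=0.03)

    def test_poisson_limit(self):
        lib = sample_library_sizes(200_000, mean=10, size=1e9, seed=2)
        assert lib.var() == pytest.approx(10, rel=0.05)


class TestGenerateCounts:
    def test_rows_sum_to_library_sizes(self, small_counts):
        _, _, cm = small_counts
        np.testing.assert_array_equal(cm.counts.sum(axis=1), cm.library_sizes)

    def test_structural_zero_frequency_matches_s(self):
        """Per-taxon zero rates converge to the requested sparsity levels."""
        p, n = 5, 10_000
        mu = np.full(p, 2.0)
        s = np.array([0.0, 0.2, 0.4, 0.6, 0.8])
        delta = sparsity_to_delta(s, mu, np.ones(p))
        cfg = ZiLNConfig(mu=mu, delta=delta, n=n, libsize_mean=1e6, seed=9)
        from ziln import CovariancePair

        pair = CovariancePair(np.eye(p), np.eye(p), 1.0)
        cm = generate_counts(None, pair, cfg)
        zero_rate = (cm.counts == 0).mean(axis=0)
        # chi-square goodness test per taxon with nonzero s, alpha = 0.001
        for j in range(1, p):
            n_zero = (cm.counts[:, j] == 0).sum()
            stat = stats.binomtest(int(n_zero), n, s[j]).pvalue
            assert stat > 0.001, f"taxon {j}: rate {zero_rate[j]} vs s {s[j]}"

    def test_mean_shift_is_scale_of_abundances_and_leaves_counts_unchanged(self):
        """Scaling all abundances by a constant (mu+c, delta+c) is a no-op on counts."""
        p = 6
        rng = np.random.default_rng(0)
        mu = rng.uniform(0, 3, p)
        delta = mu - 1
        from ziln import CovariancePair

        pair = CovariancePair(np.eye(p), np.eye(p), 1.0)
        a = generate_counts(None, pair, ZiLNConfig(mu=mu, delta=delta, n=50, seed=12))
        b = generate_counts(None, pair, ZiLNConfig(mu=mu + 3.7, delta=delta + 3.7, n=50, seed=12))
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_two_taxon_symmetry(self):
        """With exchangeable taxa the expected proportion is 1/2."""
        from ziln import CovariancePair

        pair = CovariancePair(np.eye(2), np.eye(2), 1.0)
        cfg = ZiLNConfig(
            mu=np.zeros(2), delta=np.full(2, -np.inf), n=400, libsize_mean=1e6, seed=21
        )
        cm = generate_counts(None, pair, cfg)
        frac = cm.counts[:, 0] / cm.library_sizes
        assert frac.mean() == pytest.approx(0.5, abs=0.05)

    def test_no_structural_zeros_without_thresholds(self):
        from ziln import CovariancePair

        p = 4
        pair = CovariancePair(np.eye(p), np.eye(p), 1.0)
        cfg = ZiLNConfig(mu=np.full(p, 2.0), delta=np.full(p, -np.inf), n=200,
                         libsize_mean=1e6, seed=5)
        cm = generate_counts(None, pair, cfg)
        assert (cm.counts == 0).mean() < 0.01

    def test_degenerate_configuration_fails_loudly(self):
        from ziln import CovariancePair

        p = 3
        pair = CovariancePair(np.eye(p), np.eye(p), 1.0)
        cfg = ZiLNConfig(mu=np.zeros(p), delta=np.full(p, 50.0), n=5, seed=0)
        with pytest.raises(RuntimeError, match="degenerate"):
            generate_counts(None, pair, cfg)


class TestNorta:
    def test_marginal_zero_fraction(self):
        p = 4
        cfg = NortaZinbConfig(
            covariance=np.eye(p), marginal_mean=np.full(p, 20.0), size=10,
            zero_prob=np.full(p, 0.5),
        )
        cm = generate_norta_zinb(cfg, n=10_000, seed=8)
        zero_rate = (cm.counts == 0).mean(axis=0)
        # small extra mass from NB zeros on top of the 0.5 inflation
        nb_zero = stats.nbinom.pmf(0, 10, 10 / 30)
        expected = 0.5 + 0.5 * nb_zero
        np.testing.assert_allclose(zero_rate, expected, atol=0.02)

    def test_marginal_mean_matches_configuration(self):
        mu = np.array([1.0, 2.0, 3.0])
        cfg = NortaZinbConfig(covariance=np.eye(3), marginal_mean=np.exp(mu), size=10)
        cm = generate_norta_zinb(cfg, n=50_000, seed=2)
        np.testing.assert_allclose(cm.counts.mean(axis=0), np.exp(mu), rtol=0.05)

    def test_copula_preserves_rank_correlation(self):
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        cfg = NortaZinbConfig(covariance=cov, marginal_mean=np.full(2, 50.0), size=10)
        cm = generate_norta_zinb(cfg, n=5_000, seed=3)
        rho = stats.spearmanr(cm.counts[:, 0], cm.counts[:, 1]).statistic
        assert rho > 0.8

    def test_counts_are_non_negative_under_heavy_inflation(self):
        cfg = NortaZinbConfig(
            covariance=np.eye(3), marginal_mean=np.full(3, 5.0), size=10,
            zero_prob=np.array([0.9, 0.95, 0.98]),
        )
        cm = generate_norta_zinb(cfg, n=2_000, seed=4)
        assert cm.counts.min() >= 0
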