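"""Graph metrics against brute-force and networkx oracles, plus the
monotonicity, equivariance, and parameter-recovery properties."""

import itertools

import networkx as nx
import numpy as np
import pytest

import synconnect as sc


class FakeNet:
    def __init__(self, A, W=None):
        self.A = np.asarray(A, dtype=float)
        self.W = self.A if W is None else np.asarray(W, dtype=float)


# ---------------------------------------------------------------------------
# brute-force oracles, independent of the implementation
# ---------------------------------------------------------------------------

def oracle_strength(W):
    n = W.shape[0]
    edges = [(i, j, W[i, j]) for i in range(n) for j in range(i + 1, n)
             if W[i, j] != 0]
    s = np.zeros(n)
    for i, j, w in edges:
        s[i] += w
        s[j] += w
    return s


def oracle_binary_clustering(A):
    n = A.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(1 for a, b in itertools.combinations(nbrs, 2) if A[a][b])
        c[i] = 2.0 * tri / (k * (k - 1))
    return c


def oracle_onnela_clustering(W):
    n = W.shape[0]
    wmax = W.max()
    What = W / wmax if wmax > 0 else W
    c = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if W[i, j] != 0)
        if k < 2:
            continue
        tot = 0.0
        for j in range(n):
            for l in range(n):
                tot += (What[i, j] * What[j, l] * What[l, i]) ** (1.0 / 3.0)
        c[i] = tot / (k * (k - 1))
    return c


def oracle_efficiency_floyd_warshall(L):
    """All-pairs shortest paths on length matrix L (0 = no edge)."""
    n = L.shape[0]
    d = np.where(L > 0, L, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    off = ~np.eye(n, dtype=bool)
    inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1), 0.0)
    return inv[off].sum() / (n * (n - 1))


def random_graph(rng, n, p=0.5, weighted=False):
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    if not weighted:
        return A
    W = np.triu(rng.uniform(0.1, 1.0, (n, n)), 1) * np.triu(A, 1)
    return A, W + W.T


# ---------------------------------------------------------------------------


class TestDegree:
    def test_complete_graph(self):
        A = np.ones((5, 5)) - np.eye(5)
        k, kn = sc.node_degree(FakeNet(A))
        assert np.all(k == 4) and np.allclose(kn, 0.8)

    def test_empty_graph(self):
        k, kn = sc.node_degree(FakeNet(np.zeros((4, 4))))
        assert not k.any() and not kn.any()

    def test_star_graph(self):
        A = np.zeros((4, 4))
        A[0, 1:] = A[1:, 0] = 1
        _, kn = sc.node_degree(FakeNet(A))
        assert kn[0] == pytest.approx(0.75)
        assert np.allclose(kn[1:], 0.25)

    def test_n_minus_1_option(self):
        A = np.ones((5, 5)) - np.eye(5)
        _, kn = sc.node_degree(FakeNet(A), normalize_by="n_minus_1")
        assert np.allclose(kn, 1.0)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            sc.node_degree(FakeNet(np.zeros((0, 0))))


class TestStrength:
    def test_uniform_weights_tie_at_mean(self):
        W = 0.5 * (np.ones((4, 4)) - np.eye(4))
        s, frac = sc.node_strength(FakeNet(W != 0, W))
        assert np.allclose(s, 1.5)
        assert frac == 0.0  # strict inequality at the mean

    def test_single_hub_fraction(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 0.9
        s, frac = sc.node_strength(FakeNet(W != 0, W))
        assert frac == pytest.approx(1 / 5)

    def test_matches_edge_list_oracle(self, rng):
        _, W = random_graph(rng, 12, weighted=True)
        s, _ = sc.node_strength(FakeNet(W != 0, W))
        assert np.allclose(s, oracle_strength(W), atol=1e-12)


class TestClustering:
    def test_triangle_graph(self):
        A = np.ones((3, 3)) - np.eye(3)
        c, C = sc.clustering_coefficient(FakeNet(A))
        assert np.allclose(c, 1.0) and C == 1.0

    def test_path_graph_has_no_triangles(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1
        _, C = sc.clustering_coefficient(FakeNet(A))
        assert C == 0.0

    def test_binary_matches_triple_enumeration_oracle(self, rng):
        A = random_graph(rng, 10)
        c, _ = sc.clustering_coefficient(FakeNet(A))
        assert np.allclose(c, oracle_binary_clustering(A), atol=1e-12)

    def test_binary_matches_networkx(self, rng):
        A = random_graph(rng, 12)
        c, _ = sc.clustering_coefficient(FakeNet(A))
        ref = nx.clustering(nx.from_numpy_array(A))
        assert np.allclose(c, [ref[i] for i in range(12)], atol=1e-12)

    def test_onnela_matches_brute_force(self, rng):
        _, W = random_graph(rng, 8, weighted=True)
        c, _ = sc.clustering_coefficient(FakeNet(W != 0, W),
                                         variant="onnela_weighted")
        assert np.allclose(c, oracle_onnela_clustering(W), atol=1e-9)

    def test_negative_weights_rejected(self):
        W = np.array([[0.0, -0.5], [-0.5, 0.0]])
        with pytest.raises(ValueError):
            sc.clustering_coefficient(FakeNet(W != 0, W),
                                      variant="onnela_weighted")


class TestDensity:
    def test_complete_and_empty(self):
        assert sc.network_density(FakeNet(np.ones((6, 6)) - np.eye(6))) == 1.0
        assert sc.network_density(FakeNet(np.zeros((6, 6)))) == 0.0

    def test_half_density(self):
        A = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            A[i, j] = A[j, i] = 1
        assert sc.network_density(FakeNet(A)) == pytest.approx(0.5)

    def test_undefined_below_two_nodes(self):
        assert np.isnan(sc.network_density(FakeNet(np.zeros((1, 1)))))


class TestEfficiency:
    def test_complete_binary_graph(self):
        A = np.ones((6, 6)) - np.eye(6)
        assert sc.global_efficiency(FakeNet(A)) == pytest.approx(1.0)

    def test_disconnected_graph(self):
        assert sc.global_efficiency(FakeNet(np.zeros((5, 5)))) == 0.0

    def test_weighted_matches_floyd_warshall(self, rng):
        _, W = random_graph(rng, 12, weighted=True)
        impl = sc.global_efficiency(FakeNet(W != 0, W), variant="weighted")
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1), 0.0)
        assert impl == pytest.approx(oracle_efficiency_floyd_warshall(L),
                                     abs=1e-9)

    def test_binary_matches_networkx(self, rng):
        A = random_graph(rng, 10)
        impl = sc.global_efficiency(FakeNet(A))
        assert impl == pytest.approx(
            nx.global_efficiency(nx.from_numpy_array(A)), abs=1e-12)


class TestOracleEquivalenceSmallGraphs:
    def test_exhaustive_up_to_four_nodes(self):
        # every undirected graph on up to 4 nodes
        for n in (2, 3, 4):
            pairs = list(itertools.combinations(range(n), 2))
            for mask in range(2 ** len(pairs)):
                A = np.zeros((n, n))
                for b, (i, j) in enumerate(pairs):
                    if mask >> b & 1:
                        A[i, j] = A[j, i] = 1
                net = FakeNet(A)
                k, _ = sc.node_degree(net)
                assert np.array_equal(k, A.sum(1))
                c, _ = sc.clustering_coefficient(net)
                assert np.allclose(c, oracle_binary_clustering(A))
                g = nx.from_numpy_array(A)
                assert sc.global_efficiency(net) == pytest.approx(
                    nx.global_efficiency(g), abs=1e-12)
                if n >= 2:
                    assert sc.network_density(net) == pytest.approx(
                        nx.density(g))

    def test_random_weighted_graphs_up_to_six_nodes(self, rng):
        for n in (5, 6):
            for _ in range(20):
                _, W = random_graph(rng, n, p=0.6, weighted=True)
                net = FakeNet(W != 0, W)
                s, _ = sc.node_strength(net)
                assert np.allclose(s, oracle_strength(W), atol=1e-9)
                c, _ = sc.clustering_coefficient(net, "onnela_weighted")
                assert np.allclose(c, oracle_onnela_clustering(W), atol=1e-9)
                L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1), 0.0)
                assert sc.global_efficiency(net, "weighted") == pytest.approx(
                    oracle_efficiency_floyd_warshall(L), abs=1e-9)


class TestProperties:
    def test_permutation_equivariance(self, rng):
        A, W = random_graph(rng, 8, weighted=True)
        perm = rng.permutation(8)
        P = np.eye(8)[perm]
        net, pnet = FakeNet(A, W), FakeNet(P @ A @ P.T, P @ W @ P.T)
        k, _ = sc.node_degree(net)
        kp, _ = sc.node_degree(pnet)
        assert np.allclose(kp, k[perm])
        s, _ = sc.node_strength(net)
        sp, _ = sc.node_strength(pnet)
        assert np.allclose(sp, s[perm])
        assert sc.network_density(net) == pytest.approx(sc.network_density(pnet))
        assert sc.global_efficiency(net, "weighted") == pytest.approx(
            sc.global_efficiency(pnet, "weighted"), abs=1e-12)

    def test_adding_edge_monotone(self, rng):
        A = random_graph(rng, 7, p=0.3)
        empty = [(i, j) for i in range(7) for j in range(i + 1, 7)
                 if not A[i, j]]
        i, j = empty[0]
        A2 = A.copy()
        A2[i, j] = A2[j, i] = 1
        assert sc.network_density(FakeNet(A2)) >= sc.network_density(FakeNet(A))
        assert np.all(sc.node_degree(FakeNet(A2))[0] >= sc.node_degree(FakeNet(A))[0])
        assert sc.global_efficiency(FakeNet(A2)) >= sc.global_efficiency(FakeNet(A))

    def test_participation_increases_mean_degree(self):
        # generator recovery: higher ensemble participation -> denser network
        means = []
        for part in (0.0, 0.4, 0.8):
            vals = []
            for seed in range(3):
                if part == 0.0:
                    cfg = sc.make_config("control", seed=seed, n_neurons=12,
                                         duration=60.0)
                else:
                    ens = sc.default_hyperconnected_ensembles(
                        12, participation=part)
                    cfg = sc.SimulationConfig(
                        seed=seed, n_neurons=12, duration=60.0,
                        ensemble_spec=ens, condition_label="hyperconnected")
                ts = sc.simulate_traceset(cfg)
                net = sc.build_network(sc.normalize_traces(ts))
                vals.append(sc.node_degree(net)[1].mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestCompareConditions:
    def test_identical_groups(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        res = sc.compare_conditions(g, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.direction == "equal"

    def test_power_against_closed_form(self, rng):
        # shifted gaussians: empirical power within binomial bounds of the
        # closed-form noncentral-t power
        from scipy import stats as ss
        n, delta, sigma, alpha, reps = 20, 1.0, 1.0, 0.05, 400
        nc = delta / (sigma * np.sqrt(2.0 / n))
        df = 2 * n - 2
        tcrit = ss.t.ppf(1 - alpha / 2, df)
        power = 1 - ss.nct.cdf(tcrit, df, nc) + ss.nct.cdf(-tcrit, df, nc)
        hits = 0
        for _ in range(reps):
            a = rng.normal(0, sigma, n)
            b = rng.normal(delta, sigma, n)
            hits += sc.compare_conditions(a, b).p_value < alpha
        emp = hits / reps
        half = 2.576 * np.sqrt(power * (1 - power) / reps)
        assert abs(emp - power) < max(half, 0.05)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            sc.compare_conditions([1.0], [2.0, 3.0])
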