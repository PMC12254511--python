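"""Graph statistics of gated correlation networks.

Implements the Brain-Connectivity-Toolbox family of measures used for
functional networks: node degree (normalized by the number of nodes N,
not N-1), node strength, binary and Onnela-weighted clustering
coefficients, network density, and binary/weighted global efficiency.
Weighted path lengths use L_ij = 1/W_ij; disconnected pairs contribute 0
to efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "NetworkMetrics",
    "GroupComparison",
    "node_degree",
    "node_strength",
    "clustering_coefficient",
    "network_density",
    "global_efficiency",
    "summarize_network",
    "compare_conditions",
]


def _as_adjacency(net) -> np.ndarray:
    A = net.A if hasattr(net, "A") else np.asarray(net)
    return np.asarray(A, dtype=float)


def _as_weights(net) -> np.ndarray:
    W = net.W if hasattr(net, "W") else np.asarray(net)
    return np.asarray(W, dtype=float)


def node_degree(net, *, normalize_by: str = "n") -> tuple[np.ndarray, np.ndarray]:
    """Per-node degree k_i and normalized degree.

    Normalization divides by the total number of nodes N (``normalize_by
    = 'n'``, the convention used here for comparability across fields of
    different size); ``'n_minus_1'`` gives the textbook variant.
    """
    A = _as_adjacency(net)
    n = A.shape[0]
    if n == 0:
        raise ValueError("empty network")
    k = A.sum(axis=1)
    denom = n if normalize_by == "n" else n - 1
    if denom <= 0:
        raise ValueError("cannot normalize a single-node network by N-1")
    return k, k / denom


def node_strength(net) -> tuple[np.ndarray, float]:
    """Per-node strength s_i = sum of incident edge weights, and the
    fraction of nodes whose strength strictly exceeds the network mean."""
    W = _as_weights(net)
    s = W.sum(axis=1)
    frac_above = float(np.mean(s > s.mean())) if s.size else 0.0
    return s, frac_above


def clustering_coefficient(net, variant: str = "binary"
                           ) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficient and its network mean.

    binary: c_i = 2 t_i / (k_i (k_i - 1)) with t_i the triangle count at
    node i.  onnela_weighted: weights rescaled to [0, 1] by the maximum,
    c_i = sum_{jk} (w_ij w_jk w_ik)^{1/3} / (k_i (k_i - 1)), with k from
    the binary adjacency.  Nodes with k < 2 have c_i = 0.
    """
    if variant == "binary":
        A = _as_adjacency(net)
        A = (A != 0).astype(float)
        k = A.sum(axis=1)
        tri = np.diag(A @ A @ A) / 2.0
        denom = k * (k - 1)
        c = np.where(denom > 0, 2.0 * tri / np.where(denom > 0, denom, 1.0), 0.0)
    elif variant == "onnela_weighted":
        W = _as_weights(net)
        if np.any(W < 0):
            raise ValueError("onnela_weighted requires nonnegative weights")
        wmax = W.max()
        What = W / wmax if wmax > 0 else W
        cube = np.cbrt(What)
        k = (W != 0).sum(axis=1).astype(float)
        tri = np.diag(cube @ cube @ cube) / 2.0
        denom = k * (k - 1)
        c = np.where(denom > 0, 2.0 * tri / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        raise ValueError(f"unknown clustering variant {variant!r}")
    return c, float(c.mean()) if c.size else 0.0


def network_density(net) -> float:
    """Existing edges / possible edges; undefined (nan) for N < 2."""
    A = _as_adjacency(net)
    n = A.shape[0]
    if n < 2:
        return float("nan")
    m = np.triu(A != 0, k=1).sum()
    return float(m / (n * (n - 1) / 2.0))


def global_efficiency(net, variant: str = "binary") -> float:
    """Average inverse shortest-path length over ordered node pairs.

    Weighted paths use edge lengths 1/W_ij (Dijkstra); pairs with no
    connecting path contribute 0.
    """
    if variant == "binary":
        A = (_as_adjacency(net) != 0).astype(float)
        G = A
        method = "D"
    elif variant == "weighted":
        W = _as_weights(net)
        if np.any(W < 0):
            raise ValueError("weighted efficiency requires nonnegative weights")
        with np.errstate(divide="ignore"):
            G = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
        method = "D"
    else:
        raise ValueError(f"unknown efficiency variant {variant!r}")
    n = G.shape[0]
    if n < 2:
        return 0.0
    d = shortest_path(G, method=method, directed=False, unweighted=(variant == "binary"))
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


@dataclass
class NetworkMetrics:
    """Per-node and per-network graph statistics of one field of view."""

    degree: np.ndarray
    normalized_degree: np.ndarray
    strength: np.ndarray
    clustering: np.ndarray
    mean_normalized_degree: float
    mean_clustering: float
    density: float
    efficiency: float
    strength_above_mean_fraction: float
    n_neurons: int
    condition_label: str = ""
    meta: dict = field(default_factory=dict)


def summarize_network(net, *, clustering_variant: str = "onnela_weighted",
                      efficiency_variant: str = "weighted") -> NetworkMetrics:
    """All metrics of one gated network in a single pass."""
    k, k_norm = node_degree(net)
    s, frac = node_strength(net)
    c, c_mean = clustering_coefficient(net, variant=clustering_variant)
    return NetworkMetrics(
        degree=k,
        normalized_degree=k_norm,
        strength=s,
        clustering=c,
        mean_normalized_degree=float(k_norm.mean()),
        mean_clustering=c_mean,
        density=network_density(net),
        efficiency=global_efficiency(net, variant=efficiency_variant),
        strength_above_mean_fraction=frac,
        n_neurons=int(_as_adjacency(net).shape[0]),
        condition_label=getattr(net, "meta", {}).get("condition_label", ""),
    )


@dataclass
class GroupComparison:
    """Two-sample comparison of a node-level metric between conditions."""

    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    direction: str  # 'a>b', 'b>a' or 'equal'


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(x.size))


def compare_conditions(samples_a, samples_b, *, equal_var: bool = True
                       ) -> GroupComparison:
    """Two-sample t-test on node-level metric samples from two conditions.

    The statistical unit is the node, matching common practice for
    functional-network comparisons (this is pseudo-replication with
    respect to animals; see the methods documentation).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 samples")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    ma, mb = float(a.mean()), float(b.mean())
    direction = "a>b" if ma > mb else ("b>a" if mb > ma else "equal")
    return GroupComparison(statistic=float(res.statistic),
                           p_value=float(res.pvalue),
                           mean_a=ma, mean_b=mb,
                           sem_a=_sem(a), sem_b=_sem(b),
                           n_a=a.size, n_b=b.size, direction=direction)
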