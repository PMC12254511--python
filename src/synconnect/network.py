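"""Significance-gated Spearman correlation networks.

Functional connectivity between neuron pairs is measured by Spearman's
rank correlation of their fluorescence traces.  An edge is retained when
the pairwise p-value clears a significance threshold (default alpha 0.05,
no multiple-testing correction by default); the retained edges carry the
correlation coefficient as weight.  A distance-vs-correlation control
verifies that connectivity is not explained by ROI proximity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist

from .synth import TraceSet

__all__ = [
    "CorrelationNetwork",
    "DistanceControlResult",
    "spearman_matrix",
    "gate_edges",
    "exclude_small_networks",
    "distance_control",
    "build_network",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationNetwork:
    """Correlation, p-value, adjacency and weight matrices of one field.

    Invariants (checked on construction): A is symmetric binary with zero
    diagonal; W is symmetric with zero diagonal and |W| <= 1; an edge is
    present in A exactly where W is nonzero; every retained edge is
    significant at ``alpha``.
    """

    rho: np.ndarray
    p: np.ndarray
    A: np.ndarray
    W: np.ndarray
    alpha: float
    n_frames: int
    mode: str = "weighted_positive"
    labels: list | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_neurons(self) -> int:
        return self.A.shape[0]

    def validate(self) -> None:
        A, W, p = self.A, self.W, self.p
        n = A.shape[0]
        if A.shape != (n, n) or W.shape != (n, n):
            raise ValueError("A and W must be square and matched")
        if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
            raise ValueError("A must be symmetric with zero diagonal")
        if not np.allclose(W, W.T) or np.any(np.diag(W) != 0):
            raise ValueError("W must be symmetric with zero diagonal")
        if np.any(np.abs(W) > 1 + 1e-12):
            raise ValueError("|W| must not exceed 1")
        if np.any((A == 1) != (W != 0)):
            raise ValueError("A and W must mark the same edges")
        off = ~np.eye(n, dtype=bool)
        if np.any((A[off] == 1) & ~(p[off] < self.alpha)):
            raise ValueError("every edge must satisfy p < alpha")


@dataclass
class DistanceControlResult:
    """Association between inter-ROI distance and pairwise correlation."""

    distances: np.ndarray  # µm, one entry per unordered pair
    rho_values: np.ndarray
    association_rho: float
    p_value: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < 0.05


def _spearman_p_asymptotic(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation with n-2 degrees of freedom."""
    r = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p


def spearman_matrix(t: TraceSet | np.ndarray, *, p_method: str = "asymptotic",
                    n_perm: int = 200, seed: int | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Spearman rank correlation and p-value matrices.

    Ranks use mid-rank ties followed by Pearson correlation on the ranks.
    p-values come from the two-sided t approximation by default, or from a
    circular-shift permutation null (``p_method='permutation'``) that
    respects within-trace autocorrelation.  Constant traces have undefined
    correlations: their pairs are recorded as rho 0 / p 1 with a warning.
    """
    x = t.traces if isinstance(t, TraceSet) else np.asarray(t, dtype=float)
    n_neurons, n_frames = x.shape
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    if n_frames < 10:
        raise ValueError("need at least 10 frames")

    ranks = stats.rankdata(x, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant trace(s): correlations with them "
            "are undefined and recorded as non-significant", RuntimeWarning,
            stacklevel=2)
    z = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, sd) * np.sqrt(n_frames)
    z = z / denom[:, None]
    rho = z @ z.T
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 1.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    rho[np.ix_(constant, constant)] = 0.0
    np.fill_diagonal(rho, 1.0)

    if p_method == "asymptotic":
        p = _spearman_p_asymptotic(rho, n_frames)
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        exceed = np.zeros_like(rho)
        abs_obs = np.abs(rho)
        for _ in range(n_perm):
            shifts = rng.integers(0, n_frames, size=n_neurons)
            zs = np.empty_like(z)
            for i in range(n_neurons):
                zs[i] = np.roll(z[i], shifts[i])
            null = zs @ z.T
            null = 0.5 * (null + null.T)  # symmetrize the relative shifts
            exceed += np.abs(null) >= abs_obs - 1e-15
        p = (exceed + 1.0) / (n_perm + 1.0)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")

    p = 0.5 * (p + p.T)
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(p, 1.0)
    return rho, p


def gate_edges(rho: np.ndarray, p: np.ndarray, alpha: float = 0.05,
               mode: str = "weighted_positive", *, bh_correct: bool = False,
               n_frames: int | None = None, labels: list | None = None
               ) -> CorrelationNetwork:
    """Threshold the p-value matrix into a gated network.

    Modes: ``binary`` keeps any significant edge with weight 1;
    ``weighted_positive`` (default) keeps significant positive correlations
    with rho as weight; ``weighted_signed`` keeps significant edges of
    either sign.  ``bh_correct`` applies Benjamini-Hochberg across the
    unordered pairs before gating (off by default).
    """
    if mode not in ("binary", "weighted_positive", "weighted_signed"):
        raise ValueError(f"unknown mode {mode!r}")
    rho = np.asarray(rho, dtype=float)
    p = np.asarray(p, dtype=float).copy()
    n = rho.shape[0]
    iu = np.triu_indices(n, k=1)
    if bh_correct and iu[0].size:
        adj = stats.false_discovery_control(p[iu], method="bh")
        p[iu] = adj
        p[(iu[1], iu[0])] = adj

    sig = p < alpha
    if mode == "weighted_positive":
        sig = sig & (rho > 0)
    A = sig.astype(int)
    np.fill_diagonal(A, 0)
    A = np.minimum(A, A.T)  # enforce symmetry defensively
    if mode == "binary":
        W = A.astype(float)
    else:
        W = np.where(A == 1, rho, 0.0)
    np.fill_diagonal(W, 0.0)
    return CorrelationNetwork(rho=rho, p=p, A=A, W=W, alpha=alpha,
                              n_frames=n_frames or 0, mode=mode, labels=labels)


def build_network(t: TraceSet, alpha: float = 0.05,
                  mode: str = "weighted_positive", *,
                  p_method: str = "asymptotic", n_perm: int = 200,
                  seed: int | None = None,
                  bh_correct: bool = False) -> CorrelationNetwork:
    """Trace set -> gated correlation network in one step."""
    rho, p = spearman_matrix(t, p_method=p_method, n_perm=n_perm, seed=seed)
    net = gate_edges(rho, p, alpha=alpha, mode=mode, bh_correct=bh_correct,
                     n_frames=t.n_frames)
    net.meta["condition_label"] = t.condition_label
    net.meta["region_label"] = t.region_label
    return net


def exclude_small_networks(nets: list, min_neurons: int = 4) -> list:
    """Drop networks with fewer than ``min_neurons`` neurons (strict:
    a network of exactly ``min_neurons`` is retained)."""
    kept = []
    for net in nets:
        n = net.n_neurons if hasattr(net, "n_neurons") else len(net)
        if n >= min_neurons:
            kept.append(net)
        else:
            logger.info("excluding network with %d neurons (< %d)",
                        n, min_neurons)
    return kept


def distance_control(net: CorrelationNetwork | np.ndarray,
                     centroids: np.ndarray) -> DistanceControlResult:
    """Spearman association between inter-centroid distance and pairwise
    trace correlation over all unordered pairs.

    No association (|rho| small, p large) indicates that connectivity is
    not an artifact of optical bleed-over between nearby ROIs.
    """
    rho = net.rho if isinstance(net, CorrelationNetwork) else np.asarray(net)
    centroids = np.asarray(centroids, dtype=float)
    n = rho.shape[0]
    if centroids.shape[0] != n:
        raise ValueError("centroids must cover every neuron")
    d = pdist(centroids)
    iu = np.triu_indices(n, k=1)
    r = rho[iu]
    if np.std(r) == 0 or np.std(d) == 0:
        return DistanceControlResult(distances=d, rho_values=r,
                                     association_rho=0.0, p_value=1.0,
                                     degenerate=True)
    res = stats.spearmanr(d, r)
    return DistanceControlResult(distances=d, rho_values=r,
                                 association_rho=float(res.statistic),
                                 p_value=float(res.pvalue))
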