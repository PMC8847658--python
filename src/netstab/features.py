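"""Ranked network features and the binomial null probability.

Feature extractors pick, from one weighted network, the identity of a ranked
feature: the strongest link, the set of the ``m`` strongest links, the node
of maximal strength centrality, or the node of maximal weighted local
clustering.  Under the null hypothesis of mutually independent networks the
count of the modal identity over ``n`` windows is Binomial(n, p) with ``p``
the chance of hitting one fixed identity per window; :func:`ln_binomial_tail`
evaluates the (log) tail of that law without underflow.

All tie-breaks are deterministic toward the lexicographically smallest
identity; real-valued correlation weights make ties measure-zero in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from .networks import WeightedNetwork, _as_weights

__all__ = [
    "Feature",
    "LinkId",
    "strongest_link",
    "top_m_links",
    "strength_centrality",
    "local_clustering",
    "per_trial_probability",
    "ln_binomial_tail",
    "triu_pairs",
]

LinkId = tuple[int, int]  # unordered channel pair stored as (j, k), j < k


@dataclass(frozen=True)
class Feature:
    """Which ranked feature to track.

    ``kind`` is one of ``strongest_link``, ``top_m_links``,
    ``max_strength_node``, ``max_clustering_node``; ``m`` applies only to
    ``top_m_links``.
    """

    kind: str
    m: int | None = None

    _KINDS = ("strongest_link", "top_m_links", "max_strength_node", "max_clustering_node")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "top_m_links":
            if self.m is None or self.m < 1:
                raise ValueError("top_m_links requires m ≥ 1")
        elif self.m is not None:
            raise ValueError(f"{self.kind} takes no m")

    @classmethod
    def strongest_link(cls) -> "Feature":
        return cls("strongest_link")

    @classmethod
    def top_m_links(cls, m: int) -> "Feature":
        return cls("top_m_links", m=int(m))

    @classmethod
    def max_strength_node(cls) -> "Feature":
        return cls("max_strength_node")

    @classmethod
    def max_clustering_node(cls) -> "Feature":
        return cls("max_clustering_node")

    def __str__(self) -> str:
        return f"top_{self.m}_links" if self.kind == "top_m_links" else self.kind


def triu_pairs(n_nodes: int) -> list[LinkId]:
    """All unordered pairs (j, k), j < k, in lexicographic order."""
    iu = np.triu_indices(n_nodes, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def strongest_link(net) -> LinkId:
    """Unordered pair of maximal weight; lexicographic tie-break.

    An all-zero network degenerately returns ``(0, 1)``.
    """
    w = _as_weights(net)
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    tri = w[iu]
    best = int(np.argmax(tri))  # first occurrence == lexicographically smallest
    return (int(iu[0][best]), int(iu[1][best]))


def top_m_links(net, m: int) -> frozenset[LinkId]:
    """The unordered set of the ``m`` largest-weight links.

    Boundary ties are resolved lexicographically; ``m=1`` coincides with
    ``{strongest_link(net)}``.
    """
    w = _as_weights(net)
    n = w.shape[0]
    n_links = n * (n - 1) // 2
    if not 1 <= m <= n_links:
        raise ValueError(f"m must be in [1, {n_links}], got {m}")
    iu = np.triu_indices(n, k=1)
    tri = w[iu]
    order = np.argsort(-tri, kind="stable")[:m]
    return frozenset((int(iu[0][i]), int(iu[1][i])) for i in order)


def strength_centrality(net) -> np.ndarray:
    """Per-node sum of incident link weights."""
    w = _as_weights(net)
    return w.sum(axis=1)


def local_clustering(net) -> np.ndarray:
    """Weighted local clustering per node (geometric-mean triangle intensity).

    Weights are first normalised by the network maximum, then

        C_i = (1 / ((N−1)(N−2))) Σ_{j≠h}  (ŵ_ij ŵ_ih ŵ_jh)^{1/3}

    so a uniform complete network has C_i = 1 for every node.  An all-zero
    network yields all zeros.
    """
    w = _as_weights(net)
    n = w.shape[0]
    if n < 3:
        raise ValueError("local clustering needs at least 3 nodes")
    wmax = w.max()
    if wmax == 0.0:
        return np.zeros(n)
    a = np.cbrt(w / wmax)
    # diag(A³) sums ordered (j, h) pairs; zero diagonal kills j == h terms
    tri = np.einsum("ij,jh,hi->i", a, a, a, optimize=True)
    return tri / ((n - 1) * (n - 2))


def per_trial_probability(feature: Feature, n_nodes: int) -> float:
    """Null per-window probability of one fixed feature identity.

    strongest link: 1 / (N(N−1)/2) — uniform over links; node features:
    1/N — uniform over nodes; top-m sets: 1 / C(N(N−1)/2, m) — uniform over
    unordered m-sets of links.
    """
    if n_nodes < 3:
        raise ValueError("need N ≥ 3")
    n_links = n_nodes * (n_nodes - 1) // 2
    if feature.kind == "strongest_link":
        return 1.0 / n_links
    if feature.kind in ("max_strength_node", "max_clustering_node"):
        return 1.0 / n_nodes
    if feature.kind == "top_m_links":
        if not 1 <= feature.m <= n_links:
            raise ValueError(f"m must be in [1, {n_links}]")
        n_sets = math.comb(n_links, feature.m)
        p = 1.0 / n_sets if n_sets < 1e300 else math.exp(
            -(math.lgamma(n_links + 1) - math.lgamma(feature.m + 1) - math.lgamma(n_links - feature.m + 1))
        )
        return p
    raise ValueError(feature.kind)


def ln_binomial_tail(n: int, p: float, k: int, mode: str = "tail") -> float:
    """Natural log of Binomial(n, p) probabilities, computed in log space.

    ``mode="tail"`` (default) returns ln P(X ≥ k) — the p-value of observing
    at least the modal count under independent networks; ``mode="pmf"``
    returns ln P(X = k).  Stable for n up to ~10⁶ and for tails far below
    the double-precision underflow threshold of direct summation.
    """
    n, k = int(n), int(k)
    if not 0 <= k <= n:
        raise ValueError(f"need 0 ≤ k ≤ n, got k={k}, n={n}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"need 0 < p < 1, got p={p}")
    if mode == "pmf":
        return float(binom.logpmf(k, n, p))
    if mode != "tail":
        raise ValueError(f"unknown mode {mode!r}")
    if k == 0:
        return 0.0
    if k == n:
        return n * math.log(p)
    upper = float(logsumexp(binom.logpmf(np.arange(k, n + 1), n, p)))
    if upper < math.log(0.5):
        return min(upper, 0.0)
    # near-certain tail: ln(1 − P(X < k)) via the complementary sum
    lower = float(logsumexp(binom.logpmf(np.arange(0, k), n, p)))
    return math.log1p(-math.exp(lower)) if lower < 0.0 else -math.inf
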