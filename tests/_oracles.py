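"""Independent brute-force oracles used across the test suite.

Each oracle deliberately avoids the code path it checks: correlations via
explicit covariance sums, feature ranking via full sorts or exhaustive
enumeration, and binomial tails via arbitrary-precision summation of the
exact PMF (mpmath, multiplicative recurrence).
"""

from __future__ import annotations

import itertools
import math

import mpmath as mp
import numpy as np


def abs_corr_matrix(window: np.ndarray) -> np.ndarray:
    """|Pearson| by direct covariance sums over every channel pair."""
    n = window.shape[0]
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            xj = window[j] - window[j].mean()
            xk = window[k] - window[k].mean()
            denom = math.sqrt((xj**2).sum() * (xk**2).sum())
            r = abs((xj * xk).sum() / denom) if denom > 0 else 0.0
            out[j, k] = out[k, j] = min(r, 1.0)
    return out


def strongest_pair(weights: np.ndarray) -> tuple[int, int]:
    """Exhaustive scan over all pairs, lexicographic tie-break."""
    n = weights.shape[0]
    best, best_w = (0, 1), -1.0
    for j in range(n):
        for k in range(j + 1, n):
            if weights[j, k] > best_w:
                best, best_w = (j, k), weights[j, k]
    return best

def top_m_pairs(weights: np.ndarray, m: int) -> frozenset[tuple[int, int]]:
    """Full sort of every link weight, ties lexicographic."""
    n = weights.shape[0]
    ranked = sorted(
        ((j, k) for j in range(n) for k in range(j + 1, n)),
        key=lambda jk: (-weights[jk], jk),
    )
    return frozenset(ranked[:m])


def node_strengths(weights: np.ndarray) -> np.ndarray:
    """Independent per-node summation over incident links."""
    n = weights.shape[0]
    return np.array([sum(weights[i, j] for j in range(n) if j != i) for i in range(n)])


def clustering_by_triples(weights: np.ndarray) -> np.ndarray:
    """Exhaustive enumeration over all ordered node triples."""
    n = weights.shape[0]
    wmax = weights.max()
    if wmax == 0:
        return np.zeros(n)
    w = weights / wmax
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j, h in itertools.permutations([x for x in range(n) if x != i], 2):
            acc += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        out[i] = acc / ((n - 1) * (n - 2))
    return out


def ln_binomial_tail_exact(n: int, p: float, k: int, dps: int = 50) -> float:
    """ln P(X ≥ k), X ~ Binomial(n, p), by high-precision exact summation.

    Starts from the PMF at k (via loggamma) and accumulates the upper tail
    with the multiplicative recurrence pmf(i+1)/pmf(i) = (n−i)p / ((i+1)(1−p)).
    """
    if k == 0:
        return 0.0
    with mp.workdps(dps):
        pm = mp.mpf(p)
        qm = 1 - pm
        log_pmf_k = (
            mp.loggamma(n + 1)
            - mp.loggamma(k + 1)
            - mp.loggamma(n - k + 1)
            + k * mp.log(pm)
            + (n - k) * mp.log(qm)
        )
        term = mp.e**log_pmf_k
        total = term
        for i in range(k, n):
            term *= (n - i) * pm / ((i + 1) * qm)
            total += term
        return float(mp.log(total))


def multinomial_max_counts(
    n_trials: int, n_categories: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Modal-count distribution under a uniform multinomial: max cell count."""
    counts = rng.multinomial(n_trials, np.full(n_categories, 1.0 / n_categories), size=n_draws)
    return counts.max(axis=1)
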