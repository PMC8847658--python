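"""Temporal stability of ranked features against the binomial null.

For one subject and one window length: extract the feature identity in every
window, find the identity that recurs most often (the *modal* identity, count
``k`` over ``n`` windows), and score it with ln π, the log binomial tail
probability of a count ≥ k arising if consecutive networks were independent.
Scanning window lengths gives a stability profile whose minimum locates the
timescale at which the feature is most persistent.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .features import (
    Feature,
    LinkId,
    ln_binomial_tail,
    per_trial_probability,
)
from .io import Recording
from .networks import DynamicNetworkSeries, reconstruct

__all__ = [
    "StabilityResult",
    "StabilityProfile",
    "RankGapProfile",
    "SubjectStabilitySummary",
    "default_grid",
    "feature_sequence",
    "stability_at_window",
    "stability_profile",
    "rank_gap_profile",
    "subject_summary",
    "profile_table",
    "SIX_METRIC_FEATURES",
]

#: the three features whose (min ln π, best window) pairs form the
#: six-metric subject description used for covariates and classification
SIX_METRIC_FEATURES = (
    Feature.strongest_link(),
    Feature.max_strength_node(),
    Feature.max_clustering_node(),
)


def default_grid(
    lo_ms: float = 10.0, hi_ms: float = 1000.0, n_points: int = 30
) -> np.ndarray:
    """Log-spaced window-length grid in milliseconds."""
    return np.logspace(math.log10(lo_ms), math.log10(hi_ms), n_points)


@dataclass
class StabilityResult:
    """Modal identity and its binomial-null score at one window length."""

    feature: Feature
    modal_identity: Hashable
    k: int
    n: int
    p: float
    ln_pi: float

    def as_dict(self) -> dict:
        ident = self.modal_identity
        if isinstance(ident, frozenset):
            ident = sorted(ident)
        return {
            "feature": str(self.feature),
            "modal_identity": str(ident),
            "k": self.k,
            "n": self.n,
            "p": self.p,
            "ln_pi": self.ln_pi,
        }


@dataclass
class StabilityProfile:
    """ln π across window lengths, with the minimising grid point."""

    feature: Feature
    grid: list[tuple[float, StabilityResult]]
    best_window_ms: float
    min_ln_pi: float

    @property
    def window_ms(self) -> np.ndarray:
        return np.array([w for w, _ in self.grid])

    @property
    def ln_pi(self) -> np.ndarray:
        return np.array([r.ln_pi for _, r in self.grid])


@dataclass
class RankGapProfile:
    """Mean per-window log2 gap between the two strongest links, per window length."""

    grid: list[tuple[float, float]]  # (window_ms, mean_gap)
    n_excluded: dict[float, int] = field(default_factory=dict)  # windows with s2 = 0

    @property
    def window_ms(self) -> np.ndarray:
        return np.array([w for w, _ in self.grid])

    @property
    def mean_gap(self) -> np.ndarray:
        return np.array([g for _, g in self.grid])


@dataclass
class SubjectStabilitySummary:
    """The six per-subject metrics used downstream.

    For each of strongest link, max-strength node and max-clustering node:
    the minimum ln π over the window grid and the window length (ms)
    attaining it.
    """

    subject_id: str
    min_ln_pi: dict[str, float]
    best_window_ms: dict[str, float]

    def as_vector(self) -> np.ndarray:
        """Fixed order: (ln π, w) for link, strength node, clustering node."""
        out = []
        for f in SIX_METRIC_FEATURES:
            out.append(self.min_ln_pi[str(f)])
            out.append(self.best_window_ms[str(f)])
        return np.array(out)

    @staticmethod
    def feature_names() -> list[str]:
        out = []
        for f in SIX_METRIC_FEATURES:
            out.append(f"min_ln_pi[{f}]")
            out.append(f"best_window_ms[{f}]")
        return out


def _sortable(ident: Hashable):
    # frozensets of links → sorted tuple so ties resolve set-lexicographically
    return tuple(sorted(ident)) if isinstance(ident, frozenset) else ident


def modal_identity(identities: Sequence[Hashable]) -> tuple[Hashable, int]:
    """Most frequent identity and its count; ties toward the smallest identity."""
    counts = Counter(identities)
    kmax = max(counts.values())
    winner = min((ident for ident, c in counts.items() if c == kmax), key=_sortable)
    return winner, kmax


def feature_sequence(series: DynamicNetworkSeries, feature: Feature) -> list[Hashable]:
    """Per-window feature identities, vectorised over the weight tensor."""
    w = series.weights  # (n, N, N)
    n_nodes = w.shape[1]
    if feature.kind in ("strongest_link", "top_m_links"):
        iu = np.triu_indices(n_nodes, k=1)
        tri = w[:, iu[0], iu[1]]  # (n, L) in lexicographic pair order
        if feature.kind == "strongest_link":
            best = tri.argmax(axis=1)
            return [(int(iu[0][b]), int(iu[1][b])) for b in best]
        order = np.argsort(-tri, axis=1, kind="stable")[:, : feature.m]
        return [
            frozenset((int(iu[0][i]), int(iu[1][i])) for i in row) for row in order
        ]
    if feature.kind == "max_strength_node":
        return [int(i) for i in w.sum(axis=2).argmax(axis=1)]
    if feature.kind == "max_clustering_node":
        wmax = w.max(axis=(1, 2), keepdims=True)
        safe = np.where(wmax > 0, wmax, 1.0)
        a = np.cbrt(w / safe)
        tri = np.einsum("nij,njh,nhi->ni", a, a, a, optimize=True)
        return [int(i) for i in tri.argmax(axis=1)]
    raise ValueError(feature.kind)


def stability_at_window(
    series: DynamicNetworkSeries, feature: Feature, mode: str = "tail"
) -> StabilityResult:
    """Modal identity over the windows of one series, scored by the binomial null."""
    idents = feature_sequence(series, feature)
    winner, k = modal_identity(idents)
    n = len(idents)
    p = per_trial_probability(feature, series.n_nodes)
    return StabilityResult(
        feature=feature,
        modal_identity=winner,
        k=k,
        n=n,
        p=p,
        ln_pi=ln_binomial_tail(n, p, k, mode=mode),
    )


def _feasible_grid(recording: Recording, grid_ms: Sequence[float]) -> list[float]:
    grid = [float(g) for g in grid_ms]
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid_ms must be non-empty and strictly increasing")
    feasible = []
    for g in grid:
        w = int(math.floor(g * recording.sampling_rate_hz / 1000.0))
        if w >= 2 and recording.n_samples // w >= 1:
            feasible.append(g)
        else:
            warnings.warn(f"skipping infeasible window length {g} ms", stacklevel=3)
    if not feasible:
        raise ValueError("no feasible window length in grid")
    return feasible


def stability_profile(
    recording: Recording,
    feature: Feature,
    grid_ms: Sequence[float],
    mode: str = "tail",
) -> StabilityProfile:
    """Scan window lengths; the grid minimum of ln π marks the optimal timescale.

    Ties in the minimum break toward the smallest window length.
    """
    results: list[tuple[float, StabilityResult]] = []
    for g in _feasible_grid(recording, grid_ms):
        series = reconstruct(recording, g)
        results.append((g, stability_at_window(series, feature, mode=mode)))
    best_idx = min(range(len(results)), key=lambda i: (results[i][1].ln_pi, results[i][0]))
    return StabilityProfile(
        feature=feature,
        grid=results,
        best_window_ms=results[best_idx][0],
        min_ln_pi=results[best_idx][1].ln_pi,
    )


def rank_gap_profile(recording: Recording, grid_ms: Sequence[float]) -> RankGapProfile:
    """Mean log2(s1/s2) between the two strongest link weights, per window length.

    Windows whose second-ranked weight is zero are excluded from the mean and
    counted in ``n_excluded``.
    """
    if recording.n_channels < 3:
        raise ValueError("need N ≥ 3 for a second-ranked link")
    grid: list[tuple[float, float]] = []
    excluded: dict[float, int] = {}
    for g in _feasible_grid(recording, grid_ms):
        series = reconstruct(recording, g)
        iu = np.triu_indices(series.n_nodes, k=1)
        tri = series.weights[:, iu[0], iu[1]]
        part = -np.partition(-tri, 1, axis=1)[:, :2]  # two largest per window
        s1, s2 = part[:, 0], part[:, 1]
        ok = s2 > 0
        excluded[g] = int((~ok).sum())
        mean_gap = float(np.mean(np.log2(s1[ok] / s2[ok]))) if ok.any() else math.nan
        grid.append((g, mean_gap))
    return RankGapProfile(grid=grid, n_excluded=excluded)


def subject_summary(
    recording: Recording, grid_ms: Sequence[float], mode: str = "tail"
) -> SubjectStabilitySummary:
    """Six-metric description of one subject: (min ln π, best window) × 3 features."""
    min_ln_pi: dict[str, float] = {}
    best_w: dict[str, float] = {}
    for feature in SIX_METRIC_FEATURES:
        prof = stability_profile(recording, feature, grid_ms, mode=mode)
        min_ln_pi[str(feature)] = prof.min_ln_pi
        best_w[str(feature)] = prof.best_window_ms
    return SubjectStabilitySummary(
        subject_id=recording.subject_id, min_ln_pi=min_ln_pi, best_window_ms=best_w
    )


def profile_table(profiles: Sequence[StabilityProfile], subject_id: str | None = None) -> pd.DataFrame:
    """Long-format table of one or more stability profiles."""
    rows = []
    for prof in profiles:
        for window_ms, res in prof.grid:
            row = {"window_ms": window_ms, **res.as_dict()}
            if subject_id is not None:
                row["subject_id"] = subject_id
            rows.append(row)
    return pd.DataFrame(rows)
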