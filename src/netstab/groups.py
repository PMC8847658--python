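"""Group-level aggregation of stability results.

Covers four operations: pointwise group-mean profiles with their peak
summaries; leave-one-subject-out (jackknife) envelopes quantifying how
sensitive those summaries are to any single subject; pooled intra-group
stability, where the windows of all subjects in a group form one trial
sequence scored by a single binomial probability; and the 5-part upsampling
split plus the two-sample Kolmogorov–Smirnov comparison of optimal window
lengths between groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from scipy import stats

from .features import Feature, ln_binomial_tail, per_trial_probability
from .io import Recording
from .networks import reconstruct
from .stability import (
    StabilityProfile,
    StabilityResult,
    _feasible_grid,
    feature_sequence,
    modal_identity,
)

__all__ = [
    "GroupProfile",
    "IntraGroupResult",
    "group_mean_profile",
    "jackknife_envelope",
    "intra_group_stability",
    "upsample_split",
    "compare_best_windows",
]


def _check_common_grid(profiles: Sequence[StabilityProfile]) -> np.ndarray:
    grids = [tuple(p.window_ms) for p in profiles]
    if len(set(grids)) != 1:
        raise ValueError("profiles must share one window grid")
    return np.array(grids[0])


def _peak_of_mean(window_ms: np.ndarray, mean_curve: np.ndarray) -> tuple[float, float]:
    i = int(np.argmin(mean_curve))  # first minimum == smallest window on ties
    return float(window_ms[i]), float(mean_curve[i])


@dataclass
class GroupProfile:
    """Pointwise mean ln π curve for one group, with peak summaries.

    ``best_window_ms``/``min_ln_pi`` are the peak of the *mean* curve;
    ``subject_best_windows``/``subject_min_ln_pi`` retain the per-subject
    peaks (used for distribution comparisons and classification).
    ``envelope`` maps summary name → (min, max) over leave-one-out
    recomputation, when at least two subjects are available.
    """

    group: str
    feature: Feature
    window_ms: np.ndarray
    mean_ln_pi: np.ndarray
    best_window_ms: float
    min_ln_pi: float
    subject_best_windows: np.ndarray
    subject_min_ln_pi: np.ndarray
    envelope: dict[str, tuple[float, float]] | None = None


def group_mean_profile(
    profiles: Sequence[StabilityProfile],
    group: str = "",
    with_envelope: bool = True,
) -> GroupProfile:
    """Average subjects' ln π curves pointwise; summarise the mean curve's peak."""
    if not profiles:
        raise ValueError("empty group")
    window_ms = _check_common_grid(profiles)
    curves = np.vstack([p.ln_pi for p in profiles])
    mean_curve = curves.mean(axis=0)
    best_w, min_lp = _peak_of_mean(window_ms, mean_curve)
    envelope = jackknife_envelope(profiles) if with_envelope and len(profiles) >= 2 else None
    return GroupProfile(
        group=group,
        feature=profiles[0].feature,
        window_ms=window_ms,
        mean_ln_pi=mean_curve,
        best_window_ms=best_w,
        min_ln_pi=min_lp,
        subject_best_windows=np.array([p.best_window_ms for p in profiles]),
        subject_min_ln_pi=np.array([p.min_ln_pi for p in profiles]),
        envelope=envelope,
    )


def jackknife_envelope(
    profiles: Sequence[StabilityProfile],
) -> dict[str, tuple[float, float]]:
    """Leave-one-subject-out extrema of the group-mean peak summaries.

    Returns ``{"best_window_ms": (min, max), "min_ln_pi": (min, max)}`` over
    recomputation of the group mean with each subject deleted in turn.
    """
    if len(profiles) < 2:
        raise ValueError("jackknife needs at least 2 subjects")
    window_ms = _check_common_grid(profiles)
    curves = np.vstack([p.ln_pi for p in profiles])
    best_ws, min_lps = [], []
    for leave in range(len(profiles)):
        mean_curve = np.delete(curves, leave, axis=0).mean(axis=0)
        bw, mlp = _peak_of_mean(window_ms, mean_curve)
        best_ws.append(bw)
        min_lps.append(mlp)
    return {
        "best_window_ms": (min(best_ws), max(best_ws)),
        "min_ln_pi": (min(min_lps), max(min_lps)),
    }


@dataclass
class IntraGroupResult:
    """Pooled across-subject stability: one binomial probability per window length."""

    group: str
    feature: Feature
    grid: list[tuple[float, StabilityResult]]

    @property
    def window_ms(self) -> np.ndarray:
        return np.array([w for w, _ in self.grid])

    @property
    def ln_pi(self) -> np.ndarray:
        return np.array([r.ln_pi for _, r in self.grid])


def intra_group_stability(
    recordings: Sequence[Recording],
    feature: Feature,
    grid_ms: Sequence[float],
    group: str = "",
    mode: str = "tail",
) -> IntraGroupResult:
    """Pool every subject's per-window identities into one trial sequence.

    At each window length: n = Σ_s ⌊l_s/w⌋ pooled windows, k = count of the
    globally modal identity, p as for a single subject.  For one subject this
    reduces bit-exactly to the per-subject result.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    n_nodes = {r.n_channels for r in recordings}
    if len(n_nodes) != 1:
        raise ValueError("all recordings must share the channel count")
    rates = {r.sampling_rate_hz for r in recordings}
    if len(rates) != 1:
        raise ValueError("all recordings must share the sampling rate")
    feasible = _feasible_grid(min(recordings, key=lambda r: r.n_samples), grid_ms)
    p = per_trial_probability(feature, n_nodes.pop())
    grid: list[tuple[float, StabilityResult]] = []
    for g in feasible:
        pooled: list[Hashable] = []
        for rec in recordings:
            pooled.extend(feature_sequence(reconstruct(rec, g), feature))
        winner, k = modal_identity(pooled)
        n = len(pooled)
        grid.append(
            (
                g,
                StabilityResult(
                    feature=feature,
                    modal_identity=winner,
                    k=k,
                    n=n,
                    p=p,
                    ln_pi=ln_binomial_tail(n, p, k, mode=mode),
                ),
            )
        )
    return IntraGroupResult(group=group, feature=feature, grid=grid)


def upsample_split(recording: Recording, parts: int = 5) -> list[Recording]:
    """Split one recording into ``parts`` contiguous equal-length segments.

    Each segment becomes a virtual subject (``<id>_part<i>``); the remainder
    after floor division is discarded.
    """
    if parts < 2:
        raise ValueError("parts must be ≥ 2")
    seg = recording.n_samples // parts
    if seg < 2:
        raise ValueError(
            f"recording of {recording.n_samples} samples too short for {parts} parts"
        )
    out = []
    for i in range(parts):
        piece = recording.restrict(i * seg, (i + 1) * seg)
        piece.subject_id = f"{recording.subject_id}_part{i + 1}"
        out.append(piece)
    return out


def compare_best_windows(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test on per-subject optimal window lengths."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
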