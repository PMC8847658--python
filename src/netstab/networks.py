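"""Sliding-window reconstruction of weighted functional networks.

The recording is split into non-overlapping windows of ``w`` samples
(``⌊l/w⌋`` windows; trailing samples discarded).  For each window a fully
connected weighted network is built whose link weight between channels ``j``
and ``k`` is the absolute Pearson correlation of the two windowed signals —
a value in [0, 1] with zero diagonal.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np

from .io import Recording

__all__ = [
    "WindowSpec",
    "WeightedNetwork",
    "DynamicNetworkSeries",
    "make_window_spec",
    "correlation_network",
    "reconstruct",
    "save_series",
    "load_series",
]


@dataclass(frozen=True)
class WindowSpec:
    """Window length in ms and its sample-domain consequences."""

    window_ms: float
    window_samples: int
    n_windows: int


def make_window_spec(recording: Recording, window_ms: float) -> WindowSpec:
    """Convert a window length in ms to samples (floor) and count windows.

    Raises ``ValueError`` if the window holds fewer than 2 samples or the
    recording is shorter than one window.
    """
    w = int(math.floor(window_ms * recording.sampling_rate_hz / 1000.0))
    if w < 2:
        raise ValueError(
            f"window of {window_ms} ms at {recording.sampling_rate_hz} Hz "
            f"holds {w} sample(s); need at least 2"
        )
    n = recording.n_samples // w
    if n < 1:
        raise ValueError(
            f"recording of {recording.n_samples} samples shorter than one "
            f"window of {w} samples"
        )
    return WindowSpec(window_ms=float(window_ms), window_samples=w, n_windows=n)


@dataclass
class WeightedNetwork:
    """Symmetric [0,1] weight matrix with zero diagonal, for one window."""

    weights: np.ndarray
    window_index: int = 0
    degenerate_channels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def _as_weights(net) -> np.ndarray:
    return net.weights if isinstance(net, WeightedNetwork) else np.asarray(net, dtype=float)


def _batch_abs_corr(windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """|Pearson| for a (N, n_windows, w) stack → ((n_windows, N, N), zero-var mask).

    Channels with zero variance inside a window get weight 0 on all their
    links in that window, keeping the ranking total and deterministic.
    """
    xc = windows - windows.mean(axis=2, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=2))  # (N, n_windows)
    # constant channels leave only rounding residue after centering; detect
    # them exactly so their links are zeroed rather than numerically random
    zero_var = (windows.max(axis=2) == windows.min(axis=2)) | (denom == 0.0)
    cov = np.einsum("inw,jnw->nij", xc, xc, optimize=True)
    dd = np.einsum("in,jn->nij", denom, denom)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(cov / dd)
    corr[~np.isfinite(corr)] = 0.0
    np.clip(corr, 0.0, 1.0, out=corr)
    if zero_var.any():
        mask = zero_var.T  # (n_windows, N)
        corr[mask[:, :, None] | mask[:, None, :]] = 0.0
    idx = np.arange(windows.shape[0])
    corr[:, idx, idx] = 0.0
    return corr, zero_var.T


def correlation_network(window_data: np.ndarray, window_index: int = 0) -> WeightedNetwork:
    """Absolute-Pearson network from one ``N × w`` window of signal."""
    x = np.asarray(window_data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("window_data must be N × w with w ≥ 2")
    corr, zero_var = _batch_abs_corr(x[:, None, :])
    degen = tuple(int(i) for i in np.flatnonzero(zero_var[0]))
    if degen:
        warnings.warn(
            f"zero-variance channel(s) {degen} in window {window_index}; "
            "their link weights set to 0",
            stacklevel=2,
        )
    return WeightedNetwork(weights=corr[0], window_index=window_index, degenerate_channels=degen)


@dataclass
class DynamicNetworkSeries:
    """Ordered per-window networks for one subject at one window length.

    Weights are stored as one ``(n_windows, N, N)`` tensor; ``networks``
    yields :class:`WeightedNetwork` views in window order.
    """

    subject_id: str
    window_spec: WindowSpec
    weights: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    degenerate_mask: np.ndarray | None = None  # (n_windows, N) zero-variance flags

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3 or self.weights.shape[1] != self.weights.shape[2]:
            raise ValueError("weights must be (n_windows, N, N)")
        if self.weights.shape[0] != self.window_spec.n_windows:
            raise ValueError("tensor length disagrees with window_spec.n_windows")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[1]

    @property
    def n_windows(self) -> int:
        return self.weights.shape[0]

    def __len__(self) -> int:
        return self.n_windows

    def __getitem__(self, i: int) -> WeightedNetwork:
        degen = ()
        if self.degenerate_mask is not None:
            degen = tuple(int(j) for j in np.flatnonzero(self.degenerate_mask[i]))
        return WeightedNetwork(self.weights[i], window_index=i, degenerate_channels=degen)

    @property
    def networks(self) -> list[WeightedNetwork]:
        return [self[i] for i in range(self.n_windows)]

    def __iter__(self) -> Iterator[WeightedNetwork]:
        return iter(self.networks)


WeightFn = Callable[[np.ndarray], np.ndarray]


def reconstruct(
    recording: Recording,
    window_ms: float,
    weight_fn: WeightFn | None = None,
) -> DynamicNetworkSeries:
    """Build the per-window network sequence for one recording.

    Window ``i`` covers samples ``[i·w, (i+1)·w)`` (0-based, half-open);
    trailing samples are discarded.  ``weight_fn`` may replace the default
    absolute-Pearson estimator; it receives an ``N × w`` window and must
    return an ``N × N`` weight matrix.
    """
    spec = make_window_spec(recording, window_ms)
    n, w = spec.n_windows, spec.window_samples
    stacked = recording.data[:, : n * w].reshape(recording.n_channels, n, w)
    if weight_fn is None:
        weights, zero_var = _batch_abs_corr(stacked)
        if zero_var.any():
            n_bad = int(zero_var.any(axis=1).sum())
            warnings.warn(
                f"{recording.subject_id}: zero-variance channels in {n_bad} "
                f"window(s) at {window_ms} ms; affected link weights set to 0",
                stacklevel=2,
            )
    else:
        weights = np.stack([np.asarray(weight_fn(stacked[:, i, :]), dtype=float) for i in range(n)])
        zero_var = None
    return DynamicNetworkSeries(
        subject_id=recording.subject_id,
        window_spec=spec,
        weights=weights,
        channel_labels=list(recording.channel_labels),
        degenerate_mask=zero_var,
    )


def save_series(series: DynamicNetworkSeries, path: str | Path) -> None:
    """Export the weight tensor (.npy) with a JSON sidecar of metadata."""
    path = Path(path)
    np.save(path, series.weights)
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npy" else path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "subject_id": series.subject_id,
                "window_ms": series.window_spec.window_ms,
                "window_samples": series.window_spec.window_samples,
                "n_windows": series.window_spec.n_windows,
                "channel_labels": series.channel_labels,
            },
            indent=2,
        )
    )


def load_series(path: str | Path) -> DynamicNetworkSeries:
    path = Path(path)
    weights = np.load(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = WindowSpec(
        window_ms=sidecar["window_ms"],
        window_samples=sidecar["window_samples"],
        n_windows=sidecar["n_windows"],
    )
    return DynamicNetworkSeries(
        subject_id=sidecar["subject_id"],
        window_spec=spec,
        weights=weights,
        channel_labels=sidecar["channel_labels"],
    )
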