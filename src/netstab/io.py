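"""Reading, validation and canonical in-memory containers for recordings.

A :class:`Recording` is one subject's multichannel time series: an ``N × l``
matrix of signal amplitudes (channels as rows) plus sampling rate and channel
labels.  Signals are kept raw — no filtering, detrending or re-referencing is
applied anywhere in the package; the method is defined on broadband signals.

Two on-disk formats are supported: European Data Format (EDF), read through
:mod:`mne`, and a plain delimited-text layout: an optional
``# sampling_rate_hz=<x>`` comment line, one header row with the channel
labels, then one row per channel with its samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "SubjectMetadata",
    "read_recording",
    "write_recording",
    "read_metadata",
]


@dataclass
class Recording:
    """One subject's channels × samples matrix with acquisition metadata."""

    subject_id: str
    data: np.ndarray
    sampling_rate_hz: float
    channel_labels: list[str]
    condition_tag: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels × samples matrix")
        n, l = self.data.shape
        if n < 3:
            raise ValueError(f"need at least 3 channels, got {n}")
        if l < 2:
            raise ValueError(f"need at least 2 samples per channel, got {l}")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != n:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {n} channels"
            )
        if len(set(self.channel_labels)) != n:
            raise ValueError("channel labels must be unique")
        bad = np.argwhere(~np.isfinite(self.data))
        if bad.size:
            c, s = bad[0]
            raise ValueError(
                f"non-finite value in channel {self.channel_labels[c]!r} "
                f"(row {c}) at sample {s}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def restrict(self, start: int, stop: int, condition_tag: str | None = None) -> "Recording":
        """Return a new Recording over samples ``[start, stop)`` (0-based)."""
        if not (0 <= start < stop <= self.n_samples):
            raise ValueError(f"invalid sample range [{start}, {stop})")
        return Recording(
            subject_id=self.subject_id,
            data=self.data[:, start:stop].copy(),
            sampling_rate_hz=self.sampling_rate_hz,
            channel_labels=list(self.channel_labels),
            condition_tag=condition_tag if condition_tag is not None else self.condition_tag,
        )


@dataclass
class SubjectMetadata:
    """Demographic/cognitive covariates for one subject.

    ``cognitive_scores`` maps score name (e.g. ``"MMSE"``, ``"GDS"``) to a
    real value; missing scores are stored as NaN and listed in
    ``missing_scores``.
    """

    subject_id: str
    group: str
    age: float = math.nan
    education: float = math.nan
    cognitive_scores: dict[str, float] = field(default_factory=dict)

    @property
    def missing_scores(self) -> list[str]:
        return [k for k, v in self.cognitive_scores.items() if not math.isfinite(v)]


_RATE_PREFIX = "# sampling_rate_hz="


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def read_recording(
    path: str | Path,
    format: str = "auto",
    sampling_rate_hz: float | None = None,
    subject_id: str | None = None,
    sample_range: tuple[int, int] | None = None,
    condition_tag: str | None = None,
) -> Recording:
    """Read a multichannel recording from EDF or delimited text.

    Parameters
    ----------
    path
        Input file.  With ``format="auto"`` the ``.edf`` suffix selects EDF.
    sampling_rate_hz
        Required for delimited files without a ``# sampling_rate_hz=`` line;
        ignored for EDF (the header rate is authoritative).
    sample_range
        Optional ``(start, stop)`` restriction, 0-based half-open — e.g. to
        select an eyes-open or eyes-closed segment.  Default: full recording.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        rec = _read_edf(path, subject_id)
    elif format == "delimited":
        rec = _read_delimited(path, sampling_rate_hz, subject_id)
    else:
        raise ValueError(f"unknown format {format!r}")
    if sample_range is not None:
        rec = rec.restrict(*sample_range)
    if condition_tag is not None:
        rec.condition_tag = condition_tag
    return rec


def _read_edf(path: Path, subject_id: str | None) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    return Recording(
        subject_id=subject_id or path.stem,
        data=data,
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def _read_delimited(
    path: Path, sampling_rate_hz: float | None, subject_id: str | None
) -> Recording:
    rate = sampling_rate_hz
    labels: list[str] | None = None
    rows: list[np.ndarray] = []
    delim = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith(_RATE_PREFIX):
                    rate = float(line[len(_RATE_PREFIX):])
                continue
            if labels is None:
                delim = _sniff_delimiter(line)
                labels = [tok.strip() for tok in line.split(delim)]
                continue
            toks = line.split(delim)
            try:
                rows.append(np.array([float(t) for t in toks]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if labels is None or not rows:
        raise ValueError(f"{path}: no header or no data rows")
    if rate is None:
        raise ValueError(
            f"{path}: sampling rate missing — pass sampling_rate_hz or add a "
            f"'{_RATE_PREFIX}<x>' line"
        )
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged channel rows, lengths {sorted(lengths)}")
    return Recording(
        subject_id=subject_id or path.stem,
        data=np.vstack(rows),
        sampling_rate_hz=rate,
        channel_labels=labels,
    )


def write_recording(recording: Recording, path: str | Path, delimiter: str = ",") -> None:
    """Write a Recording in the delimited layout; floats round-trip exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_RATE_PREFIX}{recording.sampling_rate_hz!r}\n")
        fh.write(delimiter.join(recording.channel_labels) + "\n")
        for row in recording.data:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


_RESERVED_COLS = {"subject_id", "group", "age", "education"}


def read_metadata(path: str | Path) -> list[SubjectMetadata]:
    """Read a subject-metadata table (delimited text).

    Requires ``subject_id`` and ``group`` columns; ``age`` and ``education``
    are recognised if present; every other column becomes a cognitive score.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"metadata table lacks required column {col!r}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id values: {dupes}")
    if df["group"].isna().any():
        bad = df.loc[df["group"].isna(), "subject_id"].tolist()
        raise ValueError(f"missing group for subjects: {bad}")
    score_cols = [c for c in df.columns if c not in _RESERVED_COLS]
    out = []
    for _, row in df.iterrows():
        scores = {c: float(row[c]) if pd.notna(row[c]) else math.nan for c in score_cols}
        out.append(
            SubjectMetadata(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]) if "age" in df.columns and pd.notna(row["age"]) else math.nan,
                education=float(row["education"])
                if "education" in df.columns and pd.notna(row["education"])
                else math.nan,
                cognitive_scores=scores,
            )
        )
    return out
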