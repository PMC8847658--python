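"""Synthetic multichannel recordings with known ground truth.

The generator emulates the acquisition geometry of a resting-state EEG
session — 32 channels at 500 Hz for 8 minutes by default — as iid Gaussian
noise, optionally with planted structure:

* **planted pairs**: two channels share a latent Gaussian signal with
  loading √ρ inside *active epochs*, so their within-epoch population
  correlation is exactly ρ.  Time is divided into consecutive epochs of
  ``epoch_ms``; each epoch is independently active with probability ``q``
  (the persistence).  This square-wave activation gives the planted link a
  well-defined target timescale for best-window recovery.
* **planted hub**: one channel is coupled to each of ``k`` peripherals
  through per-peripheral latents with hub loading √(ρ/k) and peripheral
  loading √ρ, giving hub–peripheral correlation ρ/√k while peripherals stay
  mutually uncorrelated — the hub is the unique strength-centrality apex.

No attempt is made at realistic EEG spectra (1/f background, volume
conduction); the generator's job is controllable ground truth, not
electrophysiological realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import Recording

__all__ = [
    "PlantedPair",
    "PlantedHub",
    "SyntheticSpec",
    "GroundTruth",
    "generate_null",
    "generate_planted",
    "generate_group",
]


@dataclass(frozen=True)
class PlantedPair:
    """One persistent pairwise coupling: channels (j, k), correlation ρ,
    persistence q (active-epoch probability), epoch length in ms."""

    j: int
    k: int
    rho: float = 0.9
    q: float = 1.0
    epoch_ms: float = 30.0


@dataclass(frozen=True)
class PlantedHub:
    """A hub channel coupled to several peripherals (correlation ρ/√k each)."""

    hub: int
    peripherals: tuple[int, ...]
    rho: float = 0.9


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; defaults mirror a 32-channel, 500 Hz, 8-minute
    resting-state session with unit-variance noise."""

    n_channels: int = 32
    duration_s: float = 480.0
    sampling_rate_hz: float = 500.0
    noise_sd: float = 1.0
    planted_pairs: tuple[PlantedPair, ...] = ()
    planted_hub: PlantedHub | None = None
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))

    def validate(self) -> None:
        if self.n_channels < 3:
            raise ValueError("need at least 3 channels")
        if self.n_samples < 2:
            raise ValueError("duration × rate must give at least 2 samples")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        used: set[int] = set()
        for p in self.planted_pairs:
            if not (0 <= p.j < p.k < self.n_channels):
                raise ValueError(f"invalid planted pair ({p.j}, {p.k})")
            if not (0.0 < p.rho <= 1.0 and 0.0 < p.q <= 1.0):
                raise ValueError("pair rho and q must lie in (0, 1]")
            if p.epoch_ms * self.sampling_rate_hz / 1000.0 < 1.0:
                raise ValueError("epoch shorter than one sample")
            if used & {p.j, p.k}:
                raise ValueError("planted channels must be distinct across pairs")
            used |= {p.j, p.k}
        if self.planted_hub is not None:
            h = self.planted_hub
            members = {h.hub, *h.peripherals}
            if len(members) != 1 + len(h.peripherals) or not h.peripherals:
                raise ValueError("hub and peripherals must be distinct, ≥ 1 peripheral")
            if any(not 0 <= c < self.n_channels for c in members):
                raise ValueError("hub channel index out of range")
            if not 0.0 < h.rho <= 1.0:
                raise ValueError("hub rho must lie in (0, 1]")
            if used & members:
                raise ValueError("hub channels overlap planted pairs")


@dataclass
class GroundTruth:
    """Planted identities and the per-sample activation mask of each pair."""

    planted_pairs: tuple[PlantedPair, ...]
    planted_hub: PlantedHub | None
    active_masks: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)


def _rng(spec: SyntheticSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def generate_null(spec: SyntheticSpec, subject_id: str = "null") -> Recording:
    """iid Gaussian recording — the independent-networks null, seeded."""
    spec.validate()
    if spec.planted_pairs or spec.planted_hub is not None:
        raise ValueError("generate_null requires a spec without planted structure")
    rng = _rng(spec)
    data = rng.standard_normal((spec.n_channels, spec.n_samples)) * spec.noise_sd
    return Recording(
        subject_id=subject_id,
        data=data,
        sampling_rate_hz=spec.sampling_rate_hz,
        channel_labels=[f"ch{i:02d}" for i in range(spec.n_channels)],
    )


def generate_planted(
    spec: SyntheticSpec, subject_id: str = "planted"
) -> tuple[Recording, GroundTruth]:
    """Recording with planted pair/hub couplings and its ground truth."""
    spec.validate()
    if not spec.planted_pairs and spec.planted_hub is None:
        raise ValueError("generate_planted requires at least one planted pair or hub")
    rng = _rng(spec)
    l = spec.n_samples
    data = rng.standard_normal((spec.n_channels, l))
    truth = GroundTruth(planted_pairs=spec.planted_pairs, planted_hub=spec.planted_hub)
    for pair in spec.planted_pairs:
        es = max(1, int(round(pair.epoch_ms * spec.sampling_rate_hz / 1000.0)))
        n_epochs = -(-l // es)
        active = rng.random(n_epochs) < pair.q
        mask = np.repeat(active, es)[:l]
        z = rng.standard_normal(l)
        a = math.sqrt(pair.rho)
        b = math.sqrt(1.0 - pair.rho)
        for c in (pair.j, pair.k):
            data[c] = np.where(mask, b * data[c] + a * z, data[c])
        truth.active_masks[(pair.j, pair.k)] = mask
    if spec.planted_hub is not None:
        h = spec.planted_hub
        kp = len(h.peripherals)
        a_hub = math.sqrt(h.rho / kp)
        zs = rng.standard_normal((kp, l))
        data[h.hub] = math.sqrt(1.0 - h.rho) * data[h.hub] + a_hub * zs.sum(axis=0)
        for zi, c in zip(zs, h.peripherals):
            data[c] = math.sqrt(1.0 - h.rho) * data[c] + math.sqrt(h.rho) * zi
    rec = Recording(
        subject_id=subject_id,
        data=data * spec.noise_sd,
        sampling_rate_hz=spec.sampling_rate_hz,
        channel_labels=[f"ch{i:02d}" for i in range(spec.n_channels)],
    )
    return rec, truth


def generate_group(
    n_subjects: int,
    template: SyntheticSpec,
    shared_structure: bool = True,
    subject_prefix: str = "subj",
) -> list[tuple[Recording, GroundTruth]]:
    """Seeded cohort of recordings from one template spec.

    Per-subject seeds derive deterministically from the template's seed.
    With ``shared_structure`` every subject carries the template's planted
    identities (intra-group pooling finds one common modal identity);
    otherwise each subject gets freshly drawn planted channel indices of the
    same strength, so identities differ across subjects.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be ≥ 1")
    template.validate()
    seeds = np.random.SeedSequence(template.seed).generate_state(2 * n_subjects) % (2**31)
    out = []
    for i in range(n_subjects):
        sub_spec = replace(template, seed=int(seeds[2 * i]))
        if not shared_structure:
            sub_spec = _randomize_identities(sub_spec, int(seeds[2 * i + 1]))
        rec, truth = generate_planted(sub_spec, subject_id=f"{subject_prefix}{i:03d}")
        out.append((rec, truth))
    return out


def _randomize_identities(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    rng = np.random.default_rng(seed)
    free = list(range(spec.n_channels))
    rng.shuffle(free)
    pairs = []
    for p in spec.planted_pairs:
        j, k = sorted((free.pop(), free.pop()))
        pairs.append(replace(p, j=j, k=k))
    hub = spec.planted_hub
    if hub is not None:
        members = [free.pop() for _ in range(1 + len(hub.peripherals))]
        hub = replace(hub, hub=members[0], peripherals=tuple(members[1:]))
    return replace(spec, planted_pairs=tuple(pairs), planted_hub=hub)
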