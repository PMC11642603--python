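"""Synthetic epoched EEG with configurable condition-pattern separability.

Each trial's epoch is a condition-specific mean spatiotemporal pattern
plus spatially correlated Gaussian noise.  Patterns are keyed by the
*cued* (context, combination) cell -- the epochs model the delay period
between cue and go signal, so catch trials carry the pattern of what was
cued, not of what the partner eventually draws.

Pattern presets
---------------
``integrated``
    Joint context: the two congruent combinations (CC, DD) have distinct
    patterns while both incongruent combinations (CD, DC) share a single
    "merged" pattern (plus a dedicated integration component), emulating a
    dyadic motor plan in which the two agents' contributions are fused.
    Parallel context: additive own-shape + partner-shape components, so
    every pairwise contrast is linearly separable.
``no_signal``
    All conditions share the same (zero) mean pattern; decoding is at
    chance by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from dyaddraw.design import COMBINATIONS, CONTEXTS, TrialRecord


class EEGConfigError(ValueError):
    """Raised when the EEG generator configuration is inconsistent."""


def synthetic_montage(n_channels: int = 64):
    """Synthetic 2-D electrode layout: concentric rings on the unit disc.

    A stand-in scalp layout (not a standard montage file): one vertex
    electrode plus rings of 7, 12, 20 and 24 channels at increasing radii
    for the default 64; other channel counts distribute proportionally.
    Returns ``(names, positions)`` with positions of shape (n, 2).
    """
    if n_channels < 3:
        raise EEGConfigError("montage needs >= 3 channels")
    if n_channels == 64:
        ring_counts = [1, 7, 12, 20, 24]
    else:
        ring_counts = [1]
        remaining = n_channels - 1
        k = 1
        while remaining > 0:
            c = min(remaining, 6 * k)
            ring_counts.append(c)
            remaining -= c
            k += 1
    radii = np.linspace(0.0, 1.0, len(ring_counts))
    pos = []
    for r, count in zip(radii, ring_counts):
        if count == 1 and r == 0:
            pos.append((0.0, 0.0))
            continue
        ang = 2 * np.pi * np.arange(count) / count + 0.1 * r  # offset avoids collinearity
        pos += [(r * np.cos(a), r * np.sin(a)) for a in ang]
    names = [f"E{i + 1:02d}" for i in range(n_channels)]
    return names, np.asarray(pos[:n_channels], dtype=float)


@dataclass
class EEGGenParams:
    """Configuration of the epoch generator.

    ``condition_patterns`` maps (context, combination) to a
    (n_channels, n_times) mean pattern; ``noise_sd`` sets the per-sample
    noise amplitude and ``spatial_corr`` mixes in a channel-shared noise
    component (0 = independent channels, 1 = fully shared).
    """

    n_channels: int = 64
    sfreq: float = 128.0
    epoch_length: float = 2.0
    condition_patterns: Mapping[tuple[str, str], np.ndarray] = field(default_factory=dict)
    noise_sd: float = 1.0
    spatial_corr: float = 0.3
    seed: int = 0

    @property
    def n_times(self) -> int:
        return int(round(self.epoch_length * self.sfreq))

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise EEGConfigError("noise_sd must be > 0")
        if not (0 <= self.spatial_corr <= 1):
            raise EEGConfigError("spatial_corr must be in [0, 1]")


@dataclass
class EpochSet:
    """Epoched EEG: (trials, channels, times) plus labels and montage."""

    data: np.ndarray
    sfreq: float
    labels: pd.DataFrame
    channel_names: list[str]
    channel_pos: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, times)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count does not match trial count")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel name count does not match data")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[2]) / self.sfreq

    def select(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[mask],
            sfreq=self.sfreq,
            labels=self.labels.loc[mask].reset_index(drop=True),
            channel_names=self.channel_names,
            channel_pos=self.channel_pos,
        )


def _smooth_pattern(n_channels: int, n_times: int, rng: np.random.Generator,
                    rank: int = 2) -> np.ndarray:
    """Random low-rank spatiotemporal pattern, unit Frobenius norm."""
    t = np.linspace(0.0, 1.0, n_times)
    pat = np.zeros((n_channels, n_times))
    for _ in range(rank):
        ch = rng.normal(size=n_channels)
        freq = rng.uniform(0.5, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        env = np.sin(np.pi * t)  # rise-and-fall envelope across the delay
        course = np.sin(2 * np.pi * freq * t + phase) * env
        pat += np.outer(ch, course)
    return pat / np.linalg.norm(pat)


def make_condition_patterns(
    preset: str,
    n_channels: int = 64,
    n_times: int = 256,
    amp: float = 1.5,
    seed: int = 0,
) -> dict[tuple[str, str], np.ndarray]:
    """Build the condition -> mean-pattern map for a named preset.

    ``amp`` scales pattern strength in units of ``noise_sd`` Frobenius
    norm over the whole epoch (the single SNR knob of the generator).
    """
    rng = np.random.default_rng(seed)
    zeros = np.zeros((n_channels, n_times))
    if preset == "no_signal":
        return {(cx, cb): zeros for cx in CONTEXTS for cb in COMBINATIONS}
    if preset != "integrated":
        raise EEGConfigError(f"unknown preset {preset!r}")

    # Joint: distinct congruent patterns A, B; shared incongruent pattern
    A = _smooth_pattern(n_channels, n_times, rng)
    B = _smooth_pattern(n_channels, n_times, rng)
    G = _smooth_pattern(n_channels, n_times, rng)  # integration component
    X = 0.5 * (A + B) + 0.7 * G
    # Parallel: additive own + partner shape components
    O_c = _smooth_pattern(n_channels, n_times, rng)
    O_d = _smooth_pattern(n_channels, n_times, rng)
    Q_c = _smooth_pattern(n_channels, n_times, rng)
    Q_d = _smooth_pattern(n_channels, n_times, rng)
    own = {"C": O_c, "D": O_d}
    partner = {"C": Q_c, "D": Q_d}

    patterns: dict[tuple[str, str], np.ndarray] = {}
    joint = {"CC": A, "DD": B, "CD": X, "DC": X}
    for cb in COMBINATIONS:
        patterns[("Joint", cb)] = amp * joint[cb]
        patterns[("Parallel", cb)] = amp * (own[cb[0]] + partner[cb[1]]) / np.sqrt(2.0)
    return patterns


def generate_epochs(design: Sequence[TrialRecord], params: EEGGenParams) -> EpochSet:
    """Simulate one epoch per trial: condition pattern + correlated noise."""
    rng = np.random.default_rng(params.seed)
    n_t = params.n_times
    n_ch = params.n_channels
    needed = {(t.context, t.combination) for t in design}
    missing = needed - set(params.condition_patterns)
    if missing:
        raise EEGConfigError(f"missing condition patterns for {sorted(missing)}")
    for key in needed:
        pat = np.asarray(params.condition_patterns[key])
        if pat.shape != (n_ch, n_t):
            raise EEGConfigError(
                f"pattern {key} has shape {pat.shape}, expected {(n_ch, n_t)}"
            )

    rho = params.spatial_corr
    n_trials = len(design)
    data = rng.normal(0.0, 1.0, size=(n_trials, n_ch, n_t))
    data *= np.sqrt(1 - rho**2)
    if rho:
        data += rho * rng.normal(0.0, 1.0, size=(n_trials, 1, n_t))
    data *= params.noise_sd
    for i, trial in enumerate(design):
        data[i] += params.condition_patterns[(trial.context, trial.combination)]

    names, pos = synthetic_montage(n_ch)
    labels = pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in design],
            "context": [t.context for t in design],
            "combination": [t.combination for t in design],
            "cue_pair": [t.cue_pair for t in design],
            "is_catch": [t.is_catch for t in design],
            "catch_response": [t.catch_response for t in design],
        }
    )
    return EpochSet(data=data, sfreq=params.sfreq, labels=labels,
                    channel_names=names, channel_pos=pos)
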