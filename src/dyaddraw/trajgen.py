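"""Synthetic pen trajectories.

Each trial's trajectory is a noisy realisation of the participant's cued
shape, sampled at the display refresh rate (30 Hz) over the trial's
drawing duration.  Visuomotor interference (VMI) is injected as an
additive lateral deflection toward the *partner's* shape, proportional to
the difference between the two ideal shapes and weighted per
context x congruency cell; on congruent trials the difference field is
identically zero, so only incongruent trials can be deflected.  With
probability ``swap_rate`` the participant draws the opposite shape
entirely (swap error), and with probability ``gross_error_rate`` the
trajectory is replaced by a meaningless scribble (e.g. the pen slipped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from dyaddraw.design import TrialRecord
from dyaddraw.shapes import DEFAULT_LENGTH, ideal_shape
from dyaddraw.trajectory import Trajectory

SAMPLE_HZ = 30.0


@dataclass
class TrajectoryEffects:
    """Effect parameters of the trajectory generator.

    ``vmi_shift`` maps (context, congruency) to the peak lateral pull (px)
    toward the partner's shape.  ``base_noise_sd`` is the sd (px) of the
    smooth motor noise added to every trajectory.
    """

    base_noise_sd: float = 8.0
    vmi_shift: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("Joint", "congruent"): 0.0,
            ("Joint", "incongruent"): 4.0,
            ("Parallel", "congruent"): 0.0,
            ("Parallel", "incongruent"): 14.0,
        }
    )
    duration_mean: float = 2.0
    duration_sd: float = 0.15
    swap_rate: float = 0.01
    gross_error_rate: float = 0.01
    length: float = DEFAULT_LENGTH
    seed: int = 0


def _smooth_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Low-pass-filtered Gaussian noise, tapered to zero at both ends."""
    if sd <= 0 or n < 3:
        return np.zeros((n, 2))
    raw = rng.normal(0.0, 1.0, size=(n, 2))
    k = max(3, n // 10)
    kernel = np.hanning(k)
    kernel /= kernel.sum()
    sm = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 0, raw)
    std = sm.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    sm = sm / std * sd
    taper = np.sin(np.pi * np.linspace(0.0, 1.0, n)) ** 0.5
    return sm * taper[:, None]


def generate_trajectories(
    design: Sequence[TrialRecord],
    effects: TrajectoryEffects | None = None,
) -> list[Trajectory]:
    """Simulate one pen trajectory per trial of ``design``.

    Every trajectory starts exactly at the start point (0, 0) and ends
    exactly at the end point (0, length); noise and VMI deflections are
    tapered at the endpoints.  Sample spacing follows the trial's
    ``drawing_duration`` at 30 Hz.
    """
    effects = effects or TrajectoryEffects()
    rng = np.random.default_rng(effects.seed)
    out: list[Trajectory] = []
    for trial in design:
        dur = trial.drawing_duration
        if not np.isfinite(dur) or dur <= 0:
            dur = max(0.5, rng.normal(effects.duration_mean, effects.duration_sd))
        n = max(8, int(round(dur * SAMPLE_HZ)))
        t = np.arange(n) / SAMPLE_HZ

        if rng.random() < effects.gross_error_rate:
            pts = _scribble(n, effects.length, rng)
            out.append(Trajectory(points=pts, t=t, trial_id=trial.trial_id))
            continue

        drawn = trial.own_shape
        if rng.random() < effects.swap_rate:
            drawn = "diamond" if drawn == "circle" else "circle"

        base = ideal_shape(drawn, n, effects.length)
        shift = effects.vmi_shift.get((trial.context, trial.congruency), 0.0)
        if shift != 0.0 and trial.partner_cued_shape != drawn:
            other = ideal_shape(trial.partner_cued_shape, n, effects.length)
            diff = other - base
            peak = np.abs(diff).max()
            if peak > 0:
                taper = np.sin(np.pi * np.linspace(0.0, 1.0, n))[:, None]
                base = base + shift * diff / peak * taper
        pts = base + _smooth_noise(n, effects.base_noise_sd, rng)
        pts[0] = (0.0, 0.0)
        pts[-1] = (0.0, effects.length)
        out.append(Trajectory(points=pts, t=t, trial_id=trial.trial_id))
    return out


def _scribble(n: int, length: float, rng: np.random.Generator) -> np.ndarray:
    """A meaningless random walk across the drawing area."""
    steps = rng.normal(0.0, length / 6.0, size=(n, 2))
    pts = np.cumsum(steps, axis=0)
    pts -= pts[0]
    pts[-1] = (0.0, length)
    return pts
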