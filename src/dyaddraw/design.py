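"""Trial-design generation for the paired drawing task.

The task crosses a Social context factor (Joint: synchronise with the
partner; Parallel: draw independently at a consistent ~2 s pace) with a
shape Combination factor (CC, DD, CD, DC; first letter = participant's
shape, second = partner's shape).  Each context is run as a block of
blocks; a fixed number of trials per block are catch trials in which the
partner draws the non-cued shape.  Cue symbols come in two pairs that
alternate, balanced within every design cell so that decoding cannot rely
on cue identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

CONTEXTS = ("Joint", "Parallel")
COMBINATIONS = ("CC", "DD", "CD", "DC")
CUE_PAIRS = (1, 2)

SHAPE_FOR_LETTER = {"C": "circle", "D": "diamond"}


class DesignConfigError(ValueError):
    """Raised when design parameters cannot produce a balanced design."""


@dataclass(frozen=True)
class DesignParams:
    """Parameters of the 2 (context) x 4 (combination) block design.

    Defaults reproduce the published task: 6 blocks of 48 trials per
    context, 8 catch trials per block, partner drawing durations uniform
    on 1.8-2.2 s (Joint) / 1.6-2.4 s (Parallel), partner start jittered
    +/-100 ms around the participant's running-average start time, a
    maximum allowed start time of 800 ms and a 200 ms synchronisation
    criterion on the end-point delta.
    """

    n_blocks_per_context: int = 6
    trials_per_block: int = 48
    catch_per_block: int = 8
    contexts: Sequence[str] = CONTEXTS
    combinations: Sequence[str] = COMBINATIONS
    partner_duration_joint: tuple[float, float] = (1.8, 2.2)
    partner_duration_parallel: tuple[float, float] = (1.6, 2.4)
    partner_start_jitter: float = 0.100
    max_start_time: float = 0.800
    delta_criterion: float = 0.200
    seed: int = 0

    def __post_init__(self) -> None:
        n_comb = len(self.combinations)
        if self.trials_per_block % n_comb:
            raise DesignConfigError(
                f"trials_per_block={self.trials_per_block} not divisible by "
                f"{n_comb} combinations"
            )
        if self.catch_per_block >= self.trials_per_block:
            raise DesignConfigError("catch_per_block must be < trials_per_block")
        for lo, hi in (self.partner_duration_joint, self.partner_duration_parallel):
            if not (0 < lo < hi):
                raise DesignConfigError("duration interval bounds must satisfy 0 < low < high")
        # catch and non-catch trials must each split evenly over
        # combination x cue-pair cells within one context
        n_cells = n_comb * len(CUE_PAIRS)
        total = self.n_blocks_per_context * self.trials_per_block
        n_catch = self.n_blocks_per_context * self.catch_per_block
        if n_catch % n_cells or (total - n_catch) % n_cells:
            raise DesignConfigError(
                f"catch ({n_catch}) and non-catch ({total - n_catch}) counts must "
                f"both be divisible by {n_cells} combination x cue-pair cells"
            )


@dataclass
class TrialRecord:
    """One trial: condition labels plus simulated timing events."""

    context: str
    combination: str
    cue_pair: int
    is_catch: bool
    block: int
    trial_id: int = -1
    start_time: float = float("nan")
    drawing_duration: float = float("nan")
    partner_duration: float = float("nan")
    delta_time: float = float("nan")
    catch_response: bool = False

    @property
    def own_shape(self) -> str:
        return SHAPE_FOR_LETTER[self.combination[0]]

    @property
    def partner_shape(self) -> str:
        """Shape the partner actually draws (opposite of cue on catch trials)."""
        cued = SHAPE_FOR_LETTER[self.combination[1]]
        if self.is_catch:
            return "diamond" if cued == "circle" else "circle"
        return cued

    @property
    def partner_cued_shape(self) -> str:
        return SHAPE_FOR_LETTER[self.combination[1]]

    @property
    def congruency(self) -> str:
        return "congruent" if self.combination in ("CC", "DD") else "incongruent"


def generate_design(params: DesignParams) -> list[TrialRecord]:
    """Generate a balanced, randomised trial list for both contexts.

    Per context, every combination x cue-pair cell receives the same number
    of non-catch trials and the same number of catch trials; trials are
    shuffled within blocks.  Timing events (start time, drawing duration,
    partner duration, end-point delta) are drawn from the context-specific
    distributions so that downstream behavioural statistics have realistic
    inputs.  Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    trials: list[TrialRecord] = []
    n_comb = len(params.combinations)
    cells = [(c, q) for c in params.combinations for q in CUE_PAIRS]
    n_cells = len(cells)
    total = params.n_blocks_per_context * params.trials_per_block
    n_catch = params.n_blocks_per_context * params.catch_per_block

    for context in params.contexts:
        pool: list[tuple[str, int, bool]] = []
        for comb, cue in cells:
            pool += [(comb, cue, False)] * ((total - n_catch) // n_cells)
            pool += [(comb, cue, True)] * (n_catch // n_cells)
        # shuffle while keeping the per-block catch count exact: distribute
        # catch and non-catch trials into blocks separately
        catch_pool = [t for t in pool if t[2]]
        reg_pool = [t for t in pool if not t[2]]
        rng.shuffle(catch_pool)
        rng.shuffle(reg_pool)
        for b in range(params.n_blocks_per_context):
            block_trials = (
                catch_pool[b * params.catch_per_block : (b + 1) * params.catch_per_block]
                + reg_pool[
                    b * (params.trials_per_block - params.catch_per_block) : (b + 1)
                    * (params.trials_per_block - params.catch_per_block)
                ]
            )
            order = rng.permutation(len(block_trials))
            for i in order:
                comb, cue, is_catch = block_trials[i]
                trials.append(
                    TrialRecord(context=context, combination=comb, cue_pair=cue,
                                is_catch=is_catch, block=b)
                )

    _draw_timing(trials, params, rng)
    for i, t in enumerate(trials):
        t.trial_id = i
    return trials


def _draw_timing(trials: list[TrialRecord], params: DesignParams, rng: np.random.Generator) -> None:
    """Fill in simulated timing events.

    Joint: the participant tracks the partner's duration (small end-point
    delta, sd ~50 ms around zero).  Parallel: the participant aims at 2 s
    with a mild systematic shortening, independent of the partner.
    Start times are uniform below the 800 ms criterion; catch responses are
    correct with probability ~0.93, matching the published accuracy range.
    """
    for t in trials:
        lo, hi = (
            params.partner_duration_joint
            if t.context == "Joint"
            else params.partner_duration_parallel
        )
        t.partner_duration = rng.uniform(lo, hi)
        t.start_time = rng.uniform(0.15, min(0.65, params.max_start_time))
        if t.context == "Joint":
            t.delta_time = rng.normal(0.0, 0.05)
            t.drawing_duration = max(0.8, t.partner_duration + t.delta_time)
        else:
            t.drawing_duration = max(0.8, rng.normal(1.95, 0.15))
            t.delta_time = t.drawing_duration - t.partner_duration
        if t.is_catch:
            t.catch_response = bool(rng.random() < 0.93)
        else:
            t.catch_response = bool(rng.random() < 0.01)  # rare false alarms


def design_counts(trials: Sequence[TrialRecord]) -> dict:
    """Summary counts used for design-arithmetic checks."""
    import collections

    by_cell = collections.Counter(
        (t.context, t.combination) for t in trials if not t.is_catch
    )
    catch_by_block = collections.Counter(
        (t.context, t.block) for t in trials if t.is_catch
    )
    return {
        "total": len(trials),
        "noncatch_per_cell": dict(by_cell),
        "catch_per_block": dict(catch_by_block),
    }
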