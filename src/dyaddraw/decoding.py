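"""Spatiotemporal multivariate decoding of upcoming movements.

Pipeline (per subject, contrast and social context):

1. usable trials = correctly identified catch trials plus regular trials
   without a false alarm;
2. "supertrials": averages of ``n_avg = 4`` trials of the same class,
   balanced across the two cue pairs so the classifier cannot exploit cue
   identity.  Combination contrasts (CD vs DC, CC vs DD) average four
   trials of one condition (two per cue pair); own/partner-movement
   contrasts average one trial from each condition x cue-pair cell of the
   class.  Ten supertrials per class, sampled without replacement within
   one permutation;
3. per-channel temporal demeaning and averaging into 10 bins of 200 ms
   over the 0-2 s delay window (64 channels x 10 bins = 640 features);
4. Ledoit-Wolf shrinkage LDA under stratified 5-fold cross-validation;
5. the whole pipeline repeated for ``n_perm`` fresh supertrial samplings
   (default 100) and averaged; a matching null pipeline randomises the
   class assignment of the supertrials (balanced) before classification.

Group inference: one-tailed paired t-tests of empirical vs null
accuracies per contrast, and two-tailed paired t-tests of empirical
accuracies between the two social contexts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from dyaddraw.eeggen import EpochSet
from dyaddraw.lda import ShrinkageLDA
from dyaddraw.stats import StatResult, paired_t


class InsufficientTrialsError(ValueError):
    """A design cell has fewer trials than supertrial sampling requires."""


def _stable_tag(s: str) -> int:
    """Process-independent integer tag for seeding (CRC32 of the name)."""
    import zlib

    return zlib.crc32(s.encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class ContrastSpec:
    """A two-class decoding contrast within one social context.

    ``class_a``/``class_b`` are disjoint sets of combination labels;
    ``pooled`` selects the supertrial recipe (False: four trials of one
    condition, two per cue pair; True: one trial from each
    condition x cue-pair cell).
    """

    name: str
    class_a: tuple[str, ...]
    class_b: tuple[str, ...]
    context: str = "Joint"
    pooled: bool = False

    def __post_init__(self) -> None:
        if set(self.class_a) & set(self.class_b):
            raise ValueError("contrast classes must be disjoint")

    def with_context(self, context: str) -> "ContrastSpec":
        return ContrastSpec(self.name, self.class_a, self.class_b, context, self.pooled)


#: the four published contrasts (context set at run time)
CONTRASTS: dict[str, ContrastSpec] = {
    "incongruent_combo": ContrastSpec("incongruent_combo", ("CD",), ("DC",)),
    "congruent_combo": ContrastSpec("congruent_combo", ("CC",), ("DD",)),
    "own_movement": ContrastSpec("own_movement", ("CC", "CD"), ("DC", "DD"), pooled=True),
    "partner_movement": ContrastSpec("partner_movement", ("CC", "DC"), ("CD", "DD"), pooled=True),
}


@dataclass
class Supertrial:
    """Average of ``n_avg`` same-class trials, cue-pair balanced."""

    data: np.ndarray  # (channels, times)
    class_label: str
    members: list[int]


@dataclass
class DecodingResult:
    """Per-subject decoding outcome for one contrast and context."""

    subject: object
    contrast: str
    context: str
    empirical_acc: float
    null_acc: float = np.nan
    n_permutations: int = 0
    seed: int = 0
    per_permutation: np.ndarray | None = None


def usable_trials(epochs: EpochSet, context: str) -> np.ndarray:
    """Mask of analysable trials: catch handling per the published rule.

    Correctly identified catch trials are kept; missed catch trials and
    regular trials flagged as catch (false alarms) are excluded.
    """
    lab = epochs.labels
    ok_catch = lab["is_catch"] & lab["catch_response"]
    ok_reg = ~lab["is_catch"] & ~lab["catch_response"]
    return ((lab["context"] == context) & (ok_catch | ok_reg)).to_numpy()


def _cell_indices(labels: pd.DataFrame, mask: np.ndarray, combination: str,
                  cue_pair: int) -> np.ndarray:
    sel = mask & (labels["combination"] == combination).to_numpy() \
        & (labels["cue_pair"] == cue_pair).to_numpy()
    return np.nonzero(sel)[0]


def _class_cells(
    labels: pd.DataFrame,
    mask: np.ndarray,
    conditions: Sequence[str],
    pooled: bool,
    n_super: int,
    n_avg: int,
) -> list[tuple[np.ndarray, int]]:
    """Precompute (trial indices, draws per permutation) for each cell."""
    if pooled:
        cells = [(c, q) for c in conditions for q in (1, 2)]
        per_cell = n_super  # one member per cell per supertrial
    else:
        (cond,) = conditions
        cells = [(cond, q) for q in (1, 2)]
        per_cell = n_super * (n_avg // 2)  # two members per cue pair
    out = []
    for cond, cue in cells:
        idx = _cell_indices(labels, mask, cond, cue)
        if len(idx) < per_cell:
            raise InsufficientTrialsError(
                f"cell (combination={cond}, cue_pair={cue}): have {len(idx)} "
                f"usable trials, need {per_cell}"
            )
        out.append((idx, per_cell))
    return out


def _sample_from_cells(
    cells: list[tuple[np.ndarray, int]], n_super: int, rng: np.random.Generator
) -> np.ndarray:
    """One permutation's member draw: (n_super, n_avg) trial indices."""
    cols = [
        rng.choice(idx, size=per_cell, replace=False).reshape(n_super, -1)
        for idx, per_cell in cells
    ]
    return np.concatenate(cols, axis=1)


def _sample_class_members(
    labels: pd.DataFrame,
    mask: np.ndarray,
    conditions: Sequence[str],
    pooled: bool,
    n_super: int,
    n_avg: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Member trial indices for one class: (n_super, n_avg) array."""
    cells = _class_cells(labels, mask, conditions, pooled, n_super, n_avg)
    return _sample_from_cells(cells, n_super, rng)


def make_supertrials(
    epochs: EpochSet,
    contrast: ContrastSpec,
    n_super: int = 10,
    n_avg: int = 4,
    rng: np.random.Generator | None = None,
) -> list[Supertrial]:
    """Build ``n_super`` supertrials per class for one permutation."""
    rng = rng or np.random.default_rng()
    mask = usable_trials(epochs, contrast.context)
    out: list[Supertrial] = []
    for label, conds in (("a", contrast.class_a), ("b", contrast.class_b)):
        members = _sample_class_members(
            epochs.labels, mask, conds, contrast.pooled, n_super, n_avg, rng
        )
        for row in members:
            out.append(
                Supertrial(
                    data=epochs.data[row].mean(axis=0),
                    class_label=label,
                    members=list(map(int, row)),
                )
            )
    return out


def demean(data: np.ndarray) -> np.ndarray:
    """Subtract each channel's temporal mean (last axis)."""
    return data - data.mean(axis=-1, keepdims=True)


def bin_features(
    data: np.ndarray,
    sfreq: float,
    window: tuple[float, float] = (0.0, 2.0),
    n_bins: int = 10,
) -> np.ndarray:
    """Average each channel into ``n_bins`` equal time bins; flatten.

    Bins are half-open intervals on the time axis
    ``[w0 + k*dt, w0 + (k+1)*dt)``, so at 128 Hz a 200 ms bin holds 25 or
    26 samples.  Input may be (channels, times) or (n, channels, times);
    output features are channel-major with length channels * n_bins.
    """
    single = data.ndim == 2
    if single:
        data = data[None]
    n_times = data.shape[-1]
    t = np.arange(n_times) / sfreq
    w0, w1 = window
    if w0 < -1e-12 or w1 > n_times / sfreq + 1e-12:
        raise ValueError(f"window {window} outside epoch span [0, {n_times / sfreq}]")
    dt = (w1 - w0) / n_bins
    which = np.floor((t - w0) / dt).astype(int)
    valid = (t >= w0) & (t < w1 - 1e-12)
    B = np.zeros((n_times, n_bins))
    for b in range(n_bins):
        in_bin = valid & (which == b)
        if not in_bin.any():
            raise ValueError(f"bin {b} contains no samples")
        B[in_bin, b] = 1.0 / in_bin.sum()
    feats = np.einsum("nct,tb->ncb", data, B).reshape(data.shape[0], -1)
    return feats[0] if single else feats


def stratified_folds(
    y: np.ndarray, k: int = 5, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Random stratified fold assignment: k test-index arrays.

    Each fold holds an equal share of every class (2 per class per fold
    for the default 10+10 supertrial pool).
    """
    rng = rng or np.random.default_rng()
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    folds: list[list[np.ndarray]] = [[] for _ in range(k)]
    for c in classes:
        idx = np.nonzero(y == c)[0]
        if len(idx) < k:
            raise ValueError(f"class {c!r} has fewer samples than folds")
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[f].append(chunk)
    return [np.concatenate(f) for f in folds]


def crossval_decode(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    rng: np.random.Generator | None = None,
) -> float:
    """Stratified k-fold cross-validated LDA accuracy.

    Folds are re-randomised from ``rng``; each test fold holds an equal
    number of supertrials from both classes.
    """
    y = np.asarray(y)
    accs = []
    all_idx = np.arange(len(y))
    for test in stratified_folds(y, k, rng):
        train = np.setdiff1d(all_idx, test)
        clf = ShrinkageLDA().fit(X[train], y[train])
        accs.append(clf.score(X[test], y[test]))
    return float(np.mean(accs))


def _precompute_features(
    epochs: EpochSet, window: tuple[float, float], n_bins: int
) -> np.ndarray:
    """Per-trial demeaned, binned feature rows.

    Demeaning and binning are linear, so averaging per-trial features over
    supertrial members equals binning the demeaned supertrial; this keeps
    the permutation loop out of the raw (trials x channels x times) array.
    """
    return bin_features(demean(epochs.data), epochs.sfreq, window, n_bins)


def _pipeline_accuracy(
    F: np.ndarray,
    members_a: np.ndarray,
    members_b: np.ndarray,
    k: int,
    rng: np.random.Generator,
    shuffle_labels: bool,
) -> float:
    Xa = F[members_a].mean(axis=1)
    Xb = F[members_b].mean(axis=1)
    X = np.vstack([Xa, Xb])
    y = np.array([0] * len(Xa) + [1] * len(Xb))
    if shuffle_labels:
        y = rng.permutation(y)  # preserves the 10/10 balance
    return crossval_decode(X, y, k=k, rng=rng)


def _run(
    epochs: EpochSet,
    contrast: ContrastSpec,
    n_perm: int,
    seed: int,
    subject: object,
    n_super: int,
    n_avg: int,
    k_folds: int,
    window: tuple[float, float],
    n_bins: int,
    shuffle_labels: bool,
) -> DecodingResult:
    mask = usable_trials(epochs, contrast.context)
    F = _precompute_features(epochs, window, n_bins)
    cells_a = _class_cells(epochs.labels, mask, contrast.class_a, contrast.pooled,
                           n_super, n_avg)
    cells_b = _class_cells(epochs.labels, mask, contrast.class_b, contrast.pooled,
                           n_super, n_avg)
    accs = np.empty(n_perm)
    tag = 1 if shuffle_labels else 0
    for p in range(n_perm):
        rng = np.random.default_rng(
            np.random.SeedSequence((seed, _stable_tag(contrast.name),
                                    _stable_tag(contrast.context), tag, p))
        )
        ma = _sample_from_cells(cells_a, n_super, rng)
        mb = _sample_from_cells(cells_b, n_super, rng)
        accs[p] = _pipeline_accuracy(F, ma, mb, k_folds, rng, shuffle_labels)
    return DecodingResult(
        subject=subject, contrast=contrast.name, context=contrast.context,
        empirical_acc=float("nan") if shuffle_labels else float(accs.mean()),
        null_acc=float(accs.mean()) if shuffle_labels else float("nan"),
        n_permutations=n_perm, seed=seed, per_permutation=accs,
    )


def run_contrast(
    epochs: EpochSet,
    contrast: ContrastSpec,
    n_perm: int = 100,
    seed: int = 0,
    subject: object = 0,
    n_super: int = 10,
    n_avg: int = 4,
    k_folds: int = 5,
    window: tuple[float, float] = (0.0, 2.0),
    n_bins: int = 10,
) -> DecodingResult:
    """Empirical decoding accuracy: mean over ``n_perm`` pipeline runs."""
    return _run(epochs, contrast, n_perm, seed, subject, n_super, n_avg,
                k_folds, window, n_bins, shuffle_labels=False)


def run_null(
    epochs: EpochSet,
    contrast: ContrastSpec,
    n_perm: int = 100,
    seed: int = 0,
    subject: object = 0,
    n_super: int = 10,
    n_avg: int = 4,
    k_folds: int = 5,
    window: tuple[float, float] = (0.0, 2.0),
    n_bins: int = 10,
) -> DecodingResult:
    """Null accuracy: identical pipeline with balanced label shuffling."""
    return _run(epochs, contrast, n_perm, seed, subject, n_super, n_avg,
                k_folds, window, n_bins, shuffle_labels=True)


def group_test(results: Sequence[DecodingResult]) -> dict[str, StatResult]:
    """Group statistics over subjects.

    For every (contrast, context): one-tailed paired t of empirical vs
    null accuracy (empirical > null).  For every contrast present in both
    contexts: two-tailed paired t of empirical accuracies Joint vs
    Parallel.  Requires >= 2 subjects with both values.
    """
    df = pd.DataFrame(
        [
            {
                "subject": r.subject, "contrast": r.contrast, "context": r.context,
                "empirical": r.empirical_acc, "null": r.null_acc,
            }
            for r in results
        ]
    )
    merged = (
        df.groupby(["subject", "contrast", "context"])
        .agg({"empirical": "mean", "null": "mean"})
        .reset_index()
    )
    out: dict[str, StatResult] = {}
    for (contrast, context), grp in merged.groupby(["contrast", "context"]):
        grp = grp.dropna(subset=["empirical", "null"])
        if len(grp) < 2:
            raise ValueError(f"need >= 2 subjects for {contrast}/{context}")
        res = paired_t(grp["empirical"], grp["null"], alternative="greater", bayes=True)
        res.name = f"{contrast}:{context}:empirical_gt_null"
        res.extra["mean_empirical"] = float(grp["empirical"].mean())
        res.extra["mean_null"] = float(grp["null"].mean())
        out[res.name] = res
    for contrast, grp in merged.groupby("contrast"):
        wide = grp.pivot(index="subject", columns="context", values="empirical").dropna()
        if {"Joint", "Parallel"}.issubset(wide.columns) and len(wide) >= 2:
            res = paired_t(wide["Joint"], wide["Parallel"], alternative="two-sided",
                           bayes=True)
            res.name = f"{contrast}:Joint_vs_Parallel"
            out[res.name] = res
    return out
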