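"""Channelwise decoding topographies and cluster-based permutation tests.

The spatial analysis reruns the decoding pipeline separately per channel
(features = that channel's 10 temporal bins), yielding one accuracy per
channel, subject and contrast.  Group inference thresholds per-channel
one-sample t statistics against chance, groups supra-threshold channels
into clusters connected under the Delaunay adjacency of the 2-D montage,
and compares each cluster's summed t against a max-cluster-statistic null
built from random per-subject sign flips of (accuracy - chance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats as ss
from scipy.spatial import Delaunay, QhullError

from dyaddraw.decoding import (
    ContrastSpec,
    _class_cells,
    _pipeline_accuracy,
    _precompute_features,
    _sample_from_cells,
    _stable_tag,
    usable_trials,
)
from dyaddraw.eeggen import EpochSet


@dataclass
class ChannelAccuracyMap:
    """Per-channel decoding accuracies for one subject and contrast."""

    subject: object
    contrast: str
    context: str
    acc: np.ndarray  # (n_channels,)


@dataclass
class ClusterResult:
    """Clusters of above-chance channels with permutation p-values."""

    clusters: list[list[int]]
    cluster_stat: list[float]
    p: list[float]
    n_perm: int
    t_obs: np.ndarray
    threshold: float


def channelwise_decode(
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
) -> ChannelAccuracyMap:
    """Decode with each channel's binned time course alone.

    Same supertrial/cross-validation/permutation machinery as the
    spatiotemporal pipeline; the supertrial sampling is shared across
    channels within a permutation (one sampling, 64 classifications).
    """
    mask = usable_trials(epochs, contrast.context)
    F = _precompute_features(epochs, window, n_bins)  # (trials, ch*bins)
    n_ch = epochs.data.shape[1]
    Fc = F.reshape(len(F), n_ch, n_bins)
    cells_a = _class_cells(epochs.labels, mask, contrast.class_a, contrast.pooled,
                           n_super, n_avg)
    cells_b = _class_cells(epochs.labels, mask, contrast.class_b, contrast.pooled,
                           n_super, n_avg)
    accs = np.zeros((n_perm, n_ch))
    for p in range(n_perm):
        rng = np.random.default_rng(
            np.random.SeedSequence((seed, _stable_tag(contrast.name),
                                    _stable_tag(contrast.context), 2, p))
        )
        ma = _sample_from_cells(cells_a, n_super, rng)
        mb = _sample_from_cells(cells_b, n_super, rng)
        # shared fold structure across channels within this permutation
        fold_seed = rng.integers(2**31)
        for c in range(n_ch):
            accs[p, c] = _pipeline_accuracy(
                Fc[:, c, :], ma, mb, k_folds,
                np.random.default_rng(fold_seed), shuffle_labels=False,
            )
    return ChannelAccuracyMap(
        subject=subject, contrast=contrast.name, context=contrast.context,
        acc=accs.mean(axis=0),
    )


def build_adjacency(channel_pos: np.ndarray) -> np.ndarray:
    """Channel adjacency from the Delaunay triangulation of 2-D positions.

    Returns a boolean (n, n) symmetric matrix whose edges are the
    triangulation edges.  Raises on collinear or duplicate positions.
    """
    pos = np.asarray(channel_pos, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2 or len(pos) < 3:
        raise ValueError("need >= 3 two-dimensional positions")
    if len(np.unique(pos, axis=0)) != len(pos):
        raise ValueError("duplicate channel positions")
    try:
        tri = Delaunay(pos)
    except QhullError as e:
        raise ValueError(f"degenerate (collinear?) positions: {e}") from e
    n = len(pos)
    adj = np.zeros((n, n), dtype=bool)
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            adj[a, b] = adj[b, a] = True
    return adj


def _connected_components(nodes: np.ndarray, adj: np.ndarray) -> list[list[int]]:
    """Connected components of the subgraph induced by ``nodes``."""
    nodes = list(nodes)
    node_set = set(nodes)
    seen: set[int] = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        comp = []
        stack = [start]
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.nonzero(adj[u])[0]:
                if v in node_set and v not in seen:
                    seen.add(int(v))
                    stack.append(int(v))
        comps.append(sorted(comp))
    return comps


def _clusters_and_stats(t: np.ndarray, threshold: float, adj: np.ndarray):
    supra = np.nonzero(t > threshold)[0]
    comps = _connected_components(supra, adj)
    stats = [float(t[c].sum()) for c in comps]
    return comps, stats


def cluster_permutation_test(
    maps: Sequence[ChannelAccuracyMap] | np.ndarray,
    adjacency: np.ndarray,
    chance: float = 0.5,
    threshold_p: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test of accuracy vs chance.

    Per channel, a one-sample t of (accuracy - chance) across subjects is
    thresholded at the one-sided t corresponding to ``threshold_p``
    (two-sided-equivalent critical value, applied above-chance only);
    supra-threshold channels are clustered via ``adjacency``; the cluster
    statistic is the summed t; the null is the distribution of the
    maximum cluster statistic over random per-subject sign flips.  An
    empty cluster list is a valid (null) outcome.
    """
    if isinstance(maps, np.ndarray):
        acc = maps
    else:
        acc = np.vstack([m.acc for m in maps])
    n_sub, n_ch = acc.shape
    if n_sub < 2:
        raise ValueError("need >= 2 subjects")
    if adjacency.shape != (n_ch, n_ch):
        raise ValueError("adjacency size does not match channel count")

    D = acc - chance
    threshold = float(ss.t.ppf(1 - threshold_p / 2, n_sub - 1))

    def tmap(X: np.ndarray) -> np.ndarray:
        m = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        return m / (sd / np.sqrt(n_sub))

    t_obs = tmap(D)
    clusters, stats = _clusters_and_stats(t_obs, threshold, adjacency)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_sub)
        t_p = tmap(D * signs[:, None])
        _, s_p = _clusters_and_stats(t_p, threshold, adjacency)
        null_max[i] = max(s_p) if s_p else 0.0

    pvals = [float((np.sum(null_max >= s) + 1) / (n_perm + 1)) for s in stats]
    return ClusterResult(
        clusters=clusters, cluster_stat=stats, p=pvals, n_perm=n_perm,
        t_obs=t_obs, threshold=threshold,
    )
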