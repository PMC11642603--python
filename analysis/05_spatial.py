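"""Channelwise decoding topography and cluster-based scalp inference.

For the congruent contrast in the Parallel context, decodes each channel's
binned time course separately per simulated subject, then runs the
Delaunay-adjacency cluster permutation test of accuracy vs chance.
Writes results/spatial_topography.csv (channel, mean accuracy, t, cluster
id, cluster p).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from dyaddraw.decoding import CONTRASTS
from dyaddraw.design import DesignParams, generate_design
from dyaddraw.eeggen import EEGGenParams, generate_epochs, make_condition_patterns, \
    synthetic_montage
from dyaddraw.pipeline import _subject_seed
from dyaddraw.spatial import build_adjacency, channelwise_decode, \
    cluster_permutation_test

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
N_SUB, N_CH = 10, 32
ROOT = Path(__file__).resolve().parents[1] / "results"
ROOT.mkdir(exist_ok=True)

cs = CONTRASTS["congruent_combo"].with_context("Parallel")
maps = []
for s in range(N_SUB):
    design = generate_design(DesignParams(seed=_subject_seed(SEED, s, "design")))
    patterns = make_condition_patterns(
        "integrated", N_CH, 256, seed=_subject_seed(SEED, s, "patterns")
    )
    epochs = generate_epochs(
        design, EEGGenParams(n_channels=N_CH, condition_patterns=patterns,
                             seed=_subject_seed(SEED, s, "eeg")),
    )
    maps.append(channelwise_decode(epochs, cs, n_perm=5,
                                   seed=_subject_seed(SEED, s, "spatial"), subject=s))

names, pos = synthetic_montage(N_CH)
adj = build_adjacency(pos)
res = cluster_permutation_test(maps, adj, n_perm=1000, seed=SEED)

acc = np.vstack([m.acc for m in maps])
cluster_id = np.full(N_CH, -1)
cluster_p = np.full(N_CH, np.nan)
for i, (cl, p) in enumerate(zip(res.clusters, res.p)):
    cluster_id[cl] = i
    cluster_p[cl] = p

df = pd.DataFrame({
    "channel": names, "mean_acc": acc.mean(axis=0), "t": res.t_obs,
    "cluster_id": cluster_id, "cluster_p": cluster_p,
})
df.to_csv(ROOT / "spatial_topography.csv", index=False)

print(f"channelwise decoding of {cs.name} ({cs.context}); "
      f"{len(res.clusters)} cluster(s) at threshold t={res.threshold:.2f}")
for i, (cl, st, p) in enumerate(zip(res.clusters, res.cluster_stat, res.p)):
    print(f"  cluster {i}: {len(cl)} channels, summed t={st:.1f}, p={p:.3f}")
print(f"-> {ROOT / 'spatial_topography.csv'}")
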