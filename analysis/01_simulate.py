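"""Simulate one synthetic participant: design, pen trajectories, epoched EEG.

Writes design.csv, trajectories.csv and epochs.h5 under results/sim/.
The design reproduces the task structure (2 contexts x 6 blocks x 48
trials, 8 catch per block); the EEG uses the "integrated" preset in which
the two incongruent shape combinations share one mean pattern in the
Joint context.
"""

import sys
from pathlib import Path

from dyaddraw.design import DesignParams, design_counts, generate_design
from dyaddraw.eeggen import EEGGenParams, generate_epochs, make_condition_patterns
from dyaddraw.io import write_design_csv, write_epochs_h5, write_trajectories_csv
from dyaddraw.trajgen import TrajectoryEffects, generate_trajectories

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT.mkdir(parents=True, exist_ok=True)

design = generate_design(DesignParams(seed=SEED))
counts = design_counts(design)
print(f"design: {counts['total']} trials; "
      f"non-catch per cell: {sorted(set(counts['noncatch_per_cell'].values()))}; "
      f"catch per block: {sorted(set(counts['catch_per_block'].values()))}")
write_design_csv(design, OUT / "design.csv")

trajs = generate_trajectories(design, TrajectoryEffects(seed=SEED))
write_trajectories_csv(trajs, OUT / "trajectories.csv")
print(f"trajectories: {len(trajs)} drawn at 30 Hz")

patterns = make_condition_patterns("integrated", 64, 256, seed=SEED)
epochs = generate_epochs(design, EEGGenParams(condition_patterns=patterns, seed=SEED))
write_epochs_h5(epochs, OUT / "epochs.h5")
print(f"epochs: {epochs.data.shape} at {epochs.sfreq} Hz -> {OUT}")
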