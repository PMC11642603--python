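"""Score the simulated pen trajectories: screening, templates, distortion.

Reads results/sim/ from 01_simulate.py, runs the trajectory pipeline
(spline resampling to 100 points, gross-error and swap-error screening,
per-participant shape templates, area-to-template distortion) and writes
results/distortion_records.csv plus a cell-mean summary.
"""

from pathlib import Path

from dyaddraw.io import read_design_csv, read_trajectories_csv
from dyaddraw.pipeline import score_trajectories

ROOT = Path(__file__).resolve().parents[1] / "results"
design = read_design_csv(ROOT / "sim" / "design.csv")
trajs = read_trajectories_csv(ROOT / "sim" / "trajectories.csv")

records = score_trajectories(design, trajs, subject=0)
records.to_csv(ROOT / "distortion_records.csv", index=False)

n = len(records)
print(f"scored {n} non-catch trials: "
      f"{records['gross_error'].sum()} gross errors, "
      f"{records['swap_error'].sum()} swap errors, "
      f"{records['retained'].sum()} retained")
cell_means = records[records.retained].groupby(["context", "congruency"])["area"].mean()
print("mean distortion (px^2) by cell:")
print(cell_means.to_string())
cell_means.to_csv(ROOT / "distortion_cell_means.csv")
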