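"""End-to-end orchestration of the synthetic study.

``run_study`` executes simulate -> trajectory scoring -> behavioural
statistics -> the four decoding contrasts in both social contexts ->
spatial decoding -> group inference, and returns a single report bundle
(JSON-serialisable dict) carrying every numeric output together with the
master seed and a config digest.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from dyaddraw import decoding, spatial, stats, trajectory
from dyaddraw.design import DesignParams, TrialRecord, generate_design
from dyaddraw.eeggen import EEGGenParams, generate_epochs, make_condition_patterns
from dyaddraw.trajgen import TrajectoryEffects, generate_trajectories


@dataclass
class RunConfig:
    """Configuration of one synthetic study run.

    Defaults mirror the published task parameters (6 blocks of 48 trials
    with 8 catch trials per block and context, 10 supertrials of 4 trials,
    10 bins of 200 ms, 5 folds, 100 permutations); ``n_subjects``,
    ``n_channels`` and ``n_perm`` are the scale knobs.
    """

    n_subjects: int = 20
    design: DesignParams = field(default_factory=DesignParams)
    trajectory_effects: TrajectoryEffects = field(default_factory=TrajectoryEffects)
    eeg_preset: str = "integrated"
    eeg_amp: float = 1.5
    eeg_noise_sd: float = 1.0
    eeg_spatial_corr: float = 0.3
    n_channels: int = 64
    sfreq: float = 128.0
    epoch_length: float = 2.0
    n_super: int = 10
    n_avg: int = 4
    n_bins: int = 10
    window: tuple[float, float] = (0.0, 2.0)
    k_folds: int = 5
    n_perm: int = 100
    alpha: float = 0.05
    spatial_contrasts: tuple[str, ...] = ()
    spatial_n_perm: int = 1000
    master_seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in asdict(self).items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _subject_seed(master: int, subject: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{subject}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def score_trajectories(
    design: Sequence[TrialRecord],
    trajs,
    subject: object = 0,
    length: float | None = None,
) -> pd.DataFrame:
    """Full single-participant trajectory pipeline -> distortion records.

    Resamples non-catch complete trajectories, screens gross errors,
    flags swap errors via the spline classifier, builds the participant's
    circle/diamond templates from retained trials, and computes the
    area-to-template distortion for every retained trial.  Returns a tidy
    DataFrame (one row per trial with retention flags; retained trials
    carry the ``area`` score).
    """
    by_id = {t.trial_id: t for t in design}
    rows = []
    resampled = {}
    for traj in trajs:
        trial = by_id.get(traj.trial_id)
        if trial is None or trial.is_catch:
            continue
        try:
            rs = trajectory.resample_trajectory(traj)
        except trajectory.DegenerateTrajectoryError:
            rows.append(_row(subject, trial, gross=True))
            continue
        resampled[traj.trial_id] = (traj, rs, trial)

    kwargs = {} if length is None else {"length": length}
    gross_flags = trajectory.screen_gross_errors(
        [(traj, trial.own_shape) for traj, _, trial in resampled.values()], **kwargs
    )
    kept = {}
    for (tid, (traj, rs, trial)), g in zip(resampled.items(), gross_flags):
        if g:
            rows.append(_row(subject, trial, gross=True))
        else:
            kept[tid] = (rs, trial)

    swap_flags = trajectory.detect_swap_errors(
        [(rs, trial.own_shape) for rs, trial in kept.values()]
    )
    retained = {}
    for (tid, (rs, trial)), s in zip(kept.items(), swap_flags):
        if s:
            rows.append(_row(subject, trial, swap=True))
        else:
            retained[tid] = (rs, trial)

    templates = trajectory.compute_templates(
        [rs for rs, _ in retained.values()],
        [trial.own_shape for _, trial in retained.values()],
    )
    for tid, (rs, trial) in retained.items():
        area = trajectory.area_to_template(rs, templates[trial.own_shape])
        rows.append(_row(subject, trial, area=area))
    return pd.DataFrame(rows)


def _row(subject, trial: TrialRecord, area=np.nan, gross=False, swap=False) -> dict:
    return {
        "subject": subject,
        "trial_id": trial.trial_id,
        "context": trial.context,
        "congruency": trial.congruency,
        "combination": trial.combination,
        "drawing_time": trial.drawing_duration,
        "area": area,
        "gross_error": gross,
        "swap_error": swap,
        "retained": not (gross or swap),
    }


def vmi_analysis(records: pd.DataFrame) -> dict:
    """Box-Cox transform, mixed model and directional congruency test."""
    retained = records[records["retained"]].copy()
    bc = trajectory.boxcox(retained["area"].to_numpy())
    retained["area_boxcox"] = bc["transformed"]
    spec = stats.ModelSpec(response="area_boxcox", fixed=["context", "congruency"],
                           random="subject")
    lmm = stats.fit_lmm(retained, spec)
    effects, ce = stats.congruency_effect(retained)
    return {
        "boxcox_lambda": bc["lambda"],
        "boxcox_skewness": bc["skewness"],
        "boxcox_kurtosis": bc["kurtosis"],
        "lmm": {k: v.to_dict() for k, v in lmm.items()},
        "congruency_effect": ce.to_dict(),
        "per_subject_effects": effects,
        "records": retained,
    }


def behavioral_stats(designs: dict[object, Sequence[TrialRecord]]) -> dict:
    """Compliance statistics across subjects.

    Catch accuracy Joint vs Parallel (Wilcoxon signed-rank), Joint delta
    time vs 0 and Parallel drawing time vs the instructed 2 s (one-sample
    t-tests).
    """
    rows = []
    for subject, trials in designs.items():
        df = pd.DataFrame(
            [
                {
                    "context": t.context, "is_catch": t.is_catch,
                    "catch_response": t.catch_response, "delta_time": t.delta_time,
                    "drawing_duration": t.drawing_duration,
                }
                for t in trials
            ]
        )
        row = {"subject": subject}
        for cx in ("Joint", "Parallel"):
            sub = df[df["context"] == cx]
            catch = sub[sub["is_catch"]]
            row[f"catch_acc_{cx}"] = catch["catch_response"].mean()
        row["delta_joint"] = df.loc[df["context"] == "Joint", "delta_time"].mean()
        row["duration_parallel"] = df.loc[
            df["context"] == "Parallel", "drawing_duration"
        ].mean()
        rows.append(row)
    tab = pd.DataFrame(rows)
    return {
        "catch_accuracy": stats.wilcoxon_signed_rank(
            tab["catch_acc_Joint"], tab["catch_acc_Parallel"]
        ).to_dict(),
        "delta_time_joint": stats.one_sample_t(tab["delta_joint"], 0.0).to_dict(),
        "drawing_time_parallel": stats.one_sample_t(
            tab["duration_parallel"], 2.0
        ).to_dict(),
        "table": tab,
    }


def run_study(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full synthetic study; return the report bundle."""
    t0 = time.time()
    report: dict = {
        "master_seed": config.master_seed,
        "config_digest": config.digest(),
        "stages": {},
    }

    def stage(name):
        report["stages"][name] = {"t": round(time.time() - t0, 2)}

    # --- simulate designs and trajectories -------------------------------
    designs = {}
    all_records = []
    for s in range(config.n_subjects):
        dp = DesignParams(**{**asdict(config.design),
                             "seed": _subject_seed(config.master_seed, s, "design")})
        trials = generate_design(dp)
        designs[s] = trials
        eff = TrajectoryEffects(**{**_effects_dict(config.trajectory_effects),
                                   "seed": _subject_seed(config.master_seed, s, "traj")})
        trajs = generate_trajectories(trials, eff)
        all_records.append(score_trajectories(trials, trajs, subject=s,
                                              length=eff.length))
    stage("simulate")

    records = pd.concat(all_records, ignore_index=True)
    report["behavior"] = _drop_tables(behavioral_stats(designs))
    vmi = vmi_analysis(records)
    report["vmi"] = {k: v for k, v in vmi.items()
                     if k not in ("per_subject_effects", "records")}
    report["trajectory_counts"] = {
        "n_trials_scored": int(len(records)),
        "n_retained": int(records["retained"].sum()),
        "n_gross": int(records["gross_error"].sum()),
        "n_swap": int(records["swap_error"].sum()),
    }
    stage("trajectories")

    # --- decoding ---------------------------------------------------------
    n_times = int(round(config.epoch_length * config.sfreq))
    results = []
    for s in range(config.n_subjects):
        patterns = make_condition_patterns(
            config.eeg_preset, config.n_channels, n_times, amp=config.eeg_amp,
            seed=_subject_seed(config.master_seed, s, "patterns"),
        )
        ep = EEGGenParams(
            n_channels=config.n_channels, sfreq=config.sfreq,
            epoch_length=config.epoch_length, condition_patterns=patterns,
            noise_sd=config.eeg_noise_sd, spatial_corr=config.eeg_spatial_corr,
            seed=_subject_seed(config.master_seed, s, "eeg"),
        )
        epochs = generate_epochs(designs[s], ep)
        dec_seed = _subject_seed(config.master_seed, s, "decode")
        for cname, spec in decoding.CONTRASTS.items():
            for cx in ("Joint", "Parallel"):
                cs = spec.with_context(cx)
                kw = dict(n_perm=config.n_perm, seed=dec_seed, subject=s,
                          n_super=config.n_super, n_avg=config.n_avg,
                          k_folds=config.k_folds, window=config.window,
                          n_bins=config.n_bins)
                emp = decoding.run_contrast(epochs, cs, **kw)
                nul = decoding.run_null(epochs, cs, **kw)
                emp.null_acc = nul.null_acc
                results.append(emp)
    group = decoding.group_test(results)
    report["decoding"] = {k: v.to_dict() for k, v in group.items()}
    report["decoding_table"] = [
        {"subject": r.subject, "contrast": r.contrast, "context": r.context,
         "empirical_acc": r.empirical_acc, "null_acc": r.null_acc,
         "seed": r.seed}
        for r in results
    ]
    stage("decoding")

    # --- spatial decoding -------------------------------------------------
    if config.spatial_contrasts:
        from dyaddraw.eeggen import synthetic_montage

        _, pos = synthetic_montage(config.n_channels)
        adj = spatial.build_adjacency(pos)
        report["spatial"] = {}
        for item in config.spatial_contrasts:
            cname, cx = item.split(":")
            cs = decoding.CONTRASTS[cname].with_context(cx)
            maps = []
            for s in range(config.n_subjects):
                patterns = make_condition_patterns(
                    config.eeg_preset, config.n_channels, n_times,
                    amp=config.eeg_amp,
                    seed=_subject_seed(config.master_seed, s, "patterns"),
                )
                ep = EEGGenParams(
                    n_channels=config.n_channels, sfreq=config.sfreq,
                    epoch_length=config.epoch_length, condition_patterns=patterns,
                    noise_sd=config.eeg_noise_sd,
                    spatial_corr=config.eeg_spatial_corr,
                    seed=_subject_seed(config.master_seed, s, "eeg"),
                )
                epochs = generate_epochs(designs[s], ep)
                maps.append(
                    spatial.channelwise_decode(
                        epochs, cs, n_perm=max(1, config.n_perm // 5),
                        seed=_subject_seed(config.master_seed, s, "spatial"),
                        subject=s, n_super=config.n_super, n_avg=config.n_avg,
                        k_folds=config.k_folds, window=config.window,
                        n_bins=config.n_bins,
                    )
                )
            cres = spatial.cluster_permutation_test(
                maps, adj, n_perm=config.spatial_n_perm,
                seed=_subject_seed(config.master_seed, 0, f"cluster:{item}"),
            )
            report["spatial"][item] = {
                "clusters": cres.clusters,
                "cluster_stat": cres.cluster_stat,
                "p": cres.p,
                "mean_acc": np.vstack([m.acc for m in maps]).mean(axis=0).tolist(),
            }
        stage("spatial")

    report["runtime_s"] = round(time.time() - t0, 2)

    if out_dir is not None:
        from dyaddraw.io import write_json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json(report, out / "report.json")
        records.to_csv(out / "distortion_records.csv", index=False)
        pd.DataFrame(report["decoding_table"]).to_csv(
            out / "decoding_results.csv", index=False
        )
    return report


def _effects_dict(eff: TrajectoryEffects) -> dict:
    d = asdict(eff)
    d["vmi_shift"] = dict(eff.vmi_shift)
    return d


def _drop_tables(d: dict) -> dict:
    return {k: v for k, v in d.items() if not isinstance(v, pd.DataFrame)}
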