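"""Dataset readers/writers and the end-to-end pipeline driver.

On disk, a dataset bundle is one directory per mouse containing
``trials.csv`` (the trial table), ``streams.h5`` (HDF5, one group per
session holding lick times, encoder trace, keypoints and the per-trial
LFP/raw epoch stacks) and ``truth.json`` (generator ground truth).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Dict, Optional

import h5py
import numpy as np
import pandas as pd

from . import config as cfg
from . import features as feat
from . import labeling, laminar, prediction, progression
from .synth import (MouseConfig, MouseData, SessionStreams, SyntheticTruth,
                    default_mouse_configs, gen_dataset)

SCHEMA_VERSION = 1
TRIAL_COLUMNS = ["day", "trial", "trial_type", "outcome", "punished",
                 "t_start", "t_onset", "duration", "latent_state"]
_STREAM_KEYS = ["lick_times", "encoder_voltage", "frame_times",
                "pupil_points", "eyelid_points", "lfp_epochs", "raw_epochs"]


def write_bundle(dataset: Dict[str, MouseData], path: str | Path) -> Path:
    """Write a generated dataset bundle (CSV + HDF5 + JSON sidecar)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for mouse_id, md in dataset.items():
        mdir = path / mouse_id
        mdir.mkdir(exist_ok=True)
        md.trials.to_csv(mdir / "trials.csv", index=False)
        (mdir / "truth.json").write_text(md.truth.to_json())
        with h5py.File(mdir / "streams.h5", "w", track_order=True) as h5:
            h5.attrs["schema_version"] = SCHEMA_VERSION
            for day, st in md.streams.items():
                g = h5.create_group(f"session_{day:03d}")
                for key in _STREAM_KEYS:
                    g.create_dataset(key, data=getattr(st, key),
                                     track_times=False)
                g.create_dataset("channel_depths_mm",
                                 data=st.channel_depths_mm,
                                 track_times=False)
                g.attrs["encoder_rate"] = st.encoder_rate
                g.attrs["lfp_rate"] = st.lfp_rate
                g.attrs["raw_rate"] = st.raw_rate
                g.attrs["epoch_window"] = st.epoch_window
    return path


def read_bundle(path: str | Path) -> Dict[str, MouseData]:
    """Read a dataset bundle; round-trips ``write_bundle`` losslessly.

    Unknown trial-table columns are tolerated with a warning; missing
    HDF5 datasets raise a schema error naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: Dict[str, MouseData] = {}
    for mdir in sorted(p for p in path.iterdir() if p.is_dir()):
        trials = pd.read_csv(mdir / "trials.csv")
        extra = set(trials.columns) - set(TRIAL_COLUMNS)
        if extra:
            warnings.warn(f"{mdir.name}: ignoring unknown trial columns "
                          f"{sorted(extra)}")
            trials = trials[[c for c in TRIAL_COLUMNS if c in trials.columns]]
        missing_cols = set(TRIAL_COLUMNS) - set(trials.columns)
        if missing_cols:
            raise ValueError(f"{mdir.name}/trials.csv missing columns: "
                             f"{sorted(missing_cols)}")
        truth_raw = json.loads((mdir / "truth.json").read_text())
        truth = SyntheticTruth(**truth_raw)
        streams: Dict[int, SessionStreams] = {}
        with h5py.File(mdir / "streams.h5", "r") as h5:
            for name in h5:
                g = h5[name]
                day = int(name.split("_")[1])
                kwargs = {}
                for key in _STREAM_KEYS:
                    if key not in g:
                        raise ValueError(
                            f"{mdir.name}/streams.h5:{name} missing dataset "
                            f"'{key}'")
                    kwargs[key] = g[key][...]
                streams[day] = SessionStreams(
                    **kwargs,
                    encoder_rate=float(g.attrs["encoder_rate"]),
                    lfp_rate=float(g.attrs["lfp_rate"]),
                    raw_rate=float(g.attrs["raw_rate"]),
                    epoch_window=tuple(g.attrs["epoch_window"]),
                    channel_depths_mm=g["channel_depths_mm"][...])
        out[mdir.name] = MouseData(config=MouseConfig(mouse_id=mdir.name),
                                   trials=trials, streams=streams,
                                   truth=truth)
    if not out:
        raise ValueError(f"no mouse directories found under {path}")
    return out


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def extract_features(dataset: Dict[str, MouseData]) -> pd.DataFrame:
    """Trial feature table for every mouse/session in a bundle."""
    frames = []
    for mouse_id, md in dataset.items():
        for day in sorted(md.streams):
            m = (md.trials["day"] == day)
            frames.append(feat.build_feature_table(
                md.trials[m], md.streams[day], mouse_id))
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: Optional[cfg.PipelineConfig] = None) -> Path:
    """simulate → features → label-states → predict-states → peristimulus
    → laminar, with a machine-readable manifest of every output.

    Stage failures abort with the stage name and a reproduction hint.
    """
    config = config or cfg.PipelineConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    stage = "simulate"
    try:
        from .synth import ProbeConfig
        span = (config.probe_channels - 1) * cfg.CHANNEL_SPACING_MM
        landmark = min(cfg.LANDMARK_DEPTH_MM, 0.75 * span)
        configs = default_mouse_configs(
            config.n_mice, config.seed, n_sessions=config.n_sessions,
            trials_per_session=config.trials_per_session,
            probe=ProbeConfig(n_channels=config.probe_channels),
            landmark_depth_mm=landmark,
            dipole_depth_mm=min(0.28, 0.35 * span))
        dataset = gen_dataset(configs)
        if landmark != cfg.LANDMARK_DEPTH_MM:
            manifest["landmark_depth_mm"] = landmark
        manifest["stages"][stage] = {
            "mice": list(dataset),
            "trials": int(sum(len(d.trials) for d in dataset.values()))}

        stage = "features"
        table = extract_features(dataset)
        table.to_csv(out / "features.csv", index=False)
        summaries, trends = feat.session_summaries(table,
                                                   window=config.smooth_window)
        summaries.to_csv(out / "session_summaries.csv", index=False)
        trends.to_csv(out / "session_trends.csv", index=False)
        if config.n_sessions < 2:
            manifest["stages"]["features"] = {"trend_tests": "skipped"}
        else:
            manifest["stages"]["features"] = {"rows": len(table)}

        stage = "label-states"
        labels = labeling.label_states(table, config.smooth_window,
                                       config.hist_bins,
                                       config.good_quantile)
        labels.labels.to_csv(out / "labels.csv", index=False)
        manifest["stages"][stage] = {
            "lick_cutoffs": labels.lick_cutoffs,
            "correctness_cutoffs": labels.correctness_cutoffs,
            "conflicts": labels.conflicts}

        stage = "predict-states"
        smoothed = feat.smooth_per_session(
            table, list(cfg.NONPERFORMANCE_VARS), config.smooth_window)
        auc_rows = []
        fit_rows = {}
        for mouse_id in dataset:
            msk = (table["mouse"] == mouse_id).to_numpy()
            X = smoothed[msk].reset_index(drop=True)
            y = labels.labels.loc[msk, "state"].to_numpy()
            auc_table, fits = prediction.auc_vs_pool_size(
                X, y, n_iterations=config.n_iterations,
                seed=config.seed, n_trees=config.n_trees)
            auc_table["mouse"] = mouse_id
            auc_rows.append(auc_table)
            fit_rows[mouse_id] = {
                s: dataclasses.asdict(f) for s, f in fits.items()}
        pd.concat(auc_rows, ignore_index=True).to_csv(
            out / "auc_by_pool_size.csv", index=False)
        (out / "asymptotic_fits.json").write_text(
            json.dumps(fit_rows, indent=1, default=float))
        manifest["stages"][stage] = {"iterations": config.n_iterations}

        stage = "peristimulus"
        anova_rows = []
        for mouse_id, md in dataset.items():
            msk = (labels.labels["mouse"] == mouse_id).to_numpy()
            res = progression.progression_analysis(
                md.streams, md.trials,
                labels.labels.loc[msk, "state"].to_numpy(),
                n_blocks=config.n_blocks)
            for var, sub in res.items():
                for key, (profile, anova) in sub.items():
                    if anova is None:
                        continue
                    for _, r in anova.table.iterrows():
                        anova_rows.append({
                            "mouse": mouse_id, "variable": var,
                            "state": key[0], "outcome": key[1], **r})
        pd.DataFrame(anova_rows).to_csv(out / "peristim_anova.csv",
                                        index=False)
        manifest["stages"][stage] = {"tables": len(anova_rows)}

        stage = "laminar"
        lam_rows = []
        stages_per_block = progression.block_stages(config.n_blocks)
        for mouse_id, md in dataset.items():
            msk = (labels.labels["mouse"] == mouse_id).to_numpy()
            states = labels.labels.loc[msk, "state"].to_numpy()
            retained, _ = progression.sort_subcategories(
                states, md.trials["outcome"].to_numpy())
            epochs = np.concatenate(
                [md.streams[d].raw_epochs for d in sorted(md.streams)])
            st0 = md.streams[sorted(md.streams)[0]]
            for key, idx in retained.items():
                if idx.size < 3:
                    continue
                blocks = progression.progression_blocks(idx, config.n_blocks)
                prof = laminar.block_profiles_from_epochs(
                    epochs, st0.raw_rate, st0.epoch_window[0],
                    st0.channel_depths_mm, blocks, metric="MUA")
                okb = ~np.isnan(prof).any(axis=1)
                counts = pd.Series(stages_per_block[okb]).value_counts()
                if len(counts) >= 2 and counts.min() >= 2:
                    res = laminar.laminar_stage_anova(
                        prof[okb], stages_per_block[okb], posthoc=False)
                    for _, r in res.table.iterrows():
                        lam_rows.append({"mouse": mouse_id, "metric": "MUA",
                                         "state": key[0], "outcome": key[1],
                                         **r})
        pd.DataFrame(lam_rows).to_csv(out / "laminar_anova.csv", index=False)
        manifest["stages"][stage] = {"tables": len(lam_rows)}
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage '{stage}' "
            f"(reproduce with motistate run-all --seed {config.seed}): {exc}"
        ) from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return out
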