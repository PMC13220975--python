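"""Normalized training-progression analysis of peristimulus motor activity.

Trials are sorted into eight state × outcome subcategories (unattended
persistent trials and attended disengaged trials are excluded), each
subcategory is mapped chronologically onto a common 99-block progression
axis, blocks are grouped into early/mid/late stages (33 blocks each),
and peristimulus traces (lick rate, wheel speed, pupil diameter, eyelid
aperture on an 80-bin axis over [−1, +4] s) are averaged per block and
compared across stages with a split-plot two-way ANOVA (stage between
trial blocks, peristimulus bins as repeated measures) plus
Tukey-protected per-bin stage comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import config as cfg
from .features import wheel_speed, octagon_aperture
from .synth import SessionStreams

#: (state, outcome) combinations retained for the progression analysis
RETAINED_SUBCATEGORIES = (
    ("persistent", "hit"), ("persistent", "false_alarm"),
    ("attentive", "hit"), ("attentive", "false_alarm"),
    ("attentive", "correct_rejection"), ("attentive", "miss"),
    ("disengaged", "correct_rejection"), ("disengaged", "miss"),
)

PERISTIM_VARIABLES = ("lick_rate", "wheel_speed", "pupil_diameter",
                      "eyelid_aperture")
SD_FLOOR_FRAC = 1e-6


# ---------------------------------------------------------------------------
# subcategories and progression blocks
# ---------------------------------------------------------------------------

def sort_subcategories(states: Sequence, outcomes: Sequence) -> tuple[
        Dict[tuple, np.ndarray], Dict[tuple, int]]:
    """Chronological trial indices per retained (state, outcome) key,
    plus the counts of dropped (excluded-combination) trials."""
    st = np.asarray(states, dtype=object)
    oc = np.asarray(outcomes, dtype=object)
    retained = {key: np.where((st == key[0]) & (oc == key[1]))[0]
                for key in RETAINED_SUBCATEGORIES}
    dropped = {}
    for s in cfg.STATES:
        for o in cfg.OUTCOMES:
            if (s, o) not in retained:
                n = int(np.sum((st == s) & (oc == o)))
                if n:
                    dropped[(s, o)] = n
    return retained, dropped


def progression_blocks(trial_indices: Sequence[int],
                       n_blocks: int = cfg.N_BLOCKS) -> List[np.ndarray]:
    """Split a subcategory chronologically into ``n_blocks`` contiguous
    blocks, as equal as possible (remainder spread over the earliest
    blocks).  Subcategories smaller than ``n_blocks`` yield empty blocks,
    flagged with a warning."""
    idx = np.asarray(trial_indices)
    if idx.size == 0:
        raise ValueError("subcategory is empty")
    if idx.size < n_blocks:
        warnings.warn(f"only {idx.size} trials for {n_blocks} blocks; "
                      "some blocks will be empty")
    return np.array_split(idx, n_blocks)


def block_stages(n_blocks: int = cfg.N_BLOCKS,
                 n_stages: int = len(cfg.STAGES)) -> np.ndarray:
    """Stage label per block: early / mid / late thirds."""
    per = n_blocks // n_stages
    return np.array([cfg.STAGES[min(i // per, n_stages - 1)]
                     for i in range(n_blocks)], dtype=object)


# ---------------------------------------------------------------------------
# peristimulus traces
# ---------------------------------------------------------------------------

def peristim_axis(window: tuple = cfg.PERISTIM_WINDOW,
                  n_bins: int = cfg.PERISTIM_BINS) -> np.ndarray:
    """Bin centers over the peristimulus window."""
    edges = np.linspace(window[0], window[1], n_bins + 1)
    return (edges[:-1] + edges[1:]) / 2.0


def trial_traces(streams: SessionStreams, trials: pd.DataFrame,
                 variable: str, window: tuple = cfg.PERISTIM_WINDOW,
                 n_bins: int = cfg.PERISTIM_BINS) -> np.ndarray:
    """Per-trial peristimulus traces on the common bin grid.

    Lick rates are raw binned rates; wheel speed is mean-subtracted by
    its own prestimulus mean; pupil/eyelid traces are z-scored by their
    prestimulus mean and SD (SD floored at 1e-6 of the trace range)."""
    onsets = trials["t_onset"].to_numpy()
    edges = np.linspace(window[0], window[1], n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    width = edges[1] - edges[0]
    out = np.empty((len(trials), n_bins))
    if variable == "lick_rate":
        lt = np.sort(streams.lick_times)
        for i, t0 in enumerate(onsets):
            counts, _ = np.histogram(lt - t0, bins=edges)
            out[i] = counts / width
        return out
    if variable == "wheel_speed":
        speed = wheel_speed(streams.encoder_voltage, streams.encoder_rate)
        tt = np.arange(speed.size) / streams.encoder_rate
        for i, t0 in enumerate(onsets):
            tr = np.interp(t0 + centers, tt, speed)
            out[i] = tr - tr[centers < 0].mean()
        return out
    if variable in ("pupil_diameter", "eyelid_aperture"):
        pts = (streams.pupil_points if variable == "pupil_diameter"
               else streams.eyelid_points)
        ap = octagon_aperture(pts)
        tt = streams.frame_times
        for i, t0 in enumerate(onsets):
            tr = np.interp(t0 + centers, tt, ap)
            pre = tr[centers < 0]
            sd = max(pre.std(), SD_FLOOR_FRAC * max(np.ptp(tr), 1.0))
            out[i] = (tr - pre.mean()) / sd
        return out
    raise ValueError(f"unknown peristimulus variable: {variable}")


@dataclass
class PeristimProfile:
    variable: str
    time: np.ndarray                       # bin centers, s
    block_curves: np.ndarray               # (n_blocks, n_bins)
    stages: np.ndarray                     # stage per block
    stage_mean: Dict[str, np.ndarray]
    stage_sem: Dict[str, np.ndarray]
    normalization: str


def peristim_average(traces: np.ndarray, blocks: List[np.ndarray],
                     variable: str,
                     window: tuple = cfg.PERISTIM_WINDOW) -> PeristimProfile:
    """Block-averaged peristimulus curves with per-stage mean ± SEM."""
    n_bins = traces.shape[1]
    curves = np.full((len(blocks), n_bins), np.nan)
    for b, idx in enumerate(blocks):
        if len(idx):
            curves[b] = traces[idx].mean(axis=0)
    stages = block_stages(len(blocks))
    mean, sem = {}, {}
    for s in cfg.STAGES:
        rows = curves[stages == s]
        rows = rows[~np.isnan(rows).any(axis=1)]
        mean[s] = rows.mean(axis=0) if len(rows) else np.full(n_bins, np.nan)
        sem[s] = (rows.std(axis=0, ddof=1) / np.sqrt(len(rows))
                  if len(rows) > 1 else np.full(n_bins, np.nan))
    norm = {"lick_rate": "raw", "wheel_speed": "mean_subtracted"}.get(
        variable, "z_scored")
    return PeristimProfile(variable, peristim_axis(window, n_bins),
                           curves, stages, mean, sem, norm)


# ---------------------------------------------------------------------------
# split-plot ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Two-way mixed ANOVA: stage between units, repeated measures within."""

    table: pd.DataFrame                  # effect, df1, df2, F, p
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def stage_anova(values: np.ndarray, stages: Sequence,
                posthoc_alpha: float = 0.05,
                repeated_name: str = "bin",
                posthoc: bool = True) -> AnovaResult:
    """Split-plot two-way ANOVA on a units × repeated-measures matrix.

    Units (trial blocks, pooled across mice) are nested in training
    stage (between factor); the repeated-measures axis is peristimulus
    time bins or laminar depth channels.  Units with missing cells are
    dropped.  Tukey HSD compares stages at every repeated-measure
    position (early-vs-mid and early-vs-late flags at ``posthoc_alpha``).
    """
    X = np.asarray(values, dtype=float)
    grp = np.asarray(stages, dtype=object)
    ok = ~np.isnan(X).any(axis=1)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} units with missing cells")
        X, grp = X[ok], grp[ok]
    levels = [s for s in cfg.STAGES if s in set(grp)]
    if len(levels) < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 stages and >= 2 repeated measures")
    counts = {s: int(np.sum(grp == s)) for s in levels}
    if min(counts.values()) < 2:
        raise ValueError("need >= 2 units per stage")

    n_units, n_bins = X.shape
    s = len(levels)
    grand = X.mean()
    unit_means = X.mean(axis=1)
    bin_means = X.mean(axis=0)
    ss_total_between = n_bins * np.sum((unit_means - grand) ** 2)
    ss_stage = 0.0
    cell_resid_sq = 0.0
    for lev in levels:
        sub = X[grp == lev]
        ss_stage += n_bins * len(sub) * (sub.mean() - grand) ** 2
        cell = sub.mean(axis=0)
        cell_resid_sq += len(sub) * np.sum(
            (cell - sub.mean() - bin_means + grand) ** 2)
    ss_subj = ss_total_between - ss_stage
    ss_within = np.sum((X - unit_means[:, None]) ** 2)
    ss_bins = n_units * np.sum((bin_means - grand) ** 2)
    ss_inter = cell_resid_sq
    ss_err = ss_within - ss_bins - ss_inter

    df_stage, df_subj = s - 1, n_units - s
    df_bins = n_bins - 1
    df_inter = (s - 1) * (n_bins - 1)
    df_err = (n_units - s) * (n_bins - 1)
    ms = lambda ss, df: ss / df if df > 0 else np.nan
    f_stage = ms(ss_stage, df_stage) / ms(ss_subj, df_subj)
    f_bins = ms(ss_bins, df_bins) / ms(ss_err, df_err)
    f_inter = ms(ss_inter, df_inter) / ms(ss_err, df_err)
    table = pd.DataFrame([
        {"effect": "stage", "df1": df_stage, "df2": df_subj,
         "F": float(f_stage), "p": float(stats.f.sf(f_stage, df_stage,
                                                    df_subj))},
        {"effect": repeated_name, "df1": df_bins, "df2": df_err,
         "F": float(f_bins), "p": float(stats.f.sf(f_bins, df_bins, df_err))},
        {"effect": "interaction", "df1": df_inter, "df2": df_err,
         "F": float(f_inter), "p": float(stats.f.sf(f_inter, df_inter,
                                                    df_err))},
    ])

    post_rows = []
    if posthoc and len(levels) >= 2:
        for j in range(n_bins):
            groups = [X[grp == lev, j] for lev in levels]
            res = stats.tukey_hsd(*groups)
            row = {repeated_name: j}
            for comp in ("mid", "late"):
                if comp in levels and "early" in levels:
                    p = float(res.pvalue[levels.index("early"),
                                         levels.index(comp)])
                    row[f"early_vs_{comp}_p"] = p
                    row[f"early_vs_{comp}"] = p < posthoc_alpha
            post_rows.append(row)
    return AnovaResult(table, pd.DataFrame(post_rows))


# ---------------------------------------------------------------------------
# convenience driver
# ---------------------------------------------------------------------------

def progression_analysis(streams_by_day: Dict[int, SessionStreams],
                         trials: pd.DataFrame, states: Sequence,
                         variables: Sequence[str] = PERISTIM_VARIABLES,
                         n_blocks: int = cfg.N_BLOCKS,
                         posthoc: bool = False) -> Dict[
                             str, Dict[tuple, tuple]]:
    """Profiles and stage ANOVAs per variable × subcategory for one mouse."""
    st = np.asarray(states, dtype=object)
    retained, _ = sort_subcategories(st, trials["outcome"].to_numpy())
    traces_cache: Dict[str, np.ndarray] = {}
    for var in variables:
        parts = []
        for day in sorted(streams_by_day):
            m = (trials["day"] == day).to_numpy()
            parts.append(trial_traces(streams_by_day[day],
                                      trials[m].reset_index(drop=True), var))
        traces_cache[var] = np.concatenate(parts, axis=0)
    out: Dict[str, Dict[tuple, tuple]] = {}
    for var in variables:
        out[var] = {}
        for key, idx in retained.items():
            if idx.size == 0:
                continue
            blocks = progression_blocks(idx, n_blocks)
            profile = peristim_average(traces_cache[var], blocks, var)
            anova = None
            okb = ~np.isnan(profile.block_curves).any(axis=1)
            stage_counts = pd.Series(profile.stages[okb]).value_counts()
            if len(stage_counts) >= 2 and stage_counts.min() >= 2:
                anova = stage_anova(profile.block_curves[okb],
                                    profile.stages[okb], posthoc=posthoc)
            out[var][key] = (profile, anova)
    return out
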