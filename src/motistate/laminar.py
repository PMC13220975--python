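"""Laminar CSD / MUA-power profiling of stimulus-evoked activity.

Peristimulus epochs ([−0.05, +0.25] s around stimulus onset) from the 45
topmost probe channels (~0.9 mm span, 20 µm spacing, depth 0 at the
topmost analysed channel) are processed into channel × time maps:

* CSD — second spatial derivative of the LFP, z-scored per channel,
  spatially smoothed over 5 channels and temporally over 20 ms;
* MUA power — per-channel spectrogram (4 ms window, 50% overlap), power
  summed over 500–5,000 Hz, z-scored per channel, 10 ms temporal
  smoothing, no spatial smoothing.

Maps are reduced to normalized depth profiles (mean absolute response
over 0–100 ms, 22-channel moving-mean detrend, min–max to [0, 1]), which
feed the deep-MUA landmark QC (~0.6 mm), the whisker-pair somatotopy
selection, depth-band Friedman comparisons across trial subcategories,
and stage × depth split-plot ANOVAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from . import config as cfg
from .progression import AnovaResult, stage_anova

FLAG_OK = "ok"
FLAG_DEGENERATE = "degenerate"


def _moving_mean_axis(x: np.ndarray, window: int, axis: int) -> np.ndarray:
    """Centered moving mean with truncated edges along one axis."""
    if window <= 1:
        return x
    x = np.moveaxis(x, axis, 0)
    n = x.shape[0]
    left = (window - 1) // 2
    right = window - 1 - left
    c = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)])
    i = np.arange(n)
    lo = np.maximum(i - left, 0)
    hi = np.minimum(i + right + 1, n)
    out = (c[hi] - c[lo]) / (hi - lo)[(...,) + (None,) * (x.ndim - 1)]
    return np.moveaxis(out, 0, axis)


def _zscore_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each channel over the epoch; all-constant rows stay zero
    (degeneracy flagged per row)."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    degenerate = sd[:, 0] == 0
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd, degenerate


def second_spatial_difference(x: np.ndarray) -> np.ndarray:
    """Discrete second derivative across channels (axis 0); the undefined
    edge channels are filled by replicating the nearest interior value."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("CSD needs >= 3 channels")
    csd = np.empty_like(x)
    csd[1:-1] = np.diff(x, n=2, axis=0)
    csd[0], csd[-1] = csd[1], csd[-2]
    return csd


@dataclass
class LaminarEpoch:
    """Channels × time peristimulus map (CSD or MUA power)."""

    data: np.ndarray
    time: np.ndarray                     # s relative to stimulus onset
    depths_mm: np.ndarray
    metric: str                          # "CSD" | "MUA"
    degenerate_channels: np.ndarray = None


@dataclass
class LaminarProfile:
    values: np.ndarray                   # per-channel, min-max in [0, 1]
    depths_mm: np.ndarray
    metric: str
    flag: str = FLAG_OK


def csd_map(lfp_epoch: np.ndarray, rate: float, time: np.ndarray,
            depths_mm: np.ndarray,
            spatial_window: int = cfg.CSD_SPATIAL_SMOOTH,
            temporal_s: float = cfg.CSD_TEMPORAL_SMOOTH_S) -> LaminarEpoch:
    """Current-source-density map from a channels × samples LFP epoch.

    Second spatial difference (edge channels filled by replicating the
    nearest interior value, keeping the channel count), per-channel
    z-scoring, then 5-channel spatial and 20 ms temporal moving-mean
    smoothing.  Conductivity and spacing constants are omitted: profiles
    are z-scored and normalized downstream, so physical units cancel.
    """
    x = np.asarray(lfp_epoch, dtype=float)
    csd = second_spatial_difference(x)
    z, degenerate = _zscore_rows(csd)
    z = _moving_mean_axis(z, spatial_window, axis=0)
    z = _moving_mean_axis(z, max(int(round(temporal_s * rate)), 1), axis=1)
    return LaminarEpoch(z, time, depths_mm, "CSD", degenerate)


def mua_map(raw_epoch: np.ndarray, rate: float, epoch_start: float,
            depths_mm: np.ndarray, band: tuple = cfg.MUA_BAND,
            window_s: float = cfg.MUA_SPECTROGRAM_WINDOW_S,
            temporal_s: float = cfg.MUA_TEMPORAL_SMOOTH_S) -> LaminarEpoch:
    """MUA band-power map from a channels × samples raw epoch.

    Per-channel spectrogram (4 ms window, 50% overlap), absolute power
    summed across the 500–5,000 Hz bins, z-scored per channel, 10 ms
    temporal smoothing, no spatial smoothing.
    """
    if rate < 2 * band[1]:
        raise ValueError(f"raw rate {rate} too low for {band[1]} Hz band")
    x = np.asarray(raw_epoch, dtype=float)
    nperseg = int(round(window_s * rate))
    if x.shape[1] < nperseg:
        raise ValueError("epoch shorter than one spectrogram window")
    f, t, sxx = signal.spectrogram(x, fs=rate, nperseg=nperseg,
                                   noverlap=nperseg // 2, axis=1)
    m = (f >= band[0]) & (f <= band[1])
    power = np.abs(sxx[:, m, :]).sum(axis=1)
    z, degenerate = _zscore_rows(power)
    step = t[1] - t[0] if t.size > 1 else window_s
    z = _moving_mean_axis(z, max(int(round(temporal_s / step)), 1), axis=1)
    return LaminarEpoch(z, epoch_start + t, depths_mm, "MUA", degenerate)


def depth_profile(lam: LaminarEpoch,
                  window: tuple = cfg.RESPONSE_WINDOW,
                  detrend_channels: int = cfg.DETREND_CHANNELS
                  ) -> LaminarProfile:
    """Normalized laminar depth profile of response strength.

    Absolute map values averaged over the 0–100 ms post-stimulus window
    (sinks and sources contribute equally), detrended by subtracting a
    centered 22-channel moving mean, then min–max normalized to [0, 1].
    A constant profile after detrending returns all 0.5, flagged.
    """
    m = (lam.time >= window[0]) & (lam.time <= window[1])
    if not m.any():
        raise ValueError("map does not cover the response window")
    prof = np.abs(lam.data[:, m]).mean(axis=1)
    prof = prof - _moving_mean_axis(prof, detrend_channels, axis=0)
    lo, hi = prof.min(), prof.max()
    if hi - lo <= 0:
        return LaminarProfile(np.full(prof.size, 0.5), lam.depths_mm,
                              lam.metric, FLAG_DEGENERATE)
    return LaminarProfile((prof - lo) / (hi - lo), lam.depths_mm, lam.metric)


def mua_landmark_qc(profile: LaminarProfile,
                    expected_depth: float = cfg.LANDMARK_DEPTH_MM,
                    tolerance: float = cfg.LANDMARK_TOL_MM,
                    prominence: float = 0.2) -> tuple[bool, Optional[float]]:
    """Deep-MUA landmark check: a prominent local maximum near the
    expected depth.  Failing mice are excluded from laminar analysis but
    keep contributing channel-averaged features."""
    if profile.flag == FLAG_DEGENERATE:
        return False, None
    peaks, props = signal.find_peaks(profile.values, prominence=prominence)
    if peaks.size == 0:
        return False, None
    depths = profile.depths_mm[peaks]
    near = np.abs(depths - expected_depth) <= tolerance
    if not near.any():
        return False, None
    cand = peaks[near]
    best = cand[np.argmax(profile.values[cand])]
    return True, float(profile.depths_mm[best])


def somatotopy_select(responses: Dict[str, LaminarEpoch],
                      window: tuple = (0.0, 0.25)) -> tuple[str, bool]:
    """Whisker pair with the maximum mean |CSD| over channels × 0–250 ms;
    exact ties break to the first label in lexical order (flagged)."""
    if not responses:
        raise ValueError("no candidate whisker pairs")
    scores = {}
    for pair, lam in responses.items():
        m = (lam.time >= window[0]) & (lam.time <= window[1])
        scores[pair] = float(np.abs(lam.data[:, m]).mean())
    if max(scores.values()) == 0:
        raise ValueError("all whisker-pair responses are zero")
    best = max(scores.values())
    winners = sorted(p for p, v in scores.items() if v == best)
    return winners[0], len(winners) > 1


def band_channels(depths_mm: np.ndarray, band_mm: tuple) -> np.ndarray:
    """Channel indices whose depth falls inside [lo, hi] inclusive."""
    lo, hi = band_mm
    if hi < depths_mm.min() or lo > depths_mm.max():
        raise ValueError(f"band {band_mm} outside probe span")
    return np.where((depths_mm >= lo - 1e-9) & (depths_mm <= hi + 1e-9))[0]


def depth_band_stats(block_profiles: Dict[tuple, np.ndarray],
                     depths_mm: np.ndarray, band_mm: tuple,
                     stages: np.ndarray,
                     posthoc_alpha: float = 0.01) -> pd.DataFrame:
    """Band-mean per trial block; Friedman test across the trial
    subcategories within each training stage, plus Tukey post hocs.

    ``block_profiles`` maps each (state, outcome) subcategory to a
    (n_blocks, n_channels) array sharing the 99-block progression axis.
    """
    ch = band_channels(depths_mm, band_mm)
    keys = list(block_profiles)
    band_means = {k: block_profiles[k][:, ch].mean(axis=1) for k in keys}
    rows = []
    for stage in cfg.STAGES:
        m = stages == stage
        groups = [band_means[k][m] for k in keys]
        groups = [g[~np.isnan(g)] for g in groups]
        n_min = min(len(g) for g in groups)
        if n_min < 3 or len(groups) < 3:
            warnings.warn(f"stage {stage}: too few blocks for Friedman")
            continue
        groups = [g[:n_min] for g in groups]
        stat, p = stats.friedmanchisquare(*groups)
        res = stats.tukey_hsd(*groups)
        for i, ki in enumerate(keys):
            for j in range(i + 1, len(keys)):
                rows.append({
                    "stage": stage, "group_a": "_".join(ki),
                    "group_b": "_".join(keys[j]),
                    "friedman_stat": float(stat), "friedman_p": float(p),
                    "tukey_p": float(res.pvalue[i, j]),
                    "significant": bool(res.pvalue[i, j] < posthoc_alpha),
                })
    return pd.DataFrame(rows)


def laminar_stage_anova(block_profiles: np.ndarray, stages: Sequence,
                        posthoc_alpha: float = 0.05,
                        posthoc: bool = True) -> AnovaResult:
    """Stage × depth split-plot ANOVA with trial blocks as units and the
    laminar channels as the repeated-measures axis."""
    return stage_anova(block_profiles, stages, posthoc_alpha,
                       repeated_name="depth", posthoc=posthoc)


# ---------------------------------------------------------------------------
# per-trial-block profile assembly
# ---------------------------------------------------------------------------

def block_profiles_from_epochs(
        epochs: np.ndarray, rate: float, epoch_start: float,
        depths_mm: np.ndarray, blocks: Sequence[np.ndarray],
        metric: str = "CSD",
        n_channels: int = cfg.N_LAMINAR_CHANNELS) -> np.ndarray:
    """Laminar profiles per progression block from per-trial epochs.

    Epochs (trials × channels × samples) are restricted to the topmost
    ``n_channels`` channels and the [−0.05, +0.25] s window; one map is
    computed per trial (MUA power is not phase-locked, so maps cannot be
    computed on trial-averaged raw traces), maps are averaged within each
    progression block, and each block average is reduced to a profile.
    Returns (n_blocks, n_channels); empty blocks give NaN rows.
    """
    n_ch = min(n_channels, epochs.shape[1])
    t_full = epoch_start + np.arange(epochs.shape[2]) / rate
    w = (t_full >= cfg.LAMINAR_WINDOW[0]) & (t_full <= cfg.LAMINAR_WINDOW[1])
    time = t_full[w]
    depths = depths_mm[:n_ch] - depths_mm[0]
    out = np.full((len(blocks), n_ch), np.nan)
    for b, idx in enumerate(blocks):
        if len(idx) == 0:
            continue
        maps = []
        for i in idx:
            if metric == "CSD":
                lam = csd_map(np.asarray(epochs[i], dtype=float)[:n_ch, w],
                              rate, time, depths)
            else:
                lam = mua_map(np.asarray(epochs[i], dtype=float)[:n_ch, w],
                              rate, cfg.LAMINAR_WINDOW[0], depths)
            maps.append(lam.data)
        avg = LaminarEpoch(np.mean(maps, axis=0),
                           lam.time, depths, metric)
        out[b] = depth_profile(avg).values
    return out
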