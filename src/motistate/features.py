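"""Per-trial performance and nonperformance metrics from raw streams.

Produces the trial feature table the state analysis runs on: whole-trial
lick rate and binary correctness (the performance axes), plus the eight
nonperformance variables — prestimulus lick count, whole-trial wheel
speed, pupil diameter, eyelid aperture, prestimulus power-spectrum slope
(PSS), stimulus-evoked LFP, prestimulus MUA band power, and
stimulus-evoked MUA — and per-session summaries with across-day trend
tests.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd
from scipy import signal, stats

from . import config as cfg
from .synth import SessionStreams


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def moving_mean(series, window: int, step: int = 1) -> np.ndarray:
    """Centered moving mean with shrinking (truncated) edge windows.

    Output length equals input length (for ``step`` = 1); every value is
    the unweighted mean of the trials inside the window, so the edges
    average over fewer trials rather than padding.  Sessions must be
    smoothed independently by the caller.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series is empty")
    if window == 1:
        out = x.copy()
    else:
        left = (window - 1) // 2
        right = window - 1 - left
        c = np.concatenate([[0.0], np.cumsum(x)])
        i = np.arange(x.size)
        lo = np.maximum(i - left, 0)
        hi = np.minimum(i + right + 1, x.size)
        out = (c[hi] - c[lo]) / (hi - lo)
    return out[::step] if step > 1 else out


def smooth_per_session(df: pd.DataFrame, columns: Iterable[str],
                       window: int = cfg.SMOOTH_WINDOW,
                       by=("mouse", "day")) -> pd.DataFrame:
    """Moving-mean smooth selected columns independently within each session."""
    out = df.copy()
    for col in columns:
        out[col] = out[col].astype(float)
    keys = [k for k in by if k in df.columns]
    for _, idx in df.groupby(keys, sort=False).indices.items():
        for col in columns:
            out.iloc[idx, out.columns.get_loc(col)] = moving_mean(
                df[col].to_numpy()[idx], window)
    return out


# ---------------------------------------------------------------------------
# wheel
# ---------------------------------------------------------------------------

def wheel_speed(encoder_voltage: np.ndarray, rate: float,
                circumference: float = 36.0) -> np.ndarray:
    """Signed wheel speed (cm/s) from the wrapping encoder voltage.

    Voltage (0–3.3 V) is rescaled to position on the 0–36 cm wheel
    circumference, phase-unwrapped into an ever-ascending travelled
    distance and differentiated.  Backward running gives negative speed.
    """
    v = np.asarray(encoder_voltage, dtype=float)
    if v.size == 0:
        raise ValueError("empty encoder trace")
    pos = v / 3.3 * circumference
    unwrapped = np.unwrap(pos * (2 * np.pi / circumference)) * (
        circumference / (2 * np.pi))
    speed = np.diff(unwrapped) * rate
    return np.concatenate([speed[:1], speed]) if speed.size else np.zeros(1)


def _interval_mean(values: np.ndarray, times: np.ndarray,
                   start: float, end: float) -> float:
    m = (times >= start) & (times < end)
    return float(values[m].mean()) if m.any() else np.nan


# ---------------------------------------------------------------------------
# eye
# ---------------------------------------------------------------------------

def octagon_aperture(points: np.ndarray) -> np.ndarray:
    """Euclidean distance between the topmost and bottommost octagon vertices.

    ``points`` has shape (frames, n_vertices, 2); requires >= 2 vertices.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 2:
        pts = pts[None]
    if pts.shape[1] < 2:
        raise ValueError("octagon needs at least 2 points")
    rows = np.arange(pts.shape[0])
    top = pts[rows, pts[:, :, 1].argmax(axis=1)]
    bot = pts[rows, pts[:, :, 1].argmin(axis=1)]
    return np.linalg.norm(top - bot, axis=1)


def eye_apertures(points: np.ndarray, frame_times: np.ndarray,
                  trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial aperture means, excluding punishment-extension frames.

    Returns (per-trial values, imputed flags).  Trials without any valid
    frame receive the session median, flagged.
    """
    aperture = octagon_aperture(points)
    t_start = trials["t_start"].to_numpy()
    duration = trials["duration"].to_numpy()
    punished = trials["punished"].to_numpy()
    vals = np.empty(len(trials))
    for i in range(len(trials)):
        end = t_start[i] + (cfg.TRIAL_CORE_S if punished[i] else duration[i])
        vals[i] = _interval_mean(aperture, frame_times, t_start[i], end)
    imputed = np.isnan(vals)
    if imputed.any():
        med = np.nanmedian(vals)
        vals[imputed] = med
    return vals, imputed


# ---------------------------------------------------------------------------
# licking
# ---------------------------------------------------------------------------

def lick_metrics(lick_times: np.ndarray,
                 trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Whole-trial lick rate (Hz over the 5 s core, punishment excluded)
    and prestimulus lick count, with half-open [start, end) windows."""
    lt = np.sort(np.asarray(lick_times, dtype=float))
    t_start = trials["t_start"].to_numpy()
    t_onset = trials["t_onset"].to_numpy()
    whole = (np.searchsorted(lt, t_start + cfg.TRIAL_CORE_S, "left")
             - np.searchsorted(lt, t_start, "left")) / cfg.TRIAL_CORE_S
    prestim = (np.searchsorted(lt, t_onset, "left")
               - np.searchsorted(lt, t_onset - cfg.PRESTIM_S, "left"))
    return whole.astype(float), prestim.astype(float)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def prestim_pss(epoch: np.ndarray, rate: float = cfg.LFP_RATE,
                band: tuple = cfg.PSS_BAND,
                n_bins: int = cfg.PSS_NBINS) -> float:
    """Aperiodic power-spectrum slope from a channels × samples LFP epoch.

    Welch PSD (1 s window, 50% overlap), interpolated onto ``n_bins``
    log-spaced frequencies in ``band``, log10-transformed and fitted with
    a least-squares line; the slope is averaged across channels.
    """
    x = np.atleast_2d(np.asarray(epoch, dtype=float))
    nperseg = int(round(rate))
    if x.shape[1] < nperseg:
        raise ValueError("epoch shorter than the 1 s Welch window")
    f, pxx = signal.welch(x, fs=rate, nperseg=nperseg,
                          noverlap=nperseg // 2, axis=1)
    centers = np.logspace(np.log10(band[0]), np.log10(band[1]), n_bins)
    logf = np.log10(centers)
    slopes = np.empty(x.shape[0])
    for ch in range(x.shape[0]):
        p = np.interp(centers, f, pxx[ch])
        p = np.maximum(p, np.finfo(float).tiny)
        slopes[ch] = np.polyfit(logf, np.log10(p), 1)[0]
    return float(slopes.mean())


def mua_band_power(epoch: np.ndarray, rate: float = cfg.RAW_RATE,
                   band: tuple = cfg.MUA_BAND,
                   window_s: float = 0.5) -> float:
    """Summed 500–5,000 Hz Welch power (500 Hz bins), channel-averaged."""
    if rate < 2 * band[1]:
        raise ValueError(f"sampling rate {rate} too low for {band[1]} Hz band")
    x = np.atleast_2d(np.asarray(epoch, dtype=float))
    nperseg = min(int(round(window_s * rate)), x.shape[1])
    f, pxx = signal.welch(x, fs=rate, nperseg=nperseg,
                          noverlap=nperseg // 2, axis=1)
    centers = np.arange(band[0], band[1] + 1, 500.0)
    power = np.empty(x.shape[0])
    for ch in range(x.shape[0]):
        power[ch] = np.interp(centers, f, pxx[ch]).sum()
    return float(power.mean())


def evoked_responses(lfp_epoch: np.ndarray, raw_epoch: np.ndarray,
                     lfp_rate: float, raw_rate: float,
                     epoch_start: float) -> tuple[float, float]:
    """Channel-mean evoked LFP amplitude and evoked MUA band power over
    the 200 ms stimulus window ([0, 0.2) s from stimulus onset).

    The evoked MUA uses a 50 ms Welch window: the 0.5 s prestimulus
    window cannot fit inside the stimulus period.
    """
    i0 = int(round((0.0 - epoch_start) * lfp_rate))
    i1 = int(round((cfg.STIMULUS_S - epoch_start) * lfp_rate))
    evoked_lfp = float(np.asarray(lfp_epoch, dtype=float)[:, i0:i1].mean())
    j0 = int(round((0.0 - epoch_start) * raw_rate))
    j1 = int(round((cfg.STIMULUS_S - epoch_start) * raw_rate))
    evoked_mua = mua_band_power(np.asarray(raw_epoch)[:, j0:j1],
                                raw_rate, window_s=0.05)
    return evoked_lfp, evoked_mua


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

def build_feature_table(trials: pd.DataFrame, streams: SessionStreams,
                        mouse_id: str = "m1") -> pd.DataFrame:
    """One row per trial of one session: performance + 8 nonperformance
    variables extracted from the raw streams."""
    t = trials.reset_index(drop=True)
    whole_lick, prestim_lick = lick_metrics(streams.lick_times, t)
    speed = wheel_speed(streams.encoder_voltage, streams.encoder_rate)
    t_enc = np.arange(speed.size) / streams.encoder_rate
    wheel = np.array([
        _interval_mean(speed, t_enc, s, s + cfg.TRIAL_CORE_S)
        for s in t["t_start"]])
    pupil, _ = eye_apertures(streams.pupil_points, streams.frame_times, t)
    eyelid, _ = eye_apertures(streams.eyelid_points, streams.frame_times, t)

    e0 = streams.epoch_window[0]
    n_pre_lfp = int(round(-e0 * streams.lfp_rate)) - int(
        round((-e0 - cfg.PRESTIM_S) * streams.lfp_rate))
    pre_lfp_sl = slice(int(round((-e0 - cfg.PRESTIM_S) * streams.lfp_rate)),
                       int(round(-e0 * streams.lfp_rate)))
    pre_raw_sl = slice(int(round((-e0 - cfg.PRESTIM_S) * streams.raw_rate)),
                       int(round(-e0 * streams.raw_rate)))
    pss = np.empty(len(t))
    muap = np.empty(len(t))
    evk_lfp = np.empty(len(t))
    evk_mua = np.empty(len(t))
    for i in range(len(t)):
        lfp = np.asarray(streams.lfp_epochs[i], dtype=float)
        raw = np.asarray(streams.raw_epochs[i], dtype=float)
        pss[i] = prestim_pss(lfp[:, pre_lfp_sl], streams.lfp_rate)
        muap[i] = mua_band_power(raw[:, pre_raw_sl], streams.raw_rate)
        evk_lfp[i], evk_mua[i] = evoked_responses(
            lfp, raw, streams.lfp_rate, streams.raw_rate, e0)

    out = pd.DataFrame({
        "mouse": mouse_id,
        "day": t["day"],
        "trial": t["trial"],
        "trial_type": t["trial_type"],
        "outcome": t["outcome"],
        "punished": t["punished"],
        "whole_trial_lick_rate": whole_lick,
        "correctness": t["outcome"].isin(
            ["hit", "correct_rejection"]).astype(int),
        "prestim_lick_rate": prestim_lick,
        "wheel_speed": wheel,
        "pupil_diameter": pupil,
        "eyelid_aperture": eyelid,
        "prestim_pss": pss,
        "evoked_lfp": evk_lfp,
        "prestim_mua_power": muap,
        "evoked_mua": evk_mua,
    })
    if "latent_state" in t.columns:
        out["latent_state"] = t["latent_state"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# session summaries
# ---------------------------------------------------------------------------

def session_summaries(feature_table: pd.DataFrame,
                      body_weights: Optional[Dict] = None,
                      window: int = cfg.SMOOTH_WINDOW) -> tuple[
                          pd.DataFrame, pd.DataFrame]:
    """Per-session summary metrics and across-day linear trend tests.

    Peak correctness is the maximum of the 50-trial moving mean of the
    binary correctness vector; other metrics are session means.  Trends
    are Pearson correlations of session values (aggregated across mice)
    against training day.
    """
    rows = []
    for (mouse, day), g in feature_table.groupby(["mouse", "day"], sort=True):
        row = {
            "mouse": mouse, "day": day,
            "peak_correctness": float(
                moving_mean(g["correctness"].to_numpy(), window).max()),
            "mean_wheel_speed": float(g["wheel_speed"].mean()),
            "mean_pss": float(g["prestim_pss"].mean()),
            "mean_mua_power": float(g["prestim_mua_power"].mean()),
            "lick_rate": float(g["whole_trial_lick_rate"].mean()),
            "mean_pupil_diameter": float(g["pupil_diameter"].mean()),
            "mean_eyelid_aperture": float(g["eyelid_aperture"].mean()),
        }
        if body_weights is not None:
            row["body_weight"] = body_weights.get((mouse, day), np.nan)
        rows.append(row)
    summaries = pd.DataFrame(rows)

    trend_rows = []
    metrics = [c for c in summaries.columns if c not in ("mouse", "day")]
    if summaries["day"].nunique() < 2:
        warnings.warn("single session: across-day trend tests skipped")
        trends = pd.DataFrame(columns=["metric", "r", "p"])
    else:
        for m in metrics:
            v = summaries[m].to_numpy(dtype=float)
            ok = np.isfinite(v)
            r, p = stats.pearsonr(summaries["day"].to_numpy()[ok], v[ok])
            trend_rows.append({"metric": m, "r": float(r), "p": float(p)})
        trends = pd.DataFrame(trend_rows)
    return summaries, trends
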