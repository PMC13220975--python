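"""Tripartite motivation-state labeling from licking and correctness.

Each trial is assigned to *persistent*, *disengaged* or *attentive*
using two binary axes computed per mouse on smoothed, day-concatenated
vectors: a licking axis (trial-count histogram with 100 equal-width
bins; trials at or below the upper edge of the second bin are "low/no
licking") and a correctness axis (trials at or above the mouse's 75th
sample quantile are "good performance").  Good performance wins the
precedence: attentive; otherwise low/no licking: disengaged; otherwise
persistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config as cfg
from .features import smooth_per_session


@dataclass
class LabelResult:
    labels: pd.DataFrame          # mouse, day, trial, axes, state
    lick_cutoffs: dict            # per mouse, upper edge of histogram bin 2
    correctness_cutoffs: dict     # per mouse, 75th-quantile value
    conflicts: dict               # per mouse, (low/no, good) trial count


def binarize_licking(smoothed_rates: np.ndarray,
                     n_bins: int = cfg.HIST_BINS,
                     cutoff_bin: int = cfg.LICK_CUTOFF_BIN
                     ) -> tuple[np.ndarray, float]:
    """Low/no vs moderate/high licking via a 100-bin trial-count histogram.

    Returns a boolean low/no mask and the cutoff (upper edge of the
    second bin, inclusive).  A degenerate all-equal distribution is
    low/no if the common value is 0, else an error.
    """
    x = np.asarray(smoothed_rates, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        if lo == 0.0:
            return np.ones(x.size, dtype=bool), 0.0
        raise ValueError(
            f"degenerate lick-rate distribution (all values {lo:g})")
    edges = np.linspace(lo, hi, n_bins + 1)
    cutoff = float(edges[cutoff_bin])
    return x <= cutoff, cutoff


def binarize_correctness(smoothed_correctness: np.ndarray,
                         quantile: float = cfg.GOOD_QUANTILE
                         ) -> tuple[np.ndarray, float]:
    """Good vs chance performance at the mouse's own sample quantile
    (linear interpolation; ties at the cutoff are good)."""
    x = np.asarray(smoothed_correctness, dtype=float)
    q = float(np.quantile(x, quantile))
    return x >= q, q


def tripartite(low_no: np.ndarray, good: np.ndarray) -> tuple[
        np.ndarray, int]:
    """Merge the two binary axes into the three-state category.

    Good performance takes precedence (the state is defined purely by
    performance); the count of (low/no licking, good) conflicts — a
    combination absent in well-behaved data — is returned for QC.
    """
    state = np.where(good, "attentive",
                     np.where(low_no, "disengaged", "persistent"))
    conflicts = int(np.sum(low_no & good))
    return state.astype(object), conflicts


def label_states(feature_table: pd.DataFrame,
                 window: int = cfg.SMOOTH_WINDOW,
                 n_bins: int = cfg.HIST_BINS,
                 quantile: float = cfg.GOOD_QUANTILE) -> LabelResult:
    """Full per-mouse labeling from the (unsmoothed) trial feature table."""
    sm = smooth_per_session(
        feature_table, ["whole_trial_lick_rate", "correctness"], window)
    frames, lick_cut, corr_cut, conf = [], {}, {}, {}
    for mouse, g in sm.groupby("mouse", sort=False):
        low_no, c_lick = binarize_licking(
            g["whole_trial_lick_rate"].to_numpy(), n_bins)
        good, c_corr = binarize_correctness(
            g["correctness"].to_numpy(), quantile)
        state, n_conf = tripartite(low_no, good)
        if n_conf > 0.01 * len(g):
            warnings.warn(
                f"{mouse}: {n_conf} low/no-licking trials labeled attentive "
                f"({100 * n_conf / len(g):.1f}% > 1%)")
        frames.append(pd.DataFrame({
            "mouse": mouse,
            "day": g["day"].to_numpy(),
            "trial": g["trial"].to_numpy(),
            "lick_axis": np.where(low_no, "low_no", "moderate_high"),
            "correctness_axis": np.where(good, "good", "chance"),
            "state": state,
        }))
        lick_cut[mouse], corr_cut[mouse], conf[mouse] = c_lick, c_corr, n_conf
    return LabelResult(pd.concat(frames, ignore_index=True),
                       lick_cut, corr_cut, conf)
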