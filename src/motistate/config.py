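"""Parameter registry and pipeline configuration.

Every analysis constant used across the pipeline lives here with its
default value, so that a single object documents the protocol: trial
epoch durations, smoothing windows, histogram/quantile cutoffs for state
labeling, classifier settings, the normalized training-progression block
scheme, and the laminar geometry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

# --- trial structure (seconds) -------------------------------------------
PRESTIM_S = 1.0
STIMULUS_S = 0.2
ANSWER_S = 1.8
INTERTRIAL_S = 2.0
PUNISHED_INTERTRIAL_S = 10.0
#: duration of the core (unpunished) trial analysed for whole-trial metrics
TRIAL_CORE_S = PRESTIM_S + STIMULUS_S + ANSWER_S + INTERTRIAL_S  # 5.0 s
MAX_TYPE_RUN = 3

# --- behavioral-state analysis -------------------------------------------
SMOOTH_WINDOW = 50            # trials, moving mean, 1-trial steps
HIST_BINS = 100               # lick-rate / correctness trial-count histograms
LICK_CUTOFF_BIN = 2           # trials at or below bin 2 -> low/no licking
GOOD_QUANTILE = 0.75          # correctness at or above -> good performance

# --- state prediction -----------------------------------------------------
SHUFFLE_BLOCK = 25            # row-shuffle block size (trials)
N_TREES = 30                  # bagged learning cycles
N_ITERATIONS = 100            # iterations pooled per ROC group
POOL_SIZES = tuple(range(1, 9))

NONPERFORMANCE_VARS = (
    "prestim_lick_rate",
    "wheel_speed",
    "pupil_diameter",
    "eyelid_aperture",
    "prestim_pss",
    "evoked_lfp",
    "prestim_mua_power",
    "evoked_mua",
)
PHYSIO_VARS = NONPERFORMANCE_VARS[:4]
NEURO_VARS = NONPERFORMANCE_VARS[4:]

STATES = ("persistent", "disengaged", "attentive")
OUTCOMES = ("hit", "miss", "correct_rejection", "false_alarm")

# --- training-progression analysis ---------------------------------------
N_BLOCKS = 99                 # normalized progression blocks per subcategory
BLOCKS_PER_STAGE = 33
STAGES = ("early", "mid", "late")
PERISTIM_WINDOW = (-1.0, 4.0)  # s relative to stimulus onset
PERISTIM_BINS = 80

# --- electrophysiology ----------------------------------------------------
LFP_RATE = 1250.0             # Hz
RAW_RATE = 20000.0            # Hz
MUA_BAND = (500.0, 5000.0)    # Hz
PSS_BAND = (1.0, 100.0)       # Hz, log-spaced fit range
PSS_NBINS = 100
EPOCH_WINDOW = (-1.0, 0.25)   # s, synthesized electrophysiology epochs
LAMINAR_WINDOW = (-0.05, 0.25)  # s, peristimulus laminar maps
RESPONSE_WINDOW = (0.0, 0.1)  # s, laminar quantification window
N_LAMINAR_CHANNELS = 45       # topmost channels analysed
CHANNEL_SPACING_MM = 0.020
CSD_SPATIAL_SMOOTH = 5        # channels
CSD_TEMPORAL_SMOOTH_S = 0.020
MUA_TEMPORAL_SMOOTH_S = 0.010
MUA_SPECTROGRAM_WINDOW_S = 0.004
DETREND_CHANNELS = 22         # moving-mean detrend window for depth profiles
CSD_BAND_MM = (0.20, 0.36)    # superficial CSD depth band
MUA_BAND_MM = (0.50, 0.64)    # deep MUA depth band
LANDMARK_DEPTH_MM = 0.6
LANDMARK_TOL_MM = 0.1


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (defaults reproduce the protocol)."""

    out_dir: Path = Path("motistate_out")
    seed: int = 0
    n_mice: int = 5
    n_sessions: int = 14
    trials_per_session: int = 500
    probe_channels: int = 64
    smooth_window: int = SMOOTH_WINDOW
    hist_bins: int = HIST_BINS
    good_quantile: float = GOOD_QUANTILE
    shuffle_block: int = SHUFFLE_BLOCK
    n_trees: int = N_TREES
    n_iterations: int = N_ITERATIONS
    n_blocks: int = N_BLOCKS
    peristim_bins: int = PERISTIM_BINS
    csd_band_mm: tuple = CSD_BAND_MM
    mua_band_mm: tuple = MUA_BAND_MM
    landmark_depth_mm: float = LANDMARK_DEPTH_MM

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.n_sessions < 1 or self.trials_per_session < 1:
            raise ValueError("n_sessions and trials_per_session must be >= 1")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if not 0.0 < self.good_quantile < 1.0:
            raise ValueError("good_quantile must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        return d


def trial_duration(punished: bool) -> float:
    """Total trial duration in seconds (epochs sum; punished trials 13 s)."""
    iti = PUNISHED_INTERTRIAL_S if punished else INTERTRIAL_S
    return PRESTIM_S + STIMULUS_S + ANSWER_S + iti
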