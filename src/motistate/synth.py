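"""Synthetic multi-mouse go/no-go training datasets.

Emulates head-fixed whisker-discrimination sessions: a pseudorandom
go/no-go trial sequence (max three consecutive repetitions of a type), a
latent motivation state alternating between *persistent* (licking at
chance performance), *disengaged* (little/no licking) and *attentive*
(good performance) on a ~150-trial timescale, across-session learning,
and the raw data streams the analysis consumes — lick event times, a
wrapping wheel-encoder voltage, pupil/eyelid keypoint octagons, laminar
LFP epochs with a stimulus-locked dipole, and high-rate raw epochs with
a deep multiunit-activity landmark.

State dynamics are a semi-Markov chain: geometric dwell times (mean
``state_dwell_mean`` trials) with transition probabilities biased by
within-session phase (disengagement becomes likelier late in a session)
and by training day (attentiveness becomes likelier as learning
proceeds).  The dwell clock carries across session boundaries, except
that a session never *starts* disengaged: mice begin sessions alert, so
a carried disengaged stretch is re-drawn at the first trial of a day.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import config as cfg

STATE_INDEX = {s: i for i, s in enumerate(cfg.STATES)}


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class ProbeConfig:
    """Linear silicon probe geometry and acquisition rates."""

    n_channels: int = 64
    spacing_mm: float = cfg.CHANNEL_SPACING_MM
    lfp_rate: float = cfg.LFP_RATE
    raw_rate: float = cfg.RAW_RATE

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("channel spacing must be positive")
        if self.n_channels < 3:
            raise ValueError("probe needs at least 3 channels")

    @property
    def depths_mm(self) -> np.ndarray:
        """Depth of each channel, 0 mm at the topmost channel."""
        return np.arange(self.n_channels) * self.spacing_mm


@dataclass
class StateCoupling:
    """How one nonperformance variable couples to the latent state.

    ``means`` holds the per-state expected value, ``spread`` the per-trial
    Gaussian scatter, ``drift`` a per-state additive change per training
    day (learning).
    """

    means: Dict[str, float]
    spread: float
    drift: Dict[str, float] = field(default_factory=dict)

    def mu(self, state: str, day: int) -> float:
        return self.means[state] + self.drift.get(state, 0.0) * (day - 1)


def default_feature_coupling() -> Dict[str, StateCoupling]:
    """Per-variable state couplings emulating the recorded dataset.

    Units: lick rates in Hz (prestimulus licks are counts over 1 s),
    wheel speed in cm/s, pupil/eyelid in mm, PSS dimensionless
    (log10 power / log10 frequency slope), evoked LFP in µV, MUA
    couplings in µV of broadband noise amplitude (band power scales with
    the square).  Drifts encode the across-day trends: wheel speed, MUA
    power and PSS ascend with training; the evoked dipole attenuates with
    training in persistent states while deep evoked MUA strengthens in
    attentive/disengaged states.
    """
    return {
        "prestim_lick_rate": StateCoupling(
            {"persistent": 2.5, "disengaged": 0.02, "attentive": 1.0}, 0.3),
        "wheel_speed": StateCoupling(
            {"persistent": 6.0, "disengaged": 0.5, "attentive": 3.0}, 1.0,
            {"persistent": 0.15, "disengaged": 0.02, "attentive": 0.15}),
        "pupil_diameter": StateCoupling(
            {"persistent": 1.10, "disengaged": 0.75, "attentive": 1.00}, 0.05),
        "eyelid_aperture": StateCoupling(
            {"persistent": 2.60, "disengaged": 2.10, "attentive": 2.50}, 0.08),
        "prestim_pss": StateCoupling(
            {"persistent": -1.0, "disengaged": -1.6, "attentive": -1.1}, 0.10,
            {"persistent": 0.02, "disengaged": 0.02, "attentive": 0.02}),
        "evoked_lfp": StateCoupling(
            {"persistent": -55.0, "disengaged": -35.0, "attentive": -60.0}, 8.0,
            {"persistent": 1.5}),
        "prestim_mua_power": StateCoupling(
            {"persistent": 10.0, "disengaged": 7.0, "attentive": 9.0}, 0.8,
            {"persistent": 0.15, "disengaged": 0.15, "attentive": 0.15}),
        "evoked_mua": StateCoupling(
            {"persistent": 6.0, "disengaged": 5.0, "attentive": 8.0}, 0.8,
            {"attentive": 0.4, "disengaged": 0.2}),
    }


@dataclass
class MouseConfig:
    mouse_id: str = "m1"
    n_sessions: int = 14
    trials_per_session: int = 500
    seed: int = 0
    learning_rate: float = 0.035
    state_dwell_mean: float = 150.0
    feature_coupling: Dict[str, StateCoupling] = field(
        default_factory=default_feature_coupling)
    probe: ProbeConfig = field(default_factory=ProbeConfig)
    wheel_circumference_cm: float = 36.0
    encoder_rate: float = 100.0
    keypoint_rate: float = 20.0
    dipole_depth_mm: float = 0.28
    landmark_depth_mm: float = cfg.LANDMARK_DEPTH_MM
    epoch_window: tuple = cfg.EPOCH_WINDOW

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")
        if self.state_dwell_mean < 1:
            raise ValueError("state_dwell_mean must be >= 1")
        missing = set(cfg.NONPERFORMANCE_VARS) - set(self.feature_coupling)
        if missing:
            raise ValueError(f"feature_coupling missing variables: {missing}")
        span = (self.probe.n_channels - 1) * self.probe.spacing_mm
        if not 0.0 <= self.landmark_depth_mm <= span:
            raise ValueError(
                f"landmark depth {self.landmark_depth_mm} mm outside the "
                f"probe span (0–{span:.2f} mm)")


@dataclass
class SessionStreams:
    """Raw per-session signals (electrophysiology stored as per-trial epochs)."""

    lick_times: np.ndarray                 # s, event list
    encoder_voltage: np.ndarray            # V in [0, 3.3], wrapping
    encoder_rate: float                    # Hz
    frame_times: np.ndarray                # s, one per video frame
    pupil_points: np.ndarray               # (frames, 8, 2) mm
    eyelid_points: np.ndarray              # (frames, 8, 2) mm
    lfp_epochs: np.ndarray                 # (trials, channels, samples) µV
    raw_epochs: np.ndarray                 # (trials, channels, samples) µV
    lfp_rate: float
    raw_rate: float
    epoch_window: tuple                    # s relative to stimulus onset
    channel_depths_mm: np.ndarray

    def epoch_time(self, which: str = "lfp") -> np.ndarray:
        rate = self.lfp_rate if which == "lfp" else self.raw_rate
        n = (self.lfp_epochs if which == "lfp" else self.raw_epochs).shape[-1]
        return self.epoch_window[0] + np.arange(n) / rate


@dataclass
class SyntheticTruth:
    """Generator ground truth, kept for parameter-recovery tests."""

    state_means: Dict[str, Dict[str, float]]
    session_correctness: List[float]
    dipole_depth_mm: float
    landmark_depth_mm: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class MouseData:
    config: MouseConfig
    trials: pd.DataFrame                  # all sessions, chronological
    streams: Dict[int, SessionStreams]    # keyed by session day
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# trial sequence
# ---------------------------------------------------------------------------

def gen_trial_sequence(n: int, max_run: int = cfg.MAX_TYPE_RUN,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Pseudorandom go/no-go sequence with runs capped at ``max_run``.

    Implemented by re-flipping any draw that would start a run of
    ``max_run + 1`` identical types; counts stay balanced up to binomial
    variation of the constrained process.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    types = np.empty(n, dtype=object)
    run = 0
    for i in range(n):
        t = "go" if rng.random() < 0.5 else "nogo"
        if i > 0 and t == types[i - 1] and run >= max_run:
            t = "nogo" if t == "go" else "go"
        run = run + 1 if i > 0 and t == types[i - 1] else 1
        types[i] = t
    return types


# ---------------------------------------------------------------------------
# latent state timeline
# ---------------------------------------------------------------------------

def _state_probs(phase: float, day: int, learning_rate: float) -> np.ndarray:
    """Unconditional state weights at a session phase/day."""
    p_att = min(0.12 + learning_rate * (day - 1), 0.65)
    p_dis = 0.08 + 0.55 * phase ** 2
    p_per = max(1.0 - p_att - p_dis, 0.05)
    p = np.array([p_per, p_dis, p_att])
    return p / p.sum()


def gen_state_timeline(config: MouseConfig,
                       rng: Optional[np.random.Generator] = None
                       ) -> pd.DataFrame:
    """Latent state per trial plus per-trial behavioral tendencies.

    Returns one row per trial with columns ``day``, ``trial``, ``state``,
    response probabilities, and the true mean of every nonperformance
    variable (``mu_<variable>``).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_per = config.trials_per_session
    p_switch = 1.0 / config.state_dwell_mean

    rows_day, rows_trial, rows_state = [], [], []
    state = int(rng.choice(3, p=_state_probs(0.0, 1, config.learning_rate)))
    dwell = int(rng.geometric(p_switch))
    for day in range(1, config.n_sessions + 1):
        if rows_day and cfg.STATES[state] == "disengaged":
            # sessions never start disengaged: re-draw at the day boundary
            state = int(rng.choice(
                3, p=_state_probs(0.0, day, config.learning_rate)))
            dwell = int(rng.geometric(p_switch))
        for trial in range(1, n_per + 1):
            if dwell <= 0:
                phase = trial / n_per
                p = _state_probs(phase, day, config.learning_rate)
                p = p.copy()
                p[state] = 0.0          # forced switch keeps dwell = run length
                p /= p.sum()
                state = int(rng.choice(3, p=p))
                dwell = int(rng.geometric(p_switch))
            rows_day.append(day)
            rows_trial.append(trial)
            rows_state.append(cfg.STATES[state])
            dwell -= 1

    tl = pd.DataFrame({"day": rows_day, "trial": rows_trial,
                       "state": rows_state})
    st = tl["state"].to_numpy()
    tl["p_respond_go"] = np.select(
        [st == "persistent", st == "attentive"], [0.85, 0.95], 0.02)
    tl["p_respond_nogo"] = np.select(
        [st == "persistent", st == "attentive"], [0.85, 0.10], 0.02)
    days = tl["day"].to_numpy()
    for var, coup in config.feature_coupling.items():
        mu = np.empty(len(tl))
        for s in cfg.STATES:
            m = st == s
            mu[m] = coup.means[s] + coup.drift.get(s, 0.0) * (days[m] - 1)
        tl[f"mu_{var}"] = mu
    return tl


def gen_trials(timeline: pd.DataFrame, config: MouseConfig,
               rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Trial table (types, outcomes, timing) from a state timeline."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    frames = []
    for day, tl in timeline.groupby("day", sort=True):
        n = len(tl)
        types = gen_trial_sequence(n, cfg.MAX_TYPE_RUN, rng)
        is_go = types == "go"
        p_resp = np.where(is_go, tl["p_respond_go"].to_numpy(),
                          tl["p_respond_nogo"].to_numpy())
        respond = rng.random(n) < p_resp
        outcome = np.where(
            is_go, np.where(respond, "hit", "miss"),
            np.where(respond, "false_alarm", "correct_rejection"))
        punished = outcome == "false_alarm"
        durations = np.where(punished, cfg.trial_duration(True),
                             cfg.trial_duration(False))
        t_start = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        frames.append(pd.DataFrame({
            "day": day,
            "trial": tl["trial"].to_numpy(),
            "trial_type": types,
            "outcome": outcome,
            "punished": punished,
            "t_start": t_start,
            "t_onset": t_start + cfg.PRESTIM_S,
            "duration": durations,
            "latent_state": tl["state"].to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# waveform synthesis helpers
# ---------------------------------------------------------------------------

def powerlaw_noise(n: int, alpha: float, rng: np.random.Generator,
                   scale: float = 1.0, n_channels: int = 1) -> np.ndarray:
    """Gaussian noise with power spectrum P(f) ∝ f^(-alpha) (spectral synthesis)."""
    n_freq = n // 2 + 1
    f = np.arange(n_freq, dtype=float)
    f[0] = 1.0
    shape = f ** (-alpha / 2.0)
    shape[0] = 0.0
    re = rng.standard_normal((n_channels, n_freq))
    im = rng.standard_normal((n_channels, n_freq))
    spec = (re + 1j * im) * shape
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return scale * x / sd


def _dipole_waveform(t: np.ndarray, tau: float = 0.025) -> np.ndarray:
    """Alpha-function transient within ~100 ms of stimulus onset."""
    w = np.zeros_like(t)
    m = (t >= 0) & (t <= 0.12)
    w[m] = (t[m] / tau) * np.exp(1.0 - t[m] / tau)
    return w


def _octagon(center: np.ndarray, radius: np.ndarray,
             jitter: np.ndarray) -> np.ndarray:
    """Regular octagons (vertices at 45° steps incl. top/bottom) + jitter."""
    ang = np.deg2rad(np.arange(0, 360, 45))
    unit = np.stack([np.cos(ang), np.sin(ang)], axis=-1)     # (8, 2)
    pts = center[:, None, :] + radius[:, None, None] * unit[None] + jitter
    return pts


# ---------------------------------------------------------------------------
# session streams
# ---------------------------------------------------------------------------

def gen_session_streams(timeline: pd.DataFrame, trials: pd.DataFrame,
                        config: MouseConfig,
                        rng: int | np.random.Generator = 0,
                        include_ephys: bool = True) -> SessionStreams:
    """Synthesize one session's raw streams from its timeline and trials.

    Licks are inhomogeneous point events (state-driven prestimulus
    licking, a response lick, consummatory bursts after hits); the wheel
    encoder is a wrapping voltage ramp whose slope encodes a state- and
    learning-dependent speed; keypoints trace pupil/eyelid octagons; LFP
    epochs are 1/f^α background (α state-dependent) plus a stimulus-locked
    dipole; raw epochs are broadband noise with a post-stimulus burst at
    the landmark depth.
    """
    if len(timeline) != len(trials):
        raise ValueError("timeline and trial table must cover the same trials")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    n_trials = len(trials)
    probe = config.probe
    day = int(trials["day"].iloc[0])
    t_start = trials["t_start"].to_numpy()
    t_onset = trials["t_onset"].to_numpy()
    duration = trials["duration"].to_numpy()
    session_span = float(t_start[-1] + duration[-1])
    states = timeline["state"].to_numpy()
    outcomes = trials["outcome"].to_numpy()

    # --- licks ------------------------------------------------------------
    licks: List[np.ndarray] = []
    mu_pre = timeline["mu_prestim_lick_rate"].to_numpy()
    for i in range(n_trials):
        k = rng.poisson(max(mu_pre[i], 0.0))
        licks.append(t_start[i] + rng.random(k) * cfg.PRESTIM_S)
        if outcomes[i] in ("hit", "false_alarm"):
            first = t_onset[i] + cfg.STIMULUS_S + rng.exponential(0.15)
            first = min(first, t_onset[i] + cfg.STIMULUS_S + cfg.ANSWER_S - 0.05)
            licks.append(np.array([first]))
            if outcomes[i] == "hit":        # consummatory burst
                k = rng.poisson(7.0 * 1.5)
                licks.append(first + rng.random(k) * 1.5)
        if states[i] == "persistent":       # occasional intertrial licking
            k = rng.poisson(1.0)
            licks.append(t_start[i] + 3.2 + rng.random(k) * 1.6)
    lick_times = np.sort(np.concatenate(licks)) if licks else np.empty(0)
    lick_times = lick_times[(lick_times >= 0) & (lick_times <= session_span)]

    # --- wheel encoder ------------------------------------------------------
    enc_rate = config.encoder_rate
    t_enc = np.arange(0.0, session_span, 1.0 / enc_rate)
    mu_wheel = timeline["mu_wheel_speed"].to_numpy()
    idx = np.clip(np.searchsorted(t_start, t_enc, side="right") - 1,
                  0, n_trials - 1)
    speed = mu_wheel[idx] + rng.normal(0.0, 0.5, t_enc.size)
    # learned anticipatory acceleration around the stimulus in responded
    # trials, plus a post-stimulus halt in late-training false alarms
    stage_gain = day / config.n_sessions
    rel = t_enc - t_onset[idx]
    respond = np.isin(outcomes, ("hit", "false_alarm"))[idx]
    engaged = states[idx] != "disengaged"
    ramp = np.clip((rel + 0.5) / 0.7, 0.0, 1.0) * ((rel >= -0.5) & (rel <= 0.2))
    speed += 4.0 * stage_gain * ramp * respond * engaged
    fa = (outcomes[idx] == "false_alarm") & (rel > 0.2) & (rel < 2.0)
    speed = np.where(fa, speed * (1.0 - 0.8 * stage_gain), speed)
    # smooth within the realistic motor bandwidth
    kernel = np.ones(5) / 5.0
    speed = np.convolve(speed, kernel, mode="same")
    distance = np.cumsum(speed) / enc_rate
    circ = config.wheel_circumference_cm
    encoder_voltage = np.mod(distance, circ) / circ * 3.3

    # --- eye keypoints ------------------------------------------------------
    kp_rate = config.keypoint_rate
    frame_times = np.arange(0.0, session_span, 1.0 / kp_rate)
    fidx = np.clip(np.searchsorted(t_start, frame_times, side="right") - 1,
                   0, n_trials - 1)
    relf = frame_times - t_onset[fidx]
    mu_pup = timeline["mu_pupil_diameter"].to_numpy()[fidx]
    mu_eye = timeline["mu_eyelid_aperture"].to_numpy()[fidx]
    resp_sign = np.select(
        [outcomes[fidx] == "hit", outcomes[fidx] == "false_alarm"],
        [-1.0, 1.0], 0.0)
    slope = resp_sign * 0.03 * np.clip(relf / 3.0, 0.0, 1.0) * (relf > 0)
    pup_d = mu_pup + slope + rng.normal(0.0, 0.01, frame_times.size)
    eye_d = mu_eye - slope + rng.normal(0.0, 0.015, frame_times.size)
    center_p = np.column_stack([np.full(frame_times.size, 3.0),
                                np.full(frame_times.size, 2.0)])
    center_e = center_p
    jit_p = rng.normal(0.0, 0.004, (frame_times.size, 8, 2))
    jit_e = rng.normal(0.0, 0.004, (frame_times.size, 8, 2))
    # no vertical jitter on the top/bottom vertices: the octagon's
    # top-bottom extent then equals the intended diameter exactly
    jit_p[:, [2, 6], 1] = 0.0
    jit_e[:, [2, 6], 1] = 0.0
    pupil_points = _octagon(center_p, pup_d / 2.0, jit_p)
    eyelid_points = _octagon(center_e, eye_d / 2.0, jit_e)

    # --- electrophysiology epochs ------------------------------------------
    t0, t1 = config.epoch_window
    n_lfp = int(round((t1 - t0) * probe.lfp_rate))
    n_raw = int(round((t1 - t0) * probe.raw_rate))
    t_lfp = t0 + np.arange(n_lfp) / probe.lfp_rate
    t_raw = t0 + np.arange(n_raw) / probe.raw_rate
    depths = probe.depths_mm
    # spatial patterns
    d_gauss = np.exp(-0.5 * ((depths - config.dipole_depth_mm) / 0.06) ** 2)
    dipole_pattern = np.gradient(d_gauss, depths)       # sink/source pair
    dmax = np.max(np.abs(dipole_pattern))
    if dmax > 0:
        dipole_pattern = dipole_pattern / dmax
    landmark_gain = np.exp(
        -0.5 * ((depths - config.landmark_depth_mm) / 0.05) ** 2)
    lfp_wave = _dipole_waveform(t_lfp)
    burst_win = ((t_raw >= 0.01) & (t_raw <= 0.10)).astype(float)

    if not include_ephys:        # motor/eye-only sessions (0-channel epochs)
        return SessionStreams(
            lick_times=lick_times, encoder_voltage=encoder_voltage,
            encoder_rate=enc_rate, frame_times=frame_times,
            pupil_points=pupil_points, eyelid_points=eyelid_points,
            lfp_epochs=np.empty((n_trials, 0, n_lfp), dtype=np.float32),
            raw_epochs=np.empty((n_trials, 0, n_raw), dtype=np.float32),
            lfp_rate=probe.lfp_rate, raw_rate=probe.raw_rate,
            epoch_window=config.epoch_window, channel_depths_mm=depths)

    mu_pss = timeline["mu_prestim_pss"].to_numpy()
    mu_evk = timeline["mu_evoked_lfp"].to_numpy()
    mu_mua = timeline["mu_prestim_mua_power"].to_numpy()
    mu_emu = timeline["mu_evoked_mua"].to_numpy()
    lfp_epochs = np.empty((n_trials, probe.n_channels, n_lfp), dtype=np.float32)
    raw_epochs = np.empty((n_trials, probe.n_channels, n_raw), dtype=np.float32)
    for i in range(n_trials):
        alpha = -mu_pss[i]
        bg = powerlaw_noise(n_lfp, alpha, rng, scale=20.0,
                            n_channels=probe.n_channels)
        amp = mu_evk[i]
        evoked = lfp_wave[None, :] * (
            0.6 * amp + 0.8 * abs(amp) * dipole_pattern[:, None])
        lfp_epochs[i] = bg + evoked
        noise = rng.standard_normal((probe.n_channels, n_raw)) * max(mu_mua[i], 0.1)
        burst = (rng.standard_normal((probe.n_channels, n_raw))
                 * (max(mu_emu[i], 0.0) * landmark_gain[:, None])
                 * burst_win[None, :])
        raw_epochs[i] = noise + burst

    return SessionStreams(
        lick_times=lick_times, encoder_voltage=encoder_voltage,
        encoder_rate=enc_rate, frame_times=frame_times,
        pupil_points=pupil_points, eyelid_points=eyelid_points,
        lfp_epochs=lfp_epochs, raw_epochs=raw_epochs,
        lfp_rate=probe.lfp_rate, raw_rate=probe.raw_rate,
        epoch_window=config.epoch_window, channel_depths_mm=depths)


# ---------------------------------------------------------------------------
# fast feature-level path and full dataset assembly
# ---------------------------------------------------------------------------

def gen_feature_table(timeline: pd.DataFrame, trials: pd.DataFrame,
                      config: MouseConfig,
                      rng: int | np.random.Generator = 0) -> pd.DataFrame:
    """Per-trial nonperformance table drawn directly from the timeline.

    Uses the same state couplings as the stream synthesis but skips
    waveform rendering; intended for classifier-focused experiments where
    only the trial-level variables matter.
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    out = trials[["day", "trial", "trial_type", "outcome", "punished",
                  "latent_state"]].copy()
    for var in cfg.NONPERFORMANCE_VARS:
        coup = config.feature_coupling[var]
        mu = timeline[f"mu_{var}"].to_numpy()
        if var == "prestim_lick_rate":
            out[var] = rng.poisson(np.clip(mu, 0.0, None)).astype(float)
        else:
            out[var] = mu + rng.normal(0.0, coup.spread, len(timeline))
    resp = out["outcome"].isin(["hit", "false_alarm"]).to_numpy()
    base = timeline["mu_prestim_lick_rate"].to_numpy() * 0.8
    out["whole_trial_lick_rate"] = np.clip(
        base + resp * rng.normal(2.2, 0.4, len(out)), 0.0, None)
    out["correctness"] = out["outcome"].isin(
        ["hit", "correct_rejection"]).astype(int)
    return out


def gen_mouse(config: MouseConfig, with_streams: bool = True,
              include_ephys: bool = True) -> MouseData:
    """Generate one mouse: timeline, trials and (optionally) all streams."""
    rng = np.random.default_rng(config.seed)
    timeline = gen_state_timeline(config, rng)
    trials = gen_trials(timeline, config, rng)
    streams: Dict[int, SessionStreams] = {}
    if with_streams:
        for day in range(1, config.n_sessions + 1):
            m = trials["day"] == day
            streams[day] = gen_session_streams(
                timeline[m.to_numpy()].reset_index(drop=True),
                trials[m].reset_index(drop=True), config, rng,
                include_ephys=include_ephys)
    per_session_corr = (
        trials.assign(c=trials["outcome"].isin(["hit", "correct_rejection"]))
        .groupby("day")["c"].mean().tolist())
    truth = SyntheticTruth(
        state_means={v: dict(config.feature_coupling[v].means)
                     for v in cfg.NONPERFORMANCE_VARS},
        session_correctness=per_session_corr,
        dipole_depth_mm=config.dipole_depth_mm,
        landmark_depth_mm=config.landmark_depth_mm)
    return MouseData(config=config, trials=trials, streams=streams,
                     truth=truth)


def gen_dataset(mouse_configs: List[MouseConfig],
                with_streams: bool = True,
                include_ephys: bool = True) -> Dict[str, MouseData]:
    """Deterministic multi-mouse bundle keyed by mouse id."""
    if not mouse_configs:
        raise ValueError("need at least one MouseConfig")
    ids = [c.mouse_id for c in mouse_configs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate mouse_id in configs: {ids}")
    return {c.mouse_id: gen_mouse(c, with_streams, include_ephys)
            for c in mouse_configs}


def default_mouse_configs(n_mice: int = 5, seed: int = 0,
                          **overrides) -> List[MouseConfig]:
    """Five virtual mice, 12–14 sessions each, seeds fanned out from ``seed``."""
    session_counts = [14, 13, 12, 14, 13]
    configs = []
    for i in range(n_mice):
        configs.append(MouseConfig(
            mouse_id=f"m{i + 1}",
            n_sessions=overrides.get("n_sessions",
                                     session_counts[i % len(session_counts)]),
            seed=seed * 1009 + i * 101 + 7,
            **{k: v for k, v in overrides.items() if k != "n_sessions"}))
    return configs
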