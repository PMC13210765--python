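"""Synthetic EEG and a closed-loop regulating agent.

The generator produces 1/f ("pink") background noise per channel by
spectral shaping — a 1/sqrt(f) amplitude profile with random phases — so
the log-PSD slope is exact by construction.  Band-limited oscillations
(frontal theta, central SMR) are injected as sinusoids with arbitrary
instantaneous-amplitude envelopes, and an instantaneous mixing operator
provides zero-lag volume-conduction fixtures for connectivity tests.

``simulate_closed_loop_session`` co-simulates the full training protocol
(calibration, then 4 blocks x 10 self-paced shots) against the real-time
feature extractor, the adaptive threshold staircase and the five-level
feedback mapper.  A simple regulating agent stands in for the human
learner: after every feedback event it moves its target-band amplitude by
``gain * max(level - 3, 0)`` dB in the improving direction (down for
suppression, up for enhancement) plus Gaussian noise, with an occasional
lapse, and its amplitude is floored at 0 uV.  The rectified level error
models operant learning: the learner corrects the deviations the sound
signals and holds an achieved good state instead of relaxing back toward
the threshold (an unrectified error term would regulate the feature onto
the threshold itself and freeze the staircase near 50% success).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .control import (
    BlockRecord,
    ThresholdState,
    TrialRecord,
    compute_baseline,
    evaluate_trial,
    initial_threshold,
    update_after_block,
)
from .feedback import GuardState, guarded_level, in_level3_zone, raw_level
from .realtime import BandDefinition, SMR, THETA, filter_for_band, window_feature_db
from .recording import DEFAULT_MONTAGE_32, EEGRecording


def gen_background(
    n_channels: int,
    duration: float,
    rate: float = 1000.0,
    seed: int | np.random.SeedSequence = 0,
    rms_uv: float = 10.0,
    labels: tuple[str, ...] | None = None,
) -> EEGRecording:
    """Zero-mean pink-noise background, ``rms_uv`` microvolts RMS per channel.

    Spectral shaping: amplitude proportional to f**-0.5 (power ~ 1/f) with
    phases drawn uniformly, independently per channel; bitwise reproducible
    for a fixed seed.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    phases = rng.uniform(0, 2 * np.pi, size=(n_channels, freqs.size))
    spec = amp * np.exp(1j * phases)
    spec[:, 0] = 0.0
    if n % 2 == 0:
        spec[:, -1] = spec[:, -1].real  # Nyquist bin must be real
    data = np.fft.irfft(spec, n=n, axis=1)
    data -= data.mean(axis=1, keepdims=True)
    data *= rms_uv / data.std(axis=1, keepdims=True)
    if labels is None:
        labels = tuple(DEFAULT_MONTAGE_32[:n_channels]) if n_channels <= 32 else tuple(
            f"ch{i:02d}" for i in range(n_channels)
        )
    return EEGRecording(data=data, rate=rate, labels=labels)


def inject_oscillation(
    rec: EEGRecording,
    channel: str,
    freq: float,
    amplitude_envelope: np.ndarray,
    phase: float = 0.0,
) -> EEGRecording:
    """Add a sinusoid with per-sample instantaneous amplitude to one channel."""
    if not 0 < freq < rec.rate / 2:
        raise ValueError(f"freq {freq} outside (0, Nyquist={rec.rate / 2})")
    env = np.asarray(amplitude_envelope, dtype=float)
    if env.shape != (rec.n_samples,):
        raise ValueError("envelope length must equal sample count")
    out = rec.copy()
    i = out.channel_index(channel)
    t = np.arange(rec.n_samples) / rec.rate
    out.data[i] += env * np.sin(2 * np.pi * freq * t + phase)
    return out


def mix_instantaneous(sources: EEGRecording, mixing: np.ndarray, labels=None) -> EEGRecording:
    """Zero-lag weighted sums of source channels (volume-conduction fixture)."""
    mixing = np.asarray(mixing, dtype=float)
    if mixing.ndim != 2 or mixing.shape[1] != sources.n_channels:
        raise ValueError(
            f"mixing must be (n_out, {sources.n_channels}), got {mixing.shape}"
        )
    data = mixing @ sources.data
    if labels is None:
        if mixing.shape[0] == sources.n_channels:
            labels = sources.labels
        else:
            labels = tuple(f"mix{i:02d}" for i in range(mixing.shape[0]))
    return EEGRecording(data=data, rate=sources.rate, labels=tuple(labels),
                        events=list(sources.events), start_time=sources.start_time)


# ---------------------------------------------------------------------------
# Closed-loop co-simulation


@dataclass(frozen=True)
class AgentParams:
    """Regulating agent standing in for the human learner."""

    gain: float = 0.2          # dB of amplitude change per unit level error per shot
    noise_sd: float = 0.3      # dB random walk component
    baseline_amp: float = 6.0  # uV starting amplitude of the target-band oscillation
    lapse_prob: float = 0.1    # probability of ignoring a feedback event

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.lapse_prob <= 1:
            raise ValueError("lapse_prob must be in [0, 1]")


@dataclass(frozen=True)
class Protocol:
    """Training-session protocol (defaults follow the study design)."""

    mode: Literal["theta-suppress", "smr-enhance"] = "theta-suppress"
    n_blocks: int = 4
    shots_per_block: int = 10
    isi_range_s: tuple[float, float] = (6.0, 12.0)
    calibration_s: float = 60.0
    rate: float = 1000.0
    n_channels: int = 32
    filter_order: int = 180
    step_sigma_frac: float = 0.75
    success_criterion: float = 0.7
    background_rms_uv: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("theta-suppress", "smr-enhance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_blocks < 1 or self.shots_per_block < 1:
            raise ValueError("shot counts must be positive")

    @property
    def band(self) -> BandDefinition:
        return THETA if self.mode == "theta-suppress" else SMR

    @property
    def n_shots(self) -> int:
        return self.n_blocks * self.shots_per_block


@dataclass
class SessionRecording:
    """Full closed-loop run: signal, feedback stream and engine state logs."""

    recording: EEGRecording
    feedback_log: list[tuple[float, int, float]]          # (time_s, level, feature_dB)
    trial_log: list[TrialRecord]
    block_log: list[BlockRecord]
    threshold_history: list[ThresholdState]
    baseline_mu: float = 0.0
    baseline_sigma: float = 0.0
    agent_amplitude_log: list[tuple[float, float]] = field(default_factory=list)


def _draw_fire_times(protocol: Protocol, rng: np.random.Generator) -> np.ndarray:
    lo, hi = protocol.isi_range_s
    isis = rng.uniform(lo, hi, size=protocol.n_shots)
    return protocol.calibration_s + np.cumsum(isis)


def simulate_closed_loop_session(
    agent: AgentParams,
    protocol: Protocol = Protocol(),
    seed: int | np.random.SeedSequence = 0,
) -> SessionRecording:
    """Run one full closed-loop session against the live engine.

    The session advances on the 1 s feature clock.  Each second the signal
    for that second is composed (pink background + target-band sinusoid at
    the agent's current amplitude), the feature is extracted exactly as the
    real-time path does, a feedback level is emitted through the guard
    logic, and the agent reacts.  Shots fire self-paced at uniform 6-12 s
    spacing; each is evaluated with the two-of-four rule at the threshold
    in force, and the staircase runs after every block.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_noise, s_agent, s_isi = ss.spawn(3)
    rng_agent = np.random.default_rng(s_agent)

    band = protocol.band
    mode = band.mode
    rate = protocol.rate
    filt = filter_for_band(band, rate, protocol.filter_order)
    fire_times = _draw_fire_times(protocol, np.random.default_rng(s_isi))
    duration = float(np.ceil(fire_times[-1] + 2.0))
    n_sec = int(duration)

    background = gen_background(
        protocol.n_channels, duration, rate, s_noise, protocol.background_rms_uv
    )
    data = background.data
    ch = background.labels.index(band.channel)
    t_all = np.arange(background.n_samples) / rate
    carrier = np.sin(2 * np.pi * (band.f_lo + band.f_hi) / 2.0 * t_all)

    spb = int(round(rate))
    amp = float(agent.baseline_amp)
    amp_log: list[tuple[float, float]] = []
    features: list[float] = []
    feedback_log: list[tuple[float, int, float]] = []
    cal_features: list[float] = []
    state: ThresholdState | None = None
    guard = GuardState()
    trial_log: list[TrialRecord] = []
    block_log: list[BlockRecord] = []
    threshold_history: list[ThresholdState] = []
    mu = sigma = 0.0
    shot_idx = 0
    block_trials: list[TrialRecord] = []

    for sec in range(n_sec):
        i0, i1 = sec * spb, (sec + 1) * spb
        data[ch, i0:i1] += amp * carrier[i0:i1]
        amp_log.append((float(sec), amp))
        window = data[ch, i0:i1]
        ctx = data[ch, max(0, i0 - filt.order):i0]
        feat = window_feature_db(window, filt, pre_context=ctx if ctx.size else None)
        now = float(sec + 1)
        features.append(feat)

        if now <= protocol.calibration_s:
            cal_features.append(feat)
            if now == protocol.calibration_s:
                stats = compute_baseline(cal_features)
                mu, sigma = stats.mu, stats.sigma
                state = initial_threshold(stats, mode, step=protocol.step_sigma_frac * sigma)
                threshold_history.append(state)
            continue

        assert state is not None
        level = guarded_level(raw_level(feat, state), guard, in_level3_zone(feat, state))
        feedback_log.append((now, level, feat))

        # shots that fired within this second
        fired_this_second = False
        while shot_idx < protocol.n_shots and fire_times[shot_idx] <= now:
            fired_this_second = True
            ft = fire_times[shot_idx]
            i_fire = int(round(ft * rate))
            seg = data[ch, i_fire - int(round(3.5 * rate)):i_fire]
            trial = evaluate_trial(seg, rate, state, band, filt, fire_time_s=float(ft))
            trial_log.append(trial)
            block_trials.append(trial)
            shot_idx += 1
            if len(block_trials) == protocol.shots_per_block:
                block = BlockRecord(tuple(block_trials), threshold_before=state.threshold)
                state = update_after_block(
                    block, state, block_index=len(block_log),
                    success_criterion=protocol.success_criterion,
                )
                block = BlockRecord(block.trials, block.threshold_before, state.threshold)
                block_log.append(block)
                threshold_history.append(state)
                block_trials = []

        # agent reaction to the feedback heard around the shot: correct
        # deviations the sound signals (level > 3), hold an achieved good
        # state (level <= 3) rather than relaxing back toward threshold
        if fired_this_second and rng_agent.random() >= agent.lapse_prob:
            sign = -1.0 if mode == "suppress" else 1.0
            err = max(level - 3, 0)
            delta_db = sign * agent.gain * err + rng_agent.normal(0.0, agent.noise_sd)
            amp = max(0.0, amp * 10.0 ** (delta_db / 20.0))

    rec = EEGRecording(
        data=data,
        rate=rate,
        labels=background.labels,
        events=[(float(t), "fire") for t in fire_times],
    )
    return SessionRecording(
        recording=rec,
        feedback_log=feedback_log,
        trial_log=trial_log,
        block_log=block_log,
        threshold_history=threshold_history,
        baseline_mu=mu,
        baseline_sigma=sigma,
        agent_amplitude_log=amp_log,
    )


def blockwise_mean_feature(session: SessionRecording) -> np.ndarray:
    """Mean of the four evaluation-window features per block (the block-level
    learning trajectory of the target feature)."""
    out = []
    for block in session.block_log:
        vals = [v for tr in block.trials for v in tr.window_values]
        out.append(float(np.mean(vals)))
    return np.asarray(out)
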