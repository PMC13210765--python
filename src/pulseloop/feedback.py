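"""Five-level heartbeat-sound feedback: zone mapping, guard-band hysteresis
and audio rendering.

The feature axis is split into five zones by the four boundaries at
threshold +/- 0.5 sigma and +/- 1.0 sigma.  Level 1 is always the optimal
state — highest power in enhancement mode, lowest power in suppression
mode — so the zone order is inverted between the two modes.  The sound
follows "better state, quieter feedback": a soft slow single beat at Level
1, escalating to a loud fast triple beat at Level 5.

Acoustic parameters per level (volume coefficients are ratios of the
template amplitude; playback rate is a resampling multiplier; multi-beat
bursts attenuate across beats):

    level  volumes              rate   beats  gap_ms  fade_ms
    1      0.20                 0.55   1      -       150/150
    2      0.35                 0.70   1      -       100/100
    3      0.60                 0.85   1      -       60/60
    4      0.90, 0.60           1.10   2      80      40/40
    5      1.00, 0.75, 0.50     1.30   3      60      30/30
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .control import ThresholdState


@dataclass(frozen=True)
class AcousticParams:
    level: int
    volume_coeffs: tuple[float, ...]
    rate_multiplier: float
    n_beats: int
    beat_interval_ms: float
    fade_in_ms: float
    fade_out_ms: float


_LEVEL_TABLE: dict[int, AcousticParams] = {
    1: AcousticParams(1, (0.20,), 0.55, 1, 0.0, 150.0, 150.0),
    2: AcousticParams(2, (0.35,), 0.70, 1, 0.0, 100.0, 100.0),
    3: AcousticParams(3, (0.60,), 0.85, 1, 0.0, 60.0, 60.0),
    4: AcousticParams(4, (0.90, 0.60), 1.10, 2, 80.0, 40.0, 40.0),
    5: AcousticParams(5, (1.00, 0.75, 0.50), 1.30, 3, 60.0, 30.0, 30.0),
}


def acoustic_params(level: int) -> AcousticParams:
    if level not in _LEVEL_TABLE:
        raise ValueError(f"feedback level must be 1..5, got {level}")
    return _LEVEL_TABLE[level]


def raw_level(feature_db: float, state: ThresholdState) -> int:
    """Map a feature to its zone's level, with mode inversion.

    Zones are half-open with inclusive lower bounds on the power axis.
    In suppression mode low power is optimal (zone below b1 -> Level 1);
    in enhancement mode high power is optimal (zone at/above b4 -> Level 1).
    """
    b1, b2, b3, b4 = state.boundaries
    f = float(feature_db)
    if f < b1:
        zone = 0
    elif f < b2:
        zone = 1
    elif f < b3:
        zone = 2
    elif f < b4:
        zone = 3
    else:
        zone = 4
    if state.mode == "suppress":
        return zone + 1
    return 5 - zone


def in_level3_zone(feature_db: float, state: ThresholdState) -> bool:
    """Guard band: threshold +/- 0.5 sigma (the Level-3 zone)."""
    _, b2, b3, _ = state.boundaries
    return b2 <= feature_db < b3


@dataclass
class GuardState:
    current_level: int = 3

    def __post_init__(self) -> None:
        if self.current_level not in range(1, 6):
            raise ValueError("level must be in 1..5")


def guarded_level(raw: int, guard: GuardState, in_l3_zone: bool) -> int:
    """Hysteresis around the threshold.

    While the feature sits in the Level-3 zone, levels 2-4 are held and the
    extreme levels 1 and 5 step one level toward 3, so small fluctuations
    near threshold never flip the sound.  Outside the zone the emitted
    level jumps straight to the raw zone level, signalling large
    deviations promptly.  ``guard`` is updated in place.
    """
    if raw not in range(1, 6):
        raise ValueError("raw level must be in 1..5")
    cur = guard.current_level
    if in_l3_zone:
        if cur in (2, 3, 4):
            new = cur
        elif cur == 1:
            new = 2
        else:  # cur == 5
            new = 4
    else:
        new = raw
    guard.current_level = new
    return new


# ---------------------------------------------------------------------------
# Audio


def synth_heartbeat_template(rate: int = 8000, duration: float = 0.4, f0: float = 55.0) -> np.ndarray:
    """Synthetic single-beat heartbeat template, peak-normalized to 1.0.

    A low-frequency tone under a gamma-shaped envelope peaking ~150 ms in,
    emulating the dull thump of a recorded heartbeat.  Synthetic stand-in
    for a recorded template WAV; any mono waveform can replace it.
    """
    t = np.arange(int(round(rate * duration))) / rate
    tau = 0.15
    env = (t / tau) ** 2 * np.exp(2.0 * (1.0 - t / tau))
    x = env * np.sin(2 * np.pi * f0 * t)
    return x / np.max(np.abs(x))


def render_feedback(
    params: AcousticParams,
    template: np.ndarray,
    template_rate: float,
    out_rate: float = 8000.0,
) -> np.ndarray:
    """Render one feedback burst from the heartbeat template.

    The template is polyphase-resampled by ``1/rate_multiplier`` (pitch
    shifts with rate, as with naive playback-rate change), repeated
    ``n_beats`` times with the level's silence gap, each beat scaled by its
    volume coefficient, and the whole burst shaped by linear fade-in/out.
    """
    template = np.asarray(template, dtype=float)
    if template.size == 0:
        raise ValueError("empty template")
    if out_rate <= 0:
        raise ValueError("out_rate must be positive")
    factor = Fraction(out_rate / (template_rate * params.rate_multiplier)).limit_denominator(1000)
    beat = signal.resample_poly(template, factor.numerator, factor.denominator)
    # resample_poly rounds the length up; pin it to the nearest-sample target
    n_beat = int(round(template.size * out_rate / (template_rate * params.rate_multiplier)))
    beat = beat[:n_beat] if beat.size >= n_beat else np.pad(beat, (0, n_beat - beat.size))
    gap = np.zeros(int(round(params.beat_interval_ms / 1000.0 * out_rate)))
    pieces: list[np.ndarray] = []
    for k in range(params.n_beats):
        if k > 0:
            pieces.append(gap)
        pieces.append(params.volume_coeffs[k] * beat)
    burst = np.concatenate(pieces)
    n_in = int(round(params.fade_in_ms / 1000.0 * out_rate))
    n_out = int(round(params.fade_out_ms / 1000.0 * out_rate))
    if n_in + n_out > burst.size:
        raise ValueError("fades longer than rendered burst")
    env = np.ones(burst.size)
    if n_in:
        env[:n_in] = np.arange(n_in) / n_in
    if n_out:
        env[-n_out:] = np.arange(n_out, 0, -1) / n_out
    out = burst * env
    np.clip(out, -1.0, 1.0, out=out)
    return out
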