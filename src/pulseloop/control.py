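"""Adaptive threshold logic: baseline statistics, initial thresholds, the
two-of-four trial rule, inter-shot dedup and the block-level staircase.

Thresholds start lenient — mu + 0.5 sigma for theta suppression, mu - 0.5
sigma for SMR enhancement — so early trials succeed easily.  After each
10-trial block with success rate >= 70% the threshold is stepped in the
stricter direction (down for suppression, up for enhancement) and the five
feedback-level boundaries (threshold +/- 0.5 sigma and +/- 1.0 sigma, with
the calibration sigma frozen for the session) are recomputed.

Trial success looks back at the 3 s before the firing trigger through four
overlapping 1 s sub-windows at 500 ms spacing, the last ending 500 ms
before the shot to stay clear of movement artifact; a trial succeeds when
at least two sub-windows satisfy the threshold condition.  A non-overlapping
three-window variant (two-of-three over [-3,-2], [-2,-1], [-1,0] s) is kept
as a robustness scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .realtime import BandDefinition, FilterSpec, window_feature_db

Mode = Literal["suppress", "enhance"]

#: Sub-window start offsets (s relative to firing) for the two schemes.
OVERLAP4_STARTS = (-3.0, -2.5, -2.0, -1.5)
NONOVERLAP3_STARTS = (-3.0, -2.0, -1.0)


class InsufficientDataError(ValueError):
    pass


class DegenerateBaselineError(ValueError):
    pass


@dataclass(frozen=True)
class BaselineStats:
    """Calibration-phase mean and sample SD of the target-band feature (dB)."""

    mu: float
    sigma: float
    n: int


def compute_baseline(features: Sequence[float]) -> BaselineStats:
    x = np.asarray(features, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need at least 2 calibration features")
    mu = float(x.mean())
    sigma = float(x.std(ddof=1))
    if sigma == 0.0:
        raise DegenerateBaselineError("calibration features have zero variance")
    return BaselineStats(mu=mu, sigma=sigma, n=int(x.size))


def _boundaries(threshold: float, sigma: float) -> tuple[float, float, float, float]:
    return (
        threshold - 1.0 * sigma,
        threshold - 0.5 * sigma,
        threshold + 0.5 * sigma,
        threshold + 1.0 * sigma,
    )


@dataclass(frozen=True)
class ThresholdState:
    """Current threshold plus the frozen sigma, level boundaries and history."""

    threshold: float
    sigma: float
    mode: Mode
    step: float
    boundaries: tuple[float, float, float, float]
    history: tuple[tuple[int, float], ...] = ()

    def with_threshold(self, threshold: float, block_index: int) -> "ThresholdState":
        return replace(
            self,
            threshold=threshold,
            boundaries=_boundaries(threshold, self.sigma),
            history=self.history + ((block_index, threshold),),
        )


def initial_threshold(stats: BaselineStats, mode: Mode, step: float | None = None) -> ThresholdState:
    """Lenient initial threshold: mu + 0.5 sigma (suppress) or mu - 0.5 sigma
    (enhance).  Default staircase step is 0.75 sigma (see the methods note
    on the operating zone); pass ``step`` to override."""
    if mode not in ("suppress", "enhance"):
        raise ValueError(f"unknown mode {mode!r}")
    if stats.sigma <= 0:
        raise DegenerateBaselineError("sigma must be positive")
    thr = stats.mu + 0.5 * stats.sigma if mode == "suppress" else stats.mu - 0.5 * stats.sigma
    if step is None:
        step = 0.75 * stats.sigma
    return ThresholdState(
        threshold=thr,
        sigma=stats.sigma,
        mode=mode,
        step=float(step),
        boundaries=_boundaries(thr, stats.sigma),
    )


def dedup_firing_events(times: Sequence[float], min_interval: float = 3.0) -> list[float]:
    """Greedily keep events at least ``min_interval`` apart (spurious duplicate
    trigger suppression)."""
    out: list[float] = []
    prev = -math.inf
    last_kept = -math.inf
    for t in times:
        if t < prev:
            raise ValueError("event times must be ascending")
        prev = t
        if t - last_kept >= min_interval:
            out.append(t)
            last_kept = t
    return out


def meets_criterion(value_db: float, state: ThresholdState) -> bool:
    """Strict threshold comparison: below for suppression, above for enhancement."""
    if state.mode == "suppress":
        return value_db < state.threshold
    return value_db > state.threshold


@dataclass(frozen=True)
class TrialRecord:
    fire_time_s: float
    window_values: tuple[float, ...]
    hits: int
    success: bool


def success_from_hits(hits: int, n_windows: int) -> bool:
    """Trial success rule: at least two sub-windows meet the criterion."""
    if not 0 <= hits <= n_windows:
        raise ValueError("hits out of range")
    return hits >= 2


def evaluate_windows(values_db: Sequence[float], state: ThresholdState, fire_time_s: float = 0.0) -> TrialRecord:
    """Apply the threshold criterion to precomputed sub-window features."""
    hits = sum(meets_criterion(v, state) for v in values_db)
    return TrialRecord(
        fire_time_s=fire_time_s,
        window_values=tuple(float(v) for v in values_db),
        hits=hits,
        success=success_from_hits(hits, len(tuple(values_db))),
    )


def evaluate_trial(
    segment: np.ndarray,
    rate: float,
    state: ThresholdState,
    band: BandDefinition,
    filt: FilterSpec,
    fire_time_s: float = 0.0,
    scheme: str = "overlap4",
) -> TrialRecord:
    """Evaluate one shot from the single-channel segment that ends at the
    firing instant.

    ``segment`` must cover at least the 3.5 s before firing (margin beyond
    the 3 s evaluation span).  Each sub-window runs through the same
    detrend -> FIR -> log-power pipeline as the live feature extractor.
    """
    if scheme == "overlap4":
        starts = OVERLAP4_STARTS
    elif scheme == "nonoverlap3":
        starts = NONOVERLAP3_STARTS
    else:
        raise ValueError(f"unknown window scheme {scheme!r}")
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValueError("segment must be single-channel (1-D)")
    n = segment.size
    need = int(round(3.5 * rate))
    if n < need:
        raise InsufficientDataError(f"segment must cover >= 3.5 s pre-fire ({need} samples)")
    w = int(round(rate))
    values = []
    for s in starts:
        i0 = n + int(round(s * rate))
        ctx = segment[max(0, i0 - filt.order):i0]
        values.append(window_feature_db(segment[i0:i0 + w], filt, pre_context=ctx))
    return evaluate_windows(values, state, fire_time_s)


@dataclass(frozen=True)
class BlockRecord:
    trials: tuple[TrialRecord, ...]
    threshold_before: float
    threshold_after: float | None = None

    @property
    def success_rate(self) -> float:
        if not self.trials:
            return 0.0
        return sum(t.success for t in self.trials) / len(self.trials)


def update_after_block(
    block: BlockRecord,
    state: ThresholdState,
    block_index: int,
    success_criterion: float = 0.7,
) -> ThresholdState:
    """Staircase: when block success rate reaches the criterion (>= 70%),
    tighten the threshold by one step; otherwise keep it.  History is
    appended either way and boundaries track the (frozen-sigma) threshold."""
    thr = state.threshold
    if block.success_rate >= success_criterion:
        thr = thr - state.step if state.mode == "suppress" else thr + state.step
    return state.with_threshold(thr, block_index)
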