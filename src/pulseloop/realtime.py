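"""Real-time signal path: circular buffer, windowing, FIR filtering and
log-power features.

The online system extracts, once per second, the most recent 1 s of the
target channel from a 3 s circular buffer, removes a least-squares linear
trend, applies a 180th-order linear-phase FIR bandpass (theta 4-7 Hz at Fz
or SMR 12-15 Hz at Cz), and quantifies the window as

    P_dB = 10 * log10( (1/N) * sum(x_i^2) )

with N = 1000 samples at 1000 Hz.  Windows do not overlap (update step =
window length = 1 s), so consecutive features are exactly 1 s apart.

The FIR is applied causally; its state is warmed with the samples that
immediately precede the window (which the circular buffer always holds, as
would any streaming implementation), so the window is filter-settled and no
part of it is trimmed before the power computation.  No group-delay
compensation is applied — a causal system cannot — so the feature lags the
signal by order/2 samples (90 ms at the defaults); tests account for the
delay rather than the path hiding it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np
from scipy import signal

from .recording import EEGRecording


class DegenerateSignalError(ValueError):
    """Raised when a window is identically zero and has no defined log-power."""


class UnderfilledBufferError(RuntimeError):
    """Raised when more samples are requested than the buffer has received."""


# ---------------------------------------------------------------------------
# Band definitions


@dataclass(frozen=True)
class BandDefinition:
    """A trainable frequency band bound to a channel and a regulation mode."""

    name: str
    f_lo: float
    f_hi: float
    channel: str
    mode: Literal["suppress", "enhance"]

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("require 0 < f_lo < f_hi")
        if self.mode not in ("suppress", "enhance"):
            raise ValueError(f"unknown mode {self.mode!r}")


#: Frontal-midline theta: suppression target at Fz.
THETA = BandDefinition("theta", 4.0, 7.0, "Fz", "suppress")
#: Sensorimotor rhythm: enhancement target at Cz.
SMR = BandDefinition("smr", 12.0, 15.0, "Cz", "enhance")


# ---------------------------------------------------------------------------
# FIR design


@dataclass(frozen=True)
class FilterSpec:
    """Linear-phase FIR bandpass (type I, even order, symmetric taps)."""

    order: int
    coefficients: np.ndarray
    band: tuple[float, float]
    rate: float

    @property
    def group_delay_samples(self) -> float:
        return self.order / 2.0


def design_fir_bandpass(order: int, f_lo: float, f_hi: float, rate: float) -> FilterSpec:
    """Hamming windowed-sinc bandpass with ``order + 1`` symmetric taps.

    An even order yields a type-I linear-phase filter whose group delay is
    exactly ``order/2`` samples at all frequencies.
    """
    if order % 2 != 0 or order <= 0:
        raise ValueError("order must be a positive even integer")
    nyq = rate / 2.0
    if not 0 < f_lo < f_hi < nyq:
        raise ValueError(f"band ({f_lo}, {f_hi}) must lie inside (0, {nyq})")
    h = signal.firwin(order + 1, [f_lo, f_hi], pass_zero=False, window="hamming", fs=rate)
    return FilterSpec(order=order, coefficients=h, band=(f_lo, f_hi), rate=rate)


def filter_for_band(band: BandDefinition, rate: float = 1000.0, order: int = 180) -> FilterSpec:
    return design_fir_bandpass(order, band.f_lo, band.f_hi, rate)


# ---------------------------------------------------------------------------
# Window primitives


def detrend_linear(window: np.ndarray) -> np.ndarray:
    """Remove the least-squares straight line (offset + drift) from a window."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.size < 2:
        raise ValueError("window must be 1-D with at least 2 samples")
    n = window.size
    t = np.arange(n, dtype=float)
    t -= t.mean()
    slope = (t @ window) / (t @ t)
    return window - window.mean() - slope * t


def log_power_db(window: np.ndarray) -> float:
    """Mean-square power of a window on the decibel scale."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("window must be non-empty")
    ms = float(np.mean(window**2))
    if ms == 0.0:
        raise DegenerateSignalError("all-zero window has no finite log-power")
    return float(10.0 * np.log10(ms))


def window_feature_db(
    window: np.ndarray, filt: FilterSpec, pre_context: np.ndarray | None = None
) -> float:
    """detrend -> causal FIR -> log-power, the per-window feature pipeline.

    ``pre_context`` (the samples immediately preceding the window, as a
    streaming filter would have seen) warms the FIR state so the window is
    filter-settled; the power is always taken over the full window, never
    trimmed.  Without context the filter starts from rest and the onset
    transient is included.
    """
    window = np.asarray(window, dtype=float)
    if pre_context is not None and len(pre_context) > 0:
        ctx = np.asarray(pre_context, dtype=float)[-filt.order:]
        x = detrend_linear(np.concatenate([ctx, window]))
        y = signal.lfilter(filt.coefficients, 1.0, x)[ctx.size:]
    else:
        y = signal.lfilter(filt.coefficients, 1.0, detrend_linear(window))
    return log_power_db(y)


# ---------------------------------------------------------------------------
# Circular buffer and streaming extraction


class RingBuffer:
    """Per-channel circular buffer holding the most recent ``capacity_s`` of data."""

    def __init__(self, n_channels: int, rate: float, capacity_s: float = 3.0) -> None:
        if n_channels < 1 or rate <= 0 or capacity_s <= 0:
            raise ValueError("invalid buffer dimensions")
        self.rate = float(rate)
        self.capacity = int(round(capacity_s * rate))
        self._buf = np.zeros((n_channels, self.capacity))
        self._written = 0

    @property
    def n_written(self) -> int:
        return self._written

    def append(self, chunk: np.ndarray) -> None:
        chunk = np.atleast_2d(np.asarray(chunk, dtype=float))
        if chunk.shape[0] != self._buf.shape[0]:
            raise ValueError("chunk channel count mismatch")
        k = chunk.shape[1]
        if k >= self.capacity:
            self._buf[:] = chunk[:, -self.capacity:]
        else:
            self._buf = np.roll(self._buf, -k, axis=1)
            self._buf[:, -k:] = chunk
        self._written += k

    def latest(self, n_samples: int) -> np.ndarray:
        """The most recent ``n_samples`` per channel; fails before fill."""
        if n_samples > self.capacity:
            raise ValueError("request exceeds buffer capacity")
        if self._written < n_samples:
            raise UnderfilledBufferError(
                f"buffer holds {self._written} samples, {n_samples} requested"
            )
        return self._buf[:, self.capacity - n_samples:].copy()


@dataclass(frozen=True)
class FeatureSample:
    """One 1 s band log-power value stamped at its window end time."""

    time_s: float
    band: str
    value_db: float
    n_samples: int


def extract_feature(
    buffer: RingBuffer,
    band: BandDefinition,
    filt: FilterSpec,
    now: float,
    channel_index: int,
) -> FeatureSample:
    """Feature from the most recent 1 s of the band's channel in the buffer."""
    if (filt.band[0], filt.band[1]) != (band.f_lo, band.f_hi):
        raise ValueError("filter band does not match band definition")
    n = int(round(buffer.rate))
    want = min(n + filt.order, buffer.capacity, buffer.n_written)
    chunk = buffer.latest(max(want, n))[channel_index]
    window, ctx = chunk[-n:], chunk[:-n]
    value = window_feature_db(window, filt, pre_context=ctx if ctx.size else None)
    return FeatureSample(time_s=now, band=band.name, value_db=value, n_samples=n)


def stream_features(
    rec: EEGRecording,
    band: BandDefinition,
    filt: FilterSpec,
    chunk_ms: float = 40.0,
    capacity_s: float = 3.0,
) -> Iterator[FeatureSample]:
    """Replay a recording through the buffer in small chunks, emitting one
    feature per second (non-overlapping cadence).

    Chunks emulate block-wise delivery from an acquisition stream; the
    feature clock ticks at exact 1 s boundaries of the recording.
    """
    ci = rec.channel_index(band.channel)
    buf = RingBuffer(rec.n_channels, rec.rate, capacity_s)
    chunk = max(1, int(round(chunk_ms / 1000.0 * rec.rate)))
    per_second = int(round(rec.rate))
    next_emit = per_second
    for start in range(0, rec.n_samples, chunk):
        stop = min(start + chunk, rec.n_samples)
        buf.append(rec.data[:, start:stop])
        while buf.n_written >= next_emit and stop >= next_emit:
            now = rec.start_time + next_emit / rec.rate
            yield extract_feature(buf, band, filt, now, ci)
            next_emit += per_second
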