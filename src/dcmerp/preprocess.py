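"""Continuous LFP -> tone-offset-locked evoked responses.

Down-sample to 1 kHz with anti-alias filtering, zero-phase band-pass at
1-32 Hz, epoch on tone offsets and average, then keep the channel with
the largest peak-to-trough deflection inside the analysis window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .neural_mass import EvokedResponse

__all__ = [
    "RawRecording",
    "decimate",
    "bandpass",
    "epoch_average",
    "select_best_channel",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class RawRecording:
    """Multichannel continuous LFP with tone-offset event times."""

    samples: np.ndarray  # (n_channels, n_samples)
    rate: float  # Hz
    events: np.ndarray  # tone-offset times, seconds
    regions: tuple[str, ...] = field(default_factory=tuple)  # one label per channel

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.events = np.asarray(self.events, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be > 0")
        if np.any(np.diff(self.events) <= 0):
            raise ValueError("event times must be strictly increasing")
        dur = self.samples.shape[1] / self.rate
        if len(self.events) and (self.events[0] < 0 or self.events[-1] > dur):
            raise ValueError("events must lie inside the recording")
        if not self.regions:
            self.regions = tuple(f"ch{i}" for i in range(self.samples.shape[0]))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.rate


def decimate(recording: RawRecording, target_rate: float) -> RawRecording:
    """Anti-alias filter and down-sample to ``target_rate``.

    The decimation factor must be an integer; it is applied in stages of
    at most 10 with a zero-phase order-8 Butterworth low-pass at
    0.25 x the stage's target rate before each down-sampling step.
    Event times (seconds) are unchanged.
    """
    q = recording.rate / target_rate
    if abs(q - round(q)) > 1e-9:
        raise ValueError(
            f"decimation factor {q} is not an integer ({recording.rate} -> {target_rate} Hz)")
    q = int(round(q))
    x = recording.samples
    rate = recording.rate
    while q > 1:
        stage = min(q, 10)
        # prefer the largest stage factor <= 10 that divides q
        while q % stage:
            stage -= 1
        new_rate = rate / stage
        sos = signal.butter(8, 0.25 * new_rate, btype="low", fs=rate, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=1)[:, ::stage]
        rate = new_rate
        q //= stage
    return RawRecording(samples=x, rate=rate, events=recording.events.copy(),
                        regions=recording.regions)


def bandpass(recording: RawRecording, low: float = 1.0, high: float = 32.0) -> RawRecording:
    """Zero-phase order-4 Butterworth band-pass applied per channel."""
    if not 0 < low < high < recording.rate / 2:
        raise ValueError(
            f"band ({low}, {high}) Hz outside (0, Nyquist={recording.rate / 2}) Hz")
    sos = signal.butter(4, (low, high), btype="band", fs=recording.rate, output="sos")
    x = signal.sosfiltfilt(sos, recording.samples, axis=1)
    return RawRecording(samples=x, rate=recording.rate, events=recording.events.copy(),
                        regions=recording.regions)


def epoch_average(recording: RawRecording,
                  window_ms: tuple[float, float] = (1.0, 200.0)) -> list[EvokedResponse]:
    """Average event-locked epochs; one :class:`EvokedResponse` per channel.

    ``window_ms`` is relative to tone offset (t = 0).  Events whose window
    extends past the recording edge are dropped with a warning.
    """
    lo, hi = window_ms
    step_ms = 1000.0 / recording.rate
    offsets = np.arange(np.ceil(lo / step_ms), np.floor(hi / step_ms) + 1, dtype=int)
    time_ms = offsets * step_ms
    n = recording.samples.shape[1]
    usable, dropped = [], []
    for ev in recording.events:
        c = int(round(ev * recording.rate))
        if c + offsets[0] < 0 or c + offsets[-1] >= n:
            dropped.append(ev)
        else:
            usable.append(c)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} event(s) too close to the recording edge")
        logger.warning("dropped events at %s s", dropped)
    if not usable:
        raise ValueError("no usable events: all windows extend past the recording")
    idx = np.asarray(usable)[:, None] + offsets[None, :]
    erps = []
    for ch in range(recording.n_channels):
        mean = recording.samples[ch][idx].mean(axis=0)
        erps.append(EvokedResponse(region=recording.regions[ch], time_ms=time_ms.copy(),
                                   amplitude=mean, n_trials=len(usable), channel_id=ch))
    return erps


def select_best_channel(erps: list[EvokedResponse],
                        window_ms: tuple[float, float] = (1.0, 200.0)) -> EvokedResponse:
    """ERP with the largest peak-to-trough amplitude inside ``window_ms``.

    Ties are broken by lowest channel index (list order).
    """
    if not erps:
        raise ValueError("select_best_channel requires a non-empty list")
    best, best_amp = None, -np.inf
    for erp in erps:
        m = (erp.time_ms >= window_ms[0]) & (erp.time_ms <= window_ms[1])
        if not m.any():
            raise ValueError("ERP has no samples inside the analysis window")
        amp = float(erp.amplitude[m].max() - erp.amplitude[m].min())
        if amp > best_amp:
            best, best_amp = erp, amp
    return best


def preprocess_pipeline(recording: RawRecording, target_rate: float = 1000.0,
                        low: float = 1.0, high: float = 32.0,
                        window_ms: tuple[float, float] = (1.0, 200.0),
                        per_region: bool = True):
    """decimate -> bandpass -> epoch -> per-region best-channel selection."""
    rec = bandpass(decimate(recording, target_rate), low, high)
    erps = epoch_average(rec, window_ms)
    if not per_region:
        return erps
    out = {}
    for region in dict.fromkeys(recording.regions):
        out[region] = select_best_channel(
            [e for e in erps if e.region == region], window_ms)
    return out
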