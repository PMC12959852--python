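"""Threshold-based multiunit spike detection on wideband extracellular traces.

The chain mirrors standard extracellular preprocessing: zero-phase Butterworth
band-pass (250-5000 Hz), a robust noise-SD estimate, negative-going threshold
crossings at 5x the noise SD with a short lockout, extraction of a 1.3 ms
(39-sample at 30 kHz) waveform re-centred on the negative peak, and pooling of
channel trains into one population MUA spike train.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, DataError

__all__ = [
    "DetectionParams",
    "ChannelSpikeTrain",
    "PooledMUA",
    "waveform_samples",
    "bandpass_filter",
    "estimate_noise_sd",
    "detect_spikes",
    "pool_mua",
]

#: MAD -> SD conversion for Gaussian noise (1 / Phi^-1(0.75)).
MAD_SCALE = 1.4826


def waveform_samples(duration_s: float, fs: float) -> int:
    """Number of samples spanned by a waveform of ``duration_s`` at ``fs``."""
    return int(round(duration_s * fs))


@dataclass(frozen=True)
class DetectionParams:
    """Spike-detection parameters.

    ``waveform_len`` defaults to 39 samples = 1.3 ms at 30 kHz; the alignment
    sample (negative peak) is its centre. ``search_span`` bounds how far from
    the threshold crossing the negative peak is searched for.
    """

    fs: float = 30_000.0
    band: tuple[float, float] = (250.0, 5000.0)
    threshold_multiplier: float = 5.0
    waveform_len: int = 39
    lockout: float = 0.001
    search_span: float = 0.0004
    filter_order: int = 4
    noise_method: str = "mad"  # "mad" (robust, default) or "sd"

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high < self.fs / 2:
            raise ConfigError(f"band {self.band} invalid for fs={self.fs} (need 0 < low < high < fs/2)")
        if self.threshold_multiplier <= 0:
            raise ConfigError("threshold_multiplier must be > 0")
        if self.lockout < 0 or self.search_span < 0:
            raise ConfigError("lockout and search_span must be >= 0")
        if self.waveform_len < 3:
            raise ConfigError("waveform_len too short")
        if self.noise_method not in ("mad", "sd"):
            raise ConfigError("noise_method must be 'mad' or 'sd'")

    @property
    def align_sample(self) -> int:
        return self.waveform_len // 2


@dataclass
class ChannelSpikeTrain:
    """Detected events on one channel: times (s), waveforms (n x len, uV)."""

    channel_id: int
    spike_times: np.ndarray
    waveforms: np.ndarray
    noise_sd: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        if np.any(np.diff(self.spike_times) <= 0):
            raise DataError("channel spike times must be strictly increasing")
        if self.waveforms.shape[0] != len(self.spike_times):
            raise DataError("waveform row count must equal spike count")

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass
class PooledMUA:
    """Spike times merged across channels, with per-spike channel provenance."""

    spike_times: np.ndarray
    source_channel: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.source_channel = np.asarray(self.source_channel, dtype=int)
        if np.any(np.diff(self.spike_times) < 0):
            raise DataError("pooled spike times must be sorted")
        if len(self.spike_times) != len(self.source_channel):
            raise DataError("times and channel labels must have equal length")

    def __len__(self) -> int:
        return len(self.spike_times)


def bandpass_filter(raw: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    raw = np.asarray(raw, dtype=float)
    if raw.size <= 3 * (2 * params.filter_order + 1):
        raise DataError("signal too short for the requested filter order")
    sos = sps.butter(params.filter_order, params.band, btype="bandpass", fs=params.fs, output="sos")
    return sps.sosfiltfilt(sos, raw)


def estimate_noise_sd(filtered: np.ndarray, method: str = "mad") -> float:
    """Noise-scale estimate of a filtered trace, in its own units.

    The default is the median absolute deviation scaled to the Gaussian SD,
    which is insensitive to spikes occupying a few percent of samples;
    ``method="sd"`` gives the plain sample SD for comparison.
    """
    x = np.asarray(filtered, dtype=float)
    if x.size == 0:
        raise DataError("cannot estimate noise on an empty signal")
    if method == "mad":
        est = MAD_SCALE * float(np.median(np.abs(x - np.median(x))))
    elif method == "sd":
        est = float(np.std(x))
    else:
        raise ConfigError("method must be 'mad' or 'sd'")
    if est == 0.0:
        warnings.warn("constant signal: noise SD estimate is 0", stacklevel=2)
    return est


def detect_spikes(filtered: np.ndarray, params: DetectionParams,
                  channel_id: int = 0, noise_sd: float | None = None) -> ChannelSpikeTrain:
    """Detect negative-going threshold crossings and extract aligned waveforms.

    The threshold is ``-threshold_multiplier * noise_sd``. Within each lockout
    window only the first crossing is kept; each kept event is re-centred on
    the signal minimum within ``search_span`` of the crossing, and events too
    close to either edge for a full waveform are dropped.
    """
    x = np.asarray(filtered, dtype=float)
    if x.size < params.waveform_len:
        raise DataError("signal shorter than one waveform")
    if noise_sd is None:
        noise_sd = estimate_noise_sd(x, params.noise_method)
    thr = -params.threshold_multiplier * noise_sd
    crossings = np.flatnonzero((x[1:] < thr) & (x[:-1] >= thr)) + 1

    lock = int(round(params.lockout * params.fs))
    kept = []
    last = -np.inf
    for idx in crossings:
        if idx - last > lock:
            kept.append(idx)
            last = idx

    span = int(round(params.search_span * params.fs))
    pre = params.align_sample
    post = params.waveform_len - pre - 1
    times, waves = [], []
    for idx in kept:
        lo = max(0, idx - span)
        hi = min(x.size, idx + span + 1)
        peak = lo + int(np.argmin(x[lo:hi]))
        if peak - pre < 0 or peak + post >= x.size:
            continue
        times.append(peak / params.fs)
        waves.append(x[peak - pre: peak + post + 1])

    if times:
        t = np.asarray(times)
        w = np.asarray(waves)
        # two crossings may align to the same minimum; keep the first
        uniq = np.concatenate(([True], np.diff(t) > 0))
        t, w = t[uniq], w[uniq]
    else:
        t = np.empty(0)
        w = np.empty((0, params.waveform_len))
    return ChannelSpikeTrain(channel_id, t, w, noise_sd)


def pool_mua(trains: list[ChannelSpikeTrain] | list[tuple[int, np.ndarray]]) -> PooledMUA:
    """Merge channel spike trains into one sorted population train.

    Accepts ``ChannelSpikeTrain`` objects or ``(channel_id, times)`` pairs.
    Spike count is conserved; ties across channels keep channel order (stable
    mergesort).
    """
    if not trains:
        raise DataError("at least one spike train is required")
    all_times, all_chan = [], []
    for train in trains:
        if isinstance(train, ChannelSpikeTrain):
            cid, t = train.channel_id, train.spike_times
        else:
            cid, t = train
            t = np.asarray(t, dtype=float)
        if np.any(np.diff(t) < 0):
            raise DataError(f"channel {cid}: spike times not sorted")
        all_times.append(t)
        all_chan.append(np.full(len(t), cid, dtype=int))
    times = np.concatenate(all_times)
    chans = np.concatenate(all_chan)
    order = np.argsort(times, kind="mergesort")
    return PooledMUA(times[order], chans[order])
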