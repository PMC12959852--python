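"""Event-aligned rasters, peristimulus time histograms, and sliding-window
firing-rate curves.

PSTHs bin spike times relative to an alignment event, convert per-trial
counts to rates, and average across valid trials; they are reported either as
pooled-array activity (spikes/s) or channel-normalised activity
(spikes/s/channel). The coarse display convention is 100 ms bins smoothed
with a 5-point moving average; the fine one is 10 ms bins, unsmoothed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "PSTHParams",
    "PSTH",
    "align_spike_times",
    "compute_psth",
    "moving_average",
    "sliding_rate_curve",
    "area_under_curve",
]


@dataclass(frozen=True)
class PSTHParams:
    bin_width: float = 0.010
    window: tuple[float, float] = (-0.5, 1.5)
    smoothing: int | None = None  # odd moving-average length, e.g. 5
    normalization: str = "pooled_array"  # or "per_channel"
    n_channels: int = 16

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be > 0")
        if self.window[1] <= self.window[0]:
            raise ConfigError("window must have positive span")
        if self.normalization not in ("pooled_array", "per_channel"):
            raise ConfigError("normalization must be 'pooled_array' or 'per_channel'")
        if self.smoothing is not None and self.smoothing % 2 == 0:
            raise ConfigError("smoothing length must be odd")


@dataclass
class PSTH:
    """Trial-averaged firing-rate curve plus the per-trial aligned spike
    times that implicitly define the raster (rows = valid-trial order)."""

    bin_edges: np.ndarray
    rates: np.ndarray
    n_trials: int
    alignment: str
    normalization: str
    aligned_spikes: list = field(default_factory=list)
    total_count: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def align_spike_times(spike_times, align_times, window: tuple[float, float]) -> list[np.ndarray]:
    """Per-trial spike times relative to each alignment event, within
    half-open [window[0], window[1])."""
    times = np.asarray(getattr(spike_times, "spike_times", spike_times), dtype=float)
    out = []
    for t0 in np.asarray(align_times, dtype=float):
        lo = np.searchsorted(times, t0 + window[0], "left")
        hi = np.searchsorted(times, t0 + window[1], "left")
        out.append(times[lo:hi] - t0)
    return out


def compute_psth(spike_times, align_times, params: PSTHParams = PSTHParams(),
                 alignment: str = "cue_onset") -> PSTH:
    """PSTH of pooled MUA aligned to one event across valid trials.

    The window is cut into whole bins of ``bin_width`` (a trailing partial bin
    is dropped). Rates are mean over trials of count/bin_width, divided by
    ``n_channels`` in per-channel mode, then optionally smoothed.
    """
    align_times = np.asarray(align_times, dtype=float)
    if align_times.size == 0:
        raise DataError("PSTH needs at least one valid trial")
    span = params.window[1] - params.window[0]
    n_bins = int(np.floor(span / params.bin_width + 1e-9))
    if n_bins < 1:
        raise ConfigError("window shorter than one bin")
    edges = params.window[0] + params.bin_width * np.arange(n_bins + 1)

    aligned = align_spike_times(spike_times, align_times, (edges[0], edges[-1]))
    counts = np.zeros(n_bins)
    total = 0
    for rel in aligned:
        c, _ = np.histogram(rel, bins=edges)
        counts += c
        total += int(c.sum())
    rates = counts / (align_times.size * params.bin_width)
    if params.normalization == "per_channel":
        rates = rates / params.n_channels
    if params.smoothing is not None:
        rates = moving_average(rates, params.smoothing)
    return PSTH(edges, rates, int(align_times.size), alignment,
                params.normalization, aligned, total)


def moving_average(series, k: int = 5) -> np.ndarray:
    """Centred k-point moving average with shrinking windows at the edges.

    ``k`` must be odd and no longer than the series; a constant series is
    returned unchanged.
    """
    x = np.asarray(series, dtype=float)
    if k % 2 == 0:
        raise ConfigError("moving-average length must be odd")
    if k > x.size:
        raise ConfigError("moving-average length exceeds series length")
    h = k // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo = max(0, i - h)
        hi = min(x.size, i + h + 1)
        out[i] = x[lo:hi].mean()
    return out


def sliding_rate_curve(spike_times, window: float, step: float,
                       span: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Firing-rate curve from counts in a moving window.

    rate(t_i) = count in [t_i, t_i + window) / window, with
    t_i = span[0] + i*step while the window fits inside the span. Returns
    (window start times, rates).
    """
    if step <= 0 or window < step:
        raise ConfigError("need window >= step > 0")
    t0, t1 = span
    if t1 - t0 < window:
        raise ConfigError("span shorter than one window")
    times = np.asarray(getattr(spike_times, "spike_times", spike_times), dtype=float)
    starts = []
    t = t0
    while t + window <= t1 + 1e-12:
        starts.append(t)
        t += step
    starts = np.asarray(starts)
    counts = (np.searchsorted(times, starts + window, "left")
              - np.searchsorted(times, starts, "left"))
    return starts, counts / window


def area_under_curve(t, rates, interval: tuple[float, float] | None = None) -> float:
    """Trapezoidal area under a rate curve (spikes), optionally restricted to
    the curve samples falling inside ``interval``."""
    t = np.asarray(t, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if interval is not None:
        mask = (t >= interval[0]) & (t <= interval[1])
        t, rates = t[mask], rates[mask]
    if t.size < 2:
        return 0.0
    return float(np.trapezoid(rates, t))
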