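"""Figure builders: raster + dual-resolution PSTH panels, session-wise epoch
proportion bars, and session-to-session delta curves.

All functions return a matplotlib Figure; the pipeline saves them and also
exports the underlying numbers as TSV so every figure is reproducible without
replotting.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .psth import PSTH

__all__ = ["raster_psth_figure", "proportion_bar_figure", "delta_figure"]

_EPOCH_LABELS = {"pre": "precue", "cue": "cue", "rew": "reward"}


def raster_psth_figure(fine: PSTH, coarse: PSTH, title: str = "",
                       event_times: tuple[float, ...] = (0.0,)) -> plt.Figure:
    """Raster (top) with fine 10 ms PSTH and smoothed coarse PSTH below.

    ``event_times`` marks alignment landmarks (e.g. cue onset, mean reward
    time) as dashed lines on every panel.
    """
    fig, axes = plt.subplots(3, 1, figsize=(6, 7), sharex=True,
                             gridspec_kw={"height_ratios": [2, 1, 1]})
    ax = axes[0]
    for i, rel in enumerate(fine.aligned_spikes):
        ax.vlines(rel, i + 0.5, i + 1.5, color="k", lw=0.5)
    ax.set_ylabel("valid trial")
    ax.set_ylim(0.5, fine.n_trials + 0.5)
    ax.set_title(title)

    unit = "spikes/s" if fine.normalization == "pooled_array" else "spikes/s/channel"
    axes[1].bar(fine.bin_centers, fine.rates, width=np.diff(fine.bin_edges),
                color="0.3", align="center")
    axes[1].set_ylabel(f"rate ({unit})\n10 ms bins")
    axes[2].plot(coarse.bin_centers, coarse.rates, color="tab:blue")
    axes[2].set_ylabel(f"rate ({unit})\n100 ms, smoothed")
    axes[2].set_xlabel("time from alignment (s)")
    for a in axes:
        for t in event_times:
            a.axvline(t, color="r", ls="--", lw=0.8)
    fig.tight_layout()
    return fig


def proportion_bar_figure(summaries, contrasts=None, title: str = "") -> plt.Figure:
    """Session-wise mean +/- SD epoch spike proportions as grouped bars.

    ``summaries`` is the frame from :func:`vtamua.epochs.summarize_sessions`
    for one pigeon; significance markers from ``contrasts`` (if given) are
    drawn above each session group.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    sessions = summaries["session"].to_numpy()
    width = 0.25
    for j, epoch in enumerate(("pre", "cue", "rew")):
        means = summaries[f"mean_{epoch}"].to_numpy()
        sds = summaries[f"sd_{epoch}"].to_numpy()
        ax.bar(sessions + (j - 1) * width, means, width, yerr=sds, capsize=2,
               label=_EPOCH_LABELS[epoch])
    if contrasts is not None and len(contrasts):
        for s in sessions:
            sig = contrasts[(contrasts["session"] == s) & contrasts["significant"]]
            if len(sig):
                ax.text(s, 1.02, "*", ha="center", fontsize=12)
    ax.set_xlabel("session")
    ax.set_ylabel("spike proportion")
    ax.set_ylim(0, 1.1)
    ax.set_xticks(sessions)
    ax.legend(frameon=False)
    ax.set_title(title)
    fig.tight_layout()
    return fig


def delta_figure(deltas, title: str = "") -> plt.Figure:
    """Session-to-session change in mean epoch proportions for one pigeon."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    labels = [f"S{a}→S{b}" for a, b in zip(deltas["from_session"], deltas["to_session"])]
    x = np.arange(len(labels))
    for epoch in ("pre", "cue", "rew"):
        ax.plot(x, deltas[f"delta_{epoch}"], marker="o", label=_EPOCH_LABELS[epoch])
    ax.axhline(0, color="0.6", lw=0.8)
    ax.set_xticks(x, labels)
    ax.set_ylabel("Δ proportion")
    ax.legend(frameon=False)
    ax.set_title(title)
    fig.tight_layout()
    return fig
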