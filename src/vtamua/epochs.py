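"""Epoch spike counts and proportions — the pipeline's core statistic.

For each valid trial, pooled spikes are counted in three predefined 0.5 s
epochs: precue reference (-0.5 to 0 s from cue onset), cue (0 to 0.5 s from
cue onset) and reward/outcome (0 to 0.5 s from reward onset; rewarded trials
only). Proportions divide each count by the summed counts of the epochs
available on that trial (3-way on rewarded cue+ trials, 2-way precue/cue on
cue- trials), then sessions are summarised as mean +/- SD across valid trials
and as session-to-session deltas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .errors import DataError
from .synthetic import _trial_field

__all__ = [
    "EpochWindows",
    "EpochCounts",
    "EpochProportions",
    "count_epoch_spikes",
    "epoch_proportions",
    "trial_proportion_table",
    "summarize_session",
    "summarize_sessions",
    "session_deltas",
]

EPOCHS = ("pre", "cue", "rew")


@dataclass(frozen=True)
class EpochWindows:
    """Analysis windows (s). precue/cue are relative to cue onset, reward to
    reward onset; all half-open [start, end)."""

    precue: tuple[float, float] = (-0.5, 0.0)
    cue: tuple[float, float] = (0.0, 0.5)
    reward: tuple[float, float] = (0.0, 0.5)


class EpochCounts(NamedTuple):
    n_pre: int
    n_cue: int
    n_rew: Optional[int]  # None on unrewarded (cue-) trials


class EpochProportions(NamedTuple):
    p_pre: float
    p_cue: float
    p_rew: Optional[float]
    kind: str  # "cue_plus_3way" | "cue_minus_2way"


def _count_in(times: np.ndarray, lo: float, hi: float) -> int:
    """Spikes with lo <= t < hi in a sorted time array."""
    return int(np.searchsorted(times, hi, "left") - np.searchsorted(times, lo, "left"))


def count_epoch_spikes(pooled, trial, windows: EpochWindows = EpochWindows()) -> EpochCounts:
    """Count pooled spikes in each epoch of one trial.

    ``pooled`` is a sorted spike-time array or an object with a
    ``spike_times`` attribute, on the same clock as the trial events.
    """
    times = np.asarray(getattr(pooled, "spike_times", pooled), dtype=float)
    t_cue = float(_trial_field(trial, "t_cue_on"))
    choice = _trial_field(trial, "choice")
    t_rew = _trial_field(trial, "t_reward_on")
    rewarded = choice == "green"
    if rewarded and (t_rew is None or not np.isfinite(t_rew)):
        raise DataError("rewarded trial lacks t_reward_on")

    n_pre = _count_in(times, t_cue + windows.precue[0], t_cue + windows.precue[1])
    n_cue = _count_in(times, t_cue + windows.cue[0], t_cue + windows.cue[1])
    n_rew = None
    if rewarded:
        # under QC (premature < 0.5 s excluded) the reward window cannot
        # overlap the cue window; assert rather than assume
        if float(t_rew) - t_cue < windows.cue[1] - windows.cue[0]:
            warnings.warn("reward window overlaps cue window (premature trial leaked through QC?)",
                          stacklevel=2)
        n_rew = _count_in(times, float(t_rew) + windows.reward[0], float(t_rew) + windows.reward[1])
    return EpochCounts(n_pre, n_cue, n_rew)


def epoch_proportions(counts: EpochCounts) -> Optional[EpochProportions]:
    """Normalise epoch counts to proportions of the trial's total.

    Returns ``None`` when every available count is zero (the trial is flagged
    and excluded from session means by the caller).
    """
    if counts.n_rew is None:
        total = counts.n_pre + counts.n_cue
        if total == 0:
            return None
        return EpochProportions(counts.n_pre / total, counts.n_cue / total, None, "cue_minus_2way")
    total = counts.n_pre + counts.n_cue + counts.n_rew
    if total == 0:
        return None
    return EpochProportions(counts.n_pre / total, counts.n_cue / total,
                            counts.n_rew / total, "cue_plus_3way")


def trial_proportion_table(pooled, trials: pd.DataFrame,
                           windows: EpochWindows = EpochWindows()) -> pd.DataFrame:
    """Per-trial epoch counts and proportions for a table of valid trials.

    All-zero-count trials get ``defined = False`` (NaN proportions) and are
    excluded from session summaries; their number is warned about.
    """
    rows = []
    n_undefined = 0
    for trial in trials.itertuples():
        counts = count_epoch_spikes(pooled, trial, windows)
        props = epoch_proportions(counts)
        if props is None:
            n_undefined += 1
            rows.append((trial.pigeon_id, trial.session, trial.trial,
                         counts.n_pre, counts.n_cue, counts.n_rew,
                         np.nan, np.nan, np.nan,
                         "cue_plus_3way" if counts.n_rew is not None else "cue_minus_2way",
                         False))
        else:
            rows.append((trial.pigeon_id, trial.session, trial.trial,
                         counts.n_pre, counts.n_cue, counts.n_rew,
                         props.p_pre, props.p_cue,
                         np.nan if props.p_rew is None else props.p_rew,
                         props.kind, True))
    if n_undefined:
        warnings.warn(f"{n_undefined} trial(s) with zero spikes in every epoch excluded",
                      stacklevel=2)
    return pd.DataFrame(rows, columns=["pigeon_id", "session", "trial",
                                       "n_pre", "n_cue", "n_rew",
                                       "p_pre", "p_cue", "p_rew", "kind", "defined"])


def summarize_session(props: pd.DataFrame) -> dict:
    """Mean and sample SD (ddof=1) of each epoch proportion over one session's
    defined trials; n=1 sessions report SD 0 with ``sd_degenerate=True``."""
    df = props[props["defined"]]
    if len(df) == 0:
        raise DataError("no defined trial proportions in session")
    out = {"n_trials": int(len(df)), "sd_degenerate": len(df) == 1}
    for epoch, col in zip(EPOCHS, ("p_pre", "p_cue", "p_rew")):
        vals = df[col].dropna().to_numpy()
        if len(vals) == 0:
            out[f"mean_{epoch}"] = np.nan
            out[f"sd_{epoch}"] = np.nan
        else:
            out[f"mean_{epoch}"] = float(np.mean(vals))
            out[f"sd_{epoch}"] = 0.0 if len(vals) == 1 else float(np.std(vals, ddof=1))
    return out


def summarize_sessions(props: pd.DataFrame) -> pd.DataFrame:
    """Session-level summary table (one row per pigeon x session)."""
    cols = ["pigeon_id", "session", "n_trials", "sd_degenerate",
            *[f"{k}_{e}" for e in EPOCHS for k in ("mean", "sd")]]
    rows = []
    for (pid, s), df in props.groupby(["pigeon_id", "session"], sort=True):
        row = {"pigeon_id": pid, "session": s}
        row.update(summarize_session(df))
        rows.append(row)
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def session_deltas(summaries: pd.DataFrame) -> pd.DataFrame:
    """Session-to-session change Delta = mean(session n+1) - mean(session n)
    of each epoch's mean proportion, per pigeon. One session yields an empty
    frame with a warning."""
    rows = []
    for pid, df in summaries.groupby("pigeon_id", sort=True):
        df = df.sort_values("session")
        if len(df) < 2:
            warnings.warn(f"{pid}: single session, no deltas", stacklevel=2)
            continue
        for (_, a), (_, b) in zip(df.iterrows(), df.iloc[1:].iterrows()):
            row = {"pigeon_id": pid, "from_session": int(a["session"]),
                   "to_session": int(b["session"])}
            for epoch in EPOCHS:
                row[f"delta_{epoch}"] = b[f"mean_{epoch}"] - a[f"mean_{epoch}"]
            rows.append(row)
    return pd.DataFrame(rows, columns=["pigeon_id", "from_session", "to_session",
                                       *[f"delta_{e}" for e in EPOCHS]])
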