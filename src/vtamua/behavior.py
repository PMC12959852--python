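"""Behavioral trial QC, pecking accuracy, and learning-phase labelling.

Trial tables are tidy DataFrames (one row per trial) with the columns written
by :mod:`vtamua.synthetic`. Quality control removes premature responses
(response < 0.5 s from cue onset) and movement-artifact trials; accuracy is
the proportion of green-key selections among all key-peck trials; sessions are
split into a learning phase and a consolidation phase at the first session
reaching 85% accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .synthetic import PREMATURE_CUTOFF

__all__ = [
    "TrialRecord",
    "apply_trial_qc",
    "compute_accuracy",
    "accuracy_by_session",
    "label_phases",
    "session_behavior_summary",
]

#: Default accuracy criterion separating learning from consolidation sessions.
PHASE_CRITERION = 0.85


@dataclass
class TrialRecord:
    """One behavioral trial (convenience view of a trial-table row)."""

    pigeon_id: str
    session: int
    trial: int
    cue: str
    choice: str
    t_cue_on: float
    t_response: float
    t_reward_on: float
    premature: bool
    artifact: bool

    @classmethod
    def from_row(cls, row) -> "TrialRecord":
        return cls(*(row[c] for c in ("pigeon_id", "session", "trial", "cue", "choice",
                                      "t_cue_on", "t_response", "t_reward_on",
                                      "premature", "artifact")))

    @property
    def rewarded(self) -> bool:
        return self.choice == "green"


def _keypeck_mask(trials: pd.DataFrame) -> pd.Series:
    return trials["choice"].isin(["green", "red"])


def _premature_mask(trials: pd.DataFrame) -> pd.Series:
    """Premature = flagged upstream OR response latency < 0.5 s (same rule
    for every pigeon and session); ties at exactly 0.5 s are retained."""
    latency = trials["t_response"] - trials["t_cue_on"]
    if (latency < 0).any():
        raise DataError("negative response latency in trial table")
    flagged = trials.get("premature", pd.Series(False, index=trials.index)).astype(bool)
    return _keypeck_mask(trials) & (flagged | (latency < PREMATURE_CUTOFF))


def apply_trial_qc(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove premature and artifact trials from the key-peck trial set.

    Returns ``(valid, tally)`` where ``tally`` has one row per
    (pigeon_id, session) with columns n_extracted, n_excluded_premature,
    n_excluded_artifact, n_valid. A trial carrying both flags is counted once,
    as premature (reasons are disjoint so valid = extracted - premature -
    artifact holds exactly).
    """
    trials = trials.reset_index(drop=True)
    keypeck = _keypeck_mask(trials)
    premature = _premature_mask(trials)
    artifact = trials["artifact"].astype(bool) & keypeck & ~premature
    valid_mask = keypeck & ~premature & ~artifact
    valid = trials[valid_mask].copy()
    valid["valid"] = True

    grp = trials.assign(
        _kp=keypeck, _prem=premature, _art=artifact, _valid=valid_mask
    ).groupby(["pigeon_id", "session"], sort=True)
    tally = grp[["_kp", "_prem", "_art", "_valid"]].sum().astype(int)
    tally.columns = ["n_extracted", "n_excluded_premature", "n_excluded_artifact", "n_valid"]
    return valid, tally.reset_index()


def compute_accuracy(trials: pd.DataFrame) -> float:
    """Green-key selections / all key-peck trials for one session's trials.

    No-response trials enter neither numerator nor denominator. Returns NaN
    (with a warning) if the session has no key-peck trial.
    """
    n_green = int((trials["choice"] == "green").sum())
    n_red = int((trials["choice"] == "red").sum())
    if n_green + n_red == 0:
        warnings.warn("no key-peck trials: accuracy undefined", stacklevel=2)
        return float("nan")
    return n_green / (n_green + n_red)


def accuracy_by_session(trials: pd.DataFrame) -> pd.DataFrame:
    """Per (pigeon_id, session) pecking accuracy."""
    rows = [
        {"pigeon_id": pid, "session": s, "accuracy": compute_accuracy(df)}
        for (pid, s), df in trials.groupby(["pigeon_id", "session"], sort=True)
    ]
    return pd.DataFrame(rows)


def label_phases(accuracies, criterion: float = PHASE_CRITERION) -> list[str]:
    """Label sessions 'learning' / 'consolidation'.

    Sessions before the first attainment of ``accuracy >= criterion`` are the
    learning phase; that session and all later ones are consolidation. The
    boundary is one-way: once entered, consolidation is never revoked even if
    a later session dips below the criterion.
    """
    accs = list(accuracies)
    if len(accs) == 0:
        raise DataError("need at least one session accuracy")
    if any((not np.isfinite(a)) or a < 0 or a > 1 for a in accs):
        raise DataError("accuracies must lie in [0, 1]")
    labels = []
    reached = False
    for a in accs:
        reached = reached or a >= criterion
        labels.append("consolidation" if reached else "learning")
    return labels


def session_behavior_summary(trials: pd.DataFrame,
                             criterion: float = PHASE_CRITERION) -> pd.DataFrame:
    """Per-session behavior summary mirroring the trial-accounting tables.

    Columns: pigeon_id, session, n_extracted, n_excluded_premature,
    n_excluded_artifact, n_valid, accuracy, phase. Accuracy is computed on all
    key-peck trials (pre-QC); QC protects the neural analyses, not the
    behavioral measure.
    """
    _, tally = apply_trial_qc(trials)
    acc = accuracy_by_session(trials)
    out = tally.merge(acc, on=["pigeon_id", "session"])
    phases = []
    for pid, df in out.groupby("pigeon_id", sort=False):
        phases.append(pd.Series(
            label_phases(df.sort_values("session")["accuracy"], criterion),
            index=df.sort_values("session").index,
        ))
    out["phase"] = pd.concat(phases).sort_index()
    return out
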