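"""File formats: tidy trial CSV, per-channel raw-signal arrays with a JSON
sidecar, and detected-spike CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "write_trials_csv", "read_trials_csv",
    "write_raw_signals", "read_raw_signals",
    "write_spikes_csv", "read_spikes_csv",
]

TRIAL_COLUMNS = ["pigeon_id", "session", "trial", "cue", "side", "choice",
                 "t_cue_on", "t_response", "t_reward_on", "premature", "artifact"]


def write_trials_csv(trials: pd.DataFrame, path) -> Path:
    path = Path(path)
    trials[TRIAL_COLUMNS].to_csv(path, index=False)
    return path


def read_trials_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"trial table not found: {path}")
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"trial table missing columns: {sorted(missing)}")
    df["premature"] = df["premature"].astype(bool)
    df["artifact"] = df["artifact"].astype(bool)
    return df


def write_raw_signals(signals: np.ndarray, fs: float, path_stem) -> tuple[Path, Path]:
    """Save a (n_channels, n_samples) uV array as .npy plus a JSON sidecar
    recording sampling rate, units and channel count."""
    stem = Path(path_stem)
    npy = stem.with_suffix(".npy")
    sidecar = stem.with_suffix(".json")
    signals = np.atleast_2d(np.asarray(signals, dtype=np.float32))
    np.save(npy, signals)
    sidecar.write_text(json.dumps({
        "fs": fs, "units": "uV", "n_channels": signals.shape[0],
        "n_samples": signals.shape[1], "layout": "channels x samples",
    }, indent=2))
    return npy, sidecar


def read_raw_signals(path_stem) -> tuple[np.ndarray, dict]:
    stem = Path(path_stem)
    npy, sidecar = stem.with_suffix(".npy"), stem.with_suffix(".json")
    if not npy.exists() or not sidecar.exists():
        raise ConfigError(f"raw signal pair not found: {npy} / {sidecar}")
    meta = json.loads(sidecar.read_text())
    signals = np.load(npy)
    if signals.shape[0] != meta["n_channels"]:
        raise DataError("sidecar channel count disagrees with array shape")
    return signals, meta


def write_spikes_csv(times: np.ndarray, channels: np.ndarray, path) -> Path:
    path = Path(path)
    pd.DataFrame({"channel": np.asarray(channels, dtype=int),
                  "t_spike": np.asarray(times, dtype=float)}).to_csv(path, index=False)
    return path


def read_spikes_csv(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"spike table not found: {path}")
    df = pd.read_csv(path)
    order = np.argsort(df["t_spike"].to_numpy(), kind="mergesort")
    return df["t_spike"].to_numpy()[order], df["channel"].to_numpy()[order]
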