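"""End-to-end orchestration: simulate (or load) -> detect -> QC -> epoch
metrics -> stats -> figures and a checksummed report.

A single :class:`RunConfig` (YAML-loadable) drives every stage; one global
seed is fanned out to per-stage child seeds so partial reruns are
reproducible. Outputs are tidy CSV/TSV tables, PNG figures with their
numeric TSV companions, and a ``manifest.json`` listing every artifact with
its SHA-256 checksum and the echoed configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, epochs, io, stats, synthetic, viz
from .detection import DetectionParams, bandpass_filter, detect_spikes, pool_mua
from .epochs import EpochWindows
from .errors import ConfigError, DataError, VtamuaError
from .psth import PSTHParams, compute_psth
from .synthetic import SimConfig

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline", "write_report", "child_seed"]


def child_seed(seed: int, *offsets: int) -> int:
    """Deterministic child seed (< 2^31) from a global seed and stage offsets."""
    h = hashlib.sha256(("/".join(map(str, (seed, *offsets)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    mode: str = "simulate"  # simulate | fixture | from_files
    seed: int = 0
    alpha: float = 0.05
    sim: SimConfig = field(default_factory=SimConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    windows: EpochWindows = field(default_factory=EpochWindows)
    psth_window: tuple[float, float] = (-0.5, 1.5)
    render_raw: bool = False
    trials_path: str | None = None
    signals_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "fixture", "from_files"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.mode == "from_files":
            if not self.trials_path or not Path(self.trials_path).exists():
                raise ConfigError("from_files mode requires an existing trials_path")
            if self.signals_dir and not Path(self.signals_dir).exists():
                raise ConfigError(f"signals_dir does not exist: {self.signals_dir}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "sim" in kwargs:
            kwargs["sim"] = SimConfig(**kwargs["sim"])
        if "detection" in kwargs:
            kwargs["detection"] = DetectionParams(**{
                k: tuple(v) if k == "band" else v for k, v in kwargs["detection"].items()})
        if "windows" in kwargs:
            kwargs["windows"] = EpochWindows(**{k: tuple(v) for k, v in kwargs["windows"].items()})
        if "psth_window" in kwargs:
            kwargs["psth_window"] = tuple(kwargs["psth_window"])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def echo(self) -> dict:
        """Full configuration, defaults included, as a JSON-serialisable dict."""
        d = dataclasses.asdict(self)
        d["sim"]["template"] = list(np.asarray(self.sim.template, dtype=float))
        return d


@dataclass
class ResultsBundle:
    trials: pd.DataFrame
    behavior_summary: pd.DataFrame
    valid_trials: pd.DataFrame
    proportions: pd.DataFrame | None
    session_summaries: pd.DataFrame | None
    deltas: pd.DataFrame | None
    contrasts: pd.DataFrame | None
    phase_stats: pd.DataFrame | None
    psths: dict
    spikes: dict
    config_echo: dict
    seed: int


@contextmanager
def _stage(name: str):
    try:
        yield
    except VtamuaError as exc:
        raise type(exc)(f"[{name}] {exc}") from exc


def _acquire(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Produce the trial table and per (pigeon, session) pooled spike trains."""
    if config.mode == "fixture":
        return synthetic.build_trial_count_fixture(), {}
    if config.mode == "simulate":
        sim = config.sim.with_(seed=child_seed(config.seed, 0))
        trials = synthetic.simulate_behavior(sim)
        spikes = {}
        for p_idx, (pid, ptrials) in enumerate(trials.groupby("pigeon_id", sort=True)):
            for s in sorted(ptrials["session"].unique()):
                st = ptrials[ptrials["session"] == s]
                sub_seed = child_seed(config.seed, 1, p_idx, int(s))
                if config.render_raw:
                    times, chans = _simulate_via_raw(st, int(s) - 1, sim, sub_seed, config.detection)
                else:
                    times, chans = synthetic.simulate_pooled_spikes(st, int(s) - 1, sim, seed=sub_seed)
                spikes[(pid, int(s))] = (times, chans)
        return trials, spikes
    # from_files
    trials = io.read_trials_csv(config.trials_path)
    spikes = {}
    if config.signals_dir:
        sig_dir = Path(config.signals_dir)
        for (pid, s), _ in trials.groupby(["pigeon_id", "session"], sort=True):
            spike_csv = sig_dir / f"spikes_{pid}_s{s}.csv"
            raw_stem = sig_dir / f"raw_{pid}_s{s}"
            if spike_csv.exists():
                spikes[(pid, int(s))] = io.read_spikes_csv(spike_csv)
            elif raw_stem.with_suffix(".npy").exists():
                arr, meta = io.read_raw_signals(raw_stem)
                pooled = _detect_array(arr, config.detection)
                spikes[(pid, int(s))] = (pooled.spike_times, pooled.source_channel)
            else:
                raise ConfigError(f"no spikes or raw signals for {pid} session {s} in {sig_dir}")
    return trials, spikes


def _detect_array(arr: np.ndarray, params: DetectionParams):
    trains = []
    for ch in range(arr.shape[0]):
        filtered = bandpass_filter(arr[ch], params)
        trains.append(detect_spikes(filtered, params, channel_id=ch))
    return pool_mua(trains)


def _simulate_via_raw(st: pd.DataFrame, session_idx: int, sim: SimConfig,
                      seed: int, det: DetectionParams) -> tuple[np.ndarray, np.ndarray]:
    """Full forward model: sample per-channel spikes, render voltage traces,
    then run the detection chain. Expensive; meant for small configurations."""
    rng = np.random.default_rng(seed)
    rf = synthetic.session_rate_function(st, session_idx, sim)
    t_end = float(st["t_cue_on"].max()) + 6.0
    per_chan = synthetic.RateFunction(rf.baseline / sim.n_channels,
                                      [(a / sim.n_channels, c, s) for a, c, s in rf.bumps])
    trains = []
    for ch in range(sim.n_channels):
        true_times = synthetic.sample_inhomogeneous_poisson(per_chan, 0.0, t_end, seed=rng)
        raw, _ = synthetic.render_raw_channel(true_times, sim, seed=rng, duration=t_end)
        filtered = bandpass_filter(raw, det)
        trains.append(detect_spikes(filtered, det, channel_id=ch))
    pooled = pool_mua(trains)
    return pooled.spike_times, pooled.source_channel


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Run every stage and return the in-memory results bundle."""
    with _stage("acquire"):
        trials, spikes = _acquire(config)
    with _stage("behavior_qc"):
        summary = behavior.session_behavior_summary(trials)
        valid, _ = behavior.apply_trial_qc(trials)

    proportions = session_summaries = deltas = contrasts = phase_stats = None
    psths: dict = {}
    if spikes:
        with _stage("epoch_metrics"):
            parts = []
            for (pid, s), (times, _chans) in spikes.items():
                vt = valid[(valid["pigeon_id"] == pid) & (valid["session"] == s)]
                if len(vt) == 0:
                    continue
                part = epochs.trial_proportion_table(times, vt, config.windows)
                parts.append(part)
            if not parts:
                raise DataError("no valid trials with spike data")
            proportions = pd.concat(parts, ignore_index=True)
            cue_plus = proportions[proportions["kind"] == "cue_plus_3way"]
            session_summaries = epochs.summarize_sessions(cue_plus)
            deltas = epochs.session_deltas(session_summaries)
        with _stage("stats"):
            contrasts = stats.epoch_contrast_table(proportions, alpha=config.alpha)
            phases = {(r.pigeon_id, r.session): r.phase for r in summary.itertuples()}
            phase_stats = stats.phase_comparison_table(cue_plus, phases, alpha=config.alpha)
        with _stage("psth"):
            for (pid, s), (times, _chans) in spikes.items():
                vt = valid[(valid["pigeon_id"] == pid) & (valid["session"] == s)
                           & (valid["choice"] == "green")]
                if len(vt) == 0:
                    continue
                align = vt["t_cue_on"].to_numpy()
                n_ch = config.sim.n_channels
                fine = compute_psth(times, align, PSTHParams(
                    0.010, config.psth_window, None, "pooled_array", n_ch))
                coarse = compute_psth(times, align, PSTHParams(
                    0.100, config.psth_window, 5, "pooled_array", n_ch))
                psths[(pid, int(s))] = (fine, coarse)

    return ResultsBundle(trials, summary, valid, proportions, session_summaries,
                         deltas, contrasts, phase_stats, psths, spikes,
                         config.echo(), config.seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(bundle: ResultsBundle, outdir) -> dict:
    """Write all tables, figures and the checksum manifest to ``outdir``.

    Returns the manifest dict: seed, echoed config, and a relative-path ->
    sha256 map covering every artifact written.
    """
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise DataError(f"output directory not writable: {out}") from exc

    written: list[Path] = []

    def _table(df: pd.DataFrame | None, name: str, sep: str = "\t"):
        if df is None:
            return
        path = out / name
        df.to_csv(path, sep=sep, index=False, float_format="%.12g")
        written.append(path)

    _table(bundle.trials, "trials.csv", sep=",")
    _table(bundle.behavior_summary, "behavior_summary.tsv")
    _table(bundle.proportions, "trial_proportions.tsv")
    _table(bundle.session_summaries, "session_summary.tsv")
    _table(bundle.deltas, "session_deltas.tsv")
    _table(bundle.contrasts, "epoch_contrasts.tsv")
    _table(bundle.phase_stats, "phase_comparisons.tsv")

    for (pid, s), (times, chans) in bundle.spikes.items():
        path = out / f"spikes_{pid}_s{s}.csv"
        io.write_spikes_csv(times, chans, path)
        written.append(path)

    for (pid, s), (fine, coarse) in bundle.psths.items():
        df = pd.DataFrame({"bin_start": fine.bin_edges[:-1],
                           "bin_end": fine.bin_edges[1:], "rate": fine.rates})
        _table(df, f"psth_{pid}_s{s}.tsv")
        fig = viz.raster_psth_figure(fine, coarse, title=f"{pid} session {s} (cue+)")
        fig_path = out / f"raster_psth_{pid}_s{s}.png"
        fig.savefig(fig_path, dpi=110, metadata={"Software": "vtamua"})
        written.append(fig_path)
        import matplotlib.pyplot as plt

        plt.close(fig)

    if bundle.session_summaries is not None:
        import matplotlib.pyplot as plt

        for pid, df in bundle.session_summaries.groupby("pigeon_id"):
            ctr = None
            if bundle.contrasts is not None and len(bundle.contrasts):
                ctr = bundle.contrasts[bundle.contrasts["pigeon_id"] == pid]
            fig = viz.proportion_bar_figure(df, ctr, title=f"{pid} epoch proportions (cue+)")
            p = out / f"proportions_{pid}.png"
            fig.savefig(p, dpi=110, metadata={"Software": "vtamua"})
            plt.close(fig)
            written.append(p)
            dsub = bundle.deltas[bundle.deltas["pigeon_id"] == pid]
            if len(dsub):
                fig = viz.delta_figure(dsub, title=f"{pid} session-to-session change")
                p = out / f"deltas_{pid}.png"
                fig.savefig(p, dpi=110, metadata={"Software": "vtamua"})
                plt.close(fig)
                written.append(p)

    manifest = {
        "seed": bundle.seed,
        "config": bundle.config_echo,
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
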