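"""Epoch spike counts, proportions, session summaries and deltas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vtamua import DataError, EpochWindows, count_epoch_spikes, epoch_proportions
from vtamua.detection import pool_mua
from vtamua.epochs import (EpochCounts, session_deltas, summarize_session,
                           summarize_sessions, trial_proportion_table)

WINDOWS = EpochWindows()


def _trial(t_cue=10.0, t_rew=11.0, choice="green", pigeon="P1", session=1, trial=1):
    return {"pigeon_id": pigeon, "session": session, "trial": trial, "choice": choice,
            "t_cue_on": t_cue, "t_reward_on": t_rew if choice == "green" else np.nan}


class TestCountEpochSpikes:
    def test_one_spike_per_epoch(self):
        spikes = np.array([9.7, 10.1, 11.2])
        counts = count_epoch_spikes(spikes, _trial(), WINDOWS)
        assert counts == EpochCounts(1, 1, 1)

    def test_no_spikes(self):
        counts = count_epoch_spikes(np.array([]), _trial(), WINDOWS)
        assert counts == EpochCounts(0, 0, 0)

    def test_unrewarded_trial_has_no_reward_count(self):
        counts = count_epoch_spikes(np.array([9.7, 10.1]), _trial(choice="red"), WINDOWS)
        assert counts == EpochCounts(1, 1, None)

    def test_missing_reward_time_rejected(self):
        trial = _trial()
        trial["t_reward_on"] = np.nan
        with pytest.raises(DataError):
            count_epoch_spikes(np.array([10.1]), trial, WINDOWS)

    def test_half_open_boundaries(self):
        # spike exactly at cue onset belongs to the cue epoch, not precue
        counts = count_epoch_spikes(np.array([10.0]), _trial(), WINDOWS)
        assert counts == EpochCounts(0, 1, 0)
        # spike exactly at the cue-window end is excluded
        counts = count_epoch_spikes(np.array([10.5]), _trial(), WINDOWS)
        assert counts == EpochCounts(0, 0, 0)

    def test_matches_brute_force_windows(self, rng):
        spikes = np.sort(rng.uniform(8.0, 13.0, 500))
        trial = _trial(t_cue=10.0, t_rew=11.3)
        counts = count_epoch_spikes(spikes, trial, WINDOWS)
        pre = sum(1 for t in spikes if 9.5 <= t < 10.0)
        cue = sum(1 for t in spikes if 10.0 <= t < 10.5)
        rew = sum(1 for t in spikes if 11.3 <= t < 11.8)
        assert counts == EpochCounts(pre, cue, rew)

    def test_channel_permutation_invariance(self, rng):
        times = np.sort(rng.uniform(9.0, 12.0, 200))
        chans = rng.integers(0, 16, 200)
        a = pool_mua([(c, times[chans == c]) for c in range(16)])
        shuffled = rng.permutation(chans)
        b = pool_mua([(c, times[shuffled == c]) for c in range(16)])
        trial = _trial()
        assert count_epoch_spikes(a, trial, WINDOWS) == count_epoch_spikes(b, trial, WINDOWS)


class TestProportions:
    @pytest.mark.parametrize("counts,expected", [
        (EpochCounts(10, 0, 0), (1.0, 0.0, 0.0)),
        (EpochCounts(5, 5, 5), (1 / 3, 1 / 3, 1 / 3)),
    ])
    def test_three_way(self, counts, expected):
        p = epoch_proportions(counts)
        assert (p.p_pre, p.p_cue, p.p_rew) == pytest.approx(expected)
        assert p.kind == "cue_plus_3way"

    def test_two_way(self):
        p = epoch_proportions(EpochCounts(3, 7, None))
        assert (p.p_pre, p.p_cue) == pytest.approx((0.3, 0.7))
        assert p.p_rew is None and p.kind == "cue_minus_2way"

    def test_all_zero_undefined(self):
        assert epoch_proportions(EpochCounts(0, 0, 0)) is None
        assert epoch_proportions(EpochCounts(0, 0, None)) is None

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(0, 500), st.integers(0, 500),
                     st.one_of(st.none(), st.integers(0, 500))))
    def test_normalization_invariant(self, counts):
        p = epoch_proportions(EpochCounts(*counts))
        if p is None:
            assert sum(c for c in counts if c is not None) == 0
        elif p.kind == "cue_plus_3way":
            assert abs(p.p_pre + p.p_cue + p.p_rew - 1.0) < 1e-12
        else:
            assert abs(p.p_pre + p.p_cue - 1.0) < 1e-12


class TestSessionSummaries:
    def _props(self, values, pigeon="P1", session=1):
        return pd.DataFrame({
            "pigeon_id": pigeon, "session": session, "trial": range(1, len(values) + 1),
            "n_pre": 1, "n_cue": 1, "n_rew": 1,
            "p_pre": values, "p_cue": [1 - v for v in values], "p_rew": np.nan,
            "kind": "cue_minus_2way", "defined": True,
        })

    def test_single_trial_degenerate_sd(self):
        out = summarize_session(self._props([0.4]))
        assert out["mean_pre"] == pytest.approx(0.4)
        assert out["sd_pre"] == 0.0
        assert out["sd_degenerate"]

    def test_two_trial_mean(self):
        out = summarize_session(self._props([0.2, 0.4]))
        assert out["mean_pre"] == pytest.approx(0.3)

    def test_matches_two_pass_oracle(self, rng):
        vals = rng.uniform(0, 1, 100)
        out = summarize_session(self._props(list(vals)))
        mean = sum(vals) / len(vals)
        sd = np.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
        assert out["mean_pre"] == pytest.approx(mean, abs=1e-12)
        assert out["sd_pre"] == pytest.approx(sd, rel=1e-10)

    def test_empty_session_rejected(self):
        with pytest.raises(DataError):
            summarize_session(self._props([]).iloc[0:0])

    def test_deltas(self):
        props = pd.concat([self._props([m] * 3, session=s)
                           for s, m in enumerate([0.2, 0.5, 0.6], start=1)])
        summ = summarize_sessions(props)
        deltas = session_deltas(summ)
        assert deltas["delta_pre"].tolist() == pytest.approx([0.3, 0.1])
        assert deltas["delta_cue"].tolist() == pytest.approx([-0.3, -0.1])

    def test_single_session_warns_empty(self):
        summ = summarize_sessions(self._props([0.5, 0.6]))
        with pytest.warns(UserWarning):
            deltas = session_deltas(summ)
        assert len(deltas) == 0

    def test_constant_means_zero_deltas(self):
        props = pd.concat([self._props([0.25, 0.35], session=s) for s in (1, 2, 3)])
        deltas = session_deltas(summarize_sessions(props))
        assert np.allclose(deltas[["delta_pre", "delta_cue"]], 0.0)


def test_trial_proportion_table_flags_zero_trials():
    trials = pd.DataFrame([_trial(t_cue=10.0, t_rew=11.0, trial=1),
                           _trial(t_cue=100.0, t_rew=101.0, trial=2)])
    spikes = np.array([9.8, 10.2, 11.1])  # trial 2 sees nothing
    with pytest.warns(UserWarning):
        out = trial_proportion_table(spikes, trials, WINDOWS)
    assert out["defined"].tolist() == [True, False]
    assert out.loc[0, ["n_pre", "n_cue", "n_rew"]].tolist() == [1, 1, 1]
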