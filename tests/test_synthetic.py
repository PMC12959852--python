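"""Generator tests: behavior tables, rate model, Poisson sampler, raw
rendering, and the published trial-accounting fixture."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from vtamua import ConfigError, SimConfig, simulate_behavior
from vtamua.synthetic import (GroundTruthLog, RateFunction,
                              build_trial_count_fixture, event_rate_function,
                              render_raw_channel, sample_inhomogeneous_poisson)


class TestSimulateBehavior:
    @pytest.mark.parametrize("acc,colour", [(1.0, "green"), (0.0, "red")])
    def test_degenerate_accuracy(self, acc, colour):
        cfg = SimConfig(sessions_per_pigeon=1, trials_per_session=10,
                        accuracy_curve=(acc,), premature_rate=0.0,
                        artifact_rate=0.0, no_response_rate=0.0, seed=1)
        df = simulate_behavior(cfg)
        assert len(df) == 10
        assert (df["choice"] == colour).all()
        assert not df["premature"].any() and not df["artifact"].any()

    def test_green_fraction_binomial(self):
        n = 10_000
        cfg = SimConfig(sessions_per_pigeon=1, trials_per_session=n,
                        accuracy_curve=(0.7,), no_response_rate=0.0, seed=7)
        df = simulate_behavior(cfg)
        frac = (df["choice"] == "green").mean()
        assert abs(frac - 0.7) < 3 * np.sqrt(0.7 * 0.3 / n)

    def test_trial_timeline(self):
        cfg = SimConfig(sessions_per_pigeon=1, trials_per_session=50,
                        accuracy_curve=(0.5,), seed=3)
        df = simulate_behavior(cfg)
        peck = df[df["choice"] != "none"]
        assert (peck["t_response"] >= peck["t_cue_on"]).all()
        green = df[df["choice"] == "green"]
        assert np.allclose(green["t_reward_on"], green["t_response"])
        assert df.loc[df["choice"] != "green", "t_reward_on"].isna().all()
        # rewarded trials are 6 s, others 4 s
        gaps = np.diff(df["t_cue_on"])
        expected = np.where(df["choice"].iloc[:-1] == "green", 6.0, 4.0)
        assert np.allclose(gaps, expected)

    def test_determinism(self):
        cfg = SimConfig(trials_per_session=30, seed=42)
        pd.testing.assert_frame_equal(simulate_behavior(cfg), simulate_behavior(cfg))

    @pytest.mark.parametrize("bad", [
        dict(premature_rate=1.5),
        dict(accuracy_curve=()),
        dict(accuracy_curve=(0.5,), sessions_per_pigeon=2),
        dict(cue_mod_schedule=(10.0, 5.0, 5.0, 5.0, 5.0)),  # decreasing in learning mode
    ])
    def test_invalid_config(self, bad):
        with pytest.raises(ConfigError):
            SimConfig(**bad)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(acc=st.floats(0, 1), prem=st.floats(0, 1), art=st.floats(0, 1),
           seed=st.integers(0, 2**20))
    def test_table_invariants(self, acc, prem, art, seed):
        cfg = SimConfig(sessions_per_pigeon=1, trials_per_session=15,
                        accuracy_curve=(acc,), premature_rate=prem,
                        artifact_rate=art, seed=seed)
        df = simulate_behavior(cfg)
        assert len(df) == 15
        peck = df[df["choice"] != "none"]
        lat = peck["t_response"] - peck["t_cue_on"]
        assert (lat >= 0).all()
        assert (lat[peck["premature"]] < 0.5).all()
        assert set(df["choice"]) <= {"green", "red", "none"}


class TestRateFunction:
    def test_zero_amplitudes_give_baseline(self):
        rf = RateFunction(12.0, [(0.0, 1.0, 0.1), (0.0, 2.0, 0.1)])
        t = np.linspace(0, 3, 50)
        assert np.allclose(rf(t), 12.0)

    def test_bump_decays_to_baseline(self):
        rf = RateFunction(5.0, [(40.0, 1.0, 0.1)])
        assert rf(1.0 + 1.5) == pytest.approx(5.0, abs=1e-6)
        assert rf(1.0) == pytest.approx(45.0)

    def test_integral_matches_quadrature_and_closed_form(self):
        rf = RateFunction(8.0, [(30.0, 2.0, 0.1), (20.0, 4.0, 0.1)])
        num, _ = quad(lambda t: float(rf(t)), 0.0, 6.0, limit=200)
        assert rf.integral(0.0, 6.0) == pytest.approx(num, rel=1e-8)
        # bumps fully inside the span: amplitude * sigma * sqrt(2*pi) each
        expected = 8.0 * 6.0 + (30.0 + 20.0) * 0.1 * np.sqrt(2 * np.pi)
        assert rf.integral(0.0, 6.0) == pytest.approx(expected, rel=1e-6)

    def test_event_rate_schedule_lookup(self, small_config):
        trial = {"t_cue_on": 5.0, "t_reward_on": 6.0}
        rf = event_rate_function(trial, 0, small_config)
        assert len(rf.bumps) == 2
        with pytest.raises(IndexError):
            event_rate_function(trial, 99, small_config)
        unrewarded = {"t_cue_on": 5.0, "t_reward_on": np.nan}
        assert len(event_rate_function(unrewarded, 0, small_config).bumps) == 1


class TestPoissonSampler:
    def test_zero_rate_empty(self):
        out = sample_inhomogeneous_poisson(RateFunction(0.0), 0.0, 5.0, seed=1)
        assert len(out) == 0

    def test_constant_rate_moments(self):
        lam, reps = 20.0, 1000
        rf = RateFunction(lam)
        rng = np.random.default_rng(9)
        counts = [len(sample_inhomogeneous_poisson(rf, 0.0, 1.0, seed=rng))
                  for _ in range(reps)]
        se = np.sqrt(lam / reps)
        assert abs(np.mean(counts) - lam) < 4 * se

    def test_time_reversal_symmetry(self):
        rf = RateFunction(15.0)
        rng = np.random.default_rng(4)
        fwd = [len(sample_inhomogeneous_poisson(rf, 0.0, 2.0, seed=rng)) for _ in range(400)]
        bwd = [len(sample_inhomogeneous_poisson(rf, -2.0, 0.0, seed=rng)) for _ in range(400)]
        assert abs(np.mean(fwd) - np.mean(bwd)) < 4 * np.sqrt(2 * 30 / 400)

    def test_sorted_within_span(self):
        rf = RateFunction(50.0, [(100.0, 1.0, 0.1)])
        out = sample_inhomogeneous_poisson(rf, 0.0, 2.0, seed=5)
        assert np.all(np.diff(out) >= 0)
        assert out.min() >= 0.0 and out.max() < 2.0

    def test_unbounded_rate_rejected(self):
        with pytest.raises(ValueError):
            sample_inhomogeneous_poisson(lambda t: t, 0.0, 1.0, seed=0)


class TestRenderRawChannel:
    def test_noise_sd(self):
        cfg = SimConfig(noise_sd=1.0, seed=0)
        sig, _ = render_raw_channel([], cfg, seed=2, duration=10.0)
        assert len(sig) == 300_000
        assert abs(np.std(sig) - 1.0) < 0.02

    def test_negative_peak_at_injection(self):
        cfg = SimConfig(noise_sd=1.0, spike_amp_sd=10.0, seed=0)
        sig, log = render_raw_channel([0.05], cfg, seed=3, duration=0.1)
        idx = int(np.argmin(sig))
        assert abs(idx - round(0.05 * cfg.fs)) <= len(cfg.template) // 2
        assert len(log) == 1

    def test_ground_truth_count(self, rng):
        cfg = SimConfig(seed=0)
        times = np.sort(rng.uniform(0.01, 0.99, 50))
        _, log = render_raw_channel(times, cfg, seed=4, duration=1.0)
        assert len(log) == 50

    def test_ground_truth_log_invariants(self):
        with pytest.raises(ValueError):
            GroundTruthLog([0.2, 0.1], [1.0, 1.0])
        with pytest.raises(ValueError):
            GroundTruthLog([-0.1, 0.2], [1.0, 1.0])


class TestTrialCountFixture:
    def test_published_session_counts(self, fixture_trials):
        per = fixture_trials.groupby(["pigeon_id", "session"]).size()
        assert list(per["P109"]) == [41, 55, 53, 61, 57]
        p117_valid = fixture_trials[~fixture_trials["premature"] & ~fixture_trials["artifact"]]
        p117_valid = p117_valid[p117_valid["pigeon_id"] == "P117"]
        assert list(p117_valid.groupby("session").size()) == [21, 35, 33]

    def test_channel_count(self, fixture_trials):
        assert (fixture_trials["n_channels"] == 16).all()

    def test_totals_arithmetic(self, fixture_trials):
        for pid, df in fixture_trials.groupby("pigeon_id"):
            n_excl = int((df["premature"] | df["artifact"]).sum())
            n_valid = int((~df["premature"] & ~df["artifact"]).sum())
            assert n_excl + n_valid == len(df)
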