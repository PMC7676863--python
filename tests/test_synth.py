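"""Synthetic-session generator: dynamics, schedules, gaze, and spiking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rivalry.params import (
    EncodingModelParams,
    OculomotorParams,
    RivalryDynamicsParams,
    gamma_scale_for_median,
)
from rivalry.synth import (
    POSITION_PAIRS,
    SessionConfig,
    expected_trial_rates,
    generate_eye_trace,
    generate_percept_trajectory,
    generate_population_spikes,
    generate_trial_table,
    inject_mixed_percepts,
    simulate_session,
)
from rivalry.types import MIXED_LABEL, PerceptTrajectory, spot_xy
from rivalry.units import trial_spike_counts

LABELS = ("face", "object")


class TestPerceptTrajectory:
    def test_median_duration_matches_configuration(self):
        params = RivalryDynamicsParams(seed=7)
        traj = generate_percept_trajectory(params, 2.0e7, LABELS)
        durs = (traj.ends - traj.starts)[:-1]  # last period truncated
        assert len(durs) > 2000
        assert np.median(durs) / 1000.0 == pytest.approx(7.2, rel=0.05)

    def test_gamma_scale_reproduces_median(self):
        scale = gamma_scale_for_median(7200.0, 3.0)
        rng = np.random.default_rng(0)
        draws = rng.gamma(3.0, scale, 200_000)
        assert np.median(draws) == pytest.approx(7200.0, rel=0.01)

    def test_infinite_median_gives_single_period(self):
        params = RivalryDynamicsParams(math.inf, math.inf)
        traj = generate_percept_trajectory(params, 60_000, LABELS)
        assert len(traj.labels) == 1
        assert traj.span == (0.0, 60_000.0)

    def test_same_seed_is_bit_reproducible(self):
        params = RivalryDynamicsParams(seed=3)
        a = generate_percept_trajectory(params, 1e6, LABELS)
        b = generate_percept_trajectory(params, 1e6, LABELS)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.starts, b.starts)

    @given(
        shape=st.floats(0.5, 8.0),
        med_a=st.floats(0.5, 20.0),
        med_b=st.floats(0.5, 20.0),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=25)
    def test_invariants_hold_for_random_dynamics(self, shape, med_a, med_b, seed):
        params = RivalryDynamicsParams(med_a, med_b, shape, seed=seed)
        traj = generate_percept_trajectory(params, 120_000, LABELS)
        assert traj.starts[0] == 0.0 and traj.ends[-1] == 120_000.0
        assert np.allclose(traj.starts[1:], traj.ends[:-1])
        assert not np.any(traj.labels[1:] == traj.labels[:-1])

    def test_rejects_nonpositive_median(self):
        with pytest.raises(ValueError):
            RivalryDynamicsParams(median_dominance_face_s=0.0)


class TestTrialTable:
    def test_twelve_perceptual_trials_cover_all_position_pairs(self):
        df = generate_trial_table(12, "perceptual", LABELS, seed=5)
        pairs = set(zip(df["fix_left"], df["fix_right"]))
        assert pairs == set(POSITION_PAIRS)
        assert len(pairs) == 12

    def test_two_spot_trials_never_share_a_position(self):
        df = generate_trial_table(100, "perceptual", LABELS, seed=1)
        assert (df["fix_left"] != df["fix_right"]).all()

    def test_trials_abut_with_no_gap(self):
        for cond in ("perceptual", "physical"):
            df = generate_trial_table(40, cond, LABELS, seed=2)
            assert np.array_equal(df["onset_ms"], np.arange(40) * 800.0)

    def test_physical_trials_are_monocular(self):
        df = generate_trial_table(60, "physical", LABELS, seed=0)
        one_image = (df["image_left"] == "") ^ (df["image_right"] == "")
        one_spot = (df["fix_left"] == "") ^ (df["fix_right"] == "")
        assert one_image.all() and one_spot.all()
        assert set(df["image_left"]) | set(df["image_right"]) == {"", *LABELS}


class TestEyeTrace:
    def _one_percept(self, span_ms):
        return PerceptTrajectory(np.array(["face"], dtype=object), [0.0], [span_ms])

    def test_zero_jitter_gaze_reaches_spot_after_latency_and_travel(self):
        trials = generate_trial_table(4, "perceptual", LABELS, seed=0)
        percept = self._one_percept(4 * 800.0)
        oc = OculomotorParams(
            saccade_latency_sd_ms=0.0, jitter_step_median_deg=0.0, seed=0
        )
        eye, _ = generate_eye_trace(trials, percept, oc)
        for _, tr in trials.iterrows():
            # face is in the right eye; gaze should sit on its spot
            target = spot_xy(tr["fix_right"])
            t0 = tr["onset_ms"] + 350.0 + 30.0
            seg = eye.window(t0 + 1, tr["onset_ms"] + 800.0)
            if seg is not None and len(seg):
                assert np.allclose(seg, target[None, :])

    def test_jitter_step_median_is_calibrated(self):
        from rivalry.behavior import eye_jitter_stats

        trials = generate_trial_table(20, "perceptual", LABELS, seed=0)
        percept = self._one_percept(20 * 800.0)
        eye, _ = generate_eye_trace(trials, percept, OculomotorParams(seed=4))
        med, _ = eye_jitter_stats(eye)
        assert med == pytest.approx(0.038, rel=0.20)

    def test_gaze_tracks_dominant_eye_spot(self):
        trials = generate_trial_table(10, "perceptual", LABELS, seed=3)
        percept = PerceptTrajectory(
            np.array(["object"], dtype=object), [0.0], [10 * 800.0]
        )
        oc = OculomotorParams(jitter_step_median_deg=0.01, seed=0)
        eye, _ = generate_eye_trace(trials, percept, oc)
        d_obj, d_face = [], []
        for _, tr in trials.iterrows():
            seg = eye.window(tr["onset_ms"] + 450.0, tr["onset_ms"] + 800.0)
            d_obj.append(np.linalg.norm(seg - spot_xy(tr["fix_left"]), axis=1).mean())
            d_face.append(np.linalg.norm(seg - spot_xy(tr["fix_right"]), axis=1).mean())
        assert np.mean(d_obj) < np.mean(d_face)

    def test_missing_percept_coverage_is_rejected(self):
        trials = generate_trial_table(4, "perceptual", LABELS, seed=0)
        short = self._one_percept(800.0)
        with pytest.raises(ValueError):
            generate_eye_trace(trials, short, OculomotorParams())


class TestEncodingModels:
    def _setup(self, model, w_dom=0.65, n_trials=200, rates=(20.0, 5.0)):
        trials = generate_trial_table(n_trials, "perceptual", LABELS, seed=0)
        percept = PerceptTrajectory(
            np.array(["face"], dtype=object), [0.0], [n_trials * 800.0]
        )
        params = EncodingModelParams(
            model=model,
            baseline_hz=np.array([5.0]),
            stimulus_rates_hz={"face": np.array([rates[0]]), "object": np.array([rates[1]])},
            w_dom=w_dom,
            seed=11,
        )
        return trials, percept, params

    def test_model_I_expected_count_is_rate_times_duration(self):
        trials, percept, params = self._setup("I", n_trials=400)
        rec = generate_population_spikes(trials, percept, np.empty(0), params)
        counts = trial_spike_counts(rec, trials)
        expected = 0.8 * (20.0 + 5.0)  # stimulus + baseline over 800 ms
        se = np.sqrt(expected / counts.shape[1])
        assert abs(counts.mean() - expected) < 3 * se

    def test_model_IIa_rate_is_weighted_sum(self):
        trials, percept, params = self._setup("IIa", w_dom=0.65)
        rates = expected_trial_rates(trials, percept, params)
        assert np.allclose(rates, 0.65 * 20.0 + 0.35 * 5.0)  # 14.75 Hz

    def test_w_dom_one_reduces_model_IIa_to_model_I(self):
        trials, percept, p_iia = self._setup("IIa", w_dom=1.0)
        _, _, p_i = self._setup("I")
        assert np.array_equal(
            expected_trial_rates(trials, percept, p_iia),
            expected_trial_rates(trials, percept, p_i),
        )

    def test_model_IIb_expectation_matches_model_IIa(self):
        trials, percept, p_iib = self._setup("IIb", w_dom=0.65)
        _, _, p_iia = self._setup("IIa", w_dom=0.65)
        assert np.allclose(
            expected_trial_rates(trials, percept, p_iib),
            expected_trial_rates(trials, percept, p_iia),
        )

    def test_spike_generation_is_bit_reproducible(self):
        trials, percept, params = self._setup("IIb", n_trials=50)
        a = generate_population_spikes(trials, percept, np.array([100.0]), params)
        b = generate_population_spikes(trials, percept, np.array([100.0]), params)
        pd.testing.assert_frame_equal(a.spikes, b.spikes)

    def test_spikes_fall_inside_trials(self):
        trials, percept, params = self._setup("IIa", n_trials=50)
        rec = generate_population_spikes(trials, percept, np.empty(0), params)
        t = rec.spikes["t_ms"].to_numpy()
        assert t.min() >= 0.0 and t.max() < 50 * 800.0


class TestMixedPercepts:
    def _traj(self, n_trials=1000):
        return generate_percept_trajectory(
            RivalryDynamicsParams(seed=0), n_trials * 800.0, LABELS
        )

    def test_zero_proportion_leaves_trajectory_unchanged(self):
        traj = self._traj(100)
        out = inject_mixed_percepts(traj, 0.0, seed=1)
        assert np.array_equal(out.labels, traj.labels)
        assert np.array_equal(out.starts, traj.starts)

    def test_full_proportion_makes_everything_mixed(self):
        out = inject_mixed_percepts(self._traj(100), 1.0, seed=1)
        assert set(out.labels) == {MIXED_LABEL}

    def test_mixed_trial_count_is_binomial(self):
        n = 1000
        out = inject_mixed_percepts(self._traj(n), 0.5, seed=2)
        mixed_ms = sum(e - s for lab, s, e in zip(out.labels, out.starts, out.ends) if lab == MIXED_LABEL)
        k = mixed_ms / 800.0
        sigma = np.sqrt(n * 0.25)
        assert abs(k - 0.5 * n) < 3 * sigma

    def test_mixed_trials_spike_at_mean_rate(self):
        trials = generate_trial_table(10, "perceptual", LABELS, seed=0)
        percept = PerceptTrajectory(np.array([MIXED_LABEL], dtype=object), [0.0], [8000.0])
        params = EncodingModelParams(
            model="I",
            baseline_hz=np.array([0.0]),
            stimulus_rates_hz={"face": np.array([20.0]), "object": np.array([10.0])},
        )
        rates = expected_trial_rates(trials, percept, params)
        assert np.allclose(rates, 15.0)


def test_simulated_session_is_deterministic():
    cfg = SessionConfig(n_physical_trials=10, n_perceptual_trials=12, n_units=4, seed=9)
    a = simulate_session(cfg)
    b = simulate_session(cfg)
    pd.testing.assert_frame_equal(a.trials, b.trials)
    pd.testing.assert_frame_equal(a.recording.spikes, b.recording.spikes)
    assert np.array_equal(a.eye.xy, b.eye.xy)
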