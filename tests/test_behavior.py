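"""Percept inference, saccade detection, concordance, and jitter stats."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_saccades, random_eye_trace
from rivalry.behavior import (
    compute_spot_distance,
    detect_saccades,
    eye_jitter_stats,
    infer_trial_percept,
    label_session,
    report_concordance,
    simulate_reports,
)
from rivalry.params import OculomotorParams, RivalryDynamicsParams
from rivalry.synth import generate_eye_trace, generate_percept_trajectory, generate_trial_table
from rivalry.types import SPOT_POSITIONS, UNDETERMINED, EyeTrace, spot_xy


def make_trial(fix_left="left", fix_right="top", image_left="object",
               image_right="face", onset=0.0, duration=800.0):
    return pd.Series(
        dict(
            trial_id=0,
            onset_ms=onset,
            duration_ms=duration,
            condition="perceptual",
            image_left=image_left,
            image_right=image_right,
            fix_left=fix_left,
            fix_right=fix_right,
            block_id="0",
        )
    )


def trace_at(positions_ms: list[tuple[float, np.ndarray]], n_ms: int) -> EyeTrace:
    """Piecewise-constant trace: (from_ms, xy) held until the next entry."""
    xy = np.zeros((n_ms, 2))
    for (t0, pos), nxt in zip(positions_ms, positions_ms[1:] + [(n_ms, None)]):
        xy[int(t0) : int(nxt[0])] = pos
    return EyeTrace(0.0, 1000.0, xy)


class TestSpotDistance:
    def test_l1_distance_examples(self):
        eye = EyeTrace(0.0, 1000.0, np.array([[1.0, 1.0], [0.0, 0.0]]))
        d = compute_spot_distance(eye, (0.0, 0.0))
        assert d[0] == pytest.approx(2.0)
        assert d[1] == 0.0

    def test_matches_per_sample_recomputation(self):
        rng = np.random.default_rng(0)
        eye = EyeTrace(0.0, 1000.0, rng.normal(size=(500, 2)))
        spot = np.array([0.3, -0.7])
        d = compute_spot_distance(eye, spot)
        ref = np.array([abs(x - spot[0]) + abs(y - spot[1]) for x, y in eye.xy])
        assert np.array_equal(d, ref)


class TestPerceptInference:
    def test_full_dwell_on_face_spot(self):
        trial = make_trial()
        eye = trace_at([(0.0, spot_xy("top"))], 2000)
        p = infer_trial_percept(eye, trial)
        assert p.label == "face"
        assert p.dwell_ms["face"] == pytest.approx(800.0)

    def test_split_dwell_is_undetermined(self):
        trial = make_trial()
        # 350 ms near face spot, 350 near object spot, 100 ms neither
        eye = trace_at(
            [(0.0, spot_xy("top")), (700.0, spot_xy("left")), (1050.0, np.array([5.0, 5.0]))],
            2000,
        )
        p = infer_trial_percept(eye, trial)
        assert p.label == UNDETERMINED
        assert max(p.dwell_ms.values()) < 400.0

    def test_missing_trace_coverage_is_undetermined(self):
        trial = make_trial()
        eye = trace_at([(0.0, spot_xy("top"))], 500)
        assert infer_trial_percept(eye, trial).label == UNDETERMINED

    def test_eye_relabeling_swaps_inferred_labels(self):
        eye = trace_at([(0.0, spot_xy("top"))], 2000)
        orig = make_trial(fix_left="left", fix_right="top",
                          image_left="object", image_right="face")
        swapped = make_trial(fix_left="left", fix_right="top",
                             image_left="face", image_right="object")
        assert infer_trial_percept(eye, orig).label == "face"
        assert infer_trial_percept(eye, swapped).label == "object"

    def test_determined_label_requires_half_duration_dwell(self):
        trial = make_trial()
        eye = trace_at([(0.0, spot_xy("top")), (745.0, np.array([4.0, 4.0]))], 2000)
        p = infer_trial_percept(eye, trial)  # 395 ms dwell in delayed window
        assert p.label == UNDETERMINED
        eye = trace_at([(0.0, spot_xy("top")), (755.0, np.array([4.0, 4.0]))], 2000)
        assert infer_trial_percept(eye, trial).label == "face"


class TestLabelSession:
    def _session(self, labels):
        """Build trials + trace realizing the requested inferred labels."""
        n = len(labels)
        trials = pd.DataFrame([make_trial(onset=800.0 * k) for k in range(n)])
        trials["trial_id"] = np.arange(n)
        spots = {"face": spot_xy("top"), "object": spot_xy("left")}
        events = [(350.0 + 800.0 * k, spots[lab]) for k, lab in enumerate(labels)]
        eye = trace_at(events, 800 * n + 1200)
        return trials, eye

    def test_switch_and_consistency_flags(self):
        trials, eye = self._session(["face", "face", "object", "object"])
        df = label_session(eye, trials)
        assert list(df["label"]) == ["face", "face", "object", "object"]
        assert list(df["is_switch"]) == [False, False, True, False]
        assert list(df["passes_consistency"]) == [True, False, True, False]

    def test_alternating_labels_never_pass_consistency(self):
        trials, eye = self._session(["face", "object", "face"])
        df = label_session(eye, trials)
        assert not df["passes_consistency"].any()

    def test_switch_trials_track_ground_truth_changes(self):
        traj = generate_percept_trajectory(
            RivalryDynamicsParams(3.0, 3.0, seed=2), 200 * 800.0, ("face", "object")
        )
        trials = generate_trial_table(200, "perceptual", ("face", "object"), seed=2)
        eye, _ = generate_eye_trace(trials, traj, OculomotorParams(seed=2))
        df = label_session(eye, trials)
        true_labels = [
            traj.majority_label(t, t + 800.0) for t in trials["onset_ms"]
        ]
        true_switch_trials = {
            k for k in range(1, 200) if true_labels[k] != true_labels[k - 1]
        }
        detected = set(df.index[df["is_switch"]])
        for k in detected:
            assert any(abs(k - s) <= 1 for s in true_switch_trials)


class TestSaccadeDetection:
    def test_single_step_detected_once_near_the_step(self):
        # the criterion first fires when 80% of the post flank has stepped,
        # i.e. up to ~22 ms before the step sample itself
        xy = np.zeros((1000, 2))
        xy[500:, 0] = 1.0
        events = detect_saccades(EyeTrace(0.0, 1000.0, xy))
        assert len(events) == 1
        assert events[0].time_ms == pytest.approx(500.0, abs=25.0)
        assert events[0].amplitude_deg > 0.8
        assert [int(e.time_ms) for e in events] == brute_force_saccades(xy)

    def test_close_second_step_suppressed_by_separation_rule(self):
        xy = np.zeros((1500, 2))
        xy[600:, 0] = 1.0
        xy[650:, 1] = 1.0
        impl = detect_saccades(EyeTrace(0.0, 1000.0, xy))
        ref = brute_force_saccades(xy)
        assert [int(e.time_ms) for e in impl] == ref
        times = [e.time_ms for e in impl]
        assert all(b - a >= 100.0 for a, b in zip(times, times[1:]))

    def test_slow_drift_without_stable_flanks_yields_nothing(self):
        t = np.arange(5000)
        xy = np.stack([t * 0.3e-3, np.zeros_like(t, dtype=float)], axis=1)
        assert detect_saccades(EyeTrace(0.0, 1000.0, xy)) == []

    def test_matches_bruteforce_on_random_traces(self):
        for seed in range(3):
            xy = random_eye_trace(seed, n_ms=3000)
            impl = detect_saccades(EyeTrace(0.0, 1000.0, xy))
            got = [round((e.time_ms) / 1.0) for e in impl]
            assert got == brute_force_saccades(xy)


class TestConcordance:
    def test_identical_and_complementary_streams(self):
        a = np.array(["face", "object", "face"], dtype=object)
        b = np.array(["object", "face", "object"], dtype=object)
        assert report_concordance(a, a) == 1.0
        assert report_concordance(a, b) == 0.0

    def test_undetermined_trials_are_excluded(self):
        a = np.array(["face", UNDETERMINED, "object"], dtype=object)
        b = np.array(["face", "face", "face"], dtype=object)
        assert report_concordance(a, b) == 0.5

    def test_lapsing_reporter_concordance_near_lapse_rate(self):
        rng_labels = np.where(
            np.random.default_rng(0).random(4000) < 0.5, "face", "object"
        ).astype(object)
        reported = simulate_reports(rng_labels, ("face", "object"), lapse_rate=0.05, seed=1)
        c = report_concordance(rng_labels, reported)
        sigma = np.sqrt(0.95 * 0.05 / 4000)
        assert abs(c - 0.95) < 4 * sigma

    def test_empty_intersection_raises(self):
        a = np.array([UNDETERMINED], dtype=object)
        with pytest.raises(ValueError):
            report_concordance(a, a)


class TestJitterStats:
    def test_constant_trace_has_zero_jitter(self):
        eye = EyeTrace(0.0, 1000.0, np.ones((100, 2)))
        assert eye_jitter_stats(eye) == (0.0, 0.0)

    def test_matches_bruteforce_percentiles(self):
        rng = np.random.default_rng(5)
        eye = EyeTrace(0.0, 1000.0, rng.normal(size=(2000, 2)))
        med, q99 = eye_jitter_stats(eye)
        steps = [
            float(np.hypot(*(eye.xy[i + 1] - eye.xy[i])))
            for i in range(eye.n_samples - 1)
        ]
        assert med == pytest.approx(np.median(steps))
        assert q99 == pytest.approx(np.percentile(steps, 99))


def test_inference_accuracy_degrades_with_jitter():
    """More fixational noise, fewer correctly recovered trials."""
    accs = []
    for step_median in (0.038, 0.5, 1.2):
        traj = generate_percept_trajectory(
            RivalryDynamicsParams(seed=8), 150 * 800.0, ("face", "object")
        )
        trials = generate_trial_table(150, "perceptual", ("face", "object"), seed=8)
        oc = OculomotorParams(jitter_step_median_deg=step_median, seed=8)
        eye, _ = generate_eye_trace(trials, traj, oc)
        df = label_session(eye, trials)
        truth = [traj.majority_label(t, t + 800.0) for t in trials["onset_ms"]]
        accs.append(np.mean(df["label"].to_numpy() == np.asarray(truth, dtype=object)))
    assert accs[0] > accs[1] > accs[2]
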