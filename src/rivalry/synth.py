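"""Synthetic rivalry sessions with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: alternating perceptual dominance with configurable median
durations, abutting 800-ms trials whose dichoptic fixation spots jump among
four positions, gaze that tracks the spot of the currently dominant eye
with a ~350-ms latency and calibrated fixational jitter, and Poisson
population spiking under three candidate encoding models:

* Model I   — spikes follow the dominant stimulus's rate alone;
* Model IIa — spikes are Poisson around a weighted sum of the dominant and
  suppressed stimulus rates (weight ``w_dom``);
* Model IIb — time is tiled into short epochs that alternate between a
  percept-coding rate and a physical-coding rate, occupancy chosen so the
  expected rate matches Model IIa.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .params import (
    EncodingModelParams,
    OculomotorParams,
    RivalryDynamicsParams,
    gamma_scale_for_median,
)
from .types import (
    MIXED_LABEL,
    SPOT_POSITIONS,
    TRIAL_COLUMNS,
    EyeTrace,
    PerceptTrajectory,
    PopulationRecording,
    spot_of_image,
    spot_xy,
    trial_images,
    trial_spots,
)

logger = logging.getLogger(__name__)

#: The 12 ordered (left-eye spot, right-eye spot) pairs with distinct positions.
POSITION_PAIRS: list[tuple[str, str]] = [
    (a, b)
    for a, b in itertools.product(SPOT_POSITIONS, SPOT_POSITIONS)
    if a != b
]


# ---------------------------------------------------------------------------
# Percept trajectory
# ---------------------------------------------------------------------------

def generate_percept_trajectory(
    params: RivalryDynamicsParams,
    session_length_ms: float,
    labels: tuple[str, str],
    start_ms: float = 0.0,
    rng: np.random.Generator | None = None,
) -> PerceptTrajectory:
    """Alternating dominance periods with gamma-distributed durations.

    The gamma scale is solved so the duration median equals the configured
    per-state median.  An infinite median yields a single period.
    """
    if session_length_ms <= 0:
        raise ValueError("session_length_ms must be positive")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    medians = dict(zip(labels, params.medians_ms()))
    scales = {lab: gamma_scale_for_median(m, params.duration_shape) for lab, m in medians.items()}

    state = labels[int(rng.integers(2))]
    t = float(start_ms)
    end = start_ms + session_length_ms
    labs, starts, ends = [], [], []
    while t < end:
        if math.isinf(scales[state]):
            dur = end - t
        else:
            dur = float(rng.gamma(params.duration_shape, scales[state]))
            dur = max(dur, 1.0)  # degenerate zero-length draws
        labs.append(state)
        starts.append(t)
        ends.append(min(t + dur, end))
        t += dur
        state = labels[0] if state == labels[1] else labels[1]
    return PerceptTrajectory(np.array(labs, dtype=object), starts, ends)


def inject_mixed_percepts(
    percept: PerceptTrajectory,
    proportion: float,
    seed: int,
    trial_grid_ms: float = 800.0,
) -> PerceptTrajectory:
    """Relabel a random Bernoulli(proportion) subset of trial cells 'mixed'.

    The trajectory is cut at trial boundaries (multiples of
    ``trial_grid_ms`` from its start); selected cells become a single
    'mixed' state.  Spiking under 'mixed' uses the mean of the two stimulus
    rates.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    if proportion == 0.0:
        return PerceptTrajectory(percept.labels.copy(), percept.starts.copy(), percept.ends.copy())
    rng = np.random.default_rng(seed)
    t0, t1 = percept.span
    edges = np.arange(t0, t1, trial_grid_ms)
    labs: list[str] = []
    starts: list[float] = []
    ends: list[float] = []

    def push(lab: str, s: float, e: float) -> None:
        if labs and labs[-1] == lab:
            ends[-1] = e
        else:
            labs.append(lab)
            starts.append(s)
            ends.append(e)

    for s in edges:
        e = min(s + trial_grid_ms, t1)
        if rng.random() < proportion:
            push(MIXED_LABEL, s, e)
        else:
            for lab, ss, ee in percept.segments_in(s, e):
                push(lab, ss, ee)
    return PerceptTrajectory(np.array(labs, dtype=object), starts, ends)


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

def _perceptual_trials(
    n_trials: int,
    labels: tuple[str, str],
    rng: np.random.Generator,
    duration_ms: float,
    start_ms: float,
    block_prefix: str,
) -> list[dict]:
    """Abutting rivalry trials cycling through the 12 ordered position pairs."""
    rows = []
    order: list[tuple[str, str]] = []
    block = -1
    for k in range(n_trials):
        if k % len(POSITION_PAIRS) == 0:
            idx = rng.permutation(len(POSITION_PAIRS))
            order = [POSITION_PAIRS[i] for i in idx]
            block += 1
        fix_left, fix_right = order[k % len(POSITION_PAIRS)]
        rows.append(
            dict(
                onset_ms=start_ms + k * duration_ms,
                duration_ms=duration_ms,
                condition="perceptual",
                image_left=labels[1],
                image_right=labels[0],
                fix_left=fix_left,
                fix_right=fix_right,
                block_id=f"{block_prefix}{block}",
            )
        )
    return rows


def _physical_trials(
    n_trials: int,
    labels: tuple[str, str],
    rng: np.random.Generator,
    duration_ms: float,
    start_ms: float,
    trajectory: PerceptTrajectory,
    block_prefix: str,
) -> list[dict]:
    """Monocular trials whose shown stimulus follows a switching trajectory."""
    rows = []
    names = list(SPOT_POSITIONS)
    prev = None
    for k in range(n_trials):
        onset = start_ms + k * duration_ms
        shown = trajectory.majority_label(onset, onset + duration_ms)
        choices = [nm for nm in names if nm != prev]
        pos = choices[int(rng.integers(len(choices)))]
        prev = pos
        right_eye = shown == labels[0]
        rows.append(
            dict(
                onset_ms=onset,
                duration_ms=duration_ms,
                condition="physical",
                image_left="" if right_eye else shown,
                image_right=shown if right_eye else "",
                fix_left="" if right_eye else pos,
                fix_right=pos if right_eye else "",
                block_id=f"{block_prefix}0",
            )
        )
    return rows


def generate_trial_table(
    n_trials: int,
    condition: str,
    labels: tuple[str, str],
    seed: int = 0,
    duration_ms: float = 800.0,
    start_ms: float = 0.0,
    trajectory: PerceptTrajectory | None = None,
    block_prefix: str = "",
) -> pd.DataFrame:
    """Abutting trial schedule for one condition.

    Perceptual blocks cycle through all 12 ordered distinct fixation-spot
    position pairs in randomized order; physical trials show a single
    monocular stimulus (identity following ``trajectory``, generated with
    default rivalry dynamics when omitted) with one fixation spot that
    jumps to a new position every trial.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if condition not in ("physical", "perceptual"):
        raise ValueError("condition must be 'physical' or 'perceptual'")
    rng = np.random.default_rng(seed)
    if condition == "perceptual":
        rows = _perceptual_trials(n_trials, labels, rng, duration_ms, start_ms, block_prefix)
    else:
        if trajectory is None:
            trajectory = generate_percept_trajectory(
                RivalryDynamicsParams(seed=seed), n_trials * duration_ms, labels, start_ms
            )
        rows = _physical_trials(
            n_trials, labels, rng, duration_ms, start_ms, trajectory, block_prefix
        )
    df = pd.DataFrame(rows)
    df.insert(0, "trial_id", np.arange(len(df)))
    return df[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# Eye trace
# ---------------------------------------------------------------------------

def _truncated_normal_latency(oc: OculomotorParams, size: int, rng: np.random.Generator) -> np.ndarray:
    if oc.saccade_latency_sd_ms == 0:
        return np.full(size, oc.saccade_latency_mean_ms)
    a = (oc.saccade_latency_floor_ms - oc.saccade_latency_mean_ms) / oc.saccade_latency_sd_ms
    return stats.truncnorm.rvs(
        a, np.inf, loc=oc.saccade_latency_mean_ms, scale=oc.saccade_latency_sd_ms,
        size=size, random_state=rng,
    )


def _tracked_target(trial, state: str, rng: np.random.Generator) -> np.ndarray | None:
    """Spot position the subject tracks in this trial given the percept."""
    spots = trial_spots(trial)
    if len(spots) == 1:
        return spot_xy(next(iter(spots.values())))
    if state == MIXED_LABEL:
        names = list(spots.values())
        return spot_xy(names[int(rng.integers(len(names)))])
    return spot_of_image(trial, state)


def generate_eye_trace(
    trials: pd.DataFrame,
    percept: PerceptTrajectory,
    oc: OculomotorParams,
    pad_ms: float = 800.0,
) -> tuple[EyeTrace, np.ndarray]:
    """Gaze that tracks the dominant eye's fixation spot.

    After each spot jump (trial onset) or perceptual switch, gaze relocates
    to the new target after a truncated-normal latency, traveling linearly
    over ``saccade_travel_ms``; i.i.d. Gaussian jitter is added per sample,
    calibrated so the median 1-ms step magnitude equals the configured
    value.  Returns the trace and the ground-truth saccade (movement onset)
    times.
    """
    rng = np.random.default_rng(oc.seed)
    t_start = float(trials["onset_ms"].min())
    t_end = float((trials["onset_ms"] + trials["duration_ms"]).max()) + pad_ms
    last_trial_end = float((trials["onset_ms"] + trials["duration_ms"]).max())
    if not percept.covers(t_start, last_trial_end):
        raise ValueError("percept trajectory does not cover the trial span")

    dt = 1000.0 / oc.sampling_rate_hz
    n = int(round((t_end - t_start) / dt))

    # Events: (time, new target). Trial onsets re-express the current percept
    # on the new spot layout; mid-trial switches retarget within the trial.
    events: list[tuple[float, np.ndarray]] = []
    for _, trial in trials.iterrows():
        onset = float(trial["onset_ms"])
        end = onset + float(trial["duration_ms"])
        single_spot = len(trial_spots(trial)) == 1
        segs = [(None, onset, end)] if single_spot else percept.segments_in(onset, end)
        first = True
        for lab, s, _e in segs:
            tgt = _tracked_target(trial, "" if lab is None else str(lab), rng)
            if tgt is not None:
                events.append((onset if first else s, tgt))
            first = False

    latencies = _truncated_normal_latency(oc, len(events), rng)
    target = np.empty((n, 2))
    target[:] = events[0][1]
    for (t_ev, tgt), lat in zip(events, latencies):
        i = int(round((t_ev + lat - t_start) / dt))
        if i < n:
            target[max(i, 0):] = tgt

    # Linear travel over the movement; change points are true saccade onsets.
    change = np.flatnonzero(np.any(np.diff(target, axis=0) != 0, axis=1)) + 1
    gaze = target.copy()
    travel = max(int(round(oc.saccade_travel_ms / dt)), 1)
    for c in change:
        frm = gaze[c - 1]
        to = target[c]
        m = min(travel, n - c)
        ramp = (np.arange(1, m + 1) / travel)[:, None]
        gaze[c : c + m] = frm + ramp * (to - frm)

    if oc.jitter_sigma_deg > 0:
        gaze = gaze + rng.normal(0.0, oc.jitter_sigma_deg, size=gaze.shape)
    saccade_times = t_start + change * dt
    return EyeTrace(t_start, oc.sampling_rate_hz, gaze), saccade_times


# ---------------------------------------------------------------------------
# Population rates and spikes
# ---------------------------------------------------------------------------

def draw_population_rates(
    n_units: int,
    labels: tuple[str, ...],
    seed: int,
    label_mean_hz: dict[str, float] | None = None,
    rate_shape: float = 4.0,
    baseline_mean_hz: float = 5.0,
) -> tuple[np.ndarray, dict[str, np.ndarray], pd.DataFrame]:
    """Per-unit baseline and stimulus rates (gamma-distributed across units).

    By default the first label (the preferred category of the recorded
    patch) has mean 20 Hz and the others 8 Hz, yielding a mostly
    face-preferring population with heterogeneous selectivity.
    """
    rng = np.random.default_rng(seed)
    if label_mean_hz is None:
        label_mean_hz = {lab: (20.0 if i == 0 else 8.0) for i, lab in enumerate(labels)}
    baseline = rng.gamma(rate_shape, baseline_mean_hz / rate_shape, n_units)
    rates = {
        lab: rng.gamma(rate_shape, label_mean_hz[lab] / rate_shape, n_units)
        for lab in labels
    }
    units = pd.DataFrame({"unit_id": np.arange(n_units), "baseline_hz": baseline})
    for lab in labels:
        units[f"rate_{lab}_hz"] = rates[lab]
    return baseline, rates, units


def _trial_percept_info(trial, percept: PerceptTrajectory) -> tuple[str, str | None, list[str]]:
    """(dominant label, suppressed label or None, shown images) for a trial."""
    imgs = list(trial_images(trial).values())
    onset = float(trial["onset_ms"])
    end = onset + float(trial["duration_ms"])
    if trial["condition"] == "physical":
        return imgs[0], None, imgs
    dom = percept.majority_label(onset, end)
    if dom == MIXED_LABEL:
        return MIXED_LABEL, None, imgs
    if dom not in imgs:
        raise ValueError(f"dominant state '{dom}' is not shown on trial {trial['trial_id']}")
    sup = imgs[0] if imgs[1] == dom else imgs[1]
    return dom, sup, imgs


def expected_trial_rates(
    trials: pd.DataFrame,
    percept: PerceptTrajectory,
    params: EncodingModelParams,
) -> np.ndarray:
    """Expected stimulus-driven rate (Hz) per trial and unit, gain excluded.

    For Model IIb this is the expectation over the epoch process; with
    matched rates and ``w_dom`` it equals the Model IIa rate exactly, and
    with ``w_dom = 1`` Models I and IIa coincide.
    """
    out = np.empty((len(trials), params.n_units))
    r = params.stimulus_rates_hz
    for i, (_, trial) in enumerate(trials.iterrows()):
        dom, sup, imgs = _trial_percept_info(trial, percept)
        if dom == MIXED_LABEL:
            out[i] = 0.5 * (r[imgs[0]] + r[imgs[1]])
        elif sup is None or params.model == "I":
            out[i] = r[dom]
        else:
            out[i] = params.w_dom * r[dom] + (1.0 - params.w_dom) * r[sup]
    return out


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    ms, me = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms), np.asarray(me)


def generate_population_spikes(
    trials: pd.DataFrame,
    percept: PerceptTrajectory,
    saccade_times: np.ndarray,
    params: EncodingModelParams,
    units: pd.DataFrame | None = None,
) -> PopulationRecording:
    """Poisson population spikes under Models I/IIa/IIb.

    The instantaneous rate of unit u is ``baseline_u + g(t) * r_stim(u, t)``
    where ``r_stim`` is piecewise constant per trial (per epoch for Model
    IIb) and ``g(t)`` is 1 everywhere except ``1 + saccade_gain_amplitude``
    inside the post-saccadic gain window.  Negative rates are clipped at 0
    and logged.
    """
    rng = np.random.default_rng(params.seed)
    r = params.stimulus_rates_hz
    win0, win1 = params.saccade_gain_window_ms
    gs, ge = _merge_intervals(
        np.asarray(saccade_times, dtype=float) + win0,
        np.asarray(saccade_times, dtype=float) + win1,
    )

    seg_start: list[float] = []
    seg_end: list[float] = []
    seg_rate: list[np.ndarray] = []
    lat = params.response_latency_ms

    for _, trial in trials.iterrows():
        onset = float(trial["onset_ms"]) + lat
        end = onset + float(trial["duration_ms"])
        dom, sup, imgs = _trial_percept_info(trial, percept)
        if dom == MIXED_LABEL:
            pieces = [(onset, end, 0.5 * (r[imgs[0]] + r[imgs[1]]))]
        elif sup is None or params.model == "I":
            pieces = [(onset, end, r[dom])]
        elif params.model == "IIa":
            pieces = [(onset, end, params.w_dom * r[dom] + (1 - params.w_dom) * r[sup])]
        else:  # IIb: alternate percept-coding and physical-coding epochs
            r_phys = 0.5 * (r[imgs[0]] + r[imgs[1]])
            edges = np.arange(onset, end, params.iib_epoch_ms)
            edges = np.append(edges, end)
            coding = rng.random(len(edges) - 1) < params.iib_occupancy
            pieces = [
                (float(edges[k]), float(edges[k + 1]), r[dom] if coding[k] else r_phys)
                for k in range(len(edges) - 1)
            ]
        # split each piece at saccade-gain interval boundaries
        for s, e, rate in pieces:
            cuts = np.concatenate([gs[(gs > s) & (gs < e)], ge[(ge > s) & (ge < e)], [s, e]])
            cuts = np.unique(cuts)
            for k in range(len(cuts) - 1):
                seg_start.append(float(cuts[k]))
                seg_end.append(float(cuts[k + 1]))
                seg_rate.append(rate)

    seg_start_a = np.asarray(seg_start)
    seg_end_a = np.asarray(seg_end)
    mid = 0.5 * (seg_start_a + seg_end_a)
    in_gain = np.searchsorted(gs, mid, side="right") - 1
    gained = (in_gain >= 0) & (mid < ge[in_gain]) if len(gs) else np.zeros(len(mid), bool)
    gain = np.where(gained, 1.0 + params.saccade_gain_amplitude, 1.0)

    rate_mat = params.baseline_hz[None, :] + gain[:, None] * np.vstack(seg_rate)
    n_neg = int(np.sum(rate_mat < 0))
    if n_neg:
        logger.warning("clipped %d negative rate segments at 0", n_neg)
        rate_mat = np.clip(rate_mat, 0.0, None)

    durs = (seg_end_a - seg_start_a) / 1000.0
    counts = rng.poisson(rate_mat * durs[:, None])
    s_idx, u_idx = np.nonzero(counts)
    reps = counts[s_idx, u_idx]
    starts_rep = np.repeat(seg_start_a[s_idx], reps)
    durs_rep = np.repeat(seg_end_a[s_idx] - seg_start_a[s_idx], reps)
    times = starts_rep + rng.random(len(starts_rep)) * durs_rep
    unit_rep = np.repeat(u_idx, reps)
    order = np.argsort(times, kind="stable")
    spikes = pd.DataFrame({"unit_id": unit_rep[order], "t_ms": times[order]})

    if units is None:
        units = pd.DataFrame({"unit_id": np.arange(params.n_units), "baseline_hz": params.baseline_hz})
        for lab, v in params.stimulus_rates_hz.items():
            units[f"rate_{lab}_hz"] = v
    return PopulationRecording(units=units, spikes=spikes)


# ---------------------------------------------------------------------------
# Whole sessions
# ---------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Two-stimulus session: a physical segment then a rivalry segment."""

    labels: tuple[str, str] = ("face", "object")
    n_physical_trials: int = 200
    n_perceptual_trials: int = 600
    trial_duration_ms: float = 800.0
    n_units: int = 50
    model: str = "IIa"
    w_dom: float = 0.65
    mixture_proportion: float = 0.0
    saccade_gain_amplitude: float = 0.5
    iib_epoch_ms: float = 50.0
    dynamics: RivalryDynamicsParams = field(default_factory=RivalryDynamicsParams)
    oculomotor: OculomotorParams = field(default_factory=OculomotorParams)
    label_mean_hz: dict | None = None
    baseline_mean_hz: float = 5.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["labels"] = list(self.labels)
        return d


@dataclass
class Session:
    """A complete synthetic session plus its ground truth."""

    trials: pd.DataFrame
    percept: PerceptTrajectory
    eye: EyeTrace
    recording: PopulationRecording
    saccade_times: np.ndarray  # ground-truth movement onsets
    truth: pd.DataFrame  # trial_id, true_label
    config: dict


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _concat_trajectories(pieces: list[tuple[str, float, float]]) -> PerceptTrajectory:
    labs: list[str] = []
    starts: list[float] = []
    ends: list[float] = []
    for lab, s, e in pieces:
        if labs and labs[-1] == lab:
            ends[-1] = e
        else:
            labs.append(lab)
            starts.append(s)
            ends.append(e)
    return PerceptTrajectory(np.array(labs, dtype=object), starts, ends)


def simulate_session(cfg: SessionConfig) -> Session:
    """Simulate a full two-stimulus session under the configured model."""
    seeds = _child_seeds(cfg.seed, 7)
    dur = cfg.trial_duration_ms
    dyn_phys = RivalryDynamicsParams(
        cfg.dynamics.median_dominance_face_s,
        cfg.dynamics.median_dominance_object_s,
        cfg.dynamics.duration_shape,
        0.0,
        seeds[0],
    )
    span_phys = cfg.n_physical_trials * dur
    traj_phys = generate_percept_trajectory(dyn_phys, span_phys, cfg.labels, 0.0)
    trials_phys = generate_trial_table(
        cfg.n_physical_trials, "physical", cfg.labels, seeds[1], dur, 0.0, traj_phys, "phys"
    )

    t1 = span_phys
    dyn_perc = RivalryDynamicsParams(
        cfg.dynamics.median_dominance_face_s,
        cfg.dynamics.median_dominance_object_s,
        cfg.dynamics.duration_shape,
        0.0,
        seeds[2],
    )
    traj_perc = generate_percept_trajectory(
        dyn_perc, cfg.n_perceptual_trials * dur + dur, cfg.labels, t1
    )
    if cfg.mixture_proportion > 0:
        traj_perc = inject_mixed_percepts(traj_perc, cfg.mixture_proportion, seeds[3], dur)
    trials_perc = generate_trial_table(
        cfg.n_perceptual_trials, "perceptual", cfg.labels, seeds[4], dur, t1, None, "perc"
    )
    trials_perc["trial_id"] += len(trials_phys)
    trials = pd.concat([trials_phys, trials_perc], ignore_index=True)

    # Session-wide percept: shown stimulus during physical trials, rivalry after.
    pieces: list[tuple[str, float, float]] = []
    for _, tr in trials_phys.iterrows():
        shown = list(trial_images(tr).values())[0]
        pieces.append((shown, float(tr["onset_ms"]), float(tr["onset_ms"]) + dur))
    for lab, s, e in zip(traj_perc.labels, traj_perc.starts, traj_perc.ends):
        pieces.append((str(lab), float(s), float(e)))
    percept = _concat_trajectories(pieces)

    oc = OculomotorParams(**{**asdict(cfg.oculomotor), "seed": seeds[5]})
    eye, saccades = generate_eye_trace(trials, percept, oc)

    baseline, rates, units = draw_population_rates(
        cfg.n_units, cfg.labels, seeds[6],
        label_mean_hz=cfg.label_mean_hz, baseline_mean_hz=cfg.baseline_mean_hz,
    )
    enc = EncodingModelParams(
        model=cfg.model,
        baseline_hz=baseline,
        stimulus_rates_hz=rates,
        w_dom=cfg.w_dom,
        saccade_gain_amplitude=cfg.saccade_gain_amplitude,
        iib_epoch_ms=cfg.iib_epoch_ms,
        seed=seeds[0] ^ seeds[6],
    )
    rec = generate_population_spikes(trials, percept, saccades, enc, units)

    truth = pd.DataFrame(
        {
            "trial_id": trials["trial_id"],
            "true_label": [
                _trial_percept_info(tr, percept)[0] for _, tr in trials.iterrows()
            ],
        }
    )
    return Session(trials, percept, eye, rec, saccades, truth, cfg.to_dict())


@dataclass
class BlockSessionConfig:
    """Three-image block session for the suppressed-stimulus experiment.

    Blocks alternate between rivalry pairs (A,B) and (A,C).  Each block
    holds ``physical_trials_per_block`` unambiguous monocular trials (each
    pair image at each of the four spot positions) followed by
    ``perceptual_trials_per_block`` rivalry trials cycling the 12 position
    pairs.
    """

    labels: tuple[str, str, str] = ("A", "B", "C")
    n_blocks: int = 84
    physical_trials_per_block: int = 8
    perceptual_trials_per_block: int = 12
    trial_duration_ms: float = 800.0
    n_units: int = 80
    model: str = "IIa"
    w_dom: float = 0.65
    saccade_gain_amplitude: float = 0.5
    iib_epoch_ms: float = 50.0
    dynamics: RivalryDynamicsParams = field(default_factory=RivalryDynamicsParams)
    oculomotor: OculomotorParams = field(default_factory=OculomotorParams)
    baseline_mean_hz: float = 5.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["labels"] = list(self.labels)
        return d


def simulate_block_session(cfg: BlockSessionConfig) -> Session:
    """Simulate the (A,B)/(A,C) block experiment under the configured model."""
    a, b, c = cfg.labels
    seeds = _child_seeds(cfg.seed, 4 + cfg.n_blocks)
    rng = np.random.default_rng(seeds[0])
    dur = cfg.trial_duration_ms
    n_phys = cfg.physical_trials_per_block
    n_perc = cfg.perceptual_trials_per_block

    rows: list[dict] = []
    pieces: list[tuple[str, float, float]] = []
    t = 0.0
    for blk in range(cfg.n_blocks):
        other = b if blk % 2 == 0 else c
        pair_name = f"{a}{other}"
        # physical trials: each pair image at each of the 4 positions
        combos = [(img, pos) for img in (a, other) for pos in SPOT_POSITIONS]
        combos = [combos[i] for i in rng.permutation(len(combos))][:n_phys]
        for shown, pos in combos:
            right_eye = shown == a
            rows.append(
                dict(
                    onset_ms=t,
                    duration_ms=dur,
                    condition="physical",
                    image_left="" if right_eye else shown,
                    image_right=shown if right_eye else "",
                    fix_left="" if right_eye else pos,
                    fix_right=pos if right_eye else "",
                    block_id=f"{pair_name}_{blk}",
                )
            )
            pieces.append((shown, t, t + dur))
            t += dur
        # perceptual trials with a fresh dominance trajectory for this block
        dyn = RivalryDynamicsParams(
            cfg.dynamics.median_dominance_face_s,
            cfg.dynamics.median_dominance_object_s,
            cfg.dynamics.duration_shape,
            0.0,
            seeds[4 + blk],
        )
        traj = generate_percept_trajectory(dyn, n_perc * dur, (a, other), t)
        for lab, s, e in zip(traj.labels, traj.starts, traj.ends):
            pieces.append((str(lab), float(s), float(e)))
        idx = rng.permutation(len(POSITION_PAIRS))[:n_perc]
        for i in idx:
            fix_left, fix_right = POSITION_PAIRS[i]
            rows.append(
                dict(
                    onset_ms=t,
                    duration_ms=dur,
                    condition="perceptual",
                    image_left=other,
                    image_right=a,
                    fix_left=fix_left,
                    fix_right=fix_right,
                    block_id=f"{pair_name}_{blk}",
                )
            )
            t += dur

    trials = pd.DataFrame(rows)
    trials.insert(0, "trial_id", np.arange(len(trials)))
    trials = trials[TRIAL_COLUMNS]
    percept = _concat_trajectories(pieces)

    oc = OculomotorParams(**{**asdict(cfg.oculomotor), "seed": seeds[1]})
    eye, saccades = generate_eye_trace(trials, percept, oc)

    baseline, rates, units = draw_population_rates(
        cfg.n_units, cfg.labels, seeds[2],
        label_mean_hz={a: 20.0, b: 8.0, c: 8.0},
        baseline_mean_hz=cfg.baseline_mean_hz,
    )
    enc = EncodingModelParams(
        model=cfg.model,
        baseline_hz=baseline,
        stimulus_rates_hz=rates,
        w_dom=cfg.w_dom,
        saccade_gain_amplitude=cfg.saccade_gain_amplitude,
        iib_epoch_ms=cfg.iib_epoch_ms,
        seed=seeds[3],
    )
    rec = generate_population_spikes(trials, percept, saccades, enc, units)
    truth = pd.DataFrame(
        {
            "trial_id": trials["trial_id"],
            "true_label": [
                _trial_percept_info(tr, percept)[0] for _, tr in trials.iterrows()
            ],
        }
    )
    return Session(trials, percept, eye, rec, saccades, truth, cfg.to_dict())
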