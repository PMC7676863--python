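"""Percept inference from gaze, saccade detection, and eye statistics.

The conscious percept on a trial is inferred from which dichoptic fixation
spot the subject tracked: gaze must stay within 0.5 degrees (L1 norm) of a
spot for at least half the trial duration (non-contiguously), evaluated in
a window delayed by the 350-ms average saccade latency.  Saccades are
detected from the displacement between stable 100-ms pre/post windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    UNDETERMINED,
    EyeTrace,
    spot_xy,
    trial_images,
    trial_spots,
)

logger = logging.getLogger(__name__)


def compute_spot_distance(eye: EyeTrace, spot_position) -> np.ndarray:
    """Per-sample L1 distance |dx| + |dy| (degrees) from a fixation spot."""
    spot = np.asarray(spot_position, dtype=float)
    return np.abs(eye.xy - spot[None, :]).sum(axis=1)


@dataclass
class TrialPercept:
    """Inferred percept for one trial."""

    trial_id: int
    label: str
    dwell_ms: dict[str, float]
    is_switch: bool | None = None
    passes_consistency: bool | None = None

    @property
    def determined(self) -> bool:
        return self.label != UNDETERMINED


def infer_trial_percept(
    eye: EyeTrace,
    trial,
    radius_deg: float = 0.5,
    delay_ms: float = 350.0,
) -> TrialPercept:
    """Infer the percept of one trial from gaze dwell near each spot.

    Dwell (not required to be contiguous) is accumulated over the window
    ``[onset + delay, onset + duration + delay)``; a stimulus label is
    assigned when its spot's dwell reaches half the trial duration.  Trials
    where no spot (or, guarded although geometrically impossible for
    distinct spots at this radius, both spots) qualifies are undetermined.
    """
    onset = float(trial["onset_ms"])
    duration = float(trial["duration_ms"])
    window = eye.window(onset + delay_ms, onset + duration + delay_ms)
    images = trial_images(trial)
    spots = trial_spots(trial)
    dwell = {lab: 0.0 for lab in images.values()}
    if window is None:
        logger.warning("trial %s: eye trace does not cover analysis window", trial["trial_id"])
        return TrialPercept(int(trial["trial_id"]), UNDETERMINED, dwell)

    for eye_name, label in images.items():
        name = spots.get(eye_name)
        if name is None:
            continue
        d = np.abs(window - spot_xy(name)[None, :]).sum(axis=1)
        dwell[label] = float(np.sum(d <= radius_deg)) * eye.dt_ms

    qualifying = [lab for lab, ms in dwell.items() if ms >= duration / 2.0]
    label = qualifying[0] if len(qualifying) == 1 else UNDETERMINED
    return TrialPercept(int(trial["trial_id"]), label, dwell)


def label_session(
    eye: EyeTrace,
    trials: pd.DataFrame,
    radius_deg: float = 0.5,
    delay_ms: float = 350.0,
) -> pd.DataFrame:
    """Infer percepts for every trial and flag switches and consistency.

    ``is_switch`` marks determined trials whose label differs from the
    previous determined trial; ``passes_consistency`` marks trials whose
    immediately following trial has the same inferred label (the filter
    used to exclude switch-back trials from modulation and decoding
    analyses).
    """
    percepts = [
        infer_trial_percept(eye, trial, radius_deg, delay_ms)
        for _, trial in trials.iterrows()
    ]
    prev_label: str | None = None
    for p in percepts:
        if p.determined:
            p.is_switch = prev_label is not None and p.label != prev_label
            prev_label = p.label
        else:
            p.is_switch = False
    for i, p in enumerate(percepts):
        nxt = percepts[i + 1] if i + 1 < len(percepts) else None
        p.passes_consistency = (
            p.determined and nxt is not None and nxt.label == p.label
        )

    all_labels = sorted({lab for p in percepts for lab in p.dwell_ms})
    rows = []
    for p in percepts:
        row = {
            "trial_id": p.trial_id,
            "label": p.label,
            "determined": p.determined,
            "is_switch": bool(p.is_switch),
            "passes_consistency": bool(p.passes_consistency),
        }
        for lab in all_labels:
            row[f"dwell_{lab}_ms"] = p.dwell_ms.get(lab, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SaccadeEvent:
    time_ms: float
    pre_position: tuple[float, float]
    post_position: tuple[float, float]
    amplitude_deg: float


def detect_saccades(
    eye: EyeTrace,
    threshold_deg: float = 0.5,
    window_ms: float = 100.0,
    stability_frac: float = 0.8,
    min_separation_ms: float = 100.0,
) -> list[SaccadeEvent]:
    """Displacement-based saccade detection with stable flanks.

    A saccade is detected at time t when the Euclidean distance between the
    mean eye position over ``t-100..t-2`` ms and over ``t+2..t+100`` ms
    exceeds the threshold, and within each flank at least
    ``stability_frac`` of samples lie within the threshold of that flank's
    mean.  Detections are thinned greedily in time order so consecutive
    saccades are at least ``min_separation_ms`` apart.
    """
    dt = eye.dt_ms
    w = int(round(window_ms / dt))  # flank reach in samples (offset 2..w)
    off = int(round(2.0 / dt))
    m = w - off + 1  # samples per flank
    n = eye.n_samples
    if n <= 2 * w:
        return []

    csum = np.concatenate([np.zeros((1, 2)), np.cumsum(eye.xy, axis=0)])
    t_idx = np.arange(w, n - w)
    pre_mean = (csum[t_idx - off + 1] - csum[t_idx - w]) / m
    post_mean = (csum[t_idx + w + 1] - csum[t_idx + off]) / m
    amp = np.linalg.norm(post_mean - pre_mean, axis=1)
    cand = amp > threshold_deg

    # Stability: count flank samples within threshold of the flank mean.
    pre_ok = np.zeros(len(t_idx))
    post_ok = np.zeros(len(t_idx))
    for d in range(off, w + 1):
        pre_ok += (
            np.linalg.norm(eye.xy[t_idx - d] - pre_mean, axis=1) <= threshold_deg
        )
        post_ok += (
            np.linalg.norm(eye.xy[t_idx + d] - post_mean, axis=1) <= threshold_deg
        )
    cand &= (pre_ok / m >= stability_frac) & (post_ok / m >= stability_frac)

    events: list[SaccadeEvent] = []
    last_t = -np.inf
    for k in np.flatnonzero(cand):
        t = eye.start_ms + t_idx[k] * dt
        if t - last_t < min_separation_ms:
            continue
        last_t = t
        events.append(
            SaccadeEvent(
                time_ms=float(t),
                pre_position=tuple(pre_mean[k]),
                post_position=tuple(post_mean[k]),
                amplitude_deg=float(amp[k]),
            )
        )
    return events


def saccades_to_frame(events: list[SaccadeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_ms": [e.time_ms for e in events],
            "amplitude_deg": [e.amplitude_deg for e in events],
            "pre_x": [e.pre_position[0] for e in events],
            "pre_y": [e.pre_position[1] for e in events],
            "post_x": [e.post_position[0] for e in events],
            "post_y": [e.post_position[1] for e in events],
        }
    )


def report_concordance(inferred, reported) -> float:
    """Fraction of mutually determined trials where the two labels agree."""
    inferred = np.asarray(inferred, dtype=object)
    reported = np.asarray(reported, dtype=object)
    if len(inferred) != len(reported):
        raise ValueError("label streams must be aligned")
    ok = (inferred != UNDETERMINED) & (reported != UNDETERMINED)
    if not np.any(ok):
        raise ValueError("no mutually determined trials")
    return float(np.mean(inferred[ok] == reported[ok]))


def simulate_reports(
    true_labels,
    labels: tuple[str, str],
    lapse_rate: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Button-press reports: the true percept, flipped at the lapse rate."""
    rng = np.random.default_rng(seed)
    out = []
    for lab in true_labels:
        if lab not in labels:
            out.append(UNDETERMINED)
        elif rng.random() < lapse_rate:
            out.append(labels[0] if lab == labels[1] else labels[1])
        else:
            out.append(lab)
    return np.asarray(out, dtype=object)


def eye_jitter_stats(eye: EyeTrace) -> tuple[float, float]:
    """(median, 99th percentile) of adjacent-sample step magnitudes (deg)."""
    if eye.n_samples < 2:
        raise ValueError("need at least two samples")
    steps = np.linalg.norm(np.diff(eye.xy, axis=0), axis=1)
    return float(np.median(steps)), float(np.percentile(steps, 99))
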