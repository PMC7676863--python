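"""Core in-memory containers shared across the pipeline.

All times are on a single session clock in milliseconds; trial windows are
half-open ``[onset, onset + duration)``.  Gaze coordinates are degrees of
visual angle with the screen center at the origin, x rightward, y upward.
Fixation spots sit 1 degree from the center at one of four named positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Named fixation-spot positions, 1 degree from screen center.
SPOT_POSITIONS: dict[str, tuple[float, float]] = {
    "top": (0.0, 1.0),
    "bottom": (0.0, -1.0),
    "left": (-1.0, 0.0),
    "right": (1.0, 0.0),
}

#: Label for a piecemeal/mixed percept state.
MIXED_LABEL = "mixed"

#: Label assigned to trials where gaze qualifies for no (or both) spots.
UNDETERMINED = "undetermined"

#: Column schema of a trial table.
TRIAL_COLUMNS = [
    "trial_id",
    "onset_ms",
    "duration_ms",
    "condition",
    "image_left",
    "image_right",
    "fix_left",
    "fix_right",
    "block_id",
]


def spot_xy(name: str) -> np.ndarray:
    return np.asarray(SPOT_POSITIONS[name], dtype=float)


@dataclass
class PerceptTrajectory:
    """Piecewise-constant perceptual dominance state over session time.

    ``labels[i]`` holds between ``starts[i]`` (inclusive) and ``ends[i]``
    (exclusive).  Intervals are contiguous and non-overlapping and adjacent
    states differ.
    """

    labels: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        n = len(self.labels)
        if not (len(self.starts) == len(self.ends) == n) or n == 0:
            raise ValueError("labels/starts/ends must be equal-length and non-empty")
        if np.any(self.ends <= self.starts):
            raise ValueError("every state must have positive duration")
        if n > 1:
            if not np.allclose(self.starts[1:], self.ends[:-1]):
                raise ValueError("states must be contiguous")
            if np.any(self.labels[1:] == self.labels[:-1]):
                raise ValueError("adjacent states must differ")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.starts[0]), float(self.ends[-1])

    def covers(self, t0: float, t1: float) -> bool:
        return self.starts[0] <= t0 and t1 <= self.ends[-1]

    def _index_at(self, t: float) -> int:
        i = int(np.searchsorted(self.starts, t, side="right")) - 1
        if i < 0 or t >= self.ends[i]:
            raise ValueError(f"time {t} ms outside trajectory span {self.span}")
        return i

    def state_at(self, t: float) -> str:
        return str(self.labels[self._index_at(t)])

    def states_at(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.starts, times, side="right") - 1
        if np.any(idx < 0) or np.any(times >= self.ends[idx]):
            raise ValueError("some times fall outside the trajectory span")
        return self.labels[idx]

    def segments_in(self, t0: float, t1: float) -> list[tuple[str, float, float]]:
        """States overlapping ``[t0, t1)``, clipped to that window."""
        if not self.covers(t0, t1):
            raise ValueError("trajectory does not cover the requested window")
        i0 = self._index_at(t0)
        out: list[tuple[str, float, float]] = []
        for i in range(i0, len(self.labels)):
            if self.starts[i] >= t1:
                break
            out.append(
                (
                    str(self.labels[i]),
                    float(max(self.starts[i], t0)),
                    float(min(self.ends[i], t1)),
                )
            )
        return out

    def majority_label(self, t0: float, t1: float) -> str:
        """State occupying the largest share of ``[t0, t1)``; earlier wins ties."""
        best, best_dur = None, -1.0
        totals: dict[str, float] = {}
        for lab, s, e in self.segments_in(t0, t1):
            totals[lab] = totals.get(lab, 0.0) + (e - s)
            if totals[lab] > best_dur:
                best, best_dur = lab, totals[lab]
        assert best is not None
        return best

    def switch_times(self) -> np.ndarray:
        return self.starts[1:].copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"state": self.labels, "start_ms": self.starts, "end_ms": self.ends}
        )


@dataclass
class EyeTrace:
    """Uniformly sampled 2D gaze positions in degrees of visual angle."""

    start_ms: float
    rate_hz: float
    xy: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n_samples, 2)")
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("gaze samples must be finite")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate_hz

    @property
    def n_samples(self) -> int:
        return self.xy.shape[0]

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.n_samples * self.dt_ms

    @property
    def times(self) -> np.ndarray:
        return self.start_ms + np.arange(self.n_samples) * self.dt_ms

    def index(self, t: float) -> int:
        """Sample index whose time is closest to ``t`` (no bounds clipping)."""
        return int(round((t - self.start_ms) / self.dt_ms))

    def window(self, t0: float, t1: float) -> np.ndarray | None:
        """Samples covering ``[t0, t1)``, or ``None`` if not fully recorded."""
        i0, i1 = self.index(t0), self.index(t1)
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            return None
        return self.xy[i0:i1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_ms": self.times, "x_deg": self.xy[:, 0], "y_deg": self.xy[:, 1]}
        )


@dataclass
class PopulationRecording:
    """Spike events for a population of simultaneously recorded units.

    ``units`` carries one row per unit (``unit_id`` plus metadata such as
    ground-truth rates for synthetic populations); ``spikes`` has columns
    ``unit_id`` and ``t_ms``.
    """

    units: pd.DataFrame
    spikes: pd.DataFrame
    _by_unit: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if "unit_id" not in self.units.columns:
            raise ValueError("units table needs a unit_id column")
        if self.units["unit_id"].duplicated().any():
            raise ValueError("unit_ids must be unique")
        missing = {"unit_id", "t_ms"} - set(self.spikes.columns)
        if missing:
            raise ValueError(f"spikes table missing columns: {sorted(missing)}")

    @property
    def unit_ids(self) -> np.ndarray:
        return self.units["unit_id"].to_numpy()

    @property
    def n_units(self) -> int:
        return len(self.units)

    def spike_times(self, unit_id) -> np.ndarray:
        if self._by_unit is None:
            by = {}
            for uid, grp in self.spikes.groupby("unit_id"):
                by[uid] = np.sort(grp["t_ms"].to_numpy(dtype=float))
            self._by_unit = by
        return self._by_unit.get(unit_id, np.empty(0))


def trial_images(trial) -> dict[str, str]:
    """Non-empty stimulus per eye for one trial row: {'left': lab, ...}."""
    out = {}
    for eye, col in (("left", "image_left"), ("right", "image_right")):
        lab = trial[col]
        if isinstance(lab, str) and lab:
            out[eye] = lab
    return out


def trial_spots(trial) -> dict[str, str]:
    """Fixation-spot name per eye for one trial row (empty eyes omitted)."""
    out = {}
    for eye, col in (("left", "fix_left"), ("right", "fix_right")):
        name = trial[col]
        if isinstance(name, str) and name:
            out[eye] = name
    return out


def spot_of_image(trial, label: str) -> np.ndarray | None:
    """Coordinates of the fixation spot shown in the eye carrying ``label``."""
    for eye, lab in trial_images(trial).items():
        if lab == label:
            name = trial_spots(trial).get(eye)
            return None if name is None else spot_xy(name)
    return None
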