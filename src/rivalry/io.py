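"""Session-bundle readers and writers.

A session directory holds plain-text tables sharing one session clock in
milliseconds:

* ``trials.csv``  — trial_id,onset_ms,duration_ms,condition,image_left,
  image_right,fix_left,fix_right,block_id
* ``eye.csv``     — t_ms,x_deg,y_deg (uniformly sampled)
* ``spikes.csv``  — unit_id,t_ms
* ``units.csv``   — unit metadata (optional)
* ``config.json`` — generator/run configuration and provenance
* ``truth.json``  — ground-truth percept per trial (synthetic sessions)

Validation errors name the offending file and row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .synth import Session
from .types import TRIAL_COLUMNS, EyeTrace, PopulationRecording


class SessionValidationError(ValueError):
    pass


@dataclass
class SessionBundle:
    """A validated on-disk session loaded into memory."""

    trials: pd.DataFrame
    eye: EyeTrace
    recording: PopulationRecording
    config: dict
    truth: pd.DataFrame | None = None
    path: Path | None = None


def write_session(session: Session, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(out / "trials.csv", index=False)
    session.eye.to_frame().to_csv(out / "eye.csv", index=False, float_format="%.8g")
    session.recording.spikes.to_csv(out / "spikes.csv", index=False, float_format="%.8g")
    session.recording.units.to_csv(out / "units.csv", index=False, float_format="%.6g")
    truth = {
        "per_trial": {
            str(tid): lab
            for tid, lab in zip(session.truth["trial_id"], session.truth["true_label"])
        },
        "saccade_times_ms": [float(t) for t in session.saccade_times],
        "config": session.config,
    }
    (out / "truth.json").write_text(json.dumps(truth))
    config = dict(session.config)
    config["rivalry_version"] = __version__
    (out / "config.json").write_text(json.dumps(config, indent=2))
    return out


def _require(path: Path) -> Path:
    if not path.exists():
        raise SessionValidationError(f"missing session file: {path}")
    return path


def _validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SessionValidationError(f"trials.csv missing columns: {sorted(missing)}")
    df = df.copy()
    for col in ("image_left", "image_right", "fix_left", "fix_right", "block_id"):
        df[col] = df[col].fillna("").astype(str)
    if df["trial_id"].duplicated().any():
        row = int(df.index[df["trial_id"].duplicated()][0])
        raise SessionValidationError(f"trials.csv row {row}: duplicate trial_id")
    order = df.sort_values("onset_ms")
    ends = order["onset_ms"].to_numpy() + order["duration_ms"].to_numpy()
    overlap = np.flatnonzero(order["onset_ms"].to_numpy()[1:] < ends[:-1] - 1e-9)
    if len(overlap):
        row = int(order.index[overlap[0] + 1])
        raise SessionValidationError(f"trials.csv row {row}: trial overlaps its predecessor")
    return df


def _validate_eye(df: pd.DataFrame) -> EyeTrace:
    for col in ("t_ms", "x_deg", "y_deg"):
        if col not in df.columns:
            raise SessionValidationError(f"eye.csv missing column {col}")
    t = df["t_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SessionValidationError("eye.csv needs at least two samples")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if len(bad):
        raise SessionValidationError(
            f"eye.csv row {int(bad[0]) + 1}: non-increasing timestamp"
        )
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > step * 0.01:
        row = int(np.argmax(np.abs(dt - step))) + 1
        raise SessionValidationError(f"eye.csv row {row}: non-uniform sampling")
    return EyeTrace(float(t[0]), 1000.0 / step, df[["x_deg", "y_deg"]].to_numpy(dtype=float))


def read_session(session_dir) -> SessionBundle:
    """Load and schema-validate a session directory."""
    d = Path(session_dir)
    if not d.is_dir():
        raise SessionValidationError(f"not a session directory: {d}")
    trials = _validate_trials(pd.read_csv(_require(d / "trials.csv")))
    eye = _validate_eye(pd.read_csv(_require(d / "eye.csv")))
    spikes = pd.read_csv(_require(d / "spikes.csv"))
    if not {"unit_id", "t_ms"} <= set(spikes.columns):
        raise SessionValidationError("spikes.csv must have unit_id,t_ms columns")
    t0 = float(trials["onset_ms"].min())
    t1 = float((trials["onset_ms"] + trials["duration_ms"]).max())
    out_of_bounds = np.flatnonzero(
        (spikes["t_ms"].to_numpy(dtype=float) < t0 - 1000.0)
        | (spikes["t_ms"].to_numpy(dtype=float) > t1 + 2000.0)
    )
    if len(out_of_bounds):
        raise SessionValidationError(
            f"spikes.csv row {int(out_of_bounds[0])}: spike time outside session bounds"
        )
    units_path = d / "units.csv"
    if units_path.exists():
        units = pd.read_csv(units_path)
    else:
        units = pd.DataFrame({"unit_id": np.sort(spikes["unit_id"].unique())})
    rec = PopulationRecording(units=units, spikes=spikes)

    config: dict = {}
    if (d / "config.json").exists():
        config = json.loads((d / "config.json").read_text())
    truth = None
    if (d / "truth.json").exists():
        raw = json.loads((d / "truth.json").read_text())
        truth = pd.DataFrame(
            {
                "trial_id": [int(k) for k in raw["per_trial"]],
                "true_label": list(raw["per_trial"].values()),
            }
        )
        config.setdefault("truth", {})
        config["truth"] = {k: v for k, v in raw.items() if k != "per_trial"}
    return SessionBundle(trials=trials, eye=eye, recording=rec, config=config,
                         truth=truth, path=d)


def bundle_from_session(session: Session) -> SessionBundle:
    """Wrap an in-memory synthetic session as an analysis-ready bundle."""
    config = dict(session.config)
    config["truth"] = {"saccade_times_ms": [float(t) for t in session.saccade_times]}
    return SessionBundle(
        trials=session.trials,
        eye=session.eye,
        recording=session.recording,
        config=config,
        truth=session.truth,
    )
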