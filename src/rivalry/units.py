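"""Per-unit selectivity, modulation indices, PSTHs, and saccade-triggered
response analyses.

Responses are spike counts over the full 800-ms trial window.  Selectivity
uses a two-sided two-sample t-test (pooled variance); modulation indices
are (R_face - R_object) / (R_face + R_object).  Saccade-triggered analyses
normalize each unit so its mean physical-condition object response is -1
and face response is +1, then average across units per event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import PopulationRecording

logger = logging.getLogger(__name__)

CATEGORY_CONSISTENT = "consistent_significant"
CATEGORY_INCONSISTENT = "inconsistent_significant"
CATEGORY_NONSIG = "nonsignificant"


def trial_spike_counts(rec: PopulationRecording, trials: pd.DataFrame) -> np.ndarray:
    """Unit x trial spike counts over half-open windows [onset, onset+dur)."""
    onsets = trials["onset_ms"].to_numpy(dtype=float)
    ends = onsets + trials["duration_ms"].to_numpy(dtype=float)
    counts = np.zeros((rec.n_units, len(trials)), dtype=int)
    for i, uid in enumerate(rec.unit_ids):
        t = rec.spike_times(uid)
        counts[i] = np.searchsorted(t, ends, side="left") - np.searchsorted(
            t, onsets, side="left"
        )
    return counts


def selectivity_test(counts_a, counts_b) -> tuple[float, float]:
    """Two-sided two-sample t-test with pooled variance.

    Degenerate inputs (both samples constant) return t=0, p=1 when the
    means agree and t=+/-inf, p=0 when they differ.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two trials per class")
    if np.var(a) == 0 and np.var(b) == 0:
        logger.warning("selectivity_test: zero-variance degenerate input")
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float(np.sign(np.mean(a) - np.mean(b)) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def modulation_index(r_a, r_b):
    """(R_a - R_b) / (R_a + R_b); NaN when the denominator is zero.

    Antisymmetric in its arguments, invariant to positive rescaling, zero
    at equality, and bounded in [-1, 1] for nonnegative responses.
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    denom = r_a + r_b
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = np.where(denom != 0, (r_a - r_b) / denom, np.nan)
    if np.any(denom == 0):
        logger.warning("modulation_index undefined for %d zero-denominator inputs",
                       int(np.sum(denom == 0)))
    return mi if mi.ndim else float(mi)


def compute_cell_stats(
    counts: np.ndarray,
    unit_ids,
    phys_labels,
    perc_labels,
    face_label: str,
    object_label: str,
    phys_mask: np.ndarray,
    perc_mask: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-unit responses, selectivity p-values, MIs, and categories.

    ``phys_mask``/``perc_mask`` select the analyzable trials of each
    condition (determined percept plus next-trial-consistency filter);
    ``phys_labels``/``perc_labels`` give the per-trial class labels.
    """
    phys_labels = np.asarray(phys_labels, dtype=object)
    perc_labels = np.asarray(perc_labels, dtype=object)
    rows = []
    for i, uid in enumerate(unit_ids):
        cf = counts[i, phys_mask & (phys_labels == face_label)]
        co = counts[i, phys_mask & (phys_labels == object_label)]
        pf = counts[i, perc_mask & (perc_labels == face_label)]
        po = counts[i, perc_mask & (perc_labels == object_label)]
        t_phys, p_phys = selectivity_test(cf, co)
        t_perc, p_perc = selectivity_test(pf, po)
        rows.append(
            dict(
                unit_id=uid,
                R_face=float(np.mean(cf)),
                R_object=float(np.mean(co)),
                R_face_perc=float(np.mean(pf)),
                R_object_perc=float(np.mean(po)),
                MI_physical=modulation_index(np.mean(cf), np.mean(co)),
                MI_perceptual=modulation_index(np.mean(pf), np.mean(po)),
                p_physical=p_phys,
                p_perceptual=p_perc,
                t_physical=t_phys,
                t_perceptual=t_perc,
            )
        )
    df = pd.DataFrame(rows)
    df["category"] = _categories(df, alpha)
    return df


def _categories(stats_df: pd.DataFrame, alpha: float) -> list[str]:
    cats = []
    for _, r in stats_df.iterrows():
        if not np.isfinite(r["MI_perceptual"]) or r["p_perceptual"] >= alpha:
            cats.append(CATEGORY_NONSIG)
        elif np.sign(r["MI_perceptual"]) == np.sign(r["MI_physical"]):
            cats.append(CATEGORY_CONSISTENT)
        else:
            cats.append(CATEGORY_INCONSISTENT)
    return cats


def classify_cells(stats_df: pd.DataFrame, alpha: float = 0.05) -> dict[str, int]:
    """Category counts over physically selective units.

    Units are pre-filtered to those with significant physical selectivity;
    among them, perceptual modulation is classified as consistent (same
    preference sign as the physical condition), inconsistent, or
    non-significant.
    """
    sel = stats_df[stats_df["p_physical"] < alpha]
    cats = _categories(sel, alpha)
    return {
        "n_selective": len(sel),
        CATEGORY_CONSISTENT: cats.count(CATEGORY_CONSISTENT),
        CATEGORY_INCONSISTENT: cats.count(CATEGORY_INCONSISTENT),
        CATEGORY_NONSIG: cats.count(CATEGORY_NONSIG),
    }


def mi_correlation(stats_df: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson correlation between physical and perceptual MIs."""
    ok = np.isfinite(stats_df["MI_physical"]) & np.isfinite(stats_df["MI_perceptual"])
    x = stats_df.loc[ok, "MI_physical"]
    y = stats_df.loc[ok, "MI_perceptual"]
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(ok.sum())


# ---------------------------------------------------------------------------
# PSTHs and saccade-triggered responses
# ---------------------------------------------------------------------------

def compute_psth(
    rec: PopulationRecording,
    align_times,
    window_ms: tuple[float, float] = (-400.0, 800.0),
    bin_ms: float = 1.0,
    smooth_ms: float = 100.0,
    baseline_window_ms: tuple[float, float] | None = None,
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-aligned mean firing rate per unit, box-smoothed.

    Returns (rates, bin_centers) with rates in Hz, shape
    (n_units, n_bins).  Optional baseline subtraction and peak
    normalization mirror the display convention for population averages.
    """
    align_times = np.asarray(align_times, dtype=float)
    if len(align_times) == 0:
        raise ValueError("need at least one alignment event")
    w0, w1 = window_ms
    edges = np.arange(w0, w1 + bin_ms / 2, bin_ms)
    centers = edges[:-1] + bin_ms / 2.0
    out = np.zeros((rec.n_units, len(centers)))
    for i, uid in enumerate(rec.unit_ids):
        t = rec.spike_times(uid)
        for at in align_times:
            lo = np.searchsorted(t, at + w0)
            hi = np.searchsorted(t, at + w1)
            if hi > lo:
                h, _ = np.histogram(t[lo:hi] - at, bins=edges)
                out[i] += h
    out *= 1000.0 / (bin_ms * len(align_times))  # Hz
    k = max(int(round(smooth_ms / bin_ms)), 1)
    kernel = np.ones(k) / k
    out = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 1, out)
    if baseline_window_ms is not None:
        b = (centers >= baseline_window_ms[0]) & (centers < baseline_window_ms[1])
        out = out - out[:, b].mean(axis=1, keepdims=True)
    if normalize:
        peak = np.abs(out).max(axis=1, keepdims=True)
        peak[peak == 0] = 1.0
        out = out / peak
    return out, centers


def normalize_pm1(x, face_mean: float, object_mean: float):
    """Affine map sending object_mean -> -1 and face_mean -> +1."""
    if face_mean == object_mean:
        raise ValueError("face and object means must differ")
    x = np.asarray(x, dtype=float)
    out = 2.0 * (x - object_mean) / (face_mean - object_mean) - 1.0
    return out if out.ndim else float(out)


def event_window_rates(
    rec: PopulationRecording,
    event_times,
    window_ms: tuple[float, float] = (0.0, 400.0),
    unit_ids=None,
) -> np.ndarray:
    """Firing rate (Hz) per event and unit in a window around each event."""
    event_times = np.asarray(event_times, dtype=float)
    ids = rec.unit_ids if unit_ids is None else np.asarray(unit_ids)
    w0, w1 = window_ms
    out = np.empty((len(event_times), len(ids)))
    for j, uid in enumerate(ids):
        t = rec.spike_times(uid)
        lo = np.searchsorted(t, event_times + w0)
        hi = np.searchsorted(t, event_times + w1)
        out[:, j] = (hi - lo) * 1000.0 / (w1 - w0)
    return out


def select_consistent_units(stats_df: pd.DataFrame, alpha: float = 0.05,
                            prefer_face: bool = True) -> pd.DataFrame:
    """Units significant in both conditions with consistent face preference."""
    sel = stats_df[
        (stats_df["p_physical"] < alpha)
        & (stats_df["p_perceptual"] < alpha)
        & (np.sign(stats_df["MI_physical"]) == np.sign(stats_df["MI_perceptual"]))
    ]
    if prefer_face:
        sel = sel[sel["MI_physical"] > 0]
    return sel


@dataclass
class NormalizedResponseMatrix:
    """Event x time matrix of across-unit mean +/-1-normalized responses.

    Rows (events) are sorted by the mean response in the sort window; the
    per-event scalar means feed the absolute-value distribution tests.
    """

    matrix: np.ndarray
    bin_centers_ms: np.ndarray
    event_means: np.ndarray  # sorted like matrix rows
    order: np.ndarray  # permutation applied to the input events


def unit_norm_constants(
    rec: PopulationRecording,
    phys_face_events,
    phys_object_events,
    window_ms: tuple[float, float] = (0.0, 400.0),
    unit_ids=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Physical-condition mean face/object rates per unit (the +/-1 anchors)."""
    f = event_window_rates(rec, phys_face_events, window_ms, unit_ids).mean(axis=0)
    o = event_window_rates(rec, phys_object_events, window_ms, unit_ids).mean(axis=0)
    return f, o


def normalized_event_responses(
    rec: PopulationRecording,
    event_times,
    face_means: np.ndarray,
    object_means: np.ndarray,
    window_ms: tuple[float, float] = (0.0, 400.0),
    unit_ids=None,
) -> np.ndarray:
    """Across-unit mean of +/-1-normalized rates for each event.

    Units whose face and object anchors coincide are excluded.
    """
    rates = event_window_rates(rec, event_times, window_ms, unit_ids)
    ok = face_means != object_means
    if not np.any(ok):
        raise ValueError("no unit has distinct face/object anchors")
    if not np.all(ok):
        logger.warning("excluding %d units with equal face/object means",
                       int(np.sum(~ok)))
    norm = 2.0 * (rates[:, ok] - object_means[ok]) / (face_means - object_means)[ok] - 1.0
    return norm.mean(axis=1)


def saccade_triggered_matrix(
    rec: PopulationRecording,
    event_times,
    face_means: np.ndarray,
    object_means: np.ndarray,
    unit_ids=None,
    window_ms: tuple[float, float] = (-400.0, 800.0),
    bin_ms: float = 10.0,
    smooth_ms: float = 100.0,
    sort_window_ms: tuple[float, float] = (0.0, 400.0),
) -> NormalizedResponseMatrix:
    """Event-aligned across-unit mean normalized time courses, sorted rows."""
    event_times = np.asarray(event_times, dtype=float)
    if len(event_times) == 0:
        raise ValueError("need at least one event")
    ids = rec.unit_ids if unit_ids is None else np.asarray(unit_ids)
    ok = face_means != object_means
    if not np.any(ok):
        raise ValueError("no unit has distinct face/object anchors")
    ids = np.asarray(ids)[ok]
    fm, om = face_means[ok], object_means[ok]

    w0, w1 = window_ms
    edges = np.arange(w0, w1 + bin_ms / 2, bin_ms)
    centers = edges[:-1] + bin_ms / 2.0
    acc = np.zeros((len(event_times), len(centers)))
    for j, uid in enumerate(ids):
        t = rec.spike_times(uid)
        counts = np.zeros((len(event_times), len(centers)))
        lo = np.searchsorted(t, event_times + w0)
        hi = np.searchsorted(t, event_times + w1)
        for e in range(len(event_times)):
            if hi[e] > lo[e]:
                h, _ = np.histogram(t[lo[e]:hi[e]] - event_times[e], bins=edges)
                counts[e] = h
        rates = counts * 1000.0 / bin_ms
        acc += 2.0 * (rates - om[j]) / (fm[j] - om[j]) - 1.0
    acc /= len(ids)

    k = max(int(round(smooth_ms / bin_ms)), 1)
    kernel = np.ones(k) / k
    acc = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 1, acc)

    means = normalized_event_responses(
        rec, event_times, face_means, object_means, sort_window_ms, np.asarray(ids)
    )
    order = np.argsort(means)[::-1]
    return NormalizedResponseMatrix(acc[order], centers, means[order], order)


def absolute_response_comparison(physical_means, perceptual_means,
                                 n_hist_bins: int = 20) -> dict:
    """Compare |normalized response| distributions between conditions.

    Two-sample t-test on the absolute values of per-event across-unit mean
    normalized responses; the rivalry condition is expected to span a
    smaller range than the physical condition when single cells multiplex
    the dominant and suppressed stimuli.
    """
    a = np.abs(np.asarray(physical_means, dtype=float))
    b = np.abs(np.asarray(perceptual_means, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    t, p = selectivity_test(a, b)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    edges = np.linspace(lo, hi, n_hist_bins + 1)
    return {
        "t": float(t),
        "p": float(p),
        "mean_abs_physical": float(a.mean()),
        "mean_abs_perceptual": float(b.mean()),
        "n_physical": len(a),
        "n_perceptual": len(b),
        "hist_edges": edges,
        "hist_physical": np.histogram(a, bins=edges)[0],
        "hist_perceptual": np.histogram(b, bins=edges)[0],
    }
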