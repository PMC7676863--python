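"""End-to-end orchestration: behavior -> units -> decoding -> mixture.

``run_pipeline`` executes the full analysis on a session bundle and emits a
JSON-able report (plus a markdown rendering): inferred-percept summary,
cell-category proportions, decoding accuracies with shuffle nulls, the
physical-vs-perceptual absolute-response comparison, and the mixed-percept
sweep.  Three-image block sessions additionally get the
suppressed-stimulus decoding and dual modulation-index analyses.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .behavior import detect_saccades, eye_jitter_stats, label_session, saccades_to_frame
from .decoding import (
    dual_modulation_indices,
    loo_linear_decode,
    shuffle_null,
    suppressed_stimulus_decode,
)
from .io import SessionBundle, bundle_from_session, read_session
from .mixture import mixture_sweep
from .params import OculomotorParams, RivalryDynamicsParams
from .synth import BlockSessionConfig, Session, SessionConfig, simulate_block_session, simulate_session
from .types import UNDETERMINED
from .units import (
    absolute_response_comparison,
    classify_cells,
    compute_cell_stats,
    mi_correlation,
    normalized_event_responses,
    select_consistent_units,
    trial_spike_counts,
    unit_norm_constants,
)

logger = logging.getLogger(__name__)


def _as_bundle(session) -> SessionBundle:
    if isinstance(session, SessionBundle):
        return session
    if isinstance(session, Session):
        return bundle_from_session(session)
    return read_session(session)


def _session_labels(bundle: SessionBundle) -> list[str]:
    labels = bundle.config.get("labels")
    if labels:
        return list(labels)
    imgs = set(bundle.trials["image_left"]) | set(bundle.trials["image_right"])
    return sorted(x for x in imgs if x)


def analyze_behavior(bundle: SessionBundle, radius_deg: float = 0.5,
                     delay_ms: float = 350.0) -> dict:
    """Stage 1: percept inference, saccade detection, eye statistics."""
    percepts = label_session(bundle.eye, bundle.trials, radius_deg, delay_ms)
    saccades = detect_saccades(bundle.eye)
    med, q99 = eye_jitter_stats(bundle.eye)
    out = {
        "percepts": percepts,
        "saccades": saccades,
        "jitter_median_deg": med,
        "jitter_q99_deg": q99,
    }
    if bundle.truth is not None:
        merged = percepts.merge(bundle.truth, on="trial_id")
        det = merged[merged["label"] != UNDETERMINED]
        out["n_determined"] = int(len(det))
        out["truth_recovery"] = (
            float(np.mean(det["label"] == det["true_label"])) if len(det) else np.nan
        )
    return out


def run_pipeline(
    session,
    seed: int = 0,
    alpha: float = 0.05,
    n_shuffles: int = 100,
    mixture_grid=None,
    mixture_n_rep: int = 20,
    event_window_ms: tuple[float, float] = (0.0, 400.0),
    out_dir=None,
) -> dict:
    """Run every analysis stage on a session and return the report dict.

    ``session`` may be a directory path, an on-disk bundle, or an
    in-memory synthetic session.  Stage failures propagate with the stage
    name attached.
    """
    bundle = _as_bundle(session)
    labels = _session_labels(bundle)
    report: dict = {"stages": [], "n_trials": int(len(bundle.trials)),
                    "n_units": int(bundle.recording.n_units)}

    def stage(name):
        report["stages"].append(name)
        logger.info("pipeline stage: %s", name)

    try:
        stage("behavior")
        beh = analyze_behavior(bundle)
        percepts = beh["percepts"]
        det = percepts["determined"].to_numpy()
        cons = percepts["passes_consistency"].to_numpy()
        inferred = percepts["label"].to_numpy(dtype=object)
        report["behavior"] = {
            "n_trials": int(len(percepts)),
            "n_determined": int(det.sum()),
            "n_consistent": int(cons.sum()),
            "n_saccades_detected": int(len(beh["saccades"])),
            "jitter_median_deg": beh["jitter_median_deg"],
            "jitter_q99_deg": beh["jitter_q99_deg"],
        }
        if "truth_recovery" in beh:
            report["behavior"]["truth_recovery"] = beh["truth_recovery"]

        stage("units")
        trials = bundle.trials
        counts = trial_spike_counts(bundle.recording, trials)
        phys = (trials["condition"] == "physical").to_numpy()
        perc = (trials["condition"] == "perceptual").to_numpy()
        analyzable = det & cons

        if len(labels) == 2:
            face, obj = labels
            stats_df = compute_cell_stats(
                counts, bundle.recording.unit_ids, inferred, inferred,
                face, obj, phys & analyzable, perc & analyzable, alpha,
            )
            report["cells"] = classify_cells(stats_df, alpha)
            r, p, n = mi_correlation(stats_df[stats_df["p_physical"] < alpha])
            report["cells"]["mi_pearson_r"] = r
            report["cells"]["mi_pearson_p"] = p
            report["cells"]["mi_n"] = n

            stage("responses")
            onsets = trials["onset_ms"].to_numpy(dtype=float)
            ev_phys_f = onsets[phys & analyzable & (inferred == face)]
            ev_phys_o = onsets[phys & analyzable & (inferred == obj)]
            ev_perc = onsets[perc & analyzable & np.isin(inferred, (face, obj))]
            sel = select_consistent_units(stats_df, alpha)
            resp_report = {"n_selected_units": int(len(sel))}
            mix_inputs = None
            if len(sel) and len(ev_phys_f) and len(ev_phys_o) and len(ev_perc):
                sel_ids = sel["unit_id"].to_numpy()
                fmean, omean = unit_norm_constants(
                    bundle.recording, ev_phys_f, ev_phys_o, event_window_ms, sel_ids
                )
                ev_phys = np.sort(np.concatenate([ev_phys_f, ev_phys_o]))
                resp_phys = normalized_event_responses(
                    bundle.recording, ev_phys, fmean, omean, event_window_ms, sel_ids
                )
                resp_perc = normalized_event_responses(
                    bundle.recording, ev_perc, fmean, omean, event_window_ms, sel_ids
                )
                cmp_res = absolute_response_comparison(resp_phys, resp_perc)
                resp_report.update(
                    {k: cmp_res[k] for k in
                     ("t", "p", "mean_abs_physical", "mean_abs_perceptual",
                      "n_physical", "n_perceptual")}
                )
                phys_labels_ev = np.concatenate(
                    [np.full(len(ev_phys_f), face, object), np.full(len(ev_phys_o), obj, object)]
                )[np.argsort(np.concatenate([ev_phys_f, ev_phys_o]))]
                mix_inputs = (resp_phys, phys_labels_ev, resp_perc)
            report["responses"] = resp_report

            stage("decoding")
            dec_report = {}
            m_phys = phys & analyzable & np.isin(inferred, (face, obj))
            m_perc = perc & analyzable & np.isin(inferred, (face, obj))
            if m_phys.sum() >= 4:
                dec_report["physical_accuracy"] = loo_linear_decode(
                    counts[:, m_phys], inferred[m_phys], contrast="physical face vs object"
                ).accuracy
                dec_report["n_physical_trials"] = int(m_phys.sum())
            if m_perc.sum() >= 4:
                res = loo_linear_decode(
                    counts[:, m_perc], inferred[m_perc], contrast="perceptual face vs object"
                )
                dec_report.update(
                    perceptual_accuracy=res.accuracy,
                    n_perceptual_trials=int(m_perc.sum()),
                )
                if n_shuffles > 0:
                    null = shuffle_null(counts[:, m_perc], inferred[m_perc],
                                        n_shuffles, seed, res.accuracy)
                    dec_report.update(
                        null_mean=null.mean,
                        null_p95=null.percentile(95),
                        observed_percentile=null.percentile_of_observed(),
                    )
            report["decoding"] = dec_report

            stage("mixture")
            if mix_inputs is not None:
                sweep = mixture_sweep(
                    mix_inputs[0], mix_inputs[1], mix_inputs[2],
                    grid=mixture_grid, alpha=alpha, n_rep=mixture_n_rep, seed=seed,
                )
                report["mixture"] = {
                    "indistinguishable_low": sweep.indistinguishable_low,
                    "indistinguishable_high": sweep.indistinguishable_high,
                    "midpoint": sweep.midpoint,
                }
                report["_mixture_sweep"] = sweep
        else:
            # three-image block session: suppressed-stimulus analyses
            stage("suppressed_decoding")
            common = labels[0]
            dec = suppressed_stimulus_decode(counts, trials, inferred, analyzable, common)
            sup, dom = dec["suppressed"], dec["dominant"]
            report["decoding"] = {
                "suppressed_accuracy": sup.accuracy,
                "dominant_accuracy": dom.accuracy,
                "n_suppressed_trials": sup.n_trials,
                "n_dominant_trials": dom.n_trials,
            }
            if n_shuffles > 0:
                null = shuffle_null(
                    counts[:, dec["suppressed_mask"]],
                    inferred_pair_labels(trials, dec["suppressed_mask"], common),
                    n_shuffles, seed, sup.accuracy,
                )
                report["decoding"].update(
                    null_mean=null.mean,
                    null_p95=null.percentile(95),
                    observed_percentile=null.percentile_of_observed(),
                )
            stage("dual_modulation")
            phys_sel = _physically_selective_mask(counts, trials, alpha)
            dmi = dual_modulation_indices(
                counts[phys_sel], bundle.recording.unit_ids[phys_sel],
                trials, inferred, analyzable, common,
            )
            report["dual_modulation"] = {
                "pearson_r": dmi.pearson_r,
                "pearson_p": dmi.pearson_p,
                "n_units": dmi.n_units,
                "class_counts": dmi.class_counts,
            }
            report["_dual_modulation"] = dmi
    except Exception as exc:  # annotate stage failures
        raise RuntimeError(f"pipeline failed in stage '{report['stages'][-1]}': {exc}") from exc

    report["_percepts"] = percepts
    report["_saccades"] = saccades_to_frame(beh["saccades"])
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def inferred_pair_labels(trials, mask, common: str) -> np.ndarray:
    """Block pair identity (the non-common image) for masked trials."""
    other = []
    for _, tr in trials[mask].iterrows():
        imgs = {tr["image_left"], tr["image_right"]} - {"", common}
        other.append(next(iter(imgs)))
    return np.asarray(other, dtype=object)


def _physically_selective_mask(counts, trials, alpha: float) -> np.ndarray:
    """Units selective between the common image and the others (physical)."""
    from .units import selectivity_test

    phys = trials["condition"] == "physical"
    imgs = trials.loc[phys, ["image_left", "image_right"]].agg("".join, axis=1)
    common = imgs.mode().iat[0] if len(imgs) else None
    a_mask = phys & (imgs == common).reindex(trials.index, fill_value=False)
    b_mask = phys & ~a_mask
    sel = np.zeros(counts.shape[0], dtype=bool)
    for i in range(counts.shape[0]):
        _, p = selectivity_test(counts[i, a_mask.to_numpy()], counts[i, b_mask.to_numpy()])
        sel[i] = p < alpha
    return sel


def report_to_json(report: dict) -> dict:
    """Strip non-serializable intermediates and convert numpy scalars."""

    def conv(x):
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items() if not k.startswith("_")}
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, np.ndarray):
            return x.tolist()
        return x

    return conv({k: v for k, v in report.items() if not k.startswith("_")})


def render_markdown(report: dict) -> str:
    j = report_to_json(report)
    lines = ["# Rivalry session report", ""]
    for section, payload in j.items():
        if section == "stages":
            continue
        lines.append(f"## {section}")
        if isinstance(payload, dict):
            for k, v in payload.items():
                if isinstance(v, float):
                    v = f"{v:.4g}"
                lines.append(f"- {k}: {v}")
        else:
            lines.append(f"- {payload}")
        lines.append("")
    return "\n".join(lines)


def write_report(report: dict, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report_to_json(report), indent=2, sort_keys=True))
    (out / "report.md").write_text(render_markdown(report))
    if "_percepts" in report:
        report["_percepts"].to_csv(out / "percepts.csv", index=False)
    if "_saccades" in report:
        report["_saccades"].to_csv(out / "saccades.csv", index=False)
    return out


FIXTURE_SCENARIOS = ("modelI", "modelIIa", "modelIIb", "mixed")


def make_fixture(scenario: str, seed: int = 0) -> Session:
    """Small deterministic sessions for tests (<=20 units, ~80 s)."""
    if scenario not in FIXTURE_SCENARIOS:
        raise ValueError(f"scenario must be one of {FIXTURE_SCENARIOS}")
    model = {"modelI": "I", "modelIIa": "IIa", "modelIIb": "IIb", "mixed": "IIa"}[scenario]
    cfg = SessionConfig(
        n_physical_trials=40,
        n_perceptual_trials=60,
        n_units=12,
        model=model,
        w_dom=1.0 if scenario == "modelI" else 0.65,
        mixture_proportion=0.3 if scenario == "mixed" else 0.0,
        dynamics=RivalryDynamicsParams(median_dominance_face_s=3.0,
                                       median_dominance_object_s=3.0, seed=seed),
        oculomotor=OculomotorParams(seed=seed),
        seed=seed,
    )
    return simulate_session(cfg)
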