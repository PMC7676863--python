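"""Single-trial linear population decoding with leave-one-out CV.

Features are the spike counts of all simultaneously recorded units during
the 800-ms trial; the decoder is a linear maximum-margin classifier
(liblinear SVM, squared hinge, C fixed at 1) fit on standardized features,
with standardization statistics taken from the training fold only.  Shuffle
nulls repeat the whole cross-validation under label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import LinearSVC

from .types import UNDETERMINED
from .units import modulation_index


@dataclass
class DecodingResult:
    accuracy: float
    predictions: np.ndarray
    labels: np.ndarray
    n_trials: int
    n_units: int
    contrast: str = ""


def loo_linear_decode(
    count_matrix: np.ndarray,
    labels,
    C: float = 1.0,
    standardize: bool = True,
    contrast: str = "",
) -> DecodingResult:
    """Leave-one-out cross-validated linear decoding accuracy.

    ``count_matrix`` is unit x trial.  Each fold standardizes features from
    its training trials, fits the linear SVM, and classifies the held-out
    trial by the sign of its decision value; an exact zero goes to the
    first class deterministically.
    """
    X = np.asarray(count_matrix, dtype=float).T  # trials x units
    y = np.asarray(labels, dtype=object)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least two trials per class")
    n = len(y)
    yb = (y == classes[1]).astype(int)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], yb[mask]
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            xte = (X[i] - mu) / sd
        else:
            xte = X[i]
        clf = LinearSVC(C=C, dual=False)
        clf.fit(Xtr, ytr)
        score = float(clf.decision_function(xte[None, :])[0])
        preds[i] = 1 if score > 0 else 0
    acc = float(np.mean(preds == yb))
    return DecodingResult(
        accuracy=acc,
        predictions=classes[preds],
        labels=y,
        n_trials=n,
        n_units=X.shape[1],
        contrast=contrast,
    )


@dataclass
class ShuffleNull:
    accuracies: np.ndarray
    observed_accuracy: float | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.accuracies, q))

    def percentile_of_observed(self) -> float:
        """Percentile rank of the observed accuracy within the null."""
        if self.observed_accuracy is None:
            raise ValueError("no observed accuracy attached")
        return float(
            100.0 * np.mean(self.accuracies < self.observed_accuracy)
        )

    def band(self, coverage: float = 95.0) -> tuple[float, float]:
        half = (100.0 - coverage) / 2.0
        return self.percentile(half), self.percentile(100.0 - half)


def shuffle_null(
    count_matrix: np.ndarray,
    labels,
    n_shuffles: int = 100,
    seed: int = 0,
    observed_accuracy: float | None = None,
    C: float = 1.0,
) -> ShuffleNull:
    """Decoding-accuracy null distribution under label permutation."""
    rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=object)
    accs = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(len(y))
        accs[s] = loo_linear_decode(count_matrix, y[perm], C=C).accuracy
    return ShuffleNull(accs, observed_accuracy)


# ---------------------------------------------------------------------------
# Suppressed-stimulus experiment (three-image block sessions)
# ---------------------------------------------------------------------------

def _block_pair_other(trials: pd.DataFrame, common: str) -> np.ndarray:
    """Per trial, the pair image that is not the common image A."""
    out = []
    for _, tr in trials.iterrows():
        imgs = {tr["image_left"], tr["image_right"]} - {"", common}
        out.append(next(iter(imgs)) if len(imgs) == 1 else "")
    return np.asarray(out, dtype=object)


def suppressed_stimulus_decode(
    counts: np.ndarray,
    trials: pd.DataFrame,
    inferred_labels,
    consistency_mask,
    common: str = "A",
    C: float = 1.0,
) -> dict[str, DecodingResult]:
    """Decode the suppressed and the dominant stimulus from block sessions.

    ``suppressed``: among rivalry trials whose inferred dominant percept is
    the common image A, decode the block identity — i.e. whether the
    suppressed stimulus was B or C.  ``dominant``: decode trials where B
    was dominant (in (A,B) blocks) against trials where C was dominant (in
    (A,C) blocks).
    """
    inferred = np.asarray(inferred_labels, dtype=object)
    cons = np.asarray(consistency_mask, dtype=bool)
    perc = (trials["condition"] == "perceptual").to_numpy()
    other = _block_pair_other(trials, common)

    sup_mask = perc & cons & (inferred == common)
    if sup_mask.sum() < 4:
        raise ValueError("insufficient dominant-%s rivalry trials" % common)
    sup = loo_linear_decode(
        counts[:, sup_mask], other[sup_mask], C=C,
        contrast=f"suppressed ({common} dominant): pair identity",
    )

    dom_mask = perc & cons & (inferred != common) & (inferred != UNDETERMINED)
    dom_mask &= inferred == other  # dominant percept is the block's other image
    dom = loo_linear_decode(
        counts[:, dom_mask], inferred[dom_mask], C=C,
        contrast="dominant: B vs C percept",
    )
    return {"suppressed": sup, "dominant": dom, "suppressed_mask": sup_mask,
            "dominant_mask": dom_mask}


@dataclass
class DualModulationResult:
    per_unit: pd.DataFrame  # unit_id, MI_dominant, MI_suppressed
    pearson_r: float
    pearson_p: float
    n_units: int
    class_counts: dict = field(default_factory=dict)


def dual_modulation_indices(
    counts: np.ndarray,
    unit_ids,
    trials: pd.DataFrame,
    inferred_labels,
    consistency_mask,
    common: str = "A",
) -> DualModulationResult:
    """Per-unit dominant- and suppressed-stimulus modulation indices.

    MI_dominant contrasts class means of (A,B)-blocks-with-B-dominant vs
    (A,C)-blocks-with-C-dominant (suppressed image fixed at A, dominant
    varied); MI_suppressed contrasts A-dominant trials between the two
    block types (dominant fixed at A, suppressed varied).  Units with a
    zero denominator in either index are excluded from the population
    Pearson correlation.
    """
    inferred = np.asarray(inferred_labels, dtype=object)
    cons = np.asarray(consistency_mask, dtype=bool)
    perc = (trials["condition"] == "perceptual").to_numpy()
    other = _block_pair_other(trials, common)
    pair_labels = [x for x in pd.unique(other) if x not in ("", common)]
    if len(pair_labels) != 2:
        raise ValueError("expected exactly two block pair types")
    b, c = sorted(pair_labels)

    masks = {
        "dom_b": perc & cons & (inferred == b) & (other == b),
        "dom_c": perc & cons & (inferred == c) & (other == c),
        "sup_b": perc & cons & (inferred == common) & (other == b),
        "sup_c": perc & cons & (inferred == common) & (other == c),
    }
    if any(m.sum() == 0 for m in masks.values()):
        raise ValueError("all four trial classes must be present")

    mi_dom = modulation_index(
        counts[:, masks["dom_b"]].mean(axis=1), counts[:, masks["dom_c"]].mean(axis=1)
    )
    mi_sup = modulation_index(
        counts[:, masks["sup_b"]].mean(axis=1), counts[:, masks["sup_c"]].mean(axis=1)
    )
    per_unit = pd.DataFrame(
        {"unit_id": np.asarray(unit_ids), "MI_dominant": mi_dom, "MI_suppressed": mi_sup}
    )
    ok = np.isfinite(mi_dom) & np.isfinite(mi_sup)
    r, p = stats.pearsonr(mi_dom[ok], mi_sup[ok])
    return DualModulationResult(
        per_unit=per_unit,
        pearson_r=float(r),
        pearson_p=float(p),
        n_units=int(ok.sum()),
        class_counts={k: int(m.sum()) for k, m in masks.items()},
    )
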