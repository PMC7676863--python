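"""Worst-case mixed-percept control.

If rivalry responses looked intermediate only because some trials carried
piecemeal (half-and-half) percepts, then physical-condition responses with
a fraction of trials replaced by face/object averages should reproduce
the rivalry distribution.  This module simulates that replacement and
sweeps the mixed-trial proportion for statistical indistinguishability
from observed rivalry responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def simulate_mixture(
    responses,
    labels,
    proportion: float,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Replace a Bernoulli(proportion) subset of trials by class averages.

    ``responses`` are per-trial across-unit normalized means from the
    physical condition with binary class ``labels``; each selected trial is
    replaced by the mean of one randomly drawn face-class and one randomly
    drawn object-class response (the exact half-and-half worst case).  The
    sample size is conserved.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.asarray(responses, dtype=float)
    y = np.asarray(labels, dtype=object)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    pool_a = x[y == classes[0]]
    pool_b = x[y == classes[1]]
    if len(pool_a) == 0 or len(pool_b) == 0:
        raise ValueError("both classes must be non-empty")
    out = x.copy()
    mixed = rng.random(len(x)) < proportion
    k = int(mixed.sum())
    if k:
        out[mixed] = 0.5 * (
            pool_a[rng.integers(len(pool_a), size=k)]
            + pool_b[rng.integers(len(pool_b), size=k)]
        )
    return out


@dataclass
class MixtureSweepResult:
    proportions: np.ndarray
    mean_p: np.ndarray
    alpha: float
    indistinguishable_low: float | None
    indistinguishable_high: float | None

    @property
    def midpoint(self) -> float | None:
        if self.indistinguishable_low is None:
            return None
        return 0.5 * (self.indistinguishable_low + self.indistinguishable_high)

    def to_frame(self):
        import pandas as pd

        flag = (
            (self.proportions >= (self.indistinguishable_low if self.indistinguishable_low is not None else np.inf))
            & (self.proportions <= (self.indistinguishable_high if self.indistinguishable_high is not None else -np.inf))
        )
        return pd.DataFrame(
            {
                "proportion": self.proportions,
                "mean_p": self.mean_p,
                "indistinguishable": flag,
            }
        )


def mixture_sweep(
    physical_responses,
    physical_labels,
    observed_responses,
    grid=None,
    alpha: float = 0.05,
    n_rep: int = 20,
    seed: int = 0,
) -> MixtureSweepResult:
    """Sweep the mixed-trial proportion for indistinguishability.

    For each proportion, the mixture simulation runs ``n_rep`` times; each
    run is compared to the observed rivalry responses by a two-sample
    t-test on absolute-value distributions (the statistic used for the
    bimodality comparison), and p-values are averaged.  The reported
    indistinguishable range is the contiguous run of grid points with mean
    p >= alpha containing the largest mean p.
    """
    grid = np.arange(0.0, 1.0001, 0.05) if grid is None else np.asarray(grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("grid must lie within [0, 1]")
    grid = np.sort(grid)
    obs_abs = np.abs(np.asarray(observed_responses, dtype=float))
    rng = np.random.default_rng(seed)
    mean_p = np.empty(len(grid))
    for i, prop in enumerate(grid):
        ps = np.empty(n_rep)
        for rep in range(n_rep):
            sim = simulate_mixture(physical_responses, physical_labels, prop, rng)
            ps[rep] = stats.ttest_ind(np.abs(sim), obs_abs, equal_var=True).pvalue
        mean_p[i] = ps.mean()

    ok = mean_p >= alpha
    if not np.any(ok):
        lo = hi = None
    else:
        best = int(np.argmax(mean_p))
        i0 = best
        while i0 > 0 and ok[i0 - 1]:
            i0 -= 1
        i1 = best
        while i1 + 1 < len(grid) and ok[i1 + 1]:
            i1 += 1
        lo, hi = float(grid[i0]), float(grid[i1])
    return MixtureSweepResult(grid, mean_p, alpha, lo, hi)
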