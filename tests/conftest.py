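import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_session():
    """Small Model IIa session shared by fast tests."""
    from rivalry.pipeline import make_fixture

    return make_fixture("modelIIa", seed=0)


def brute_force_saccades(
    xy: np.ndarray,
    threshold: float = 0.5,
    window: int = 100,
    offset: int = 2,
    stability: float = 0.8,
    min_separation: int = 100,
) -> list[int]:
    """Exhaustive reference saccade scan (1-ms sampling, sample indices).

    Recomputes the detection criterion independently at every sample, then
    applies greedy earliest-first thinning.  Used as the oracle for the
    vectorized detector.
    """
    n = len(xy)
    cands = []
    for t in range(window, n - window):
        pre = xy[t - window : t - offset + 1]
        post = xy[t + offset : t + window + 1]
        pm = pre.mean(axis=0)
        qm = post.mean(axis=0)
        if np.hypot(*(qm - pm)) <= threshold:
            continue
        if np.mean(np.linalg.norm(pre - pm, axis=1) <= threshold) < stability:
            continue
        if np.mean(np.linalg.norm(post - qm, axis=1) <= threshold) < stability:
            continue
        cands.append(t)
    out: list[int] = []
    last = -(10**9)
    for t in cands:
        if t - last >= min_separation:
            out.append(t)
            last = t
    return out


def random_eye_trace(seed: int, n_ms: int = 10_000) -> np.ndarray:
    """Random gaze trace mixing steps, drifts, and jitter (1 kHz)."""
    rng = np.random.default_rng(seed)
    xy = np.zeros((n_ms, 2))
    pos = rng.uniform(-1, 1, 2)
    t = 0
    while t < n_ms:
        hold = int(rng.integers(100, 1500))
        drift = rng.uniform(-1.0, 1.0, 2) / 1000.0 * rng.random()  # deg/ms
        seg = min(hold, n_ms - t)
        xy[t : t + seg] = pos + np.arange(seg)[:, None] * drift
        pos = xy[min(t + seg, n_ms - 1) - 1] + rng.uniform(0.2, 2.0) * rng.choice(
            [-1, 1], 2
        ) * rng.random(2)
        t += seg
    xy += rng.normal(0, rng.uniform(0.0, 0.05), size=xy.shape)
    return xy
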