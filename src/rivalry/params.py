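"""Parameter containers for the synthetic-session generator.

Defaults encode the study conditions the analyses assume: 7.2 s median
dominance durations for both rivaling stimuli, 800-ms trials, a 350-ms
average saccade latency, and fixational jitter whose median 1-ms step is
0.038 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special


@dataclass
class RivalryDynamicsParams:
    """Dominance-duration process for the perceptual alternation.

    Durations are gamma distributed (the standard right-skewed choice for
    rivalry), with the scale solved so the distribution's median equals the
    configured per-state median.  Only medians are externally constrained.
    """

    median_dominance_face_s: float = 7.2
    median_dominance_object_s: float = 7.2
    duration_shape: float = 3.0
    mixture_proportion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.median_dominance_face_s <= 0 or self.median_dominance_object_s <= 0:
            raise ValueError("median dominance durations must be positive")
        if self.duration_shape <= 0:
            raise ValueError("duration_shape must be positive")
        if not 0.0 <= self.mixture_proportion <= 1.0:
            raise ValueError("mixture_proportion must lie in [0, 1]")

    def medians_ms(self) -> tuple[float, float]:
        return (
            self.median_dominance_face_s * 1000.0,
            self.median_dominance_object_s * 1000.0,
        )


def gamma_scale_for_median(median: float, shape: float) -> float:
    """Scale of a gamma(shape) whose median equals ``median``."""
    if math.isinf(median):
        return math.inf
    if median <= 0:
        raise ValueError("median must be positive")
    return median / float(special.gammaincinv(shape, 0.5))


# Median of the Euclidean step between two i.i.d. N(0, s^2 I_2) jitter
# samples: the step is N(0, 2 s^2 I_2), whose magnitude is Rayleigh with
# scale s*sqrt(2) and median 2 s sqrt(ln 2).
_STEP_MEDIAN_PER_SIGMA = 2.0 * math.sqrt(math.log(2.0))


def jitter_sigma_for_step_median(step_median_deg: float) -> float:
    """Per-axis Gaussian jitter s.d. giving the target median 1-ms step."""
    if step_median_deg < 0:
        raise ValueError("step median must be nonnegative")
    return step_median_deg / _STEP_MEDIAN_PER_SIGMA


@dataclass
class OculomotorParams:
    """Gaze-tracking behavior: latency, travel, and fixational jitter."""

    saccade_latency_mean_ms: float = 350.0
    saccade_latency_sd_ms: float = 50.0
    saccade_latency_floor_ms: float = 100.0
    saccade_travel_ms: float = 30.0
    jitter_step_median_deg: float = 0.038
    sampling_rate_hz: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.saccade_latency_mean_ms <= 0:
            raise ValueError("saccade latency mean must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.jitter_step_median_deg < 0:
            raise ValueError("jitter step median must be nonnegative")

    @property
    def jitter_sigma_deg(self) -> float:
        return jitter_sigma_for_step_median(self.jitter_step_median_deg)


@dataclass
class EncodingModelParams:
    """Population encoding model used to generate Poisson spikes.

    model
        'I'   — rate follows the dominant stimulus alone;
        'IIa' — rate = baseline + g(t) * (w_dom * r_dominant +
                (1 - w_dom) * r_suppressed);
        'IIb' — trials are tiled into epochs alternating between a
                percept-coding rate (r_dominant) and a physical-coding rate
                (mean of the two stimulus rates), with percept-epoch
                occupancy 2*w_dom - 1 so that the expected rate matches IIa.
    g(t) is a multiplicative saccade gain, elevated by
    ``saccade_gain_amplitude`` inside ``saccade_gain_window_ms`` after each
    saccade onset.  The physical (monocular) condition uses the presented
    stimulus's rate in every model.
    """

    model: str = "IIa"
    baseline_hz: np.ndarray = field(default_factory=lambda: np.array([5.0]))
    stimulus_rates_hz: dict[str, np.ndarray] = field(default_factory=dict)
    w_dom: float = 0.65
    response_latency_ms: float = 0.0
    saccade_gain_amplitude: float = 0.5
    saccade_gain_window_ms: tuple[float, float] = (130.0, 400.0)
    iib_epoch_ms: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("I", "IIa", "IIb"):
            raise ValueError("model must be one of 'I', 'IIa', 'IIb'")
        self.baseline_hz = np.atleast_1d(np.asarray(self.baseline_hz, dtype=float))
        self.stimulus_rates_hz = {
            k: np.atleast_1d(np.asarray(v, dtype=float))
            for k, v in self.stimulus_rates_hz.items()
        }
        if np.any(self.baseline_hz < 0) or any(
            np.any(v < 0) for v in self.stimulus_rates_hz.values()
        ):
            raise ValueError("rates must be nonnegative")
        for k, v in self.stimulus_rates_hz.items():
            if v.shape != self.baseline_hz.shape:
                raise ValueError(f"rate vector for '{k}' does not match baseline shape")
        if not 0.0 <= self.w_dom <= 1.0:
            raise ValueError("w_dom must lie in [0, 1]")
        if self.model == "IIb" and self.w_dom < 0.5:
            raise ValueError(
                "Model IIb requires w_dom >= 0.5 (percept-epoch occupancy 2*w_dom - 1)"
            )
        if self.iib_epoch_ms <= 0:
            raise ValueError("iib_epoch_ms must be positive")

    @property
    def n_units(self) -> int:
        return len(self.baseline_hz)

    @property
    def iib_occupancy(self) -> float:
        return 2.0 * self.w_dom - 1.0
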