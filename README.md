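# rivalry

Analysis toolkit for **no-report binocular rivalry** electrophysiology.

When incompatible images — say a face and an object — are shown separately
to the two eyes, conscious perception alternates between them even though
the retinal input is constant. Classically, the subject reports the
dominant percept with a lever or button, which confounds neural correlates
of consciousness with the act of report. In the fixation-based no-report
paradigm this package supports, each eye's image carries its own fixation
spot (at one of four positions, jumping every 800-ms trial), and the
percept is inferred from *which spot the subject tracks*. This package
implements the complete analysis for such experiments, plus a synthetic
session generator with known ground truth so every stage can be validated.

## What it computes

**Percept inference.** A trial is labeled with the stimulus whose fixation
spot the gaze stayed within 0.5° of (L1 norm) for at least half the trial
duration, non-contiguously, in a window delayed by the 350-ms average
saccade latency. Trials where no spot qualifies are `undetermined`; a
next-trial-consistency filter removes switch-back trials.

**Saccade detection.** A saccade is flagged at time *t* when the mean eye
position over *t*−100…*t*−2 ms and over *t*+2…*t*+100 ms differ by more
than 0.5°, each flank is stable (≥80% of samples within 0.5° of its
mean), and consecutive detections are ≥100 ms apart.

**Single-unit statistics.** For responses R (spike count per 800-ms
trial), selectivity is a two-sided two-sample t-test between face and
object trials, and modulation is the index

    MI = (R_face − R_object) / (R_face + R_object)

computed separately for the physical condition (monocular stimuli actually
switched) and the perceptual condition (constant dichoptic stimulus,
internally generated switches). Cells are classified as
consistently/inconsistently/non-significantly modulated by the conscious
percept.

**Population decoding.** A linear maximum-margin classifier on
standardized spike-count vectors, leave-one-out cross-validated, with
label-shuffle nulls (100 permutations). Three-image block designs —
rivalry pairs (A,B) and (A,C) presented in alternating blocks — support
decoding of the *suppressed* stimulus: among trials where A is dominant,
the decoder discriminates whether B or C was suppressed. Per-unit
dominant- and suppressed-stimulus modulation indices and their population
Pearson correlation quantify whether the same cells carry both signals.

**Normalized response distributions.** Per event (saccade or trial onset),
responses of selective units are mapped affinely so the mean physical
object response is −1 and the mean face response is +1, then averaged
across units. Comparing |response| distributions between conditions tests
whether rivalry responses are compressed toward the middle — the signature
of a code that multiplexes the dominant and suppressed stimulus.

**Mixed-percept control.** The worst case in which some trials are
half-face/half-object percepts is simulated by replacing a proportion of
physical-condition responses with face/object trial averages; a sweep
reports the proportion range statistically indistinguishable from the
observed rivalry distribution.

**Synthetic sessions.** The generator produces percept trajectories
(gamma dominance durations, median 7.2 s), trial tables (the 12 ordered
fixation-spot position pairs per rivalry block), gaze traces (350 ± 50 ms
latency, 0.038° median 1-ms jitter step) and Poisson population spiking
under three encoding models: **I** (rate follows the dominant stimulus
alone), **IIa** (rate ∝ w·r_dominant + (1−w)·r_suppressed) and **IIb**
(short epochs alternating between percept-coding and physical-coding
rates, occupancy matched so the expected rate equals IIa's).

## Worked example

```python
from rivalry import SessionConfig, simulate_session
from rivalry.pipeline import run_pipeline

session = simulate_session(SessionConfig(
    n_physical_trials=40, n_perceptual_trials=60, n_units=12,
    model="IIa", w_dom=0.65, seed=0))
report = run_pipeline(session, seed=0, n_shuffles=20)
```

prints (via the report dictionary):

```
determined trials        : 100/100
truth recovery           : 1.000
median 1-ms gaze step    : 0.0384 deg
selective cells          : 11/12 (8 consistent)
MI physical vs perceptual: r=0.77
decoding physical        : 1.00
decoding perceptual      : 0.81 (null mean 0.47)
|response| physical      : 1.00
|response| perceptual    : 0.40 (p=6.9e-14)
mixture indistinguishable: 0.55-0.90
```

Reading this: every trial's percept was recovered from the synthetic gaze;
most units are face/object selective and keep their preference during
rivalry; the percept is decodable on single trials well above the shuffle
null; and the rivalry |response| distribution is compressed relative to
the physical one (mean 0.40 vs 1.00) — under Model IIa the population
carries both the dominant and the suppressed stimulus, and only a large
proportion of hypothetical mixed percepts could mimic that compression.

The same pipeline runs from the shell on session directories
(`trials.csv`, `eye.csv`, `spikes.csv`, `config.json`):

```
rivalry simulate --config config.json --out session/ --seed 1
rivalry behavior --session session/
rivalry run --session session/ --out report/
```

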