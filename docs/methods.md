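# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the `rivalry` package. Everything here describes
what the code does; no empirical claim is made beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Conventions

All times share one session clock in milliseconds; trial windows are
half-open `[onset, onset + duration)`. Gaze is in degrees of visual
angle, screen-center origin, x rightward, y upward; the four fixation-spot
positions map to (0,1), (0,−1), (−1,0), (1,0). CSV files are
comma-separated with a mandatory header, UTF-8, `.` decimal.

## Percept inference

The percept on a trial is the stimulus whose fixation spot the gaze dwelt
within `radius_deg` (default 0.5°, **L1 norm**) of for at least half the
trial duration, with dwell accumulated non-contiguously over the window
`[onset + 350 ms, onset + duration + 350 ms)` — the delay absorbs the
average saccade latency. Defaults encode the 800-ms monkey trial; the
2000-ms human variant is reached by changing `duration_ms` (the
half-duration criterion scales automatically), and the 350-ms delay is
applied uniformly. Trials where no spot reaches criterion are
`undetermined` and excluded from all downstream statistics; the guard for
*both* spots qualifying (geometrically impossible for distinct spots at
0.5° radius but cheap to keep) also yields `undetermined`. Switch trials
are determined trials whose label differs from the previous determined
trial; `passes_consistency` requires the *next* trial to carry the same
label and is the filter applied before modulation-index, decoding and
response-distribution analyses, excluding trials on which the percept
switched right back.

## Saccade detection

Detection at sample *t* compares the mean position over the closed flanks
*t*−100…*t*−2 and *t*+2…*t*+100 ms (99 samples each at 1 kHz). The
displacement must exceed 0.5° (flank-mean distance and amplitude use the
Euclidean norm — the criterion's "distance" is metric-ambiguous, and this
choice is mirrored exactly by the brute-force oracle in the tests), and at
least 80% of each flank's samples must lie within 0.5° of that flank's
mean. Candidates are thinned greedily in time order to a 100-ms minimum
separation (earliest detection survives). Boundary samples without full
flanks are skipped. Note one consequence of the exact criterion: for an
ideal instantaneous step, detection first fires when 80% of the post flank
has stepped, i.e. up to ~22 ms *before* the step sample.

## Single-unit statistics

Responses are spike counts over the full 800-ms trial (no latency
offset). Selectivity is a pooled-variance two-sided two-sample t-test;
fully degenerate inputs (both samples constant) are flagged and mapped to
t=0, p=1 when means agree and p=0 otherwise. The modulation index
(R_a − R_b)/(R_a + R_b) is undefined (NaN, excluded and logged) when the
denominator is zero rather than set to 0, to avoid fabricating
selectivity. Cell categories: among physically selective units
(p < α = 0.05), a unit is *consistent_significant* if its perceptual
modulation is significant with the same sign as its physical MI,
*inconsistent_significant* with the opposite sign, otherwise
*nonsignificant*. PSTHs use 1-ms bins smoothed with a 100-ms box kernel.

## Normalized response distributions

Per-unit responses are rates in a 0–400 ms window after the alignment
event (saccade onset or trial onset). The affine map
x ↦ 2(x − object_mean)/(face_mean − object_mean) − 1 uses means from the
**physical** condition only and is then applied unchanged to perceptual
events; units with equal anchors are excluded. Event-level responses are
across-unit means over units that are significantly modulated in both
conditions with consistent face preference. The physical-vs-perceptual
comparison is a two-sample t-test on the absolute values of these
per-event means.

## Decoding

Features are per-trial spike-count vectors, standardized with mean and
s.d. estimated from the training fold only. The classifier is a linear
maximum-margin SVM; the implementation uses liblinear in its primal
squared-hinge form with the regularization constant fixed at C = 1, which
at these problem sizes is numerically indistinguishable from the
kernelized linear SVM while roughly an order of magnitude faster per
leave-one-out fold — that matters because the shuffle null refits the
whole cross-validation 100 times. A held-out trial with decision value
exactly 0 is assigned to the first class deterministically. Trials enter
decoding only if determined and consistency-passing. In the three-image
block design, the suppressed contrast restricts to trials with dominant
percept A and decodes the block pair (suppressed B vs C); the dominant
contrast decodes B-dominant (A,B) trials against C-dominant (A,C) trials.
MI_dominant uses the latter pair of classes and MI_suppressed the former,
following the disambiguation in the experiment's text description (the
figure caption prints the same symbols for both).

## Mixed-percept control

The worst-case piecemeal scenario replaces each physical-condition
response, independently with probability p, by the average of one
randomly drawn face-trial and one object-trial response. The sweep
(default grid 0…1 in steps of 0.05, 20 repetitions per point) compares
each simulated sample to the observed rivalry responses with the same
absolute-value t-test used for the bimodality comparison — the
indistinguishability criterion and α = 0.05 are package choices exposed
as parameters, since no canonical test exists for this control — and
reports the contiguous run of grid points with mean p ≥ α containing the
largest mean p.

## Synthetic sessions

The generator exists so that every analysis can be checked against ground
truth; its defaults are the study conditions the analyses assume.

* **Dominance durations**: i.i.d. gamma (the standard right-skewed choice
  for rivalry), shape 3 by default, scale solved in closed form
  (`median / gammaincinv(shape, 1/2)`) so the median equals the configured
  7.2 s per state. Only medians are externally constrained; the shape and
  the independence of successive durations are modeling choices. Infinite
  medians degenerate to a single dominance period.
* **Trial schedule**: abutting 800-ms trials. Rivalry blocks cycle
  through all 12 ordered (left-eye, right-eye) spot-position pairs in
  randomized order; monocular (physical) trials carry one spot that jumps
  to a new position each trial, with the shown stimulus following its own
  gamma switching process so that run lengths resemble rivalry. The
  three-image block design alternates (A,B) and (A,C) blocks of 8
  physical trials (each pair image at each position) plus 12 rivalry
  trials with a fresh dominance trajectory per block.
* **Gaze**: tracks the fixation spot of the eye carrying the dominant
  stimulus. After each spot jump or perceptual switch the gaze retargets
  after a truncated-normal latency (mean 350 ms, s.d. 50 ms, floor
  100 ms; only the mean is externally constrained) and travels linearly
  over 30 ms. Fixational jitter is i.i.d. Gaussian per sample and axis
  with σ = target/(2√ln2) so the median Euclidean 1-ms step equals
  0.038°. During a `mixed` state the tracked spot is chosen at random.
* **Spiking**: piecewise-constant-rate Poisson. Per-unit rates are gamma
  across the population (baseline mean 5 Hz; preferred-category mean
  20 Hz, non-preferred 8 Hz — chosen once as typical IT response ranges).
  Model I uses the dominant stimulus's rate; Model IIa uses
  w·r_dom + (1−w)·r_sup (default w = 0.65); Model IIb tiles trials into
  50-ms epochs that are percept-coding (r_dom) with probability
  2w − 1 and otherwise physical-coding at the mean of the two stimulus
  rates — that occupancy is *derived*, not assumed: it is the unique
  value making IIb's expected rate equal IIa's given the physical-epoch
  rate choice, and it requires w ≥ 0.5 (enforced). A multiplicative
  saccade gain (boxcar, amplitude 0.5) applies 130–400 ms after each
  saccade onset, motivated by the observed post-saccadic response onset;
  the boxcar shape is a package choice. Mixed-state trials spike at the
  mean of the two stimulus rates. Negative rates are clipped at zero and
  logged. The percept label of a trial is the state occupying its
  majority, mirroring the ≥400-ms inference rule.
* **Mixed percepts**: a Bernoulli(p) subset of 800-ms trial cells of the
  trajectory is relabeled `mixed`.

All generators are bit-reproducible given their seeds; whole-session
seeds are fanned out through `numpy.random.SeedSequence`.

### What the generator does and does not emulate

It reproduces the statistical structure the analyses rely on —
alternation dynamics, latency and jitter of tracked gaze, Poisson
population spiking with heterogeneous selectivity, saccade-evoked
transients, trial-locked schedules. It deliberately omits: smooth
pursuit, optokinetic nystagmus, blinks and pupil dynamics; spatially
piecemeal rivalry (mixture is a trial-level state); firing-rate
adaptation, drift, correlated noise across units, and non-Poisson
variability; eye-dominance imbalance and contrast-balancing dynamics.
Passing tests therefore validate the *analysis chain* under the stated
assumptions; they do not certify performance on real recordings, where
these omitted features (especially correlated noise and non-stationarity)
would lower inference and decoding accuracy.

## Problem sizes used in the validation suite

The model-discrimination checks run on 72-block three-image sessions
(~2,000 trials, 80 units, ≥200 suppressed-contrast trials per class,
decoding on 50 units) and 800-trial two-stimulus sessions (200 physical +
600 perceptual, 50 units); calibration checks use 10⁴ dominance periods
and 10⁴-trial single-state spiking simulations. These sizes were chosen
so that each qualitative signature (chance vs above-null suppressed
decoding, response compression, MI correlation) is resolved with wide
statistical margins on a single core in minutes.

## Known limitations

* Percept inference near-saturates on default synthetic sessions
  (recovery ≳ 99%), so concordance-style numbers from the generator are
  upper bounds relative to real behavior.
* The null hypothesis tests asserting *non*-significance (Model I
  response-distribution comparison) inherit the test's false-positive
  rate at any fixed seed.
* The LOO shuffle null has the usual slight pessimistic bias on
  label-balanced noise (training folds are imbalanced by one trial);
  with ≥100 trials this is well under the chance-band width.
* `suppressed_stimulus_decode` assumes exactly two block pair types
  sharing one common image; richer designs need the lower-level
  `loo_linear_decode` directly.
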