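# Methods

`doublestep` implements the standard analysis chain for double-step
(target-perturbation) pointing experiments, together with a synthetic
trajectory generator that emulates the recordings such experiments
produce. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not
establish about real data.

## Task model and geometry

The simulated task is a centre-out pointing movement to a touch screen at
a 40 cm viewing/reaching distance. The initial target sits 4.5° of visual
angle above fixation (y = 40·tan 4.5° ≈ 3.15 cm on the screen); on half
of the trials the target jumps 10° left or right of centre
(x = ±40·tan 10° ≈ ±7.05 cm) either 0 ms or 200 ms after reach onset
(release of the start key). Blocks hold 80 trials in an exactly
counterbalanced, randomly interleaved 50/25/25 static/left/right mix,
six blocks per session, recorded at 240 Hz.

Coordinates: screen plane at z = 0, x positive rightward, y positive
upward; the reach starts at (0, 0, 40) cm. Degrees convert to cm through
the exact arctangent geometry at the 40 cm viewing distance
(`deg = atan(cm / 40)`), so the conversion is odd and strictly monotone.

## Trajectory model

The primary reach follows a Beta-shaped speed profile: speed ∝
τ²(1−τ)^(b−1) over normalized movement time τ, position given by the
regularized incomplete beta function I_τ(3, b). With the default b = 3
this is *exactly* the minimum-jerk law
s(τ) = 10τ³ − 15τ⁴ + 6τ⁵, whose closed forms anchor the validation
suite: peak speed 1.875·D/T at τ = ½ for a reach of amplitude D and
duration T. The parameter is exposed as `accel_fraction`
(= (a−1)/(a+b−2), the fraction of movement time before peak speed);
values below ½ lengthen the deceleration phase, which is how the older
group's longer homing phase is modelled without abandoning the
minimum-jerk family.

A corrective response is modelled as superposition: a second minimum-jerk
displacement in x, from 0 to the full ±7.05 cm target displacement,
starting at perturbation time plus a drawn correction latency and lasting
a drawn submovement duration (default 260 ± 40 ms). The touch occurs when
both movements have completed, so late corrections lengthen the reach —
the behaviour time-pressure feedback curbs but does not remove in real
participants. Submovement superposition is the standard
submovement-decomposition convention; no claim is made that real
corrections are planned this way, only that the resulting traces have the
statistical structure the detector assumes.

Each trial records a pre-movement baseline: the tracker runs from target
onset while the finger rests on the start key, so the stream covers
[target onset, touch] on a grid aligned at reach onset. This matters for
detection (below).

## Sources of variability

Three stochastic components, all configurable:

* **Timing.** Reach latency, duration, correction latency and submovement
  duration are truncated normal draws (±2 SD). Defaults: younger latency
  266 ± 50 ms, duration 496.3 ± 45 ms; older 294 ± 60 ms and
  532.3 ± 55 ms (a +28 ms latency and +36 ms duration offset, i.e. 10%
  and 7% percent differences); correction latency 330 ± 40 ms (0 ms
  condition) and 297 ± 40 ms (200 ms condition). Truncation reflects the
  bounded range of compliant reaction times — a participant who triples
  their latency is a lapse, which the generator injects separately — and
  it is what makes "zero false removals" a meaningful calibration target
  for robust outlier screening.
* **Constant lateral offset.** Each trial draws a per-trial constant x
  offset, N(0, 0.25 cm) by default, modelling start-key placement and
  sensor-mounting scatter that persists through the reach. This is the
  dominant across-trial variability of the horizontal trace, and it is
  deliberately *slow* (constant within a trial): the envelope detector's
  specificity hinges on across-trial variability being wide relative to
  within-trial fluctuation.
* **Sensor noise.** White Gaussian noise per axis (0.05 cm SD), zero-phase
  low-pass filtered at 10 Hz, approximating the smoothed output of an
  electromagnetic tracker.

Contaminants for the cleaning stages: apparatus/participant-error trials
(missing touch, premature start, >3 consecutive dropped samples) at 5%,
and behavioural outlier trials (latency shifted by +8 SD, an attention
lapse) at 5%. Every injected feature is written to a ground-truth table.

## Cleaning

Stage 1 screens rule-violating trials: missing touch response, reach
onset before target onset, a sample gap exceeding 3 consecutive missing
samples, or a zero-length trajectory. Stage 2 flags per-trial measures
(reach latency by default) whose robust z score
|v − median| / (1.4826·MAD) exceeds 3, per participant × condition ×
direction cell; a degenerate MAD of zero flags any value off the median,
and cells under 4 values are left untouched with a warning. The threshold
of 3 is the conservative end of the usual 2.5–3 recommendation and is a
CLI flag (`--mad-threshold`).

## Kinematic dependent variables

Trajectories are low-pass filtered at 20 Hz with a 4th-order Butterworth
applied forward and backward (zero phase; the two-way pass squares the
magnitude response, so the effective attenuation is 8th-order). Speed is
the 3D tangential magnitude by central differences (horizontal-plane-only
mode available). Landmarks: reach latency = reach onset − target onset;
duration = touch − reach onset; acceleration time = time of peak speed −
reach onset (ties broken to the earliest sample); deceleration time =
duration − acceleration time, so the two phases sum to the duration
exactly by construction. Absolute x accuracy is |atan((touch_x −
final target x)/40)| in degrees, with the displaced location as the
reference on perturbed trials. Profiles whose speed peaks at the first or
last sample are flagged degenerate, not dropped.

## Correction detection

Non-perturbed trials of one grouping unit (participant × block by
default, participant-pooled optionally) are aligned at reach onset on the
240 Hz grid; per sample, the mean and sample SD (ddof = 1) of x define
the envelope x̄(t) ± 1.5·s(t) over the contiguous region supported by at
least two trials, with boundary values held outside it. Support during
the reach is non-increasing as shorter trials finish.

A perturbed trial elicits a detected correction when its x leaves the
band **on the side of the perturbed target** and stays outside for at
least 3 consecutive samples (~12.5 ms; `sustain=1` reproduces the bare
threshold rule). The scan covers perturbation + 80 ms (the minimum
visuomotor delay) to touch. The reported latency is the *start* of the
sustained excursion relative to perturbation onset, floored at 80 ms —
so an excursion that begins between the perturbation and the 80 ms floor,
or exactly at the perturbation, is reported at exactly 80 ms. Two
causality rules:

* An excursion already in progress *at* perturbation onset is a
  pre-existing deviation, not a response; the trial is flagged
  `pre_deviated` and no latency is recorded. The pre-movement baseline is
  what makes this decidable for the 0 ms condition: a constant placement
  offset is outside the band from the first recorded sample, long before
  any perturbation.
* Sustained excursions away from the perturbed target are logged
  (`opposite_crossing`) but never counted.

Latencies are computed in integer sample counts (the perturbation is
grid-aligned), so identical crossings yield bit-identical latencies.

Path curvature: L = A/B with B the straight-line distance from reach
start to end and A the maximum perpendicular distance of any sample from
the infinite line through them (cross-product form, well conditioned for
near-collinear paths; L = 0 is a perfectly straight path). A is the
maximum path offset (MPO); its latency is the time of the
offset-maximising sample minus perturbation onset, the same clock as
correction latency. Both the dimensionless L and A in cm are reported.
Paths with B = 0 are flagged undefined. The geometric gloss sometimes
attached to L = 1 ("circular") is not relied on — a semicircle gives
L = ½ — the implementation follows the formula.

## Summaries

Cell summaries use two-stage aggregation (trial → participant mean →
cell mean), so participants with unequal retained-trial counts contribute
equally; pooled aggregation is available behind a flag. The percent
difference between two scores is |a − b| divided by their mean, ×100,
rounded to the nearest integer. Correction frequency tables report the
percentage of perturbed trials with a detected correction per
group × perturbation time × direction cell; empty cells are missing, not
zero. Inferential statistics (mixed models, post hocs, effect sizes) are
out of scope by design; the participant-level export is formatted for an
external stats environment.

## Detector calibration and the design of the defaults

The ±1.5 SD rule has an inconvenient property: if the across-trial
variability of x were Gaussian and shared by the trial under test, the
one-sided exceedance of the band would be ≈6.7% — before any allowance
for multiple looks along the trace — so a naive simulation would show a
false-positive rate well above what the method is trusted to deliver in
practice. Specificity comes from structure, and the generator's defaults
encode that structure deliberately:

* the dominant across-trial variability (the constant offset) produces
  excursions that begin *before* the perturbation and are excluded by the
  causality rule;
* fast sensor noise is small relative to the band (≈0.014 cm filtered vs
  a ≈0.38 cm half-width), so noise-initiated sustained excursions on the
  correct side inside the scan window are rare;
* the sustain requirement removes isolated threshold grazes.

Measured on perturbation-scheduled sessions generated *without*
corrections at default settings, the detection rate is 3–4% across seeds.
True corrections traverse the band within a few tens of ms of onset
(7 cm displacement against a ≈0.4 cm threshold), so sensitivity for
full-amplitude corrections is limited only by pre-deviated trials
(~6–8% at defaults).

Validation of latency recovery uses the noiseless limit (no noise, no
offsets, fixed submovement duration): there the estimate exceeds the true
onset only by the grid ceiling (0.8–4.2 ms, +2.5 ms mean over onsets of
120/160/200 ms) and rank agreement is exact. The limit is not a
convenience: with only three distinct true onsets, any within-group
estimator jitter spreads ranks across each tied block and caps Spearman's
ρ at √(8/9) ≈ 0.943 regardless of how small the jitter is, so rank-perfect
recovery is observable only where estimates quantize onto the sampling
grid. Similarly, frequency-table recovery uses the noiseless geometry so
that detection is exact and recovered percentages differ from the
configured rates only by binomial sampling. In these degenerate
validation setups detection runs on raw traces: the 20 Hz zero-phase
filter leaks a symmetric lead-in of the submovement that is irrelevant at
realistic band widths but poisons a zero-width band.

## What the synthetic validation does not show

The generator reproduces the statistical structure the analysis assumes —
smooth single-peaked reaches, superimposed corrections, slow-plus-fast
lateral variability, rule-identifiable artifacts — not real motor
behaviour. Real trajectories contain mid-frequency motor variability
(sub-movement jitter, tremor, drift) that is neither constant within a
trial nor as fast as sensor noise; the detector's false-positive rate on
real data depends on that spectrum and should be estimated per dataset,
e.g. by running the detector on static trials against an envelope built
from the remaining static trials. Group parameter defaults (the +28 ms /
+36 ms / +37 ms older-group offsets, the correction probabilities) are
configuration defaults motivated by published observations, not ground
truth about ageing.

## Numerical choices and conventions

* All trial-relative times are measured from reach onset; correction and
  MPO latencies from perturbation onset.
* Reaches are generated and analysed on the per-trial 240 Hz grid aligned
  at reach onset; the last sample falls at or just past movement
  completion, and the touch is the final sample's screen position.
* Zero-phase filtering requires > 27 samples (pad length of the two-way
  4th-order filter); shorter trials are excluded with a named reason.
* `filtfilt` idempotence on band-limited signals holds away from the
  pad-and-reflect edges; tests compare the interior.
* Peak-velocity ties break to the earliest sample; summary rows are
  deterministically ordered; session CSVs are written with 9-decimal
  fixed format so identical analyses are byte-identical.
* Problem sizes in the validation suite (480–1,920-trial sessions,
  500-trial oracle comparisons, 120 trials per frequency cell) were
  chosen to keep binomial/recovery tolerances meaningful at desk scale.
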