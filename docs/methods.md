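# Methods

This note records the models implemented in `pushpull`, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions a maintainer would want written
down.  Units throughout: millimeters, milliseconds (integer event
times), mm/s for speeds; simulated sampling is 1 kHz unless configured.
Coordinates: +x anterior (push), −x posterior (pull), +y up.

## Signal chain

The rig digitizes each joystick axis with a 10-bit ADC spanning 0–5 V,
codes 0–1023, resting near mid-scale.  `Calibration` maps codes to mm as
`x = slope·(code − center_code) + offset`; `center_code` defaults to 512
(the exact midpoint of the code range; physical sticks rest near ~500
and per-box calibration absorbs the difference).  Volts are exposed as
`full_scale · code / max_code`, exact at both endpoints.

Smoothing is a **causal trailing mean** over 20 ms — each output sample
averages the inputs in `(t − 20, t]` — because that is what a real-time
controller can compute; a centered filter would use future samples the
box does not have.  Re-baselining takes the mean over the first 50 ms
after joystick extension and reports displacements from it, absorbing
slow drift; traces shorter than the window use every sample and warn.

Choice detection uses a **strict** inequality (`|x| > threshold`,
default 3 mm on the anteroposterior axis) and first crossing wins;
samples after the first crossing cannot change the result.  The
auditory task's displacement threshold is a free config parameter
(`AuditoryMotorConfig.threshold_mm`, default `None`): the platform
treats it as box-specific, so the package refuses to invent a value.
Simulation helpers pass 3 mm — the value task's threshold — as an
explicit, package-level simulation choice only.

## Task engines

Both engines are pure functions of (agent, config, seed); the same seed
reproduces a session bit-for-bit, and every session log carries its
config snapshot and seed.

*Auditory-motor 2AFC.*  2–5 s uniform pretrial interval, 500 ms cue,
5 s response window, 200 ms reward delay, 5 s omission noise with reset
ITI, cap at 30 min or 100 rewards (first reached), 10 µl per reward.
Daily training runs the two single-association phases (low→pull,
high→push) back to back with alternating order; a perfect performer
therefore completes 200 correct trials and earns 2 ml per day.  The
omission-noise duration is configurable because sub-second variants of
the same rig exist; 5 s is the default.

*Two-armed bandit.*  Joystick extension, 100 ms wait, GO cue, 10 s
response window; outcomes rewarded (2.5–8 s ITI), unrewarded (same ITI),
omission and premature (white noise + 15 s timeout).  Rewards are
Bernoulli(0.8) on the high side and Bernoulli(0.2) on the low side.
Blocks last `17 + G` rewarded trials with `G ~ Geometric(p = 0.4)` on
{0, 1, 2, …} — the non-negative support is the only convention under
which the printed minimum of 17 is attainable (numpy's generator lives
on {1, 2, …}; we subtract one).  Reversals are un-cued.  In the
changing-volume phase the per-reward volume is redrawn uniformly from
{2, 4, 8} µl at each reversal; the exact schedule is not otherwise
constrained, and uniform redraw is the least-structured choice.

With a `TracePolicy`, every bandit trial gets a synthetic
anteroposterior trace and the engine registers the choice by running the
actual real-time chain (20 ms smoothing, threshold detection) on it, so
outcome labels are consistent with the trace by construction rather than
by bookkeeping.

*Tones.*  Cue tones are harmonic stacks: fundamental plus five
overtones at k·f, k = 1…6.  The amplitude law 1/k is a standard
harmonic-series rolloff chosen for want of a printed spectrum; it is
configurable.  Harmonics at or above Nyquist are dropped with a warning
instead of aliasing.  WAV export is 16-bit PCM via the standard library.

## Synthetic agents and trajectory generators

The Q agent implements the two-parameter forgetting model (below) as a
behaving policy.  Optional couplings regenerate the vigor phenomena in
simulation: peak displacement gains `vigor_gain · (Q_push + Q_pull)` and
latency loses `latency_gain · (Q_push + Q_pull)`, floor-clamped; and an
opt-in `volume_sensitive` flag scales the *agent's subjective* reward by
`volume / 8 µl` so total value — and therefore vigor — tracks the
block's reward volume.  These couplings are a minimal mechanism for
producing the orderings, not a claim about murine physiology, and the
fitted model never sees scaled rewards (see below).

`generate_trajectory_2d` produces out-and-back reaches toward a target
at effective jitter `jitter·(1 − stage)` and effective speed
`speed·(0.25 + 0.75·stage)`: the stage knob moves batches monotonically
from naive (circuitous, dissimilar, spread out, slow) to expert
(straight, stereotyped, compact, fast).  Pushes head downward–forward,
pulls upward–backward (vertical bias 40 % of the target displacement).
Jitter is box-smoothed Gaussian noise with endpoints pinned, so reaches
start and end at rest.

`generate_ap_trace` builds 1-D traces from programmed bouts.  Each bout
has a cosine-ramp / plateau / cosine-ramp speed profile, which lets a
spec fix direction, peak speed, duration *and* displacement whenever
`displacement ∈ [peak·dur/2, peak·dur)`; omitting displacement yields a
pure raised-cosine profile.  Inconsistent triples raise rather than
being silently adjusted.

What these generators do **not** emulate: limb biomechanics, paw slips,
grip changes, lick artifacts, session-scale fatigue, or any fitted
correspondence to real mouse traces.  Tests passing on them show the
*analysis chain* is correct and the *orderings* are recoverable, not
that real data will show effects of any particular size.

## Kinematics

Preprocessing removes consecutive duplicate coordinate pairs and centers
on the per-trajectory coordinate medians.  Tortuosity divides path
length by the first-to-last chord and is reported in two modes: `full`
(the literal definition) and `outbound` (truncated at the point of
maximum displacement), because the full ratio is undefined for closed
out-and-back reaches.  Net displacements under `epsilon_net = 0.5 mm`
are excluded with a recorded reason rather than producing unstable
ratios; `summarize_session` defaults to the outbound mode.

The Fréchet distance is the **discrete** variant computed by dynamic
programming over the coupling lattice (numba-JIT inner loop, pure-Python
fallback); at 1 kHz sampling the continuous variant would change
distances negligibly and orderings not at all.  Session similarity is
the mean over all n(n−1)/2 unordered pairs.

Explored area counts visited bins of a 1 × 1 mm grid with half-open
edges `[k, k+1)` anchored at the workspace minimum; the workspace itself
comes from pooled coordinate extrema, so a point outside it is an error,
not a clip.  Angular deviation is `sqrt(2 (1 − R̄))` with R̄ the mean
resultant length.  The session-level mean pools **inter-sample
displacement directions** by the occupancy bin of each segment's start
point, computes the deviation per bin (≥ 2 angles), and averages over
bins.  Pooling by occupancy bin and using displacement directions (not
point angles about the origin) was a genuinely open choice; it is the
one that makes the statistic a *local* directional-variability measure,
and it is fixed and documented here.  Note the mean angular deviation is
not part of the learning-trend contract — straight expert reaches
retrace themselves, so a bin can legitimately hold opposed angles.

## Movement bouts and vigor

Velocity is the central finite difference of the 20 ms-smoothed
anteroposterior position (one-sided at the ends); smoothing before
differentiation is fixed so the mm/s thresholds keep their meaning at
1 kHz.  A candidate episode is a maximal run of same-direction samples
strictly above the 2.5 mm/s floor; it becomes a bout when it contains a
sample strictly above 7.5 mm/s and its floor-to-floor span strictly
exceeds 50 ms.  Measuring the sustain over the whole episode (rather
than only after the initiation sample) is required for the canonical
raised-cosine test bout — peak 10 mm/s, 100 ms — to count as a bout; the
criteria themselves do not say otherwise.  A sign change closes a bout
and may immediately open an opposite one if that sample already clears
the initiation speed; joystick retraction truncates everything after it.

Per-trial readouts: peak displacement `max |x|`; path length `Σ |Δx|`;
bout count; directional consistency = bouts in the majority direction ÷
all bouts (∈ [0.5, 1] whenever bouts exist); decisive-bout mean velocity
as the mean **absolute** velocity within the bout containing the
threshold crossing (magnitudes are what the contrasts compare); choice
latency = crossing time − GO.  When smoothing pushes the crossing
outside every bout, the nearest preceding bout is used and the result is
flagged — never silently.

## Value model and companion analyses

The fitted model is the two-parameter forgetting Q-learner:

    chosen:    Q ← Q + α (r − Q)
    unchosen:  Q ← (1 − α) Q
    choice:    P(push) = σ(β (Q_push − Q_pull))

with r ∈ {0, 1}, Q initialized at 0, α ∈ (0, 1] shared between learning
and forgetting ("nondifferential"), β ≥ 0, and no bias term (two
parameters exactly; a bias is available but off).  Rewards enter the
model unscaled by volume; volume effects are analyzed through
kinematics.  Omission and premature trials are dropped before fitting
(they carry no choice) and retained in session logs.

Fitting minimizes the exact negative log-likelihood, written with
`logaddexp` so large β cannot underflow.  The optimizer is a coarse
deterministic grid (α: 0.025…0.975 step 0.025; β: 0…20 step 0.25) —
vectorized over β for each α — followed by Nelder–Mead from the grid
optimum; the reported NLL never exceeds the best grid NLL and the whole
procedure is deterministic for a given series.  The fitting recursion is
an inlined copy of the agent update for speed; a test pins its exact
equivalence to `agents.q_update`/`softmax_choice_prob` so there is one
behavioral definition.  Parameter recovery over α ∈ {0.2, 0.5, 0.8} ×
β ∈ {1, 3, 10} at 5,000 trials lands the median |α̂ − α| well inside
0.1 in the test suite.

|ΔQ| splits use the median by default: trials strictly below it are the
high-uncertainty class.  Win-stay/lose-switch rates condition on the
previous completed trial.  The repetition regression predicts
`repeat_t = [choice_t = choice_{t−1}]` from per-lag rewarded/unrewarded
indicators, fit by IRLS (statsmodels GLM, tol 1e-8, max 100 iterations)
with a ridge-IRLS fallback (penalty 1e-4, flagged) under perfect
separation.  Because each lag's indicator pair sums to one on completed
trials, an intercept would be perfectly collinear with it; the default
fit therefore has **no intercept** (reported as 0), which makes the
weights directly interpretable — `P(repeat | win) = σ(w_R)`,
`P(repeat | lose) = σ(w_U)`.  For lags beyond the first, indicators are
signed by whether the lagged choice agrees with the choice being
repeated.  One lag is the default.

Vigor-versus-value summaries use medians plus rank statistics computed
by explicit rank sums: an ordered-alternative (Jonckheere-style) trend
across the 2/4/8 µl volume levels, and two-group rank sums for the
low/high-|ΔQ| contrasts, with seeded permutation p-values (default
1,000 reps in the library call; `reps = 0` yields statistics only).
Permutation nulls were chosen over named asymptotic tests because group
sizes per volume block are modest and the statistic is already
rank-based.  Groups with fewer than 3 trials are excluded and named.

## Problem sizes and determinism

Simulated checks run at the sizes the quantities need: 10,000 trials for
the oracle reward rate (binomial ±1 % at that n), 5,000-trial sessions ×
20 replicates per cell for parameter recovery, 20,000 trials for
regression-weight recovery, 100 randomized fixtures for bout-segmentation
recovery, 200 random curve pairs (length ≤ 6) for the Fréchet
DP-versus-recursion equivalence, and 25–50 trajectories per learning
stage for the trend suites.  Every stochastic path takes an explicit
seed or `numpy` Generator; there is no hidden global state, and
`scripts/acceptance.py` derives all of its streams from its `--seed`
argument via `SeedSequence`.

## Known limitations

* The forgetting/softmax form is the standard reading of the
  two-parameter model family; alternative parameterizations (differential
  forgetting, dual learning rates, bias terms) are out of scope except as
  noted config switches.
* Bout analysis is 1-D by design; the value task physically constrains
  motion to the anteroposterior axis, and no 2-D segmentation is offered.
* The trajectory generators are stylized; nothing here should be read as
  a fitted model of mouse forelimb kinematics.
* Cohort-level inferential statistics on real animals (ANOVA/Dunnett,
  paired t-tests, sex differences) are outside the package's scope.
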