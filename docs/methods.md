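# Methods

This note documents the models, the numerical choices, and what the
synthetic-data experiments do and do not establish.

## Task environment

The cross-modal block-switching task is discretised into steps. Every
trial begins with an end-of-trial cue (a lick there is a needless lick,
punished −1 as an internal cost), odour-block trials contain an irrelevant
grating with probability 0.7 (a lick there is punished −1), and the final
step presents the reward-relevant cue: lick → +1 for stimulus 1, −1 for
stimulus 2; no-lick → 0. Trials therefore have 2 steps, or 3 in
odour-block trials with an irrelevant grating. A trial is *correct* when
the final-step response is correct and no needless lick occurred earlier.

Blocks switch automatically when the response to the relevant stimuli is
strictly above 80% over the last 30 trials and, in odour blocks, every
irrelevant grating over the last 10 trials was ignored. Immediately after
a switch a transition period forces the stimulus sequence: into a visual
block, the rewarded grating is shown until three consecutive correct
licks; into an odour block, the irrelevant grating is forced — variant V1
shows the unrewarded grating first (so the switch is signalled by the
unexpected odour, not by reward omission) and the rewarded grating
afterwards, variant V2 forces the rewarded grating throughout. A
`fixed_transition_trials` option replaces the three-consecutive-correct
rule with a fixed number of forced trials, since the two descriptions of
the protocol differ; the consecutive-correct rule is the default.

Real-time delays (running initiation, stimulus durations, timeouts) are
abstracted away; the environment is purely step-based. Blocks that an
agent can never complete are force-ended after `max_block_trials`
(default 500) and flagged, so simulations of degenerate policies
terminate; the cap never fires under the actual experimental protocol.

One consequence of pinning the end-of-trial cue's Q-values at zero is
that the ε-greedy policy at that cue is a coin flip (ties break uniformly
at random), so agents emit uninformative licks at the end-of-trial step.
These never enter the per-stimulus lick probabilities used for fitting or
the relevant-stimulus performance used by the switch criterion.

## Agents

**Basic RL** is tabular SARSA over the four stimulus cues and two actions:
δ = r + Q(s′, a′) − Q(s, a), Q ← Q + αδ, ε-greedy. It keeps learning in
the test phase, exactly as during training.

**Belief-state RL** holds two Q-tables (visual and odour context) and a
belief b = (p(v), p(o)), initialised to (0.5, 0.5) — an uninformative
prior, a choice this package makes where the protocol leaves it open. At
each step the assumed context is the argmax of the belief (an exact tie
keeps the previous assumption); SARSA updates go only to the assumed
context's table. On steps presenting the unrewarded grating a separate
exploration rate ε′ replaces ε, in both block types (the narrower reading
— odour blocks only — is available via a flag). At each trial end the
detected block d (one-hot by the modality of the final cue) yields
χ = d − b; a single scalar ξ ~ N(0,1) multiplies both components as
χ′ = f·χ·(1 + βξ), where f is the silencing factor of the detected
modality (1 when no silencing is simulated; silencing applies in the test
phase only, training is always unsilenced). The belief update
b′ = b + ζχ′ is clipped to a floor of 1e−9 (so renormalisation is always
well defined) and renormalised; if both components hit the floor the
belief resets to (0.5, 0.5). In the test phase Q-learning is frozen
(α = 0) unless `alpha_test` explicitly keeps it on, which warns.

Default parameters are the best-fit values for the primary dataset:
ζ = 0.6858, β = 1.997, ε = 0.049, ε′ = 0.280, training α = 0.1; the
silencing-dataset companions are ζ = 0.7698, β = 1.987, ε = 0.1072,
ε′ = 0.4516 with fitted factors (0.2143, 0.5016) for visual- and
odour-detected trials.

## Fitting

The target is p(lick|cue) by trial position in a ±20-trial window around
block transitions, separately for transitions into visual and into odour
blocks (the alignment window is this package's choice). Cells never
observed — e.g. the unrewarded grating during the forced transition
period — are missing and excluded from the RMSE, which is computed over
cells defined in both curves. Multiple sessions pool by trial counts.

A candidate parameter set is scored by simulating SARSA training for half
the configured steps and a test half (frozen Q for the belief model),
across several seeds split 2:3 between the two transition-period variants
(the ratio of experimental sessions), and taking the RMSE against the
target per seed. Three numerical choices matter at desk scale:

* **Median across seeds.** Rare parameter/seed combinations corrupt
  training — the multiplicative belief noise (1 + βξ) reverses the update
  direction on roughly Φ(−1/β) of trials, and an unlucky streak can poison
  the assumed-context Q-tables so blocks hit the trial cap for the rest of
  the run. A single such seed dominates a mean; the median is robust.
  Seeds with any capped block are additionally flagged degenerate and
  dropped (a candidate with a majority of degenerate seeds is excluded).
* **Final re-scoring.** After the grid search and Nelder–Mead refinement
  (box constraints by clamping, top-2 grid starts by default), the leading
  candidates are re-scored on fresh seeds at higher fidelity and the
  winner chosen from those scores. With hundreds of noisily scored
  candidates the preliminary minimum is biased low (winner's curse); the
  re-score removes that selection bias at negligible cost.
* **Variant matching.** The fitting simulations must use the same mix of
  transition-period variants as the data; fitting a single-variant
  session against mixed-variant simulations biases ζ upward measurably.

Cross-validation folds are contiguous fifths of the data's transition
sequence; for each fold the best candidate by training-fold RMSE is
selected from the evaluated pool and its held-out RMSE reported. Model
selection compares these held-out RMSEs fold by fold.

The silencing-factor fit holds all base parameters fixed and frees only
the two factors (grid over [0.1, 1.0] plus simplex refinement and the
same final re-score). Silenced sessions switch slowly and so contain few
transitions per step; the synthetic recovery experiments therefore use
400k-step silenced datasets, below which the odour factor is not
identified within a useful tolerance.

Simulations inside the fitter run on numba-compiled kernels (~40×
faster than the object-oriented reference implementation) when numba is
importable, and fall back to the reference path otherwise. The two paths
share trial semantics but not RNG streams; the test suite asserts their
transition-aligned curves agree within sampling error.

Default problem sizes (100k steps per candidate simulation, 5 grid seeds,
16 re-scoring seeds at 4× steps) are desk-scale choices that keep a full
fit under a minute while resolving ζ to about ±0.2 and ε to ±0.05 on
100k-step datasets; study-scale step counts (N = 500k–2M) are reachable
through `FitConfig`.

## Behavioural metrics

Behavioural d′ = Φ⁻¹(H) − Φ⁻¹(F) with rates clipped to
[1/(2n), 1 − 1/(2n)] so perfect sessions stay finite (the clipping
convention is this package's choice). Stable-period d′ uses trials outside
transition periods and at least 5 trials after a transition period ends.

Switching speed is the number of trials elapsed before the first run of
three consecutive correct responses to the *rewarded* grating of the new
block begins (licking it after a switch into a visual block; ignoring it
after a switch into an odour block — the never-rewarded grating carries no
evidence of a switch and does not enter the run). Zero elapsed trials is a
fluke (a correct response before any evidence of the switch), excluded
from speed statistics; one is a one-shot transition. Blocks without a
qualifying run report the block length and are flagged unconverged.

The model's prediction-error amplitude for a transition is
|χ′₁| + |χ′₂| at the end of the first post-transition trial — the noisy
signal that actually drives the belief update; a switch compares χ
instead, since which of the two the original analysis used is ambiguous.
Up to 70 transitions per outcome group are sampled before the two-sided
rank-sum test, matching the experimental transition count.

## Calcium analysis

ΔF/F uses a baseline F0(t): the running minimum, over the preceding 60 s,
of the causally smoothed trace (0.75 s moving average). Both windows are
trailing and the start of the trace uses the available history
(implemented with edge-replicated trailing filters; an explicit
brute-force oracle checks this in the tests). Seconds convert to frames
by rounding to nearest with a minimum of one frame. Neurons whose baseline
is ever non-positive are flagged and excluded.

The prediction-error screen measures mean activity in 1.5 s epochs:
(1) 2.0 s after the offset of the first post-transition grating, provided
it drew no lick (the moment the expected odour fails to arrive);
(2) at odour onsets late in the preceding odour block, after correctly
ignored gratings; (3) 2.0 s after unrewarded-grating offsets later in the
visual block, outside the transition period and excluding the block's
last 10 trials. Conditions 2–3 average up to 7 eligible trials per
transition, taking the 7 nearest the transition when more exist (a
random-7 option is available). Two Wilcoxon rank-sum tests across
transitions (prediction-error vs each control condition) at two-sided
α = 0.05 without multiple-comparison correction classify each neuron:
both significant → prediction-error neuron, signed by whether its
prediction-error mean is the largest (positive) or smallest (negative) of
the three; one significant → Type A (odour comparison) or Type B
(no-odour comparison). Under the dual criterion the empirical null rate
is well below α because the two tests share the prediction-error sample
(~1–2% at α = 0.05 in the null simulations). At least 5 usable
transitions are required, otherwise neurons are labelled indeterminate.

Decoding uses a per-frame L2-regularised logistic classifier (fixed
penalty C = 1 by default) with stratified 5-fold cross-validation after
balancing classes by subsampling the larger one. The bootstrap CI for a
class proportion resamples with replacement (10,000 times by default) and
takes the 0.5th/99.5th percentiles for a 99% interval. The encoding model
builds time-shifted regressor copies (sensory: 0 to +2 s; motor (running,
licking): −0.5 to +2 s, one-frame steps) and fits ridge regression per
neuron, selecting the penalty from 36 log-spaced values in [1e−2, 1e5] by
5-fold cross-validated R²; ΔR² against a model without the motor
regressors quantifies overt-behaviour coding.

## Synthetic data

The scripted behavioural generator emits licks i.i.d. from a per-cue table
under the current rule, switching rules a fixed number of trials after
each block boundary; the first three gratings of each block are the
rewarded one, a fixed-length stand-in for the task's forced transition
period. The agent-driven generator runs the belief-state agent in the
environment and returns its test-phase log and mismatch trace.
`generate_study_dataset` produces five sessions in the 2:3
variant ratio, emulating the composition of the experimental dataset.

The calcium generator lays trials on a timeline (8 s trial period,
grating 0.5–2.3 s, odour — when present — 2.0 s after grating offset,
mirroring the delay used for epoching), then plants neuron classes as
single-exponential transients (τ = 0.7 s, a GCaMP7f-like decay) at their
class-defining events plus i.i.d. Gaussian noise per frame: positive
(negative) prediction-error neurons respond (are suppressed) only at the
first post-transition expected-odour time; Type A neurons respond at
every odour onset; Type B neurons at odour onsets and prediction-error
times equally. Defaults are 4.8 Hz frame rate, response amplitude 0.3
ΔF/F and noise SD 0.1 (a 3:1 amplitude-to-noise ratio).

What these synthetic data do *not* emulate: correlated (shared) noise
across neurons, baseline drift and neuropil contamination, lick- and
running-locked global modulation, variable trial timing, or partial-trial
responses. Passing the round-trip tests therefore shows the screening and
decoding machinery is correct and calibrated under the stated generative
assumptions, not that real recordings would yield the same sensitivity.

## Known limitations

* ζ and β trade off along a shallow ridge of the RMSE objective; at
  100k-step datasets ζ is only resolvable to roughly ±0.2 even with exact
  model match, and β often pins at a grid edge. The odour silencing factor
  is similarly weakly identified, needing several hundred thousand steps
  of silenced data for ±0.15.
* The fitter's compiled and reference simulators are checked for
  statistical, not bit-level, agreement.
* The environment does not model within-stimulus lick timing, reward
  volume, or running dynamics; analyses that need them (pupil/running
  controls) are out of scope.
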