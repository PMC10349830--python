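# Methods

This note documents the models, statistics and numerical choices behind
`neurocue`, and what its synthetic data can and cannot show.

## The task

The paradigm is exogenous (stimulus-driven) spatial cueing of near-threshold
detection.  A peripheral, non-predictive dot cue (50 ms) precedes a tilted
Gabor target (16 ms) by a 300 ms onset asynchrony; the target appears on the
cued side (valid), the opposite side (invalid), or not at all (catch, 20% of
trials).  Observers first discriminate the tilt (2AFC, alternatives 30
degrees apart, drawn from 12 orientations offset to exclude the cardinal
axes) and then report the target's perceived presence and side.  Each block
holds exactly 110 trials — 44 valid, 44 invalid (left/right counterbalanced
exactly within validity) and 22 catch — shuffled by seed.  Counterbalancing
is exact rather than stochastic so that fixtures carry no sampling noise in
their condition counts.

### Simulated observers

The behavioral observer is a logistic psychometric function
`P(seen) = 1/(1 + exp(-slope (c - threshold)))` with an additive detection
shift on validly cued trials (default +0.05, the liberal criterion shift
that exogenous cues produce), a catch-trial false-alarm rate (default 0.10,
reported on the cued side with probability 0.75), discrimination accuracies
conditional on seen/unseen (0.85 / 0.55), and lognormal response times.
Probabilities are clamped to [0, 1] after the shift, with a warning.

### Staircase calibration

Target contrast is calibrated by two randomly interleaved one-up one-down
staircases (contrast down after "seen", up after "unseen"), which converge
on the 50% detection point; the calibrated contrast is the mean of the two
converged values, each the mean of that staircase's last 16 reversals.  The
step starts at 6% of the contrast range and is halved after each of the
first 4 reversals.  These values were chosen by simulation: starting from
maximum contrast, a small first step spends half the trial budget on the
initial descent, and averaging few reversals at a very small final step
inherits the random-walk offset of the staircase.  A quantitative caveat:
with a slope-30 observer and a 200-trial budget, the Fisher information of
the staircase data bounds any estimator of the 50% point to an SE of about
3.5–4 percentage points in detection probability, so single calibrations
scatter accordingly; the package's tests therefore assess the median over
independent calibrations.

### Signal detection indices

Sensitivity is the nonparametric `a' = 0.5 + (H-F)(1+H-F)/(4H(1-F))` for
hit rate H ≥ false-alarm rate F, with the standard mirror correction
`a'(H,F) = 1 - a'(F,H)` below the diagonal (logged when applied), and bias
is `C = -(Z(H)+Z(F))/2`.  Rates computed from counts are clamped as
`(count + 0.5)/(n + 1)` so the probit stays finite at 0 and 1.

## Synthetic contact data

The generator emulates the statistical structure that the clustering and
statistics stages assume, not the biophysics of intracranial recordings.
Contacts belong to one of five temporal-profile families or a null family;
each family is defined by the time windows (target-locked, −300..+500 ms at
100 Hz) in which reported targets evoke more high-frequency-broadband (HFBB)
power than unreported ones:

| profile           | seen > unseen windows (ms)                         | interaction |
|-------------------|----------------------------------------------------|-------------|
| visual            | 90–350, 380–430                                    | valid-seen boosted, 190–220 |
| sustained         | −140..−90 (pre-target), 160–200, 240–300, 340–430, 450–500 | valid-seen boosted, 270–330 |
| late accumulation | 300–500 (linear ramp)                              | valid-seen boosted, 360–430 |
| reorienting       | 160–190 (Gaussian bump, σ = 15 ms, at 180 ms)       | invalid-seen boosted, 160–190 |
| conscious report  | 310–450                                            | none (validity-independent) |

Window shapes are boxcars with 10 ms raised-cosine edges (transient and
sustained windows), a linear ramp (late accumulation) and a truncated
Gaussian bump (reorienting); the shapes themselves are this package's
choice — only the windows are constrained.  The interaction term is added
antisymmetrically (±half the interaction amplitude on valid-seen vs
invalid-seen) so the marginal seen−unseen difference stays exactly the
stated profile.  Amplitudes are free parameters in z-units (defaults:
profile 1.0, interaction 0.5), calibrated only by recovery requirements.
Activity is `gain × profile mean + N(0, noise_sd)` with a per-contact
lognormal(0, 0.2) gain emulating electrode heterogeneity; trials carry a
complete, balanced 2×2×2 condition labelling.  The default dataset is 300
contacts × 200 trials; the patient-scale proportions (42/148/67/19/38 of
727) are available as a preset.

What passing tests on this generator show: that the clustering recovers
planted temporal families at realistic noise, and that the statistics are
calibrated under the null and sensitive to planted effects.  What they do
not show: robustness to 1/f background, epileptic artifacts, inter-patient
heterogeneity, or correlated noise across contacts — real recordings have
all of these and the generator has none.

A separate raw-signal generator injects amplitude-modulated 70–140 Hz
bursts at known times into pink noise, providing ground truth for the
spectral pipeline.

## Spectral preprocessing

Bipolar re-referencing differences adjacent contacts within an electrode
(n contacts → n−1 bipoles).  HFBB power uses complex Morlet wavelets with 7
cycles at 14 equally spaced center frequencies spanning 70–140 Hz
inclusively (step 70/13 Hz); per band, power is z-scored per trial against
the 200 ms pre-cue baseline *before* averaging across bands, which
normalizes the 1/f slope across the band (the alternative dialect,
average-then-z, is a single-line change).  The band average is then
low-pass filtered (4th-order zero-phase Butterworth at 40 Hz) and sampled
on an exact 10 ms grid aligned to target onset.  Artifact rejection flags
trials whose per-trial maximal amplitude, maximal z, variance or kurtosis
deviates from the contact's median by more than a threshold (defaults 8, 8,
5, 5 SDs); contacts lose their keep-flag when >30% of their trials are
rejected.

## Trajectory k-means

Entities (contacts or model units) are represented by their condition ×
time matrices of trial-averaged activity, z-scored per entity over the
concatenated values of all conditions and timepoints (a zero-variance
entity maps to zeros, not NaN).  The distance between trajectories is the
sum of time-point-by-time-point Manhattan distances across conditions —
order-preserving, no temporal warping.  Lloyd iterations therefore update
centroids with the element-wise *median* (the L1-optimal center; the mean
is available as a dialect flag), assign by exhaustive nearest centroid with
ties broken to the lowest cluster index, repair empty clusters by
re-seeding at the entity farthest from its assigned centroid, and assert
that inertia never increases.  The best of `n_restarts` random restarts by
inertia is kept (default 20 at desk scale; thousands are available — the
restart count, not the Lloyd iteration cap, dominates solution quality).
The number of clusters is the silhouette-mean argmax over a k sweep, with
cluster-membership stability reported as the best-match Jaccard overlap
between consecutive k solutions.

## Time-resolved statistics

Cluster-level tests treat the contact (or unit) as the observational unit:
trials are first averaged within contact × condition, then a balanced
N-way fixed-effects ANOVA runs across contacts at every timepoint.  Sums of
squares are computed from marginal means by Moebius inversion and partition
exactly; the implementation is vectorized over time and cross-checked
against statsmodels OLS on toy designs.  Holm–Bonferroni (step-down)
controls the familywise error over timepoints per term; Holm–Šidák is used
across connection-graph edges.  Both corrections are direct implementations
(cross-checked against statsmodels, whose `multipletests` forces a garbage
collection per call and is three orders of magnitude slower in per-timepoint
loops).  Effect sizes are partial η² per term and Cohen's d (mean over
pooled SD across contacts) for the attention × report interaction contrast
`(seen valid − unseen valid) − (seen invalid − unseen invalid)`; the
across-cluster gradient is tested by one-way ANOVA plus a linear polynomial
contrast with equally spaced centered weights.  RT analyses bin trials into
20 equal-count quantiles by discrimination RT (stable sort; rank-based
edges), run a one-way ANOVA across bins per timepoint in 0–1000 ms, and
compare the slowest to the fastest half of bins with Holm-corrected
t-tests.  Trials with RT < 150 ms or beyond 3 SD are excluded before all
behavioral statistics.

## The recurrent task model

A single recurrent layer of N = 50 rectified-linear units, 80% excitatory,
obeys

    tau dx/dt = -x + f(W_rec r + b_rec + W_in u + sqrt(2 tau sigma_rec^2) xi),
    r = f(x),  z = W_out r + b_out,

with tau = 100 ms, sigma_rec = 0.05 and f = ReLU, discretized by an Euler
step at dt = 10 ms: `x <- (1-dt/tau) x + (dt/tau) f(drive)`.  Dale's
principle is enforced on W_rec and W_out: a unit's outgoing weights (a
column, in this package's convention W[i,j] = j→i) share its sign, and the
recurrent diagonal is held at zero (no self-connections).  The affine
readout is squashed by a logistic so the two reported outputs lie in
[0, 1]; the squash lives in the readout/loss layer as a documented dialect
of the affine output equation.

Trials mirror the human task: 200 ms fixation; a 50 ms cue pulse of
amplitude 0.30 on the cued input channel; the target pulse (amplitude =
contrast, drawn from 12 levels spanning 0–0.13) 300 ms after cue onset on
the cued or opposite channel, absent in 20% catch trials; a response window
of 300 ms opening 150 ms after target offset; Gaussian background input
noise of SD 0.05 throughout.  Training minimizes the masked mean squared
error between the squashed outputs and target traces (target-side output 1
inside the response window on present trials, all else 0) by
backpropagation through time — implemented by hand in numpy with
numba-jitted sequential loops and single-precision arithmetic inside
training only — using Adam (learning rate 1e-2, cosine-decayed to 10%,
gradient norm clip 1.0, batch 50), with the Dale constraints re-imposed by
projection after every update.  The desk-scale default is 20,000 iterations
(≈2.5 min on one CPU core); the full-scale regime is two to ten times
longer and available by flag.  Initialization is Glorot-Gaussian truncated
to [−1, 1], sign-folded for Dale, with inhibitory columns scaled by the E/I
ratio (4×) so total excitatory and inhibitory drive start balanced.

Behavioral readout: discrimination is the argmax of the two window-averaged
outputs on target-present trials; a present trial is "seen" when the
windowed maximum of the target-side output exceeds 0.5, and a catch trial
is a false alarm when either output's windowed maximum does.  Detection is
correct on present-and-seen or absent-and-not-seen trials.  Psychometric
curves are least-squares logistic fits with floor/ceiling asymptotes;
degenerate (flat or non-monotone) data is flagged but still returns
parameters.

Unit clustering re-uses the trajectory k-means in the three-condition space
(validly cued seen / invalidly cued seen / no target) on condition-averaged
unit rates from 1,000 trials at the intermediate contrast 0.10, with a
silhouette sweep over k = 2..10, followed by per-cluster seen/unseen
time-resolved t-tests (Holm-corrected).  Functional labels (visual /
sustained / late accumulation / reorienting) are a deterministic heuristic:
the reorienting cluster maximizes early invalid-seen minus valid-seen
activity; the rest are ordered by the center-of-mass latency of their
valid-seen activity.  The connection graph averages directed unit-to-unit
weights between the excitatory/inhibitory subgroups of the named clusters
(self-pairs exclude the zero diagonal) and tests each edge against zero
with a one-sample t-test, Holm–Šidák corrected.  Lesions zero a group's
input, recurrent (both directions) and output weights and re-evaluate
performance under a seed shared with the intact control, so deltas are
attributable to the lesion alone.  Model–brain similarity draws batches of
trials, correlates the model cluster's seen/unseen mean trajectories
(resampled to the neural time base) with the neural cluster's, and compares
the trained against the untrained distribution with a one-sided permutation
test (add-one corrected).

### Numerical notes

- Simulation and evaluation run in float64; the Euler step reproduces hand
  arithmetic to 1e-12 and the noise-free relaxation to `f(b_rec)` follows
  the discrete exponential exactly.  Training runs in float32 for speed;
  gradients are accumulated into float64 Adam state.
- The drive noise term follows the dynamics equation literally
  (`sqrt(2 tau sigma_rec^2) xi` inside f, per Euler step).
- Divergence guards: |x| > 1e6 raises an instability error; NaN loss aborts
  training with diagnostics.
- Halving dt changes noise-free windowed outputs by < 5% RMS (checked).

## Problem sizes in the test suite

The suite runs the full protocol at desk scale: five models trained from
seeds 0–4 at 20,000 iterations each for the cluster-count and lesion
checks; 200 contacts × 200 trials for clustering recovery; 200 replicates
for familywise-error calibration; 10,000 trials for rate estimates.  The
methodological scaling knobs (training iterations, restart counts, batch
counts) are package defaults and can be raised to the full-scale regime by
configuration.

## Known limitations

- Contacts are pooled as exchangeable observations; there are no random
  effects for patients (the synthetic generator has no patient structure).
- The unit-cluster count of a scaled-down-trained model is a stochastic
  outcome of training; at 20,000 iterations the silhouette sweep often
  prefers fewer clusters than a fully trained model would (see the
  cluster-count acceptance check for the operative definition).
- Because the cue is non-predictive and the target pulse is equally
  legible on either input channel, desk-scale training gives the model
  little incentive to use the cue: intact valid/invalid detection rates
  differ only marginally, so downstream validity-dependent analyses
  (reorienting-cluster identification, validity-selective lesion deficits)
  probe an effect that emerges only in much longer training regimes.
- The synthetic observer has no lapses, attention fluctuations or
  sequential effects; the staircase estimator inherits the information
  floor discussed above.
- The raw-signal generator's pink-noise background is stationary and
  artifact injection is limited to simple outliers.
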