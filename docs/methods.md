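# Methods

`egoallo` re-implements, as a tested pipeline over synthetic data, a set of
analyses that dissociate self-centered (egocentric) movement-direction coding
from world-centered (allocentric) position coding in neural populations
recorded during a multi-directional orienting task. This note describes the
models and procedures, the choices that were genuinely open, and what the
synthetic-data results do and do not establish.

## Task geometry

The task is played on a vertical wall of 7 nose ports: a central port at the
origin and six ports at the vertices of a regular hexagon. The inter-port
spacing is not physically pinned down by the task description; the default is
50 mm and is configurable — all analyses depend only on relative geometry, so
absolute errors scale linearly with the spacing. Port radius is 11 mm.

Movements connect ports. Of the 42 ordered start–target pairs, 30 are legal
trajectories: the 24 ordered pairs of adjacent ports ("short", one spacing)
plus the 6 vertex-to-opposite-vertex movements ("long", two spacings, passing
through the center). Each of the six movement directions (0°, ±60°, ±120°,
180°; 0° = rightward, counterclockwise positive) has exactly 5 trajectories
(4 short + 1 long) and 4 distinct target ports, which is what makes start
port, direction and target port statistically separable: target = start +
direction holds as a vector identity, so the three variables are pairwise
but not jointly independent.

Three session designs are provided: *reference* (all 24 short trajectories),
*distance* (per direction, the two collinear spoke movements plus the long
movement, 18 total; which two short movements enter is not dictated by the
task description — the collinear spokes were chosen so each direction's
trajectories share a line), and *four-direction* (the 16 short trajectories
of the four oblique directions).

## Synthetic sessions and neurons

`generate_session` allocates trials to trajectories in balanced blocks
(⌊n/K⌋ per trajectory plus a random remainder, order shuffled). This
guarantees the ≥8-trials-per-condition inclusion requirement deterministically
whenever n ≥ 8K, rather than with high probability under iid sampling. Event
times per trial: fixation-in at 1.0–1.3 s (so that the 900 ms pre-cue warped
windows stay inside the trial), visual cue 0–0.29 s after fixation-in,
go sound after a 0.5–1.2 s fixation (the cue delay therefore always precedes
the go sound), fixation-out 0.1–0.3 s later, target arrival 0.15–0.4 s after
that, and 1 s of post-arrival recording. Error and fixation-violation trials
are generated at configurable rates (default 0) and excluded downstream.

Neurons are inhomogeneous Poisson processes, piecewise-constant within a
trial: a baseline rate everywhere plus a condition-tuned rate inside a
tuning-kind-specific epoch — start tuning from trial start to go+0.3 s,
direction tuning from cue to arrival, target tuning from go to trial end
(mixed kinds: cue to trial end). The epoch assignment is a modeling choice
(the per-window count statistics are what the downstream analyses consume);
it makes the sequential start→direction→target encoding observable in time
courses. Spikes are placed uniformly within epochs, so per-window counts are
exactly Poisson with mean rate × duration.

Tuning strengths: baselines are log-normal (median ≈ 5 Hz) clipped to
1–20 Hz; modulation depths uniform in 0.5–3 × baseline. These stand in for
the matched-to-real-neuron tuning strengths used in the original validation,
which cannot be reproduced without the recordings; they span weakly to
strongly tuned neurons, and the weak tail is what produces false negatives in
recovery. Spatial tuning is a Gaussian bump over port coordinates
(σ = 0.6–1.2 spacings); direction tuning a Gaussian in angle (σ = 30–80°).
Parameter draws that would predict a negative rate anywhere on the condition
set are rejected and redrawn, which in practice truncates mixed-model depths
near 1.

What the generator does *not* emulate: non-Poisson spiking (bursting,
refractoriness), slow drifts, correlated noise across neurons within a
session, behavioral errors correlated with neural state, and real tuning
curve shapes. Recovery results on this synthetic family therefore validate
the *procedures* (their calibration and discrimination), not claims about
any particular recorded population.

## Single-neuron selectivity

Spike counts in a window are fit to three one-variable Poisson GLMs (start
port: 7 levels; direction: 6; target port: 7; dummy coding). With a single
categorical regressor the Poisson MLE equals the per-level mean counts for
any link, so fits are closed-form. Two quality measures:

- **CV log-likelihood**: leave-one-out; the held-out prediction for trial i
  is the mean count of the remaining trials at its level, and
  LL = Σ log P(yᵢ | ŷᵢ) under Poisson. The closed form
  ŷᵢ = (S_l − yᵢ)/(n_l − 1) equals brute-force refitting exactly (tested).
  A LOO prediction of 0 is floored at 10⁻⁶ so log P stays finite; the floor
  only matters for silent levels of near-silent neurons.
- **R²** (non-cross-validated): variance of counts explained by level means,
  used for time-course displays.

Significance is a permutation test: labels shuffled (default 5,000×, 1,000×
in desk-scale simulations), p = fraction of shuffled CV log-likelihoods
strictly greater than the observed one; the minimum attainable p is 0.
Labels are shuffled independently per GLM. A neuron's *best* variable is the
one with the smallest p (ties → larger CV log-likelihood); min p ≥ α (0.01)
→ "none". Across windows, each variable's p is its minimum over the four key
windows (pre-cue −300–0 ms to cue; post-cue 0–300 ms; go 0–300 ms to go;
arrival ±150 ms to poke), matching the "selective in at least one window"
convention. Sliding windows are causal (the value at t covers (t−width, t]);
warped windows are 3×300 ms pre-cue, 3 equal cue→go, 5 equal go→arrival,
3×300 ms post-arrival.

## Tuning geometry

Preferred direction is the angle of the rate-weighted vector sum of the six
direction unit vectors; a zero resultant is flagged undefined and excluded
from angular summaries. Preferred position is the argmax port (ties → lowest
id, logged). The start–target tuning correlation is the Pearson r between
the 7-port start tuning vector (pre-cue) and target tuning vector (arrival);
the split-half variant correlates tuning from disjoint trial halves in both
directions and averages, so shared trial noise cannot inflate it. Population
inference Fisher-z transforms the correlations and bootstraps the mean
(10⁴ draws), reporting the fraction of bootstrap means at or below zero,
floored at 1/n_boot, Bonferroni-multiplied across simultaneous window pairs.

The start→target switch time fits start and target GLMs in causal sliding
windows aligned to the go sound, smooths both R² curves with a 3-bin moving
average, and returns the first window after the positive peak of
R²_start − R²_target where the difference turns negative. Causal windows lag
a step change by about half a window width; consumers should treat the
estimate as (reported time − width/2) when absolute timing matters.

The per-trajectory rate map uses a shrinkage (MAP-style) estimator: the
description of a "Poisson prior whose mean was estimated from all trials" is
not a proper prior on a rate, so it is interpreted as conjugate gamma
shrinkage with prior mean = grand mean rate and a prior weight of one trial —
this reproduces the intended behavior (low-n trajectories pulled toward the
all-trial mean, high-n trajectories ≈ sample means) and is documented as an
interpretation rather than silently guessed.

## Mixed selectivity (encoding models)

Four firing-rate models over θ (direction relative to the neuron's preferred
direction, wrapped to (−180°, 180°]) and start coordinates (x, y) in mm,
with N(θ; σ) the *normalized* Gaussian density in degrees (so amplitudes
multiplying N carry Hz·degree units):

1. direction: f = b₀ + b₁ N(θ; σ)
2. start plane: f = b₀ + b₁x + b₂y
3. gain field: f = b₀ + (b₁x + b₂y) · N(θ; σ)
4. additive: f = b₀ + b₁x + b₂y + b₃ N(θ; σ)

The preferred direction is fixed beforehand from the vector sum (not co-fit).
Fits are Poisson MLE on counts in the 0–500 ms post-cue window (the
−300–500 ms go-aligned window is available as an option) with L-BFGS-B under
bounds (σ ∈ [10°, 180°], b₀ ∈ [0, 100] Hz, slope/amplitude bounds scaled to
the neuron's mean rate), analytic gradients, 10 random restarts, and f ≥ 0
enforced by clipping plus a quadratic penalty on negative rates. CV R² uses
20-fold CV stratified by (direction × start) condition; each fold is
warm-started from the full-data optimum (per-fold multi-start is not
tractable at population scale and was never observed to change a fold
optimum on synthetic data). CV R² is not clamped and can be negative.

Population comparison: neurons with mean CV R² over the four models > 0.05
are included; for each model pair the statistic is the mean difference of
Fisher-z-transformed CV R²s, with a neuron-resampling bootstrap (default
10⁵ draws) giving a one-sided p floored at 1/n_boot. CV R² values at or
beyond ±1 are clipped to ±(1−10⁻¹⁰) before atanh (negative CV R² below −1
is possible). Because target coordinates are a fixed translation of start
coordinates at any given direction, start- and target-based position terms
are interchangeable in models 3–4 up to a change of b₀.

## Pseudopopulation decoding

Per neuron and decoded variable, correct trials are split into 2 folds per
condition and 32 pseudo-trials per fold per condition are resampled with
replacement using an independent stream per neuron (destroying noise
correlations): 224 pseudo-trials/fold for the 7 position conditions, 192 for
the 6 directions. Neurons are additionally bootstrapped, so each of the
(default 100) pseudopopulations contains ≈ 63.2% of the unique neurons.

Decoding z-scores the combined train+test counts, projects onto the first
4 PCs (fit on train+test jointly, as the source procedure specifies — a
leakage-free variant is behind a flag), and maps PC scores to the
condition's (x, y) with OLS under 2-fold CV. The error is the Euclidean
distance between predicted and true coordinates; central-port conditions
((0,0)) are excluded from mean position errors because degenerate decoders
cluster predictions at the origin. Chance level is the mean distance of
condition coordinates from their centroid (≈ spacing for these designs).

Error-difference time courses are paired per pseudopopulation; significance
is a paired sign-flip permutation over pseudopopulations (5,000 flips,
two-sided) — the source names only "permutation test with 5,000 shuffles".
Cross-window generalization trains at one window and tests at another
(2-fold CV throughout); the multiple-comparison correction is an
extreme-pixel permutation test with one label-shuffled map per
pseudopopulation. Because lower error is better, the extreme statistic of a
shuffled map is taken as its *minimum* error, and a pixel is significant
when the observed mean error beats the α-quantile of those null extremes;
the alternative max-extreme reading of the procedure would make the null
easier to beat, so the min-extreme convention is the conservative one.

## Reference-frame RNNs

Four input/output contingencies (ego-ego, ego-allo, allo-ego, allo-allo) of
the same visually guided task are simulated. Input: 11 frames of a
100×100-px scene — visual-frame border, 50×50-px world-frame border (world
origin at its center), start port, target port (visible only on frame 4),
and 3 static distractors — area-average-downsampled to 40×40 and flattened
(1600 inputs). Intensities: start 0.7, target 1.0, distractors 0.2, frame
outlines 0.3/0.4. Ports render as 7×7-px blocks at the 100-px scale (the
port's pixel size is not specified by the task description; smaller blocks
slow learning sharply because sub-pixel alignment after 2.5× pooling makes
the target's pooled intensity unstable). Ego input pins the start port to
the visual-frame center (the world frame shifts); allo input pins the world
frame. The demanded output at frame 11 is the movement vector
(target − start, world px) for ego output and the target position for allo
output.

The network is a vanilla recurrent layer of 100 tanh units (orthogonal
recurrent initialization; input weights scaled ×5 to compensate for the
sparse, low-intensity images) with a linear 2-unit readout, trained by
stochastic gradient descent (Adam, lr 10⁻³, batch 64, fresh random trials
every batch, ≤2000 steps, early stop at mean readout error < 4 px) with
gradients from backpropagation through time. The loss is applied at frame 11
only, as the task demands.

Hidden-unit analyses: (i) per-frame CV R² of ridge decoding of start,
movement vector and target position from hidden activity on *randomly
generated* test trials — random rather than the 24 discrete trajectories,
because with ≤24 conditions and 100 hidden units any condition-dependent
variable is trivially linearly separable (a condition lookup), which
saturates every R² at 1; (ii) gain-field unit detection, fitting the
additive vs gain-field encoding forms to frame-11 activity by least squares
(Gaussian noise) and scoring the CV R² difference; (iii) RSA: the synthetic
population (windows pre-cue/post-cue/go) and each network (frames 3/7/11)
are condition-averaged over the 24 reference trajectories, reduced to 4 PCs
(component signs canonicalized by skewness so the RDM is basis-invariant),
summarized by correlation-distance RDMs, and compared by the Pearson r of
their lower triangles.

## Problem sizes and calibration checks

Simulation scales used by the tests and the acceptance script (chosen as
desk-scale analogs of the original 541-neurons-per-class / 100-pseudopopulation
/ 20-replicate settings): 100 synthetic neurons per class with 1,000
permutations for selectivity recovery; 50 per class for encoding-model
recovery; 10–20 pseudopopulations in decoding checks; 2 network replicates
per contingency at ≤1,200 training steps. Permutation and bootstrap tests
are verified to hold their nominal type-I error on null simulations within
binomial confidence bounds.

## Known limitations

- The Poisson generator cannot probe robustness to overdispersion; the
  permutation test remains valid under the null regardless, but power
  statements are Poisson-specific.
- The encoding-model recovery operates near the discrimination boundary:
  additive and gain-field predictions differ only off the preferred
  direction, so weakly tuned neurons are recovered as the wrong mixed model
  at some rate; the inclusion filter (mean CV R² > 0.05) removes most of
  them, as it does in the original procedure.
- RNNs are trained to a few px of readout error, not to convergence; the
  qualitative decodability orderings are stable at this scale but absolute
  R² values are not meaningful beyond rank comparisons.
- Multi-session pooling is emulated with a single shared synthetic session;
  the pseudopopulation machinery accepts it transparently, but cross-session
  heterogeneity (drift, different trial counts) is not simulated.
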