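# egoallo

Analysis pipeline for dissociating **self-centered (egocentric) movement
direction** from **world-centered (allocentric) position** coding in neural
populations recorded during a multi-directional orienting task — with a
synthetic-data generator that makes every stage testable against known
ground truth.

## The problem

In a task where a subject fixates at a start port on a 7-port hexagonal wall
and then moves to a cued target port, three spatial variables are entangled
by the vector identity **target = start + direction**. A neuron firing before
movement could encode the planned movement direction (egocentric), the
upcoming target position (allocentric), or the current start position. The
task's 30 trajectories (6 directions × up to 4 targets each) make the three
variables statistically separable, and this package implements the analyses
that exploit that:

- **Single-neuron selectivity** — per-window Poisson GLMs
  (`Spikes ~ β₀ + β₁·X` with X dummy-coding start port, direction, or target
  port), scored by leave-one-out cross-validated log-likelihood
  `LL = Σᵢ log P(yᵢ | ŷᵢ)` and a label-permutation test; the best variable
  is the smallest permutation p (ties by CV log-likelihood, α = 0.01).
- **Tuning geometry** — vector-sum preferred directions, preferred ports,
  split-half start–target tuning correlations with Fisher-z bootstrap
  inference, start→target encoding switch times, shrinkage per-trajectory
  rate maps, causal half-Gaussian PETHs.
- **Mixed selectivity** — four encoding models of the rate over direction θ
  (relative to preferred) and start position (x, y):
  pure direction `b₀ + b₁N(θ;σ)`, pure position plane `b₀ + b₁x + b₂y`,
  **gain field** `b₀ + (b₁x + b₂y)·N(θ;σ)` (multiplicative), and additive
  `b₀ + b₁x + b₂y + b₃N(θ;σ)`; Poisson MLE, 20-fold CV R², and a
  neuron-bootstrap comparison of Fisher-z CV R² differences.
- **Pseudopopulation decoding** — 2 folds × 32 pseudo-trials per condition
  per neuron (224/fold for positions, 192 for directions), neurons
  bootstrapped (≈63.2% unique per pseudopopulation), z-score → 4 PCs →
  multivariate linear regression to (x, y), 2-fold CV, Euclidean error;
  delta-error time courses and cross-window generalization with an
  extreme-pixel permutation test.
- **Reference-frame RNNs** — 100-unit tanh networks trained by SGD/BPTT on
  pixel renderings of the task under four input/output reference-frame
  contingencies (ego-ego, ego-allo, allo-ego, allo-allo); hidden-unit
  decoding, gain-field unit detection, and RSA (4-PC correlation-distance
  RDMs over the 24 trajectories) against a spiking population.

All stages run on synthetic sessions from `egoallo.simulate`: balanced trial
tables over the task's session designs and inhomogeneous-Poisson neurons
whose start/direction/target/additive/gain-field tuning is known, so
recovery, calibration, and discrimination are directly checkable.

## Worked example

Recover the generative spatial variable of 160 synthetic neurons (40 per
class) with the three-GLM permutation assignment:

```bash
python analysis/02_single_neuron_selectivity.py
```

```
confusion (rows generative, columns assigned):
assigned    direction  none  start  target
generative
direction          38     1      0       1
none                3    36      0       1
start               0     1     39       0
target              1     1      0      38

correct assignment: 95.8% overall, 98.3% excluding false negatives
false-negative rate 2.5%, misclassification 1.7%
```

Most neurons land on their generative variable; the rare errors are mostly
failures to detect any selectivity (weakly tuned neurons), not confusions
between variables — which is what licenses the assignment procedure.

The other drivers follow the same pattern: `01` writes a full synthetic
session to `scratch/session/`, `03` recovers preferred ports/directions and
start–target correlations, `04` separates additive from gain-field mixing
(majority of included neurons best-fit by their generative model), `05`
shows the sequential start → direction → target decoding profile of a
pseudopopulation (errors approach the 11 mm port radius scale at each
variable's best window, against a ~50 mm chance level), and `06` trains the
four RNN classes and ranks them by RDM similarity to a synthetic
sequentially-tuned population (ego-ego wins at the post-cue and go frames).

## Layout

```
src/egoallo/     geometry, simulate, selectivity, tuning, encoding,
                 decoding, rnn, rsa
analysis/        numbered narrative drivers (01–06) writing to results/
tests/           pytest suite incl. oracle and acceptance tests
docs/methods.md  models, assumptions, numerical choices, limitations
```
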