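# Methods

## The model

A go/no-go trial with a compound stimulus is represented as a binary input
vector over a fixed stimulus layout: one input unit per stimulus, value 1
for the two compound members, 0 elsewhere. The network is a fully connected
three-layer perceptron — `n` input units, one hidden layer of `H` logistic
units, one logistic output unit — with bias units on the hidden and output
layers. The forward pass is

    h_j = σ(s · (Σ_i x_i w_ij + b_j)),   y = σ(s · (Σ_j h_j v_j + b_o)),

with σ(z) = 1/(1+e^(−z)) and steepness s (default 1). The output unit is
the response: target 1 for *go* (same-class compound), 0 for *no-go*
(mixed-class compound). A single output unit suffices because go and no-go
are mutually exclusive responses; no two-unit yes/no coding is used.

Training is incremental (online) gradient descent on the squared error
E = ½(y − t)² of each trial, with the classic momentum rule
Δw(t) = −η ∇E + α Δw(t−1). One *epoch* is one pass over the training table
in its printed order; one *iteration* is one single-trial update, so
iterations = epochs × trials per epoch. After every epoch the error readout
over the whole table is evaluated with learning disabled; training stops
when it reaches the threshold. Testing always runs with frozen weights.

An experiment is `n_runs` statistically independent runs ("simulated
participants"), each with fresh uniformly drawn initial weights. A run
*forms classes* when all four transitivity-test activations fall in their
expected bands; it shows the *inverse pattern* when every same-class test
compound classifies no-go **and** every mixed-class compound classifies go.
The two flags are mutually exclusive by construction, and non-convergent
runs count as neither.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `learning_rate` η | 0.3 | step size of each weight update (study condition) |
| `momentum` α | 0.0 | weighting of the previous update; inert at 0 (study condition) |
| `rms_threshold` | 0.0025 | stopping threshold on the error readout (study condition) |
| `criterion_metric` | `mse` | which readout the threshold applies to; see below |
| `init_low`, `init_high` | 0, 1 | uniform weight-initialization range (study condition) |
| `n_hidden` H | 3 | hidden-layer width; see below |
| `steepness` s | 1.0 | sigmoid slope |
| `go_min`, `nogo_max` | 0.85, 0.15 | response bands for scoring test activations (study condition) |
| `n_runs` | 6 | simulated participants per experiment (study condition) |
| `max_epochs` | 100 000 | safety cap; exceeding it flags the run non-convergent instead of raising |
| `shuffle_each_epoch` | off | trial order within an epoch (fixed table order by default) |
| `update_mode` | `incremental` | per-trial updates; `batch` accumulates one update per epoch |
| `use_bias` | on | trainable bias units on hidden and output layers |

Per-run seeds derive as `SeedSequence((base_seed, run_index))`: adding runs
never perturbs earlier ones, and an identical spec reproduces bit-identical
results.

### Stopping-criterion readout

The stopping rule is quoted in the source literature as "RMS ≤ 0.0025", but
the library that tradition used (FANN) reports a *mean squared error*. The
two readings differ enormously in practice: requiring sqrt(MSE) ≤ 0.0025
(MSE ≤ 6.25·10⁻⁶) does not terminate within tens of thousands of epochs at
these hyperparameters, while MSE ≤ 0.0025 (RMS ≈ 0.05) terminates in the
low thousands — the order of magnitude the published epoch counts report.
The default is therefore `criterion_metric="mse"`; the strict
root-mean-square reading remains available as `criterion_metric="rms"`.

### Hidden-layer width

The published architecture diagrams are schematic and never state the
hidden-layer width, yet the emergent-test outcome depends on it strongly:
wide hidden layers (≥ 6 units) memorize the training table without relating
the AC compounds (class formation in well under half of runs), while a
narrow bottleneck forces the shared-class structure into the hidden code.
With H = 3 the simulation reproduces the published pattern — roughly 60 %
of auxiliary-trained runs form classes (published: 4 of 6), and without
auxiliary training formation collapses while wholly inverse response
patterns appear in roughly a third of runs (published: 2 of 6 formed, 3 of
6 inverse). H = 3 is therefore the default, exposed as
`--hidden-units`/`n_hidden`. A FANN-style sigmoid steepness of 0.5 was also
examined and rejected: it multiplies epoch counts several-fold beyond the
published values and drives formation to ceiling.

### Training phases

The auxiliary-class trials (XY, YZ, XZ — including the direct transitivity
relation XZ, trained to guarantee the auxiliary class) are trained *jointly*
with the baseline trials as one eleven-trial table, because the stopping
criterion is defined over all training vectors at once. A
`staged_pretraining` switch trains the auxiliary trials to criterion first
and then the full table, for sensitivity analysis; epoch and iteration
counts then sum over both stages.

## Numerical and scoring choices

* Sigmoid pre-activations are clipped at ±500 before exponentiation; output
  activations are strictly inside (0, 1) in float64.
* Response-band edges are inclusive (activation ≥ 0.85 → go, ≤ 0.15 →
  no-go), so every activation in [0, 1] receives exactly one of the three
  labels; the edge cases have measure zero in practice.
* Mean epochs/iterations are averaged over converged runs only;
  non-convergent runs are reported as a separate count (sentinel −1 in
  per-run tables). An all-non-convergent experiment carries an explicit
  warning state.
* `backprop_step` accepts real targets in [0, 1] (a target equal to the
  current output is an exact fixed point); the built-in tables only ever
  use 0 and 1.
* Backpropagated gradients are audited against central finite differences
  (ε = 10⁻⁶) to a relative tolerance of 10⁻⁵ (`gonogonet gradcheck`).
* Custom stimulus sets are laid out by greedy class interleaving so that no
  two adjacent input units hold same-class stimuli, the arrangement rule the
  built-in layouts follow; impossible class-size profiles raise.
* The between-condition comparison reports the iteration ratio and the
  class-formation rate difference with a two-proportion bootstrap interval,
  rather than asserting a parametric significance test the run counts would
  not support.

## What the simulation does and does not capture

The built-in trial tables, hyperparameters and run counts *are* the study
conditions; there is no other data source, so passing tests show that the
implementation reproduces the behavior of this model class under those
conditions — not that the model describes any particular human data set.
Known limitations, inherent to the design:

* Weights are frozen during testing, so test order and re-testing cannot
  affect outcomes; effects of test structure observed with human
  participants are outside the model.
* Compounds are unordered and stimuli have no spatial representation, so a
  relation and its symmetric counterpart share one input vector and symmetry
  tests are impossible.
* Outcome statistics (formation counts, mean epochs) are sampling outcomes
  over random initializations and, given the under-determined hidden width,
  are comparable to the published values only at order-of-magnitude
  resolution. The acceptance script uses 30 runs per condition to keep the
  Monte-Carlo error of these means small at desk-scale runtimes.
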