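# Methods

## Model

`survnn` fits proportional-hazards models whose prognostic index
(log hazard ratio) is produced by a feed-forward network:

* zero hidden layers: `θ_i = x_iᵀ β` — standard Cox-PH;
* one hidden layer (default): `θ_i = tanh(W x_i + b)ᵀ β`;
* two hidden layers: a second tanh layer of the same width between the
  first layer and the output.

The hidden width defaults to `round(sqrt(J))` for `J` input genes (the
"pyramid" rule; 1000 genes → 32 nodes).  The proportional-hazards
assumption is inherited from the Cox output layer: covariate effects
multiply a common, unspecified baseline hazard and do not vary with time.
Inputs are expected to be normalized, log-transformed expression values;
the package performs no count normalization.

### Objective

Training maximizes the Breslow-tie Cox partial log-likelihood of θ minus a
ridge penalty `λ(‖β‖² + ‖W‖²)` (biases unpenalized).  The inner sum over
risk sets is computed as one matrix product with the risk-set indicator
`R_ij = 1{t_j ≥ t_i}`, stabilized by log-sum-exp: a global shift covers the
common case in one BLAS call, and any row that still underflows (members
~745 log-units below the maximum) is recomputed with per-row
stabilization.  The likelihood value and its analytic gradient are finite
for |θ| up to 700.  Gradients of all parameters are exact back-propagation,
verified against central finite differences (relative tolerance 1e-4) for
every architecture and regularization combination in the test suite.

Risk-set orientation follows the standard Cox convention — the risk set at
patient *i*'s event time is `{j : t_j ≥ t_i}` — the only orientation under
which the matrix form equals the textbook nested-sum partial likelihood
(checked against a brute-force double loop to 1e-10, with ties and
censoring).  Ties are handled by the Breslow approximation throughout;
Efron weighting is out of scope.  An event recorded at time 0 is rejected
(its risk interval is empty); censoring at time 0 is allowed.

### Dropout

`dropout_p` is the probability of *retaining* a hidden node (default 1.0 =
off).  During training, a fresh Bernoulli(p) mask per hidden layer is drawn
each iteration and applied to the layer's activations (nodes, not inputs,
are dropped); gradients treat the mask as fixed.  At evaluation,
activations are scaled by p (the classical weight-scaling rule), making
prediction deterministic.  With p = 1 the train and eval paths are
bit-identical.  Ridge and dropout may be combined.

### Optimization

Full-batch gradient descent, classical momentum, or Nesterov accelerated
gradient (default; momentum coefficient 0.9).  The learning rate starts at
0.1 and is multiplied by 0.9 on every iteration whose cost fails to improve
on the best cost seen so far; iteration count is fixed by the caller
(library default 10,000; the CLI defaults to 2,000).  Runs are deterministic
given the config seed, and a non-finite cost aborts with the iteration
number.

Two preconditioning choices make the schedule robust across data scales.
First, inputs are standardized (per-gene z-score) inside `train` and the
standardization is folded back into the first-layer weights of the returned
model — an exact reparameterization (for the linear model the folded
constant is invisible to the partial likelihood).  Second, the update uses
the gradient divided by the number of events; this rescales the objective
by a constant, leaves the optimum unchanged, and makes the effective step
size independent of cohort size.  The recorded loss trace is the raw
sum-form regularized cost.  On ridge Cox problems the trainer reaches the
same optimum as an off-the-shelf quasi-Newton optimizer run on the
identical objective.

Initialization: hidden weights uniform on ±sqrt(6/(fan_in+fan_out))
(Glorot, appropriate for tanh), biases and β zero, seeded.

## Model selection

`cv_search` runs event-stratified k-fold cross-validation (default k = 5)
over a grid of ridge/dropout settings, scoring each held-out fold by
Harrell's C (chosen over IPCW for speed; validation folds are small and the
two agree closely at moderate censoring).  Folds deal shuffled events and
censored patients round-robin, so every fold contains an event whenever
events ≥ k.  Score ties are broken toward stronger regularization (larger
λ, then smaller p, then lower grid index).  Default grids:
λ ∈ {1e-4, …, 1e2} (decades), p ∈ {0.3, 0.5, 0.7, 0.9, 1.0}.  The final
model is refit on the full training set at the selected setting.  A fold
whose fit aborts is recorded as missing and excluded from that setting's
mean.

## Evaluation metrics

* **Harrell's C** — comparable pair = earlier time is an event and times
  differ; concordant if the earlier-event patient has the higher θ; ties in
  θ count 0.5.  Pairs with a censored earlier time, and tied-time pairs,
  are not comparable.
* **IPCW C** — same pairs and scores, weighted `1/Ĝ(t_i−)²` with Ĝ the
  Kaplan–Meier estimator of the *censoring* survival (left limit at the
  earlier event time).  No truncation time is applied.  Pairs with Ĝ = 0
  are excluded with a warning.  With no censoring, equals Harrell's C
  exactly; both metrics map C → 1−C under score negation.  Values agree to
  machine precision with scikit-survival's implementations on tie-free data.
* **Log-rank p** — patients are dichotomized at the median θ (exact median
  → low-risk group); the two-sample log-rank test comes from lifelines.
* **Integrated Brier score** — predicted survival
  `S_i(t) = exp(−Ĥ0(t) e^{θ_i})` uses the Breslow baseline cumulative
  hazard from the training set (with θ = 0 this estimator reduces to
  Nelson–Aalen); the IPCW Brier score
  `BS(t) = mean[ S² 1{died by t}/Ĝ(t−) + (1−S)² 1{alive at t}/Ĝ(t) ]`
  is integrated by the trapezoid rule on the grid {0} ∪ event times ∪
  {t_max} and divided by t_max.  Step functions are right-continuous.
  Censoring weights come from the training-set Ĝ in the holdout harness.

`repeated_holdout` runs the full protocol: random 80/20 split (both parts
must contain an event; redrawn up to 100 times), CV selection on the
training part, refit, all four metrics on the held-out part; per-repeat
seeds derive deterministically from the master seed.

## Interpretation

Gene importance is the partial derivative of θ with respect to each input,
averaged over patients, computed through the deterministic eval-mode
network (`Σ_h β_h · p · (1 − tanh²) · W_hj` for one hidden layer); for the
linear model it equals β exactly, anchoring the scores to the classical
Cox interpretation.  Node-level derivatives (∂a_h/∂x_j averaged) are also
exposed.  A node's contribution to a patient is activation × β_h; the
contributions sum column-wise to θ at machine precision, so nodes form an
exact additive decomposition of the prognostic index.  Nodes can be ranked
by across-patient variance (ties → lower index), and node–gene Pearson
correlations are exportable as descending two-column ranked lists, the
pre-ranked input format of enrichment tools.  Zero-variance genes yield
missing correlations and are dropped from exports.

## Simulator

`simulate_dataset` emulates a grouped cohort: 4 groups × 200 patients,
1000 genes (defaults).  Gene baseline means are log-normal (log-mean 3.0,
log-sd 1.0, i.e. typical counts in the tens); counts are negative-binomial
via a gamma–Poisson mixture with dispersion 0.2 (variance μ + 0.2 μ²;
dispersion 0 degenerates to Poisson); per group, a random 20% of genes have
their means shifted by a fold change uniform in ±[0.5, 2] on the log2
scale.  Model input is log2(count + 1).

Survival: the true prognostic index is a centered linear combination of
100 randomly chosen signal genes' log expression, with raw coefficients
uniform on ±[0.1, 0.5], standardized so the index has standard deviation
`pi_sd` (default 2.0).  Event times invert the Weibull proportional-hazards
survival function (shape 1.5; scale calibrated so the median event time at
zero index is 10 time units); censoring times are exponential with rate
0.05, independent of everything else.  Observed time is the minimum and
the event indicator marks whether the event came first.

The default `pi_sd = 2.0` is calibrated so the *true* index achieves a
Harrell C of roughly 0.84 (verified in the test suite) — a strong, clearly
detectable signal.  Even so, the signal is spread thinly over 100 genes
among 1000, so fitted models at n = 800 recover only part of that ceiling;
the repeated-holdout benchmark in the acceptance tests measures exactly
this gap.  What the simulator does *not* emulate: gene–gene correlation and
co-regulation structure, batch effects, library-size variation, and
covariate-dependent (informative) censoring.  Tests passing on simulated
data therefore demonstrate correctness of the algorithms and calibration of
the metrics, not expected performance on real tumor cohorts, where
correlated gene modules typically make prediction easier for a given
signal strength and violated assumptions make it harder.

## Problem sizes used in the checks

Likelihood-equivalence and gradient checks run on instances of n ≤ 12 and
toy networks (6 patients, 4 genes, up to 2×3 hidden nodes).  Coefficient
recovery uses a single-group linear-hazard cohort of n = 800 with 30 genes.
Metric calibration uses 500 datasets of n = 100; the log-rank null uses 500
datasets of n = 60.  The repeated-holdout benchmark runs the full default
cohort (800 × 1000) for 10 repeats with 5-fold CV over a two-point λ grid
at 250 training iterations per fit.  The acceptance script regenerates its
quantities from scratch at 500 × 100 and 100,000 draws respectively.

## Known limitations

Time-varying covariates, stratified baselines, Efron tie handling,
competing risks and GPU execution are out of scope.  Dropout retention is
constrained to (0, 1].  The CV metric is Harrell's C only.  Feature
importance assumes a fitted single- or zero-hidden-layer model for the
node-level matrix (output-level importance works for two layers as well).
Very heavy censoring can zero out IPCW weights near the end of follow-up;
affected pairs are excluded with a warning rather than extrapolated.
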