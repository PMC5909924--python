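# survnn

Neural-network proportional-hazards survival modelling for high-dimensional
gene-expression data.

## What problem this solves

Predicting patient prognosis from transcriptomic profiles is usually framed
as Cox proportional-hazards (Cox-PH) regression: each patient's hazard is
`h(t | x_i) = h0(t) exp(θ_i)`, where the prognostic index (log hazard
ratio) is linear in the covariates, `θ_i = x_iᵀβ`. With tens of thousands
of genes, a purely linear index can miss interactions and nonlinear
structure. `survnn` replaces the linear predictor with a small feed-forward
network whose *output layer is itself a Cox regression*:

```
θ_i = G(W x_i + b)ᵀ β,        G = tanh
```

and trains all parameters jointly by maximizing the regularized Cox partial
log-likelihood

```
pl(θ) = Σ_{i: event_i=1} [ θ_i − log Σ_{j: t_j ≥ t_i} exp(θ_j) ]
Cost  = −pl(θ) + λ (‖β‖² + ‖W‖²)
```

with optional dropout on the hidden nodes.  The inner conditional sum is
evaluated as a single matrix product with the risk-set indicator matrix
`R_ij = 1{t_j ≥ t_i}` (log-sum-exp stabilized), which makes full-batch
gradient training fast; ties share one denominator (Breslow convention).
With zero hidden layers the model degenerates exactly to ridge Cox-PH.

The package is aimed at biostatisticians and computational biologists who
want, in one place:

* the model and trainer (plain/momentum/Nesterov full-batch gradient
  descent with a decay-on-plateau learning-rate schedule),
* 5-fold cross-validated selection of the ridge penalty λ or dropout
  retention probability p,
* censoring-aware accuracy metrics — Harrell's C, IPCW-weighted C,
  median-split log-rank p, and the IPCW integrated Brier score via the
  Breslow baseline hazard,
* interpretation tools — average-partial-derivative gene importance, the
  exact additive decomposition of θ into hidden-node contributions
  (activation × output coefficient), and node–gene Pearson correlations
  exportable as pre-ranked lists for enrichment tools,
* a synthetic RNA-seq survival simulator (grouped negative-binomial
  expression, Weibull proportional-hazards event times, exponential
  censoring) with full ground truth for power and calibration studies.

## Worked example

Simulate a 200-patient, 200-gene cohort with 40 signal genes, fit a
one-hidden-layer model, and score it:

```
$ survnn simulate --out sim --groups 4 --patients-per-group 50 \
      --genes 200 --signal-genes 40 --seed 7
wrote 200 patients x 200 genes (123 events) to sim

$ survnn train sim/expression.tsv sim/survival.tsv \
      --out-model model.json --out-pi pi.tsv --ridge 10 --iterations 400 --seed 1
final training partial log-likelihood: -459.2792
model written to model.json

$ survnn evaluate model.json sim/expression.tsv sim/survival.tsv
 c_harrell   c_ipcw    logrank_p  integrated_brier  n_test  n_events_test
  0.884793 0.858358 1.671916e-40          0.077118     200            123
```

Read the numbers as follows: `c_harrell` 0.88 means 88% of comparable
patient pairs are ranked correctly by the fitted prognostic index (0.5 is
chance); `c_ipcw` is the same quantity reweighted to remove censoring bias;
the log-rank p-value tests the survival-curve separation after splitting
patients at the median index; the integrated Brier score (lower is better;
0.25 equals a coin-flip survival probability) is the time-averaged squared
error of the predicted survival curves.  These are training-set numbers —
use `survnn benchmark` for repeated 80/20 holdout estimates with CV-based
hyperparameter selection, and `survnn importance` for the gene- and
node-level interpretation tables.

The same functionality is available as a library (`survnn.train`,
`survnn.cv_search`, `survnn.repeated_holdout`, `survnn.feature_importance`,
`survnn.simulate_dataset`, ...); see `docs/methods.md` for the underlying
models and all numerical conventions.

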