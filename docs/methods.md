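# Methods

This note documents the models implemented in `rxngp`, the choices made
where the methods leave details open, what the synthetic task suite does
and does not emulate, and the numerical conventions used throughout.

## Problem setting

The package targets few-shot prediction of reaction outcomes, with
transition-metal-catalysed asymmetric hydrogenation of olefins (AHO) as
the motivating chemistry.  Enantioselectivity is treated as a binary
classification problem: a reaction is "highly selective" when its %ee
strictly exceeds a threshold (default 80; 85 and 90 supported).  Ties at
the threshold go to the low class so the rule is unambiguous.

Rather than fitting one model to one large table, the data are carved
into *tasks*.  A meta-learner is trained across many related tasks so
that, given a new task and a handful of labelled reactions (the support
set S), it predicts the remaining reactions (the query set Q).  Test
performance is the area under the precision–recall curve (AUPRC), which
is sensitive to the ~65/35 class imbalance; an uninformative scorer
attains the positive prevalence.

## Featurization

Each reaction is a fixed 1544-dimensional vector:

| block | width |
|---|---|
| olefin Morgan fingerprint (radius 2) | 512 |
| ligand Morgan fingerprint | 512 |
| solvent Morgan fingerprint | 512 |
| metal one-hot (Ir, Rh, Ru) | 3 |
| additive present/absent one-hot | 2 |
| temperature (°C), pressure (bar), catalyst loading (mol%) | 3 |

The 3+2 decomposition of the eight non-fingerprint slots is our
reconstruction: only the total dimension is fixed by the representation.
Unknown metals are rejected rather than bucketed.  SMILES are
canonicalised (parsed to molecules) before fingerprinting, so spelling
variants map to identical features.  The three condition scalars are
z-standardised with statistics fit on training data only; raw bar/°C
magnitudes would otherwise dominate binary fingerprint bits in any
distance-based kernel.  Substrate clustering uses the 166-bit MACCS
structural keys (RDKit's unused bit 0 dropped).

## Deep kernel Gaussian processes

All Bayesian models share a deep kernel
`k(x, x') = k'(f(x; θ_NN), f(x'; θ_NN); θ_GP)` with a feed-forward
extractor `f` (default two tanh hidden layers 256→128, latent dimension
64) and an RBF base kernel (Matérn-5/2 available) with scalar
lengthscale, outputscale, and noise variance, all optimised in
log-space.  Classification is GP *label regression* on targets {−1, +1}
under a Gaussian likelihood: this keeps the marginal likelihood and the
joint predictive density in closed form, which the meta-learning
objectives require.  Class probabilities use the moderated link
`p = σ(μ / sqrt(1 + v))` on the predictive mean μ and variance v —
monotone in μ, shrunk toward 1/2 by uncertainty.

Numerics: every solve is Cholesky-based; the log-determinant comes from
the Cholesky diagonal.  If a factorisation fails, diagonal jitter
`1e-6 × outputscale` is added and escalated tenfold at most three times
before a conditioning error is raised.  Gradients of the marginal
likelihood with respect to both the kernel hyperparameters and the
latent embeddings are analytic; the extractor is trained by
backpropagating the embedding gradient through the network.  The whole
stack is NumPy/SciPy; there is no autodiff framework behind it, and the
gradient code is verified against finite differences and dense
linear-algebra oracles in the test suite.

## The five models

* **DKL** (single-task baseline): (θ_NN, θ_GP) minimise the NLML on one
  training set jointly (Adam; mini-batches of 256 when the set is
  large).  With an identity extractor this reduces to an exact GP whose
  three hyperparameters are fit with L-BFGS.
* **DKT**: one shared (θ_NN, θ_GP) minimises the expected NLML over
  episodes sampled from batches of five training tasks.  No parameters
  adapt at test time; the GP is conditioned on the support set.
* **ADKF**: bilevel.  Inner loop: θ_GP minimises the support NLML by
  backtracking gradient descent from a fixed initialisation
  (lengthscale 1, outputscale 1, noise 0.1) — θ_GP is purely
  task-specific, as in the original adaptive deep kernel fitting
  scheme.  Outer loop: θ_NN minimises the mean negative log joint
  predictive posterior of the query given the support.  Outer gradients
  are first-order (the inner solution is treated as a constant); an
  implicit-function-theorem correction was considered and deliberately
  left out — at the adaptation budgets used here the first-order
  estimator is cheaper and, in our experiments, indistinguishable.
* **ADKF-prior**: places a Gaussian prior N(φ, σ²I) over θ_NN.  Inner
  loop: [θ_GP, θ_NN] minimise the support NLML plus the MAP penalty
  ‖θ_NN − φ‖²/(2σ²), with θ_NN initialised at φ and θ_GP at its
  *meta-learned* initialisation.  Outer loop: the meta-parameters are
  [φ, θ_GP-init, log σ²].  φ receives the first-order gradient of the
  query loss evaluated at the adapted weights.  The θ_GP initialisation
  is consolidated toward the centroid of the task-adapted optima
  (a Reptile-style update, i.e. the gradient of ½‖h₀ − h*‖²): a
  plain first-order gradient here is unreliable because the inner loop
  partially converges, making the identity Jacobian assumption wrong,
  and in development it drove the initialisation into overconfident
  corners.  log σ² receives the proximal estimate g·(θ_NN* − φ), the
  directional effect of allowing larger deviations from the prior mean.
  σ² starts at 1e-3 per weight — the prior is meant to permit only
  small task-specific deviations, and a loose prior lets the inner loop
  overfit the support set badly enough to corrupt the outer gradients.
* **Protonet**: metric baseline.  Episodic training of the extractor by
  cross-entropy of a softmax over negative squared Euclidean distances
  from query embeddings to class prototypes (support class means).

The inner loop everywhere is block gradient descent with backtracking
(default 50 iterations, one θ_GP step and, for ADKF-prior, one θ_NN
step per iteration; steps that fail to decrease the objective are
rejected, and the loop stops early when an iteration improves the loss
by <1e-5).  Rejected steps make the inner loss non-increasing by
construction.  This design also gives an exact degenerate limit:
σ² → 0 pins θ_NN at φ (every weight step is rejected), so ADKF-prior
collapses onto ADKF's adaptation path — a property the tests check.

## Task construction

* **Random splits**: an 80:20 train/test partition; 10% of the training
  pool is held out as validation tasks; each pool is shuffled and cut
  into near-equal tasks of the requested size, so tasks are disjoint
  and cover their pool.
* **Substrate-based splits**: unique substrates (deduplicated feature
  rows) are embedded from MACCS keys to 2-D with UMAP and clustered
  with k-means (default six clusters); reactions inherit their
  substrate's cluster.  Leave-one-cluster-out: each cluster serves as
  the test task exactly once, the remaining clusters form the training
  tasks, so test substrates never appear in training.  UMAP neighbour
  count and minimum distance keep their library defaults and are
  recorded; exact reproduction of any particular clustering is not a
  goal (the embedding is stochastic; we fix its seed).
* **Time-based splits**: train on reactions published up to a cutoff
  (default 2020), test on a later window (default 2023+); rows in the
  gap are excluded and counted.

Episode sampling is without replacement, support and query disjoint,
and stratified by default so the support always contains both classes
(adaptation and prototypes are degenerate otherwise; the flag can be
turned off).  Every sampler, partitioner, and trainer is deterministic
given its seed.

## Evaluation

AUPRC is computed in average-precision form with tied-block handling:
examples are walked in decreasing-score order and each tied-score block
contributes its positives at the precision measured at the block end.
This makes the metric invariant under strictly monotone transforms of
the scores and gives a constant scorer exactly the positive prevalence.
Tie handling is pinned down deliberately — it changes third-decimal
results.  Aggregation reports the mean over support/query resamplings
with the sample standard deviation (random splits) or the standard
error (substrate and time-based splits), matching the reporting
conventions of the protocols; aggregated tables render at 4 decimals.

## Synthetic task suite

The AHO literature dataset is license-restricted and not bundled, so
the package ships a generator that emulates its statistical shape:
sparse binary fingerprint-like features (Bernoulli bits, on-rate 0.1)
plus three Gaussian "condition" columns; tasks that share a global
latent direction with task-specific perturbations
(v_t = v + shift·ε_t through a common random projection); labels drawn
from a logistic squashing of the latent score whose intercept is solved
by bisection so the expected positive fraction equals the target
prevalence (default 0.65, matching the high/low enantioselectivity
imbalance).  The noise scale is the logistic temperature relative to
the latent score's standard deviation; at zero the labels become a hard
threshold and a linear oracle separates them perfectly.  On top of the
base temperature, each task carries a log-normal noise multiplier
(`noise_heterogeneity`, default sd 0.5): tasks differ not only in their
latent direction but in how reliable their labels are.  Without this,
the per-task optimal GP hyperparameters coincide across tasks — the
shared-kernel assumption behind DKT would hold exactly and the suite
could not distinguish adaptive from shared-kernel methods; literature
data subsets likewise differ in label reliability.

What the generator does *not* emulate: real chemistry.  There is no
substructure correlation between fingerprint bits, no olefin/ligand
co-occurrence sparsity, and no covariate shift between tasks beyond the
latent-direction perturbation.  Passing benchmarks on this suite shows
that the meta-learners exploit shared task structure and adapt from
small supports under class imbalance — not that any particular AUPRC
level would be attained on literature data.  A separate GP-generative
option draws regression data from a known-hyperparameter GP for
recovery experiments.

## Benchmark scale and study conditions

The self-contained benchmark (`rxngp.experiments.few_shot_benchmark`)
runs on one CPU, so it uses a reduced scale, fixed once: 32 binary
feature columns + 3 condition columns, latent dimension 8, ten tasks
of 256 reactions (six train, one validation, three test), task shift
1.5 (tasks related but substantially distinct — the regime where
few-shot adaptation, rather than pure transfer, carries the signal),
label-noise temperature 0.5 with per-task heterogeneity 0.5,
prevalence 0.65.  Models use a (32, 16)→8 extractor, meta-training
episodes of 64 support / 32 query in batches of five tasks, 60 outer
iterations, and 15-step inner adaptation.  Meta-testing follows the
protocol: support sizes {8, 16, 32, 64, 128} with query 128, episodes
resampled on each of the three test tasks (averaging over test tasks
suppresses single-task idiosyncrasy), plus support 5 with more repeats
for the low-data comparison of ADKF-prior against ADKF.  At full scale
the defaults revert to the protocol constants (support 512 / query 64
episodes, 1544-dimensional inputs, 256→128→64 extractor, 50 inner
steps).

## Known limitations

* The classification likelihood is Gaussian label regression, not a
  Bernoulli likelihood with latent GP; this is what makes the
  meta-learning objectives closed-form, but calibrated probabilities
  are not a design goal — ranking (AUPRC) is.
* First-order outer gradients bias the bilevel optimisation; the
  Reptile-style consolidation for the θ_GP initialisation trades
  asymptotic fidelity for robustness.
* The NumPy extractor is practical for the reduced-scale benchmark and
  for datasets in the tens of thousands of rows, but it is not a GPU
  training stack.
* Single-class supports are accepted for the GP models (regression on a
  constant target) with a warning; prototypes require both classes.
* At very small supports (~5 examples) ADKF-prior's behaviour largely
  coincides with ADKF's under first-order training: the MAP
  displacement of the extractor is bounded by
  ‖δ‖ ≤ sqrt(2·ΔNLML·σ²), which for a support NLML improving by a
  fraction of a nat and a stability-compatible σ² is too small to
  change the query ranking; its remaining distinguishing ingredient is
  the meta-learned θ_GP initialisation.  A consistent low-data
  advantage of ADKF-prior over ADKF therefore does not emerge at the
  reduced benchmark scale — the benchmark reports the paired
  comparison rather than assuming it.
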