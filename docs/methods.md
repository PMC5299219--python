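# Methods

## Problem setting

`wolfsel` performs *wrapper* feature selection for binary classification of
tabular clinical data: candidate feature subsets are scored by actually
training and evaluating a classifier on them, and a population metaheuristic
searches the 2^N − 1 possible subsets.  The package implements three search
modes — a genetic algorithm (GA), grey wolf optimization (GWO), and the
GA-seeded "improved" variant (IGWO) — all scored by a kernel extreme
learning machine (KELM), together with the repeated cross-validation harness
used to compare them.

## The KELM classifier

A KELM is a single-hidden-layer network trained in closed form.  With RBF
kernel

    K(x, y) = exp(−‖x − y‖² / (2γ²))

and Gram matrix Ω over the m training samples, the output weights solve the
regularized system (Ω + I/C) w = t, with t the ±1 class targets.  Decision
values for new points are K(X_new, X_train) w and the predicted class is
their sign; a value of exactly 0 is resolved to the positive class.

Numerical choices:

* Ω is positive semi-definite, so Ω + I/C is symmetric positive definite for
  any finite C > 0; the system is solved by Cholesky factorization, never an
  explicit inverse, and training asserts a residual below 1e−8.
* Targets are a single ±1 column rather than a two-column one-hot block; for
  binary problems the two encodings are affinely equivalent and the single
  column halves the solve.
* Defaults C = 32 and γ = 0.5 are the values an 11×11 grid over
  {2⁻⁵ … 2⁵} selects on the clinical voice / breast-mass benchmarks this
  tool targets.  Note the 2γ² denominator: grids for the common
  exp(−γ‖·‖²) convention do not transfer.

## Grey wolf optimization

The three best solutions found so far (alpha, beta, delta) guide every other
wolf.  Per leader L: A = 2a·r1 − a, C = 2·r2 (component-wise, r1, r2 ~
U[0,1)), D = |C∘X_L − X|, candidate X_L′ = X_L − A∘D; the new position is
the mean of the three candidates, clipped to the box domain.  The
exploration coefficient a decays linearly from 2 to 0; inside a T-iteration
run it is evaluated at t = 0 … T−1, so the first update explores at a = 2.

Determinism contract: one `numpy.random.Generator` drives a run; each wolf
update consumes, for alpha then beta then delta, one r1 vector then one r2
vector.  Fixing this order makes trajectories bit-reproducible and lets the
test suite replay the exact stream through an independent transcription of
the update equations.

Leaders are *best-so-far*: they persist across iterations and are displaced
only by strictly better fitness, so equal-fitness newcomers never churn the
hierarchy and the best-so-far curve is monotone by construction.

## Binary encoding of subset search

A wolf's position lives in [0,1]^N continuously; it is *binarized only at
fitness evaluation*: bit i = 1 iff position_i ≥ 0.5 (a stochastic sigmoid
transfer is available as an option).  An all-zero result is repaired by
switching on the largest component, because the fitness is undefined on an
empty subset.  Keeping the internal state continuous preserves the hunting
dynamics; pure-binary arithmetic would make A∘D meaningless.

The subset fitness is the scalarization

    fitness = α·P + (1 − α)·(N − L)/N,      α = 0.99 by default,

with P ∈ [0,1] the classification accuracy on the flagged columns, L the
subset size and N the feature count.  Accuracy dominates; the size term
breaks ties toward smaller subsets.  P is estimated by default with an inner
stratified 10-fold CV of the KELM, *pooled* (total correct / n) over the
folds — identical to the per-fold mean when fold sizes are equal, and the
convention the exhaustive-enumeration test oracle shares.  Resubstitution
("train") and single-holdout estimates are selectable.  The inner folds are
drawn once per run from a seed independent of the optimizer stream, so every
subset within a run is scored on identical splits and the landscape the
optimizer sees is a deterministic function.

## GA seeding and the IGWO decode

The IGWO variant diversifies the initial population with one genetic pass:
random binary chromosomes → roulette (fitness-proportional) selection →
single-point crossover (probability 0.8) → uniform mutation (probability
0.01 per gene) → decode.  One generation is the default; more are supported
(with single-chromosome elitism), as the right iteration count is genuinely
open.  All-zero chromosomes are repaired by switching on one uniform gene.

Decode: each gene is embedded as a continuous position sampled uniformly
from its half-interval — gene 1 → U[0.5, 1), gene 0 → U[0, 0.5).  This
binarizes back to exactly the seeded subset, and (for fair-coin genes) makes
the initial positions marginally U[0,1], i.e. the IGWO start differs from
the GWO start only by the pattern information the GA contributes.  The
obvious alternative — placing wolves at the exact 0/1 vertices — is
degenerate: a component at exactly 0 shared by a wolf and all three leaders
has D = 0 under every draw and freezes for the entire run, which measurably
makes the seeded search explore *less* than a uniform start.  GA fitness
evaluations during seeding do not count against the GWO iteration budget.

## Evaluation protocol

The harness is stratified k-fold CV (k = 10) repeated 10 times; reports give
mean ± sd over repeats for accuracy, sensitivity, specificity, precision,
G-mean = √(sens·spec) and F-measure ((β²+1)·prec·sens / (β²·prec + sens),
β = 1), plus the subset size, as percentages to two decimals.  A metric with
a zero denominator is reported as 0 and flagged — the same convention as
scoring F = 0 when every positive is misclassified — so aggregation stays
total.

Ambiguities in this benchmark tradition are explicit flags, with these
defaults:

* **Selection scope** — the wrapper runs once per repeat on the whole
  dataset, and the chosen subset is scored on that repeat's k test folds
  (one subset size per repeat, as the benchmark tables report).  This
  protocol leaks selection information into the test folds; a leakage-safe
  `selection_scope="fold"` mode re-runs selection per training fold at 10×
  the cost.  Reported accuracies under the default should be read as the
  benchmark's quantity, not as an unbiased generalization estimate.
* **Normalization** — min–max scaling of every feature into [−1, 1],
  computed globally before splitting (per-fold fitting available).  Constant
  columns map to 0.
* **Averaging** — confusion counts are pooled (micro-averaged) over the k
  test folds of a repeat; macro-averaging is a flag.
* **sd** — across the 10 repeats, not across all 100 folds.
* **Inner folds across repeats** — each repeat draws fresh inner-CV folds
  (fixed within the repeat).  Run-to-run variation in which features are
  selected — the substance of the frequency tables — comes from re-drawn
  partitions; with one frozen landscape every repeat would return the same
  subset.

The stratified allocator satisfies two constraints simultaneously: total
fold sizes differ by ≤ 1 and each class's per-fold count is within 1 of its
proportional share (e.g. 195 samples split 147/48 yield folds of 19–20 with
14–15 positives).  Allocating each class independently can violate the first
constraint, which is why the splitter is implemented here and cross-checked
against scikit-learn only where the conventions agree.

## Synthetic data

The generator emulates the structure of the clinical tables this method is
used on: `n_informative` features are class-conditional Gaussians with means
±separation/2 and unit variance; `n_redundant` features are random linear
combinations of the informative block plus N(0, 0.1²) noise; `n_noise`
features are standard normal and class-independent.  Defaults — 100 samples,
5 informative at separation 2, 15 noise, balanced classes — are the
benchmark conditions used throughout the tests.

What passing tests on this generator do **not** show: real clinical tables
have correlated noise, heavy-tailed and bounded measurements, and
informative features of very unequal strength; recovery rates here are an
upper bound on what identical settings achieve on such data.  At separation
2 the classes are separable enough that KELM reaches perfect inner-CV
accuracy on several 2–3-feature subsets, so the size penalty actively
suppresses *surplus* informative features — high frequency for every
informative feature should only be expected across repeats with re-drawn
folds, not within one frozen landscape.

## Problem sizes in the distributed checks

The test suite and the acceptance script run entirely on generated data at
the package's standard study conditions: the comparison study uses the
default generator with 10×10-fold CV, pop 8, 100 iterations; the
exhaustive-oracle check enumerates all 255 subsets of an 8-feature problem
(60 samples, 3 informative); the continuous-search benchmark maximizes
−Σx² in [−1,1]¹⁰ with pop 8 over 500 iterations.

## Known limitations

* Binary classification only; no missing-value handling (missing cells are
  an error by design, the target tables are complete).
* The scalarized fitness gives one point on the accuracy/size trade-off; no
  Pareto treatment.
* No significance testing between methods; the harness reports mean ± sd
  and per-repeat tables that downstream tools can test or plot.
* Subset-size and frequency results depend on the inner-evaluation design
  (see above); the flags make the choices explicit rather than resolving
  them.
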