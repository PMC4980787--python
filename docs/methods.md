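# Methods

## Problem and model

Gene selection from labeled expression matrices is a wrapper
feature-selection problem: find a small binary mask over genes whose
selected columns let a classifier separate the diagnostic classes.
`mabc` implements a bee-colony metaheuristic with two additions to the
basic algorithm — per-gene pheromone trails and a bee-to-bee
communication operator — plus optional local search inside the employed
and onlooker phases. Both additions can be disabled
(`ablation='basic_abc'`), which reduces the loop to the basic bee colony
with local search and is the baseline used in the benchmark comparison.

The fitness of a mask is

    fitness(X) = w1 * accuracy(X) + (1 - w1) * (n - ns) / n

with LOOCV-SVM accuracy as a *fraction* in [0, 1], so fitness itself lives
in [0, 1]; reports convert accuracy to percent. Keeping one scale inside
the optimizer pins the tradeoff: at w1 = 0.85, a one-gene reduction in a
32-gene space is worth 0.15/32 ≈ 0.5 % accuracy.

## Statistical prefilter

* Kruskal–Wallis: mid-rank ties, the standard tie-correction divisor
  1 − Σ(t³−t)/(N³−N), and chi-square tail probabilities with C−1 degrees
  of freedom (computed by the regularized incomplete gamma function via
  `scipy.stats.chi2.sf`). A fully constant gene is assigned K = 0, p = 1
  rather than the undefined 0/0. Equivalence with `scipy.stats.kruskal`
  is enforced to 1e-9 in the tests; the in-package implementation exists
  because the statistic, its tie handling and the ranking policy are part
  of the method's contract, with scipy serving as the independent oracle.
* F-score: population-SD convention, so the denominator Σ n_k σ_k² is the
  pooled within-class sum of squared deviations. Zero denominator with
  distinct class means gives +inf (ranked first); equal class means give 0.
* Pre-selection keeps `floor(th_n * n)` genes (minimum one); the rounding
  rule is a package decision, pinned by tests. Threshold mode keeps genes
  with p ≤ value so a threshold of 1.0 keeps every gene.
* Ties in p-value or score break by original gene index, making rankings
  deterministic.

## Swarm mechanics and conventions

* **Initialization / scouts** (`init_random`): gene d is selected with
  probability `alpha * sigmoid(p_d)`. `alpha` defaults to 0.05, chosen so
  that with the initial uniform pheromone (p_d = tmax = 5,
  sigmoid ≈ 0.993) the expected initial subset is ~5 % of the
  post-prefilter genes — sparse starts suit the drop-only neighborhood
  move. An all-zero draw is repaired with one pheromone-proportional gene.
* **Neighborhood**: drops `k = max(1, round(nd * ns))` selected genes,
  rounding half up (the worked example with nd = 0.3, ns = 10 → 3 does not
  distinguish round/floor/ceil; the tests pin round). Dropping the last
  gene leaves an empty mask; the phase repairs it with one
  pheromone-proportional gene before any evaluation, so the evaluator can
  treat an empty mask as a hard error that surfaces operator bugs.
* **Greedy selection** keeps the incumbent on fitness ties (avoids churn).
* **Trial counters** increment on every candidate evaluation that fails to
  improve the bee's personal best and reset on strict improvement — the
  standard bee-colony convention, and the only reading under which the
  default `limit = 35` is reachable within `MAX_ITER = 20`. Several bees
  may scout in the same iteration.
* **Communication** replaces the bee's position outright (it is a
  knowledge transfer, not a candidate subject to greedy selection); the
  personal/global bests still only update on improvement.
* **Deposition** happens after the employed phase and again after the
  onlooker phase, each bee depositing with the stage-end masks and bests;
  evaporation runs once per iteration, at the end.
* **Inertia**: the decaying rule is implemented exactly as printed in its
  source, `w ← (w−0.4)(MAX_ITER−iter)/(MAX_ITER+0.4)`, which reaches 0 at
  the final iteration; since the printed denominator is a plausible typo,
  `eq5_corrected=True` switches to `(w−0.4)(MAX_ITER−iter)/MAX_ITER+0.4`.
  The default rule is the randomized one (`wt='eq6'`, w uniform in
  [0.5, 1]); the tuned tables do not name which rule they used.
* **Local search**: SA starts at temperature 1.0 (in fitness units; the
  published schedule factor 0.5 is retained, but no starting temperature
  was given) and skips the acceptance draw when the acceptance
  probability underflows to zero, so the cold-temperature trajectory
  coincides exactly with hill climbing on a shared seed. SAHCR replaces
  the current solution with the best of its `n_tweaks` tweaks even when
  worse, tracking the global best separately. Local search is applied to
  the neighbor produced in the bee phase, not to the bee's stored
  position.
* All randomness flows from one `numpy.random.default_rng(seed)` per run;
  the seed is recorded in the result.

## LOOCV evaluation

LOOCV of an SVM with C = 2000 dominates the runtime, so the evaluator:

* memoizes (accuracy, fitness) by exact mask bit-pattern — identical masks
  recur heavily in swarm search, and evaluation is a pure function of the
  mask, so a cache may also be shared across runs on the same dataset;
* uses scikit-learn's bundled libsvm bindings directly, with an exact
  shortcut: a fold whose held-out sample is not a support vector of the
  full-data fit cannot change the solution (removing an inactive
  constraint), and a non-support sample is on the correct side of every
  pairwise decision function, so its one-versus-one vote is correct — only
  support-vector folds are refitted. For the binary linear kernel the
  decision value is reconstructed from the dual solution (dec > 0 predicts
  the numerically smaller class label, verified against `libsvm` predict);
  multiclass and RBF paths call the library's predict. A portable
  `backend='svc'` runs a plain fold loop through `sklearn.svm.SVC`; tests
  assert both backends agree.
* caps libsvm at `svm_max_iter = 2000` iterations per fit. With C = 2000,
  subsets that do not separate the classes can take >10^5 solver
  iterations; informative subsets converge in a few hundred. Benchmark
  outcomes were identical across caps of 500–10000 and the uncapped
  solver on the separable fixtures; set -1 for the uncapped solver.
* holds out a sample whose class would vanish from the training fold by
  scoring that fold incorrect (the fold cannot predict an absent class).
* uses no class weighting (imbalance handling is out of scope).

## Synthetic benchmark

`SyntheticSpec` defaults define the study conditions used throughout the
tests and the acceptance script: 60 samples × 500 genes, 5 informative
genes, two balanced classes, unit noise SD, class means of informative
genes spaced 4 SD apart. The class count and noise scale are package
choices (a binary diagnosis is the simplest realistic case; the effect
size is quoted in SD units so the noise scale is a free unit). Planted
gene positions are drawn uniformly per seed; run k of an experiment uses
seed `base + k`.

The generator emulates only the feature that makes selection well-posed —
mean-shifted informative genes in Gaussian noise. It does not model
heavy-tailed microarray noise, probe saturation, correlated gene blocks,
or batch effects, so passing benchmarks demonstrate that the search
recovers planted signal under ideal noise, not performance on real
platform data. Real datasets in the distributed `.mat`/CSV layout can be
run unchanged through `mabc select`.

## Problem sizes in the shipped checks

The repeated-run checks use 15 seeded runs per arm on the 60 × 500
benchmark (the tuned preset keeps 32 genes after the 6.5 % prefilter) and
5 runs on a 60 × 200 variant for the invariant sweep; these sizes keep
the full suite comfortably re-runnable on a laptop while leaving the
study conditions (preset values, iteration counts, effect sizes)
untouched.

## Known limitations

* The communication operator assumes a meaningful bee ordering (bee i
  learns from bee i−1); the ordering is the population index, as in the
  original formulation.
* Fitness caching makes memory grow with the number of distinct masks
  evaluated (bytes per mask ≈ post-prefilter gene count); for the shipped
  benchmarks this is a few MB.
* With `wt='eq5'` the inertia becomes 0 at the final iteration, so the
  last deposition retains no memory of the previous field; this is the
  printed behavior, not a bug.
* The search is stochastic; single runs can miss planted genes. All
  shipped comparisons aggregate ≥ 15 seeded runs.
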