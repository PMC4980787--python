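"""Pheromone-guided artificial bee colony search over gene masks.

Each bee holds a candidate gene subset (a binary mask, its "food source").
Every iteration runs three phases — employed, onlooker, scout — after which
the per-gene pheromone field evaporates and the inertia weight updates.

The two modifications relative to the basic bee colony are (i) a
pheromone field borrowed from ant-colony optimization, deposited after
each bee phase from the bee's current mask, its personal best, and the
global best, bounded to a max-min band ``[tmin, tmax]`` with a dynamic
ceiling that grows whenever a new global best is found; and (ii) a
communication operator through which an employed bee inherits its
predecessor's selected genes whose pheromone exceeds ``tmax / 2``.
Both can be switched off (``ablation=True``), reducing the loop to the
basic bee colony with local search — the baseline the modified algorithm
is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .datasets import ExpressionDataset
from .fitness import FitnessEvaluator
from .operators import (
    LocalSearchConfig,
    local_search,
    neighborhood,
    pheromone_proportional_gene,
    select_parent,
    sus_slate,
)
from .params import MabcParams, get_preset
from .prefilter import normalize_expression, preselect, rank_genes
from .results import GeneSelectionResult

__all__ = [
    "PheromoneField",
    "Bee",
    "sigmoid",
    "init_random",
    "deposit_pheromone",
    "update_inertia",
    "evaporate",
    "update_tmax",
    "communicate",
    "update_best",
    "run",
    "MabcGeneSelector",
]


def sigmoid(x):
    """Logistic function 1 / (1 + e^-x); maps pheromone to a selection bias."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class PheromoneField:
    """Per-gene pheromone values bounded to [tmin, tmax].

    ``tmax`` is dynamic (grows with each new global best); ``tmin`` is a
    fixed floor, zero by default.
    """

    p: np.ndarray
    tmax: float
    tmin: float = 0.0

    @classmethod
    def initialize(cls, n_genes: int, tmax: float, tmin: float = 0.0):
        """All genes start at the ceiling ``tmax``."""
        return cls(p=np.full(n_genes, float(tmax)), tmax=float(tmax), tmin=float(tmin))

    def clamp(self) -> None:
        np.clip(self.p, self.tmin, self.tmax, out=self.p)


@dataclass
class Bee:
    """One food source: current mask and fitness, personal best, and the
    count of consecutive evaluations that failed to improve the personal
    best (``trial``)."""

    position: np.ndarray
    fit: float
    pbest: np.ndarray
    pbest_fit: float
    trial: int = 0


@dataclass
class _SwarmState:
    gbest: np.ndarray
    gf: float
    field: PheromoneField
    trace: list = dc_field(default_factory=list)


def init_random(pheromone: PheromoneField, rng, n: int, alpha: float = 0.05):
    """Random mask biased toward high-pheromone genes.

    Gene ``d`` is selected independently with probability
    ``alpha * sigmoid(p_d)``; the small ``alpha`` keeps initial subsets
    sparse.  An all-zero draw is repaired by selecting one gene drawn
    pheromone-proportionally.
    """
    probs = alpha * sigmoid(pheromone.p[:n])
    bits = (rng.random(n) < probs).astype(np.uint8)
    if not bits.any():
        bits[pheromone_proportional_gene(pheromone.p[:n], rng)] = 1
    return bits


def deposit_pheromone(bee: Bee, gbest, gf, field: PheromoneField, w, params, rng):
    """One bee's pheromone deposition.

    p_d <- p_d * w + r0 c0 f_i [d in X_i] + r1 c1 pf_i [d in pbest_i]
                   + r2 c2 gf [d in gbest],
    with fresh uniform r0, r1, r2, then clamped to [tmin, tmax].
    """
    r0, r1, r2 = rng.random(3)
    field.p *= w
    field.p += (r0 * params.c0 * bee.fit) * bee.position
    field.p += (r1 * params.c1 * bee.pbest_fit) * bee.pbest
    field.p += (r2 * params.c2 * gf) * np.asarray(gbest)
    field.clamp()


def update_inertia(w, iteration, params: MabcParams, rng):
    """Inertia update: nonlinear decay (eq5) or randomised in [0.5, 1] (eq6).

    The decay rule is implemented as printed in its source,
    ``(w - 0.4) (MAX_ITER - iter) / (MAX_ITER + 0.4)``; the flag
    ``eq5_corrected`` switches to the plausible intended form
    ``(w - 0.4) (MAX_ITER - iter) / MAX_ITER + 0.4``.
    """
    if params.wt_rule == "eq6":
        return (1.0 + rng.random()) / 2.0
    if params.eq5_corrected:
        return (w - 0.4) * (params.max_iter - iteration) / params.max_iter + 0.4
    return (w - 0.4) * (params.max_iter - iteration) / (params.max_iter + 0.4)


def evaporate(field: PheromoneField, rho: float) -> None:
    """Multiply every pheromone by the retention factor rho ((1 - rho) is
    the evaporation coefficient), clamped to the floor."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    field.p *= rho
    field.clamp()


def update_tmax(field: PheromoneField, gf: float, rho: float) -> None:
    """Grow the pheromone ceiling on a new global best:
    tmax <- tmax * (1 + rho * gf)."""
    field.tmax *= 1.0 + rho * gf


def communicate(i, bees, field: PheromoneField, evaluator, rng):
    """Bee ``i`` inherits its predecessor's selected genes whose pheromone
    exceeds tmax / 2; the resulting mask replaces its position and is
    re-evaluated (an all-zero result is repaired with one
    pheromone-proportional gene)."""
    if i < 1:
        raise ValueError("the first bee has no predecessor to communicate with")
    strong = field.p > field.tmax / 2.0
    bits = (bees[i - 1].position.astype(bool) & strong).astype(np.uint8)
    if not bits.any():
        bits[pheromone_proportional_gene(field.p, rng)] = 1
    bee = bees[i]
    bee.position = bits
    bee.fit = evaluator.fitness(bits)
    if bee.fit > bee.pbest_fit:
        bee.pbest = bits.copy()
        bee.pbest_fit = bee.fit
        bee.trial = 0


def update_best(bee: Bee, candidate, candidate_fit, state: _SwarmState, rho: float):
    """Greedy selection plus best bookkeeping.

    The candidate replaces the bee's position only when strictly better
    (ties keep the incumbent).  The personal best updates on strict
    improvement, resetting ``trial``; otherwise ``trial`` increments.  A
    personal best that beats the global best replaces it and grows the
    pheromone ceiling.
    """
    if candidate_fit > bee.fit:
        bee.position = np.asarray(candidate, dtype=np.uint8)
        bee.fit = candidate_fit
    if candidate_fit > bee.pbest_fit:
        bee.pbest = np.asarray(candidate, dtype=np.uint8).copy()
        bee.pbest_fit = candidate_fit
        bee.trial = 0
    else:
        bee.trial += 1
    if bee.pbest_fit > state.gf:
        state.gbest = bee.pbest.copy()
        state.gf = bee.pbest_fit
        update_tmax(state.field, state.gf, rho)


def _ls_config(params: MabcParams, method: str) -> LocalSearchConfig:
    iters = {"HC": params.hc_iter, "SA": params.sa_iter, "SAHCR": params.sahc_iter}
    return LocalSearchConfig(
        method=method,
        iterations=iters[method],
        n_tweaks=params.sahc_tweak,
        schedule=params.schedule,
    )


def _candidate_from(position, ls_method, params, state, evaluator, rng):
    """Neighborhood move, optionally refined by local search.

    Dropping a one-gene mask leaves it empty; before any evaluation the
    mask is repaired with a single pheromone-proportional gene (the same
    zero-case rule the neighborhood operator itself applies)."""
    neighbor = neighborhood(position, params.nd, state.field.p, rng)
    if not neighbor.any():
        neighbor[pheromone_proportional_gene(state.field.p, rng)] = 1
    if rng.random() < params.prob_ls:
        neighbor = local_search(
            neighbor, _ls_config(params, ls_method), evaluator, state.field.p, rng
        )
    return neighbor


def employed_phase(bees, state, evaluator, params, w, rng, ablation=False):
    """Each employed bee: optional communication with its predecessor,
    neighborhood move, optional local search, greedy selection, best
    updates; afterwards every bee deposits pheromone."""
    for i, bee in enumerate(bees):
        if not ablation and i > 0 and rng.random() < params.r4:
            communicate(i, bees, state.field, evaluator, rng)
            if bee.pbest_fit > state.gf:
                state.gbest = bee.pbest.copy()
                state.gf = bee.pbest_fit
                update_tmax(state.field, state.gf, params.rho)
        cand = _candidate_from(bee.position, params.ls_e, params, state, evaluator, rng)
        update_best(bee, cand, evaluator.fitness(cand), state, params.rho)
    if not ablation:
        for bee in bees:
            deposit_pheromone(bee, state.gbest, state.gf, state.field, w, params, rng)


def onlooker_phase(bees, state, evaluator, params, w, rng, ablation=False):
    """Each onlooker picks a source bee by fitness (tournament / FPS /
    SUS slate), explores near it, and the source bee keeps the candidate
    under greedy selection; afterwards every bee deposits pheromone."""
    fits = [b.fit for b in bees]
    if params.selection == "sus":
        sources = sus_slate(fits, params.ps, rng)
    else:
        sources = [
            select_parent(fits, params.selection, rng, t=params.t)
            for _ in range(params.ps)
        ]
    for i in sources:
        bee = bees[i]
        cand = _candidate_from(bee.position, params.ls_o, params, state, evaluator, rng)
        update_best(bee, cand, evaluator.fitness(cand), state, params.rho)
    if not ablation:
        for bee in bees:
            deposit_pheromone(bee, state.gbest, state.gf, state.field, w, params, rng)


def scout_phase(bees, state, evaluator, params, rng, ablation=False):
    """Every bee whose trial counter reached ``limit`` abandons its food
    source and re-initializes (pheromone-biased); several bees may scout
    in the same iteration."""
    n = state.gbest.size
    for bee in bees:
        if bee.trial >= params.limit:
            bee.position = init_random(state.field, rng, n, params.alpha)
            bee.fit = evaluator.fitness(bee.position)
            bee.trial = 0
            if bee.fit > bee.pbest_fit:
                bee.pbest = bee.position.copy()
                bee.pbest_fit = bee.fit
            if bee.pbest_fit > state.gf:
                state.gbest = bee.pbest.copy()
                state.gf = bee.pbest_fit
                update_tmax(state.field, state.gf, params.rho)


def run(dataset: ExpressionDataset, params: MabcParams, seed: int,
        evaluator: FitnessEvaluator | None = None, ablation: bool = False,
        observer=None):
    """Full swarm search over an already-prefiltered dataset.

    Parameters
    ----------
    dataset : ExpressionDataset
        Post-prefilter matrix; masks range over its genes.
    params : MabcParams
        Search settings.
    seed : int
        Drives every stochastic draw of the run.
    evaluator : FitnessEvaluator, optional
        Pass a shared evaluator to reuse its LOOCV cache across runs on
        the same dataset (evaluation is a pure function of the mask).
    ablation : bool
        Basic bee colony baseline: pheromone frozen at its initial value
        (no deposition, evaporation or ceiling growth) and no
        communication operator.
    observer : callable, optional
        Called after each iteration as ``observer(iteration, state)``
        with the live ``_SwarmState`` (pheromone field, gbest, trace) —
        an instrumentation hook for invariant checks and logging.

    Returns
    -------
    GeneSelectionResult
        Global best of the final iteration; its trace is non-decreasing
        by construction (a perfect-accuracy subset is *not* a stopping
        criterion — later iterations may find a smaller one).
    """
    if evaluator is None:
        evaluator = FitnessEvaluator(
            dataset, w1=params.w1, kernel=params.kernel, C=params.svm_c,
            gamma=params.svm_gamma, max_iter=params.svm_max_iter,
        )
    rng = np.random.default_rng(seed)
    n = dataset.n_genes
    field = PheromoneField.initialize(n, params.tmax, params.tmin)

    bees = []
    for _ in range(params.ps):
        bits = init_random(field, rng, n, params.alpha)
        f = evaluator.fitness(bits)
        bees.append(Bee(position=bits, fit=f, pbest=bits.copy(), pbest_fit=f))
    best_i = int(np.argmax([b.fit for b in bees]))
    state = _SwarmState(
        gbest=bees[best_i].pbest.copy(), gf=bees[best_i].pbest_fit, field=field
    )

    w = params.w
    for iteration in range(1, params.max_iter + 1):
        employed_phase(bees, state, evaluator, params, w, rng, ablation)
        onlooker_phase(bees, state, evaluator, params, w, rng, ablation)
        scout_phase(bees, state, evaluator, params, rng, ablation)
        if not ablation:
            evaporate(field, params.rho)
        w = update_inertia(w, iteration, params, rng)
        state.trace.append((state.gf, int(state.gbest.sum())))
        if observer is not None:
            observer(iteration, state)

    acc, _ = evaluator.evaluate(state.gbest)
    sel = np.flatnonzero(state.gbest)
    return GeneSelectionResult(
        selected_genes=[dataset.gene_ids[j] for j in sel],
        selected_indices=[int(j) for j in sel],
        accuracy=100.0 * acc,
        fitness=state.gf,
        seed=int(seed),
        trace=state.trace,
        params=params.to_dict(),
    )


class MabcGeneSelector:
    """Gene-selection model over a labeled expression matrix.

    Normalizes expression per gene, ranks genes with the configured
    statistical prefilter, keeps the top ``th_n`` fraction, and searches
    that reduced space with the pheromone-guided bee colony.  ``fit``
    returns a :class:`GeneSelectionResult` whose gene identifiers and
    indices refer to the *original* matrix.

    Examples
    --------
    >>> model = MabcGeneSelector(dataset, params=get_preset("table2"))
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
    """

    def __init__(self, dataset: ExpressionDataset, params: MabcParams | None = None,
                 ablation: bool = False, normalize: bool = True):
        self.dataset = dataset
        self.params = params or get_preset("default")
        self.ablation = ablation
        self.normalize = normalize
        self._prepare()

    @classmethod
    def from_dataframe(cls, df, label_column=0, **kwargs):
        """Build from a DataFrame whose ``label_column`` holds the diagnosis
        and whose remaining columns are genes."""
        cols = list(df.columns)
        label_col = cols[label_column] if isinstance(label_column, int) else label_column
        gene_cols = [c for c in cols if c != label_col]
        dataset = ExpressionDataset(
            values=df[gene_cols].to_numpy(dtype=float),
            labels=df[label_col].to_numpy(),
            gene_ids=[str(c) for c in gene_cols],
        )
        return cls(dataset, **kwargs)

    def _prepare(self):
        ds = normalize_expression(self.dataset) if self.normalize else self.dataset
        self.ranking_ = rank_genes(ds, self.params.prefilter)
        self.kept_indices_ = preselect(self.ranking_, "percentage", self.params.th_n)
        self.search_dataset_ = ds.subset_genes(self.kept_indices_)
        self.evaluator_ = FitnessEvaluator(
            self.search_dataset_, w1=self.params.w1, kernel=self.params.kernel,
            C=self.params.svm_c, gamma=self.params.svm_gamma,
            max_iter=self.params.svm_max_iter,
        )

    def fit(self, seed: int = 0, observer=None) -> GeneSelectionResult:
        """Run the swarm search once; the evaluator cache persists across
        repeated fits so deterministic re-evaluations are free."""
        res = run(
            self.search_dataset_, self.params, seed,
            evaluator=self.evaluator_, ablation=self.ablation, observer=observer,
        )
        original = [self.kept_indices_[j] for j in res.selected_indices]
        return GeneSelectionResult(
            selected_genes=[self.dataset.gene_ids[j] for j in original],
            selected_indices=original,
            accuracy=res.accuracy,
            fitness=res.fitness,
            seed=res.seed,
            trace=res.trace,
            params=res.params,
        )
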