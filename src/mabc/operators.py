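"""Neighborhood/tweak move operators, local searches, and parent selection.

The search works on binary gene masks.  The neighborhood operator only
*drops* selected genes (driving subsets smaller); the tweak operator flips
one uniformly chosen bit.  Three local searches refine a candidate mask —
hill climbing (HC), simulated annealing (SA), and steepest-ascent hill
climbing with replacement (SAHCR) — and three schemes pick the source bee
exploited by an onlooker: tournament, fitness-proportionate (FPS), and
stochastic universal sampling (SUS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LocalSearchConfig",
    "neighborhood",
    "tweak",
    "local_search",
    "select_parent",
    "sus_slate",
    "pheromone_proportional_gene",
]


@dataclass
class LocalSearchConfig:
    """Settings for one local-search method.

    ``schedule`` is the multiplicative cooling factor applied to the SA
    temperature each round; ``n_tweaks`` is the number of candidate tweaks
    per SAHCR round.
    """

    method: str = "SA"  # HC | SA | SAHCR
    iterations: int = 14
    n_tweaks: int = 9
    schedule: float = 0.5
    initial_temperature: float = 1.0

    def __post_init__(self):
        if self.method not in ("HC", "SA", "SAHCR"):
            raise ValueError(f"unknown local search method {self.method!r}")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.n_tweaks < 1:
            raise ValueError("n_tweaks must be >= 1")
        if not 0.0 < self.schedule < 1.0:
            raise ValueError("schedule must lie in (0, 1)")


def pheromone_proportional_gene(pheromone: np.ndarray, rng) -> int:
    """Draw one gene index with probability proportional to its pheromone
    (uniform when the field is all zero)."""
    p = np.asarray(pheromone, dtype=float)
    total = p.sum()
    if total <= 0.0:
        return int(rng.integers(len(p)))
    return int(rng.choice(len(p), p=p / total))


def neighborhood(mask, nd, pheromone, rng):
    """Drop a fraction ``nd`` of the selected genes (at least one).

    With ``ns`` genes selected, ``k = max(1, round(nd * ns))`` uniformly
    chosen selected genes are deselected (round half up).  An empty input
    mask is instead repaired by selecting a single gene drawn
    pheromone-proportionally.  No other bits change.
    """
    if not 0.0 < nd <= 1.0:
        raise ValueError("nd must lie in (0, 1]")
    bits = np.asarray(mask, dtype=np.uint8).copy()
    selected = np.flatnonzero(bits)
    ns = selected.size
    if ns == 0:
        bits[pheromone_proportional_gene(pheromone, rng)] = 1
        return bits
    k = max(1, int(np.floor(nd * ns + 0.5)))
    drop = rng.choice(selected, size=min(k, ns), replace=False)
    bits[drop] = 0
    return bits


def tweak(mask, rng):
    """Flip exactly one uniformly chosen position (0 <-> 1)."""
    bits = np.asarray(mask, dtype=np.uint8).copy()
    j = int(rng.integers(bits.size))
    bits[j] ^= 1
    return bits


def _tweak_repaired(bits, pheromone, rng):
    """Tweak, restoring one pheromone-proportional gene if the mask empties."""
    out = tweak(bits, rng)
    if not out.any():
        out[pheromone_proportional_gene(pheromone, rng)] = 1
    return out


def local_search(start, cfg: LocalSearchConfig, evaluator, pheromone, rng):
    """Refine ``start`` with the configured local search; return the best
    mask seen (never worse than ``start`` for HC/SAHCR bookkeeping).

    HC adopts a tweak only when it improves fitness.  SA always accepts
    improvements and accepts a worsening candidate with probability
    ``exp((f_new - f_cur) / T)``, multiplying the temperature by
    ``schedule`` each round; as the temperature approaches zero its
    trajectory coincides with HC.  SAHCR generates ``n_tweaks`` candidates
    per round and replaces the current solution with the best of them even
    if worse, tracking the global best separately.
    """
    cur = np.asarray(start, dtype=np.uint8).copy()
    if cfg.iterations == 0:
        return cur
    f_cur = evaluator.fitness(cur)
    best, f_best = cur.copy(), f_cur

    if cfg.method == "HC":
        for _ in range(cfg.iterations):
            cand = _tweak_repaired(cur, pheromone, rng)
            f_cand = evaluator.fitness(cand)
            if f_cand > f_cur:
                cur, f_cur = cand, f_cand
                if f_cur > f_best:
                    best, f_best = cur.copy(), f_cur
        return best

    if cfg.method == "SA":
        temp = cfg.initial_temperature
        for _ in range(cfg.iterations):
            cand = _tweak_repaired(cur, pheromone, rng)
            f_cand = evaluator.fitness(cand)
            accept = f_cand > f_cur
            if not accept:
                ratio = (f_cand - f_cur) / temp if temp > 0 else -np.inf
                # skip the acceptance draw when it cannot succeed, so the
                # cold-temperature trajectory coincides with hill climbing
                threshold = np.exp(ratio) if ratio > -745.0 else 0.0
                accept = threshold > 0.0 and rng.random() < threshold
            if accept:
                cur, f_cur = cand, f_cand
                if f_cur > f_best:
                    best, f_best = cur.copy(), f_cur
            temp *= cfg.schedule
        return best

    # SAHCR
    for _ in range(cfg.iterations):
        round_best, f_round = None, -np.inf
        for _ in range(cfg.n_tweaks):
            cand = _tweak_repaired(cur, pheromone, rng)
            f_cand = evaluator.fitness(cand)
            if f_cand > f_round:
                round_best, f_round = cand, f_cand
        cur, f_cur = round_best, f_round  # replacement: even if worse
        if f_cur > f_best:
            best, f_best = cur.copy(), f_cur
    return best


def select_parent(fitnesses, method, rng, t=5):
    """Index of the source bee an onlooker exploits.

    tournament: fittest of ``t`` draws with replacement (ties to the
    lowest index).  fps: roulette-wheel draw with probability
    ``f_i / sum(f)``; an all-zero population falls back to uniform.
    """
    f = np.asarray(fitnesses, dtype=float)
    m = f.size
    if m == 0:
        raise ValueError("population is empty")
    if method == "tournament":
        picks = rng.integers(m, size=max(1, int(t)))
        return int(picks[np.argmax(f[picks])])
    if method == "fps":
        total = f.sum()
        probs = np.full(m, 1.0 / m) if total <= 0 else f / total
        return int(rng.choice(m, p=probs))
    raise ValueError(f"unknown selection method {method!r} (use sus_slate for SUS)")


def sus_slate(fitnesses, n_select, rng):
    """Stochastic universal sampling: a full slate of ``n_select`` source
    indices from one uniform start and evenly spaced pointers.

    Every bee is chosen at least ``floor(n_select * f_i / sum(f))`` times
    (low-variance resampling).  An all-zero population falls back to a
    uniform slate.
    """
    f = np.asarray(fitnesses, dtype=float)
    m = f.size
    if m == 0:
        raise ValueError("population is empty")
    total = f.sum()
    if total <= 0:
        return [int(rng.integers(m)) for _ in range(n_select)]
    cum = np.cumsum(f)
    step = total / n_select
    start = rng.uniform(0.0, step)
    pointers = start + step * np.arange(n_select)
    return [int(j) for j in np.searchsorted(cum, pointers, side="right")]
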