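"""Statistical prefiltering of genes.

Before the swarm search runs, every gene is scored for class association and
only a top fraction is kept.  Two univariate filters are provided:

* Kruskal-Wallis rank-sum test (non-parametric): genes are ranked by
  ascending chi-square p-value with the standard mid-rank tie correction.
* Fisher score / F-test (parametric): ratio of between-class to
  within-class weighted variance, genes ranked by descending score.

Expression values are first min-max normalized per gene to [0, 1] so that no
gene dominates the classifier by scale alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import chi2, rankdata

from .datasets import ExpressionDataset

__all__ = [
    "GeneRanking",
    "normalize_expression",
    "kruskal_wallis_pvalues",
    "f_scores",
    "preselect",
    "rank_genes",
    "write_ranking_tsv",
]


@dataclass
class GeneRanking:
    """Per-gene statistics plus the best-to-worst ordering.

    ``order`` sorts by ascending p-value (Kruskal-Wallis) or descending
    score (F-test); ties broken by original gene index so runs are
    deterministic.
    """

    scores: np.ndarray
    order: np.ndarray
    method: str
    pvalues: Optional[np.ndarray] = None
    gene_ids: Optional[list] = None


def normalize_expression(dataset: ExpressionDataset) -> ExpressionDataset:
    """Min-max normalize each gene to [0, 1].

    A constant gene maps to all zeros (the 0/0 case of the affine map);
    such genes carry no class information and rank last in either filter.
    """
    v = dataset.values
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    span = hi - lo
    out = np.zeros_like(v)
    nz = span > 0
    out[:, nz] = (v[:, nz] - lo[nz]) / span[nz]
    return ExpressionDataset(
        values=out,
        labels=dataset.labels.copy(),
        gene_ids=list(dataset.gene_ids),
        label_names=list(dataset.label_names),
    )


def _tie_correction(ranked_column: np.ndarray, n: int) -> float:
    """Standard Kruskal-Wallis tie factor 1 - sum(t^3 - t) / (N^3 - N)."""
    _, counts = np.unique(ranked_column, return_counts=True)
    t = counts[counts > 1]
    if t.size == 0:
        return 1.0
    return 1.0 - (t**3 - t).sum() / (n**3 - n)


def kruskal_wallis_pvalues(dataset: ExpressionDataset) -> GeneRanking:
    """Kruskal-Wallis statistic and chi-square p-value per gene.

    For each gene the N expression values are ranked across all samples
    (mid-ranks for ties); the statistic

        K = 12 / (N (N+1)) * sum_k n_k (rbar_k - (N+1)/2)^2

    is divided by the tie-correction factor when ties exist, and
    p = Pr(chi2_{C-1} >= K).  A fully tied (constant) gene is assigned
    K = 0, p = 1.
    """
    y = dataset.labels
    n = dataset.n_samples
    c = dataset.n_classes
    if n < c:
        raise ValueError("need at least as many samples as classes")
    ranks = rankdata(dataset.values, method="average", axis=0)
    mid = (n + 1) / 2.0

    stats = np.empty(dataset.n_genes)
    for j in range(dataset.n_genes):
        r = ranks[:, j]
        k = 0.0
        for cls in range(c):
            rk = r[y == cls]
            k += rk.size * (rk.mean() - mid) ** 2
        k *= 12.0 / (n * (n + 1))
        corr = _tie_correction(r, n)
        stats[j] = 0.0 if corr == 0.0 else k / corr
    pvals = chi2.sf(stats, df=c - 1)
    order = np.lexsort((np.arange(dataset.n_genes), pvals))
    return GeneRanking(
        scores=stats, pvalues=pvals, order=order,
        method="kruskal_wallis", gene_ids=list(dataset.gene_ids),
    )


def f_scores(dataset: ExpressionDataset) -> GeneRanking:
    """Fisher score per gene: between-class over within-class weighted variance.

    Uses the population standard-deviation convention, so the denominator
    sum_k n_k sigma_k^2 equals the pooled within-class sum of squared
    deviations.  Zero within-class variance with distinct class means gives
    +inf (ranked first); a constant gene gives 0.
    """
    y = dataset.labels
    v = dataset.values
    mu = v.mean(axis=0)
    num = np.zeros(dataset.n_genes)
    den = np.zeros(dataset.n_genes)
    for cls in range(dataset.n_classes):
        vk = v[y == cls]
        nk = vk.shape[0]
        mk = vk.mean(axis=0)
        num += nk * (mk - mu) ** 2
        den += nk * vk.var(axis=0)  # population variance
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / den
    scores[num == 0.0] = 0.0          # equal class means (incl. constant genes)
    scores[(den == 0.0) & (num > 0.0)] = np.inf
    order = np.lexsort((np.arange(dataset.n_genes), -scores))
    return GeneRanking(
        scores=scores, order=order, method="f_test",
        gene_ids=list(dataset.gene_ids),
    )


def rank_genes(dataset: ExpressionDataset, method: str = "kruskal_wallis") -> GeneRanking:
    if method == "kruskal_wallis":
        return kruskal_wallis_pvalues(dataset)
    if method == "f_test":
        return f_scores(dataset)
    raise ValueError(f"unknown prefilter method: {method!r}")


def preselect(ranking: GeneRanking, mode: str = "percentage", value: float = 0.065):
    """Indices of the genes kept for the search, best first.

    ``percentage`` keeps the top ``floor(value * n)`` ranked genes (at
    least one); ``threshold`` keeps genes with p-value <= ``value``
    (Kruskal-Wallis rankings only).
    """
    if not 0.0 < value <= 1.0:
        raise ValueError("preselection value must lie in (0, 1]")
    n = len(ranking.order)
    if mode == "percentage":
        k = max(1, int(np.floor(value * n)))
        return [int(j) for j in ranking.order[:k]]
    if mode == "threshold":
        if ranking.pvalues is None:
            raise ValueError("threshold mode requires a p-value ranking (Kruskal-Wallis)")
        kept = [int(j) for j in ranking.order if ranking.pvalues[j] <= value]
        if not kept:
            raise ValueError(
                f"no gene has p-value <= {value}; relax the threshold "
                "or use percentage mode"
            )
        return kept
    raise ValueError(f"unknown preselection mode: {mode!r}")


def write_ranking_tsv(ranking: GeneRanking, path) -> None:
    """Export the full ranking as TSV (rank, gene, statistic, p-value)."""
    with open(path, "w") as fh:
        fh.write("rank\tgene\tstatistic\tp_value\n")
        for pos, j in enumerate(ranking.order, start=1):
            gid = ranking.gene_ids[j] if ranking.gene_ids else f"g{j}"
            p = "" if ranking.pvalues is None else f"{ranking.pvalues[j]:.6g}"
            fh.write(f"{pos}\t{gid}\t{ranking.scores[j]:.6g}\t{p}\n")
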