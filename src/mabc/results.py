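"""Result record for one gene-selection run: selected genes, LOOCV accuracy,
fitness, the per-iteration trace of the global best, and the parameter
snapshot needed to reproduce the run."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = ["GeneSelectionResult", "write_result", "read_result"]


@dataclass
class GeneSelectionResult:
    """Outcome of a single swarm-search run.

    Attributes
    ----------
    selected_genes : list of str
        Identifiers of the genes in the final best subset.
    selected_indices : list of int
        Column indices of those genes in the original dataset.
    accuracy : float
        LOOCV classification accuracy of the subset, in percent.
    fitness : float
        Final global-best fitness in [0, 1] (accuracy/parsimony tradeoff).
    trace : list of (float, int)
        Per-iteration (global-best fitness, global-best subset size).
    seed : int
        Seed that drove every stochastic draw of the run.
    params : dict
        Snapshot of the resolved search parameters.
    """

    selected_genes: list
    selected_indices: list
    accuracy: float
    fitness: float
    seed: int
    trace: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_selected < 1:
            raise ValueError("a run must select at least one gene")
        if not 0.0 <= self.accuracy <= 100.0:
            raise ValueError("accuracy must be a percentage in [0, 100]")
        if not 0.0 <= self.fitness <= 1.0:
            raise ValueError("fitness must lie in [0, 1]")
        fits = [f for f, _ in self.trace]
        if any(b < a - 1e-12 for a, b in zip(fits, fits[1:])):
            raise ValueError("global-best fitness trace must be non-decreasing")

    @property
    def n_selected(self) -> int:
        return len(self.selected_genes)

    def summary_line(self) -> str:
        return (
            f"selected {self.n_selected} genes | LOOCV accuracy "
            f"{self.accuracy:.2f}% | fitness {self.fitness:.4f} | seed {self.seed}"
        )

    def summary(self) -> str:
        """Human-readable report, one selected gene per line."""
        lines = [
            "Gene selection results",
            "=" * 54,
            f"Selected genes     {self.n_selected}",
            f"LOOCV accuracy     {self.accuracy:.2f} %",
            f"Fitness            {self.fitness:.4f}",
            f"Iterations traced  {len(self.trace)}",
            f"Seed               {self.seed}",
            "-" * 54,
            "genes: " + ", ".join(map(str, self.selected_genes)),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "selected_genes": list(map(str, self.selected_genes)),
            "selected_indices": [int(i) for i in self.selected_indices],
            "n_selected": self.n_selected,
            "accuracy": self.accuracy,
            "fitness": self.fitness,
            "seed": int(self.seed),
            "trace": [[float(f), int(s)] for f, s in self.trace],
            "params": self.params,
            "summary": self.summary_line(),
        }


def write_result(result: GeneSelectionResult, path) -> None:
    """Write a machine-readable JSON record (with a human-readable summary line)."""
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
        fh.write("\n")


def read_result(path) -> GeneSelectionResult:
    with open(path) as fh:
        d = json.load(fh)
    return GeneSelectionResult(
        selected_genes=d["selected_genes"],
        selected_indices=d["selected_indices"],
        accuracy=d["accuracy"],
        fitness=d["fitness"],
        seed=d["seed"],
        trace=[tuple(t) for t in d["trace"]],
        params=d.get("params", {}),
    )
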