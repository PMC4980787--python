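"""Search parameters and the published tuned presets.

Field names follow the parameter tables of the tuning study, so a config
file written with those names verbatim resolves directly:

================  =============================================================
probLS            probability of refining a neighbor by local search
rho               pheromone retention factor; (1 - rho) is the evaporation rate
w                 initial inertia weight on retained pheromone
w1                accuracy weight in the fitness tradeoff
th_n              fraction of top-ranked genes kept by the prefilter
sahc_iter/tweak   SAHCR rounds and tweaks per round
sa_iter, hc_iter  SA and HC iteration counts
t                 tournament size
schedule          SA multiplicative cooling factor
tmax, tmin        initial pheromone ceiling and fixed floor
c0                weight of the bee's own fitness in deposition
                  (c1 = c2 = (1 - c0) / 2 weight personal/global bests)
MAX_ITER          swarm iterations
limit             stagnation threshold before a bee scouts
nd                fraction of selected genes dropped by the neighborhood move
PS                population size
r4                probability of applying the communication operator
ls_e, ls_o        local search used in the employed / onlooker phase
selection         tournament | fps | sus
kernel            SVM kernel (linear | rbf); C and gamma are fixed SVM settings
wt                inertia update rule: eq5 (nonlinear decay, as printed) or
                  eq6 (randomised, w in [0.5, 1])
prefilter         kruskal_wallis | f_test
uph               accepted for compatibility with published configs; unused
================  =============================================================
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

__all__ = ["MabcParams", "get_preset", "PRESETS", "params_from_config"]


@dataclass
class MabcParams:
    prob_ls: float = 0.7
    rho: float = 0.8
    w: float = 1.4
    w1: float = 0.85
    th_n: float = 0.065
    sahc_iter: int = 12
    sahc_tweak: int = 9
    sa_iter: int = 14
    hc_iter: int = 10
    t: int = 5
    schedule: float = 0.5
    tmax: float = 5.0
    tmin: float = 0.0
    c0: float = 0.6
    max_iter: int = 20
    limit: int = 35
    nd: float = 0.035
    ps: int = 25
    r4: float = 0.5
    ls_e: str = "SA"
    ls_o: str = "SAHCR"
    selection: str = "tournament"
    kernel: str = "linear"
    svm_c: float = 2000.0
    svm_gamma: float = 1e-4
    wt_rule: str = "eq6"
    eq5_corrected: bool = False
    prefilter: str = "kruskal_wallis"
    alpha: float = 0.05           # scale of the sigmoid selection probability at init
    svm_max_iter: int = 2000
    uph: bool = True              # documented no-op from the published tables

    def __post_init__(self):
        for name in ("prob_ls", "r4", "nd", "th_n", "rho", "w1", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.nd == 0.0 or self.th_n == 0.0:
            raise ValueError("nd and th_n must be positive")
        if self.ps < 2:
            raise ValueError("population size PS must be >= 2")
        if self.max_iter < 1 or self.limit < 1:
            raise ValueError("MAX_ITER and limit must be >= 1")
        if self.tmin < 0 or self.tmax <= self.tmin:
            raise ValueError("need tmax > tmin >= 0")
        for name in ("ls_e", "ls_o"):
            if getattr(self, name) not in ("HC", "SA", "SAHCR"):
                raise ValueError(f"{name} must be one of HC, SA, SAHCR")
        if self.selection not in ("tournament", "fps", "sus"):
            raise ValueError("selection must be tournament, fps or sus")
        if self.wt_rule not in ("eq5", "eq6"):
            raise ValueError("wt rule must be eq5 or eq6")
        if self.prefilter not in ("kruskal_wallis", "f_test"):
            raise ValueError("prefilter must be kruskal_wallis or f_test")

    @property
    def c1(self) -> float:
        return (1.0 - self.c0) / 2.0

    @property
    def c2(self) -> float:
        return (1.0 - self.c0) / 2.0

    def to_dict(self) -> dict:
        return asdict(self)


# The three tuned settings of the published tables, plus "default" mirroring
# the optimized (first) one.  "first" differs from "default" only in sa_iter,
# where the two tables disagree (14 vs 10); both are shipped.
PRESETS = {
    "default": MabcParams(),
    "table2": MabcParams(),
    "first": MabcParams(sa_iter=10),
    "second": MabcParams(
        prob_ls=0.4, th_n=0.03, sahc_iter=16, sahc_tweak=15, hc_iter=10,
        c0=0.5, limit=100, nd=0.02, ps=40, r4=0.7, ls_e="HC", ls_o="SAHCR",
        selection="tournament",
    ),
    "third": MabcParams(
        prob_ls=0.7, th_n=0.03, sahc_iter=16, sahc_tweak=15,
        c0=0.5, limit=100, nd=0.035, ps=40, r4=0.7, ls_e="SAHCR",
        ls_o="SAHCR", selection="sus",
    ),
}

# config keys as printed in the parameter tables -> dataclass field names
_CONFIG_KEYS = {
    "probLS": "prob_ls",
    "rho": "rho",
    "w": "w",
    "w1": "w1",
    "th_n": "th_n",
    "sahc_iter": "sahc_iter",
    "sahc_tweak": "sahc_tweak",
    "sa_iter": "sa_iter",
    "hc_iter": "hc_iter",
    "t": "t",
    "schedule": "schedule",
    "tmax": "tmax",
    "tmin": "tmin",
    "c0": "c0",
    "MAX_ITER": "max_iter",
    "limit": "limit",
    "nd": "nd",
    "PS": "ps",
    "r4": "r4",
    "ls_e": "ls_e",
    "ls_o": "ls_o",
    "selection": "selection",
    "kernel": "kernel",
    "C": "svm_c",
    "gamma": "svm_gamma",
    "wt": "wt_rule",
    "prefilter": "prefilter",
    "alpha": "alpha",
    "svm_max_iter": "svm_max_iter",
    "eq5_corrected": "eq5_corrected",
    "uph": "uph",
}

_SELECTION_ALIASES = {
    "tournament": "tournament",
    "tournament selection": "tournament",
    "fps": "fps",
    "fitness proportionate selection": "fps",
    "sus": "sus",
    "stochastic universal sampling": "sus",
}


def get_preset(name: str) -> MabcParams:
    """A fresh copy of a named preset."""
    try:
        return replace(PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def params_from_config(config: dict, preset: str = "default") -> MabcParams:
    """Resolve a flat config mapping (table parameter names) over a preset.

    Unknown keys are rejected so typos surface immediately.
    """
    base = get_preset(preset)
    overrides = {}
    for key, value in config.items():
        if key not in _CONFIG_KEYS:
            raise KeyError(f"unknown parameter {key!r} in config")
        field_name = _CONFIG_KEYS[key]
        if field_name == "selection":
            value = _SELECTION_ALIASES.get(str(value).strip().lower(), value)
        if field_name == "kernel":
            value = str(value).strip().lower()
        if field_name == "prefilter":
            value = str(value).strip().lower().replace("-", "_")
        overrides[field_name] = value
    return replace(base, **overrides)
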