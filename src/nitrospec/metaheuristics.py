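"""Population metaheuristics: biogeography-based optimization (BBO), the
imperialist competitive algorithm (ICA), and harmony search (HS).

All three minimise a generic :class:`Objective` and are used in two roles:
searching wavelength subsets (``index-subset`` encoding) and training
feed-forward network weights (``continuous`` encoding).  Conventions:

* costs are minimised throughout — the "habitat suitability index" of BBO
  is stored as a cost, since the quantity actually optimised downstream is
  a mean squared error;
* every optimizer is deterministic under a fixed seed and returns
  ``(best Habitat, history)`` where ``history[g]`` is the best cost seen up
  to generation/epoch/improvisation ``g`` (length budget + 1, entry 0 being
  the best of the random initial population);
* ``index-subset`` solutions are fixed-length vectors of *distinct* integer
  indices; duplicate indices arising from migration, assimilation or pitch
  adjustment are repaired deterministically by moving each duplicate to the
  nearest unused index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "Objective", "Habitat", "BBOParams", "ICAParams", "HSParams",
    "bbo_optimize", "ica_optimize", "hs_optimize",
    "continuous_objective", "subset_objective",
]

CONTINUOUS = "continuous"
INDEX_SUBSET = "index-subset"


@dataclass
class Objective:
    """A minimisation target.

    ``evaluate`` maps a decoded solution vector to a finite cost (lower is
    better) and must be deterministic for a given solution.  For the
    ``index-subset`` encoding, solutions are sorted arrays of ``dimension``
    distinct integers in ``[0, n_choices)``.
    """

    evaluate: Callable[[np.ndarray], float]
    dimension: int
    lower: np.ndarray
    upper: np.ndarray
    encoding: str = CONTINUOUS
    n_choices: int | None = None

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        self.lower = np.broadcast_to(
            np.asarray(self.lower, dtype=float), (self.dimension,)).copy()
        self.upper = np.broadcast_to(
            np.asarray(self.upper, dtype=float), (self.dimension,)).copy()
        if not (np.all(np.isfinite(self.lower)) and np.all(np.isfinite(self.upper))):
            raise ValueError("bounds must be finite")
        if np.any(self.lower >= self.upper):
            raise ValueError("lower bounds must be < upper bounds")
        if self.encoding not in (CONTINUOUS, INDEX_SUBSET):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.encoding == INDEX_SUBSET:
            if self.n_choices is None:
                raise ValueError("index-subset objective needs n_choices")
            if self.dimension > self.n_choices:
                raise ValueError("subset size exceeds number of choices")

    # -- encode/decode ------------------------------------------------
    def decode(self, position: np.ndarray) -> np.ndarray:
        """Map an internal position to an evaluable solution."""
        if self.encoding == CONTINUOUS:
            return np.clip(position, self.lower, self.upper)
        idx = np.clip(np.rint(position).astype(int), 0, self.n_choices - 1)
        return _repair_duplicates(idx, self.n_choices)

    def cost(self, position: np.ndarray) -> float:
        value = float(self.evaluate(self.decode(position)))
        if not np.isfinite(value):
            raise ValueError(
                f"objective returned non-finite cost {value!r} for solution "
                f"{self.decode(position)!r}"
            )
        return value

    def random_position(self, rng: np.random.Generator) -> np.ndarray:
        if self.encoding == CONTINUOUS:
            return rng.uniform(self.lower, self.upper)
        return np.sort(rng.choice(self.n_choices, size=self.dimension,
                                  replace=False)).astype(float)


def _repair_duplicates(indices: np.ndarray, n_choices: int) -> np.ndarray:
    """Replace duplicate indices with the nearest unused index (sorted out)."""
    seen: set[int] = set()
    out = []
    for v in indices:
        v = int(v)
        if v not in seen:
            seen.add(v)
            out.append(v)
            continue
        for step in range(1, n_choices):
            for cand in (v + step, v - step):
                if 0 <= cand < n_choices and cand not in seen:
                    seen.add(cand)
                    out.append(cand)
                    break
            else:
                continue
            break
    return np.sort(np.asarray(out, dtype=int))


@dataclass
class Habitat:
    """A candidate solution (suitability index variables) with its cost."""

    siv: np.ndarray
    hsi: float


def continuous_objective(fn, lower, upper, dimension) -> Objective:
    return Objective(evaluate=fn, dimension=dimension, lower=lower,
                     upper=upper, encoding=CONTINUOUS)


def subset_objective(fn, n_choices: int, subset_size: int) -> Objective:
    return Objective(evaluate=fn, dimension=subset_size, lower=0,
                     upper=n_choices - 1, encoding=INDEX_SUBSET,
                     n_choices=n_choices)


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

def _check_rate(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class BBOParams:
    population: int = 30
    generations: int = 50
    mutation_prob: float = 0.05
    elitism_count: int = 2
    max_immigration: float = 1.0
    max_emigration: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.population < 1 or self.generations < 0:
            raise ValueError("population >= 1 and generations >= 0 required")
        if self.elitism_count > self.population:
            raise ValueError("population smaller than elitism_count")
        for name in ("mutation_prob", "max_immigration", "max_emigration"):
            _check_rate(name, getattr(self, name))


@dataclass(frozen=True)
class ICAParams:
    population: int = 30
    generations: int = 50
    n_imperialists: int = 5
    assimilation_beta: float = 2.0
    revolution_rate: float = 0.3
    colony_power_weight: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.population < 2 or self.generations < 0:
            raise ValueError("population >= 2 and generations >= 0 required")
        if self.n_imperialists < 1 or self.n_imperialists >= self.population:
            raise ValueError("need 1 <= n_imperialists < population")
        if self.population - self.n_imperialists < self.n_imperialists:
            raise ValueError("need at least one colony per imperialist")
        _check_rate("revolution_rate", self.revolution_rate)
        if self.assimilation_beta <= 0:
            raise ValueError("assimilation_beta must be positive")


@dataclass(frozen=True)
class HSParams:
    memory_size: int = 20
    improvisations: int = 1500
    memory_consider_rate: float = 0.9
    pitch_adjust_rate: float = 0.3
    bandwidth: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.memory_size < 1 or self.improvisations < 0:
            raise ValueError("memory_size >= 1 and improvisations >= 0 required")
        _check_rate("memory_consider_rate", self.memory_consider_rate)
        _check_rate("pitch_adjust_rate", self.pitch_adjust_rate)
        if self.bandwidth is not None and self.bandwidth < 0:
            raise ValueError("bandwidth must be >= 0")


# ---------------------------------------------------------------------------
# biogeography-based optimization
# ---------------------------------------------------------------------------

def bbo_optimize(objective: Objective, params: BBOParams = BBOParams()):
    """Minimise ``objective`` by biogeography-based optimization.

    Habitats are ranked by cost; rank k of n receives immigration rate
    λ_k = I·k/(n−1) and emigration rate μ_k = E·(1−k/(n−1)) (rank 0 being
    the best).  Each SIV immigrates with probability λ, replacing it by the
    corresponding SIV of a donor drawn proportionally to μ; mutation
    re-randomises SIVs with probability ``mutation_prob``; the top
    ``elitism_count`` habitats survive each generation unchanged.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, dim = params.population, objective.dimension
    pop = np.stack([objective.random_position(rng) for _ in range(n)])
    costs = np.array([objective.cost(p) for p in pop])

    order = np.argsort(costs, kind="stable")
    pop, costs = pop[order], costs[order]
    history = [float(costs[0])]

    ranks = np.arange(n, dtype=float)
    denom = max(n - 1, 1)
    lam = params.max_immigration * ranks / denom
    mu = params.max_emigration * (1.0 - ranks / denom)
    mu_p = mu / mu.sum() if mu.sum() > 0 else np.full(n, 1.0 / n)

    for _ in range(params.generations):
        elites = pop[:params.elitism_count].copy()
        elite_costs = costs[:params.elitism_count].copy()

        new_pop = pop.copy()
        immigrate = rng.random((n, dim)) < lam[:, None]
        n_events = int(immigrate.sum())
        if n_events:
            donors = rng.choice(n, size=n_events, p=mu_p)
            rows, cols = np.nonzero(immigrate)
            new_pop[rows, cols] = pop[donors, cols]
        mutate = rng.random((n, dim)) < params.mutation_prob
        if mutate.any():
            if objective.encoding == CONTINUOUS:
                randoms = rng.uniform(
                    np.broadcast_to(objective.lower, (n, dim)),
                    np.broadcast_to(objective.upper, (n, dim)))
            else:
                # half the index mutations explore globally, half step to a
                # nearby band so the search can settle on a sharp optimum
                glob = rng.integers(0, objective.n_choices,
                                    size=(n, dim)).astype(float)
                steps = rng.integers(1, 4, size=(n, dim)) * rng.choice(
                    [-1.0, 1.0], size=(n, dim))
                local = np.clip(new_pop + steps, 0, objective.n_choices - 1)
                randoms = np.where(rng.random((n, dim)) < 0.5, local, glob)
            new_pop[mutate] = randoms[mutate]

        new_costs = np.array([objective.cost(p) for p in new_pop])
        order = np.argsort(new_costs, kind="stable")
        new_pop, new_costs = new_pop[order], new_costs[order]
        if params.elitism_count:
            new_pop[-params.elitism_count:] = elites
            new_costs[-params.elitism_count:] = elite_costs
            order = np.argsort(new_costs, kind="stable")
            new_pop, new_costs = new_pop[order], new_costs[order]
        pop, costs = new_pop, new_costs
        history.append(min(history[-1], float(costs[0])))

    best = objective.decode(pop[0])
    return Habitat(siv=best, hsi=float(objective.cost(pop[0]))), np.array(history)


# ---------------------------------------------------------------------------
# imperialist competitive algorithm
# ---------------------------------------------------------------------------

def _power_lottery(rng, total_costs: np.ndarray, exclude: int) -> int:
    """Pick an empire proportionally to normalised power (lower cost wins)."""
    candidates = [e for e in range(total_costs.size) if e != exclude]
    norm = total_costs[candidates] - total_costs.max()
    weights = np.abs(norm)
    if weights.sum() <= 0:
        return int(rng.choice(candidates))
    return int(rng.choice(candidates, p=weights / weights.sum()))


def ica_optimize(objective: Objective, params: ICAParams = ICAParams()):
    """Minimise ``objective`` by the imperialist competitive algorithm.

    The strongest countries become imperialists and the rest are divided
    among them proportionally to normalised power.  Each epoch colonies are
    assimilated towards their imperialist (per-dimension step U(0, β·d)),
    occasionally re-randomised (revolution), and swap roles with their
    imperialist when they surpass it; the weakest empire loses its weakest
    colony to a power-weighted lottery winner, and empties collapse.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, dim = params.population, objective.dimension
    pop = np.stack([objective.random_position(rng) for _ in range(n)])
    costs = np.array([objective.cost(p) for p in pop])
    order = np.argsort(costs, kind="stable")
    pop, costs = pop[order], costs[order]

    n_imp = params.n_imperialists
    imps, imp_costs = pop[:n_imp].copy(), costs[:n_imp].copy()
    cols, col_costs = pop[n_imp:].copy(), costs[n_imp:].copy()
    n_col = cols.shape[0]

    # initial allocation proportional to normalised imperialist power
    norm = imp_costs - imp_costs.max()
    weights = np.abs(norm)
    shares = (weights / weights.sum()) if weights.sum() > 0 else np.full(
        n_imp, 1.0 / n_imp)
    counts = np.floor(shares * n_col).astype(int)
    counts[np.argsort(-shares, kind="stable")[:n_col - counts.sum()]] += 1
    owner = np.repeat(np.arange(n_imp), counts)
    rng.shuffle(owner)

    history = [float(min(imp_costs.min(), col_costs.min() if n_col else np.inf))]

    alive = list(range(n_imp))
    for _ in range(params.generations):
        # assimilation: move colonies toward their imperialist
        u = rng.uniform(0.0, params.assimilation_beta, size=cols.shape)
        cols = cols + u * (imps[owner] - cols)
        cols = np.clip(cols, objective.lower, objective.upper)
        # revolution: re-randomise some colonies
        rev = rng.random(n_col) < params.revolution_rate
        for j in np.nonzero(rev)[0]:
            cols[j] = objective.random_position(rng)
        col_costs = np.array([objective.cost(c) for c in cols])
        # a colony better than its imperialist takes over the empire
        for e in alive:
            members = np.nonzero(owner == e)[0]
            if members.size == 0:
                continue
            j = members[np.argmin(col_costs[members])]
            if col_costs[j] < imp_costs[e]:
                imps[e], cols[j] = cols[j].copy(), imps[e].copy()
                imp_costs[e], col_costs[j] = col_costs[j], imp_costs[e]
        # imperialistic competition
        if len(alive) > 1:
            totals = {}
            for e in alive:
                members = np.nonzero(owner == e)[0]
                mean_col = col_costs[members].mean() if members.size else 0.0
                totals[e] = imp_costs[e] + params.colony_power_weight * mean_col
            total_arr = np.array([totals[e] for e in alive])
            weakest = alive[int(np.argmax(total_arr))]
            members = np.nonzero(owner == weakest)[0]
            winner = alive[_power_lottery(
                rng, total_arr, exclude=alive.index(weakest))]
            if members.size:
                j = members[np.argmax(col_costs[members])]
                owner[j] = winner
                if members.size == 1:
                    # empire kept only its imperialist; it joins as a colony
                    cols = np.vstack([cols, imps[weakest]])
                    col_costs = np.append(col_costs, imp_costs[weakest])
                    owner = np.append(owner, winner)
                    n_col += 1
                    alive.remove(weakest)
            else:
                cols = np.vstack([cols, imps[weakest]])
                col_costs = np.append(col_costs, imp_costs[weakest])
                owner = np.append(owner, winner)
                n_col += 1
                alive.remove(weakest)
        best_now = min(imp_costs[e] for e in alive)
        history.append(min(history[-1], float(best_now)))

    e_best = min(alive, key=lambda e: imp_costs[e])
    best = objective.decode(imps[e_best])
    return Habitat(siv=best, hsi=float(objective.cost(imps[e_best]))), np.array(history)


# ---------------------------------------------------------------------------
# harmony search
# ---------------------------------------------------------------------------

def hs_optimize(objective: Objective, params: HSParams = HSParams()):
    """Minimise ``objective`` by harmony search.

    Each improvisation draws every variable from the harmony memory with
    probability ``memory_consider_rate`` (then pitch-adjusts it within
    ±``bandwidth`` with probability ``pitch_adjust_rate``), else uniformly
    at random from the bounds; the new harmony replaces the worst memory
    entry when it is better.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    dim = objective.dimension
    if params.bandwidth is None:
        bandwidth = 0.05 * float(np.max(objective.upper - objective.lower))
        if objective.encoding == INDEX_SUBSET:
            bandwidth = max(bandwidth, 1.0)
    else:
        bandwidth = params.bandwidth

    memory = np.stack([objective.random_position(rng)
                       for _ in range(params.memory_size)])
    mem_costs = np.array([objective.cost(p) for p in memory])
    history = [float(mem_costs.min())]

    for _ in range(params.improvisations):
        consider = rng.random(dim) < params.memory_consider_rate
        rows = rng.integers(0, params.memory_size, size=dim)
        new = np.where(consider, memory[rows, np.arange(dim)],
                       rng.uniform(objective.lower, objective.upper))
        adjust = consider & (rng.random(dim) < params.pitch_adjust_rate)
        if adjust.any():
            new = new + adjust * bandwidth * (2.0 * rng.random(dim) - 1.0)
        new = np.clip(new, objective.lower, objective.upper)
        cost = objective.cost(new)
        worst = int(np.argmax(mem_costs))
        if cost < mem_costs[worst]:
            memory[worst], mem_costs[worst] = new, cost
        history.append(min(history[-1], float(mem_costs.min())))

    i_best = int(np.argmin(mem_costs))
    best = objective.decode(memory[i_best])
    return Habitat(siv=best, hsi=float(objective.cost(memory[i_best]))), np.array(history)
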