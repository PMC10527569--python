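"""Genetic-algorithm hyperparameter search over a declared parameter space.

Replaces manual hyperparameter assignment for any estimator exposing a
fit/score contract: declare a search space (log-scale or linear continuous,
integer, or categorical parameters), supply a fitness function mapping a
parameter dict to a score (higher is better), and evolve.

Operators: tournament selection (size 2), uniform crossover, per-gene
mutation (Gaussian on continuous/integer genes, resampling on categorical
genes) with bound clipping, and top-k elitism, so the best-so-far fitness
never decreases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParamSpec", "SearchSpace", "Chromosome", "init_population", "evolve"]

_KINDS = ("log", "linear", "int", "categorical")


@dataclass(frozen=True)
class ParamSpec:
    """One search-space dimension."""

    name: str
    kind: str
    low: float | None = None
    high: float | None = None
    choices: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind == "categorical":
            if not self.choices:
                raise ValueError(f"categorical parameter {self.name!r} needs choices")
        else:
            if self.low is None or self.high is None or self.high < self.low:
                raise ValueError(f"parameter {self.name!r} needs ordered bounds")
            if self.kind == "log" and self.low <= 0:
                raise ValueError(f"log-scale parameter {self.name!r} needs low > 0")

    def sample(self, rng: np.random.Generator):
        if self.kind == "categorical":
            return self.choices[rng.integers(len(self.choices))]
        if self.kind == "log":
            return float(10 ** rng.uniform(np.log10(self.low), np.log10(self.high)))
        if self.kind == "int":
            return int(rng.integers(int(self.low), int(self.high) + 1))
        return float(rng.uniform(self.low, self.high))

    def mutate(self, value, rng: np.random.Generator):
        if self.kind == "categorical":
            return self.choices[rng.integers(len(self.choices))]
        if self.kind == "log":
            lo, hi = np.log10(self.low), np.log10(self.high)
            z = np.clip(np.log10(value) + rng.normal(0, 0.1 * (hi - lo)), lo, hi)
            return float(10**z)
        if self.kind == "int":
            z = value + rng.normal(0, max(1.0, 0.1 * (self.high - self.low)))
            return int(np.clip(round(z), self.low, self.high))
        z = value + rng.normal(0, 0.1 * (self.high - self.low))
        return float(np.clip(z, self.low, self.high))

    def clip(self, value):
        if self.kind == "categorical":
            return value if value in self.choices else self.choices[0]
        if self.kind == "int":
            return int(np.clip(value, self.low, self.high))
        return float(np.clip(value, self.low, self.high))


@dataclass(frozen=True)
class SearchSpace:
    params: tuple[ParamSpec, ...]

    def __post_init__(self) -> None:
        if not self.params:
            raise ValueError("search space must not be empty")

    def sample(self, rng: np.random.Generator) -> dict:
        return {p.name: p.sample(rng) for p in self.params}


@dataclass
class Chromosome:
    """Encoded candidate: one value per parameter plus its fitness (if scored)."""

    values: dict
    fitness: float | None = field(default=None)


def init_population(space: SearchSpace, pop_size: int, seed) -> list[Chromosome]:
    """Uniform (log-uniform where declared) seeded sampling within bounds."""
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [Chromosome(values=space.sample(rng)) for _ in range(pop_size)]


def _evaluate(pop: list[Chromosome], fitness_fn) -> None:
    for chrom in pop:
        if chrom.fitness is None:
            try:
                chrom.fitness = float(fitness_fn(chrom.values))
            except Exception:
                chrom.fitness = -np.inf  # failed configuration keeps the run alive


def _tournament(pop: list[Chromosome], rng: np.random.Generator) -> Chromosome:
    i, j = rng.integers(len(pop)), rng.integers(len(pop))
    return pop[i] if pop[i].fitness >= pop[j].fitness else pop[j]


def evolve(
    population: list[Chromosome],
    space: SearchSpace,
    fitness_fn,
    generations: int = 30,
    cx_rate: float = 0.8,
    mut_rate: float = 0.1,
    elitism_k: int = 2,
    seed: int = 0,
):
    """Evolve a population and return ``(best_chromosome, trace)``.

    ``trace`` is the best-so-far fitness after each generation (monotone
    non-decreasing thanks to elitism).  A fitness_fn failure scores that
    chromosome as worst and the run continues.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(seed)
    pop = [Chromosome(values=dict(c.values), fitness=c.fitness) for c in population]
    _evaluate(pop, fitness_fn)
    best = max(pop, key=lambda c: c.fitness)
    best = Chromosome(values=dict(best.values), fitness=best.fitness)
    trace = [best.fitness]

    for _ in range(generations):
        pop.sort(key=lambda c: c.fitness, reverse=True)
        elites = [Chromosome(values=dict(c.values), fitness=c.fitness)
                  for c in pop[: max(0, elitism_k)]]
        offspring: list[Chromosome] = []
        while len(offspring) < len(pop) - len(elites):
            p1, p2 = _tournament(pop, rng), _tournament(pop, rng)
            child = dict(p1.values)
            if rng.random() < cx_rate:  # uniform crossover
                for p in space.params:
                    if rng.random() < 0.5:
                        child[p.name] = p2.values[p.name]
            for p in space.params:
                if rng.random() < mut_rate:
                    child[p.name] = p.mutate(child[p.name], rng)
                child[p.name] = p.clip(child[p.name])
            offspring.append(Chromosome(values=child))
        _evaluate(offspring, fitness_fn)
        pop = elites + offspring
        gen_best = max(pop, key=lambda c: c.fitness)
        if gen_best.fitness > best.fitness:
            best = Chromosome(values=dict(gen_best.values), fitness=gen_best.fitness)
        trace.append(best.fitness)

    return best, np.asarray(trace)
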