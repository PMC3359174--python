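"""Genetic-algorithm wrapper feature selection at fixed subset size.

Chromosomes are 180-bit masks constrained to exactly ``subset_dim`` ones
(the prescribed feature-subset dimensionality). Fitness is the LDA mean
probability of error estimated by resubstitution on the training data — the
wrapper method: subsets are judged by the predictive performance of the
classifier itself. Operators follow the standard configuration: population
250, 1 elite, roulette-wheel parent selection, scattered crossover at rate
0.7 (with a cardinality-repair step, since mask mixing can change the
number of selected features), uniform per-gene mutation at rate 0.2
(selected indices swap with random unselected ones, preserving
cardinality), 30 generations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .lda import resubstitution_error_fitness


@dataclass(frozen=True)
class GaConfig:
    population_size: int = 250
    search_space_dim: int = 180
    elite_count: int = 1
    crossover_rate: float = 0.7
    mutation_rate: float = 0.2
    max_generations: int = 30
    subset_dim: int = 10
    seed: int | None = None

    def validate(self) -> None:
        if not (0 < self.subset_dim < self.search_space_dim):
            raise ValueError("need 0 < subset_dim < search_space_dim")
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("crossover_rate and mutation_rate must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0 <= self.elite_count < self.population_size):
            raise ValueError("elite_count must be < population_size")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


@dataclass(frozen=True)
class Chromosome:
    """A feature subset of exactly ``subset_dim`` indices plus its fitness."""

    indices: tuple[int, ...]
    fitness: float


@dataclass(eq=False)
class GaResult:
    best: Chromosome
    trace: np.ndarray  # generation-best fitness, length max_generations
    final_population: list[Chromosome] = field(default_factory=list)
    n_evaluations: int = 0


def _repair(mask: np.ndarray, subset_dim: int, rng: np.random.Generator) -> None:
    """Restore exact cardinality after crossover, in place."""
    ones = np.flatnonzero(mask)
    if ones.size > subset_dim:
        drop = rng.choice(ones, size=ones.size - subset_dim, replace=False)
        mask[drop] = False
    elif ones.size < subset_dim:
        zeros = np.flatnonzero(~mask)
        add = rng.choice(zeros, size=subset_dim - ones.size, replace=False)
        mask[add] = True


def _mutate(mask: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Uniform per-gene mutation: swap selected with unselected, in place."""
    if rate <= 0:
        return
    ones = np.flatnonzero(mask)
    flip = ones[rng.random(ones.size) < rate]
    if flip.size == 0:
        return
    zeros = np.flatnonzero(~mask)
    if flip.size > zeros.size:  # near-full masks: only as many swaps as free slots
        flip = rng.choice(flip, size=zeros.size, replace=False)
    repl = rng.choice(zeros, size=flip.size, replace=False)
    mask[flip] = False
    mask[repl] = True


def ga_run(
    X: np.ndarray | None,
    y: Sequence | None,
    config: GaConfig,
    seed: int | None = None,
    fitness: Callable[[tuple[int, ...]], float] | None = None,
) -> GaResult:
    """One GA run; returns the best chromosome ever seen plus its trace.

    ``fitness`` defaults to the LDA resubstitution mean error on (X, y);
    a custom callable (indices -> error) may be supplied instead, in which
    case X and y may be None. Deterministic for a fixed seed. Fitness
    values are cached per subset, so converged populations re-evaluate
    cheaply.
    """
    config.validate()
    if fitness is None:
        if X is None or y is None:
            raise ValueError("either (X, y) or an explicit fitness callable is required")
        X = np.asarray(X, dtype=float)
        if X.shape[1] < config.search_space_dim:
            raise ValueError(
                f"feature matrix has {X.shape[1]} columns < search_space_dim "
                f"{config.search_space_dim}"
            )
        if config.subset_dim >= X.shape[0]:
            raise ValueError(
                f"subset_dim {config.subset_dim} >= sample count {X.shape[0]}: "
                "LDA covariance would be unfittable"
            )
        fitness = resubstitution_error_fitness(X, y)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dim, pop_n, d = config.search_space_dim, config.population_size, config.subset_dim

    pop = np.zeros((pop_n, dim), dtype=bool)
    for i in range(pop_n):
        pop[i, rng.choice(dim, size=d, replace=False)] = True

    cache: dict[tuple[int, ...], float] = {}
    n_eval = 0

    def evaluate(mask: np.ndarray) -> tuple[tuple[int, ...], float]:
        nonlocal n_eval
        key = tuple(int(i) for i in np.flatnonzero(mask))
        if key not in cache:
            cache[key] = fitness(key)
            n_eval += 1
        return key, cache[key]

    best: Chromosome | None = None
    trace = np.empty(config.max_generations)
    fits = np.empty(pop_n)
    for gen in range(config.max_generations):
        keys = []
        for i in range(pop_n):
            key, f = evaluate(pop[i])
            keys.append(key)
            fits[i] = f
        order = np.argsort(fits, kind="stable")
        gen_best = Chromosome(indices=keys[order[0]], fitness=float(fits[order[0]]))
        if best is None or gen_best.fitness < best.fitness:
            best = gen_best
        trace[gen] = fits[order[0]]

        if gen == config.max_generations - 1:
            final = [Chromosome(indices=keys[i], fitness=float(fits[i]))
                     for i in range(pop_n)]
            break

        # roulette-wheel weights: proportional to (1 - error), floored so the
        # worst individual keeps a small nonzero selection probability
        weights = np.maximum(1.0 - fits, 1e-6)
        probs = weights / weights.sum()

        new_pop = np.zeros_like(pop)
        new_pop[: config.elite_count] = pop[order[: config.elite_count]]
        n_off = pop_n - config.elite_count
        n_cross = int(round(config.crossover_rate * n_off))
        for j in range(n_off):
            if j < n_cross:
                pa, pb = rng.choice(pop_n, size=2, p=probs)
                template = rng.random(dim) < 0.5
                child = np.where(template, pop[pa], pop[pb])
                _repair(child, d, rng)
            else:
                child = pop[rng.choice(pop_n, p=probs)].copy()
            _mutate(child, config.mutation_rate, rng)
            new_pop[config.elite_count + j] = child
        pop = new_pop

    assert best is not None
    return GaResult(best=best, trace=trace, final_population=final, n_evaluations=n_eval)


def select_best_of_runs(runs: Sequence[GaResult]) -> Chromosome:
    """The lowest-error chromosome across runs; ties keep the earliest run."""
    if not runs:
        raise ValueError("no GA runs supplied")
    best = runs[0].best
    for r in runs[1:]:
        if r.best.fitness < best.fitness:
            best = r.best
    return best


def exhaustive_search(
    fitness: Callable[[tuple[int, ...]], float],
    search_space_dim: int,
    subset_dim: int,
) -> Chromosome:
    """Brute-force minimum over all subsets (tiny problems only)."""
    import itertools

    best: Chromosome | None = None
    for combo in itertools.combinations(range(search_space_dim), subset_dim):
        f = fitness(combo)
        if best is None or f < best.fitness:
            best = Chromosome(indices=combo, fitness=f)
    assert best is not None
    return best
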