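"""Genetic algorithm over MLP hyperparameter chromosomes.

A chromosome is four real genes in [0, 1) decoding to (activation, solver,
first hidden-layer size, second hidden-layer size) — a 4 x 3 x 50 x 50
search space. The GA is generational and non-elitist: tournament selection
(k = 4 by default), single-point crossover with probability Pc, per-gene
uniform-resample mutation with probability Pm, children fully replace
parents each generation, and a separate archive keeps the best solution
seen over the whole run. Fitness values are cached per decoded genotype so
that re-encountered hyperparameter combinations are never re-trained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np

ACTIVATIONS = ("identity", "logistic", "tanh", "relu")
SOLVERS = ("lbfgs", "sgd", "adam")
MAX_LAYER = 50


class DecodedGenotype(NamedTuple):
    activation_id: int  # 0..3
    solver_id: int      # 0..2
    h1: int             # 1..50
    h2: int             # 1..50

    @property
    def activation(self) -> str:
        return ACTIVATIONS[self.activation_id]

    @property
    def solver(self) -> str:
        return SOLVERS[self.solver_id]


@dataclass(frozen=True)
class MLPGenotype:
    genes: tuple[float, float, float, float]

    def __post_init__(self):
        if len(self.genes) != 4:
            raise ValueError("genotype has exactly 4 genes")


@dataclass
class GAConfig:
    population_size: int = 50
    generations: int = 200
    crossover_prob: float = 1.0
    mutation_prob: float = 0.001
    tournament_k: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 1 <= self.tournament_k <= self.population_size:
            raise ValueError("tournament_k must be in 1..population_size")


@dataclass
class EvaluatedSolution:
    genotype: MLPGenotype
    fitness: float  # accuracy percentage in [0, 100]


@dataclass
class GARunResult:
    best: EvaluatedSolution
    per_generation: list[tuple[int, float, float]]  # (gen, best-so-far, pop mean)
    evaluations: int
    cache: dict = field(repr=False, default_factory=dict)


def decode(genotype: MLPGenotype) -> DecodedGenotype:
    """Map four unit-interval genes to discrete MLP hyperparameters.

    activation = floor(g1*4), solver = floor(g2*3), layer sizes
    floor(g*50)+1 — the scaled-floor mapping keeps crossover and mutation
    closed over valid genotypes.
    """
    g = genotype.genes
    if any((not math.isfinite(x)) or x < 0 or x >= 1 for x in g):
        raise ValueError(f"genes must lie in [0, 1): {g}")
    return DecodedGenotype(
        activation_id=int(g[0] * len(ACTIVATIONS)),
        solver_id=int(g[1] * len(SOLVERS)),
        h1=int(g[2] * MAX_LAYER) + 1,
        h2=int(g[3] * MAX_LAYER) + 1,
    )


def random_population(config: GAConfig, rng: np.random.Generator) -> list[MLPGenotype]:
    """n genotypes with genes i.i.d. uniform on [0, 1)."""
    return [MLPGenotype(tuple(rng.random(4)))
            for _ in range(config.population_size)]


def tournament_select(
    pop: list[EvaluatedSolution], k: int, rng: np.random.Generator
) -> EvaluatedSolution:
    """Sample k distinct contestants; the fittest wins, ties to the lowest index."""
    if not pop:
        raise ValueError("empty population")
    if not 1 <= k <= len(pop):
        raise ValueError(f"tournament k={k} out of range for |pop|={len(pop)}")
    idx = rng.choice(len(pop), size=k, replace=False)
    winner = min(idx, key=lambda i: (-pop[i].fitness, i))
    return pop[winner]


def single_point_crossover(
    p1: MLPGenotype, p2: MLPGenotype, pc: float, rng: np.random.Generator
) -> tuple[MLPGenotype, MLPGenotype]:
    """With probability pc, swap gene suffixes at a cut point in {1, 2, 3}."""
    if rng.random() < pc:
        c = int(rng.integers(1, 4))
        child1 = p1.genes[:c] + p2.genes[c:]
        child2 = p2.genes[:c] + p1.genes[c:]
        return MLPGenotype(child1), MLPGenotype(child2)
    return MLPGenotype(p1.genes), MLPGenotype(p2.genes)


def mutate(g: MLPGenotype, pm: float, rng: np.random.Generator) -> MLPGenotype:
    """Resample each gene independently, uniform on [0, 1), with probability pm."""
    mask = rng.random(4) < pm
    if not mask.any():
        return g
    genes = list(g.genes)
    for i in np.flatnonzero(mask):
        genes[i] = float(rng.random())
    return MLPGenotype(tuple(genes))


def run_ga(
    config: GAConfig,
    fitness_fn: Callable[[MLPGenotype], float],
) -> GARunResult:
    """Evolve MLP hyperparameter chromosomes, maximizing ``fitness_fn``.

    One run of the generational loop: evaluate the random initial
    population; for each of ``generations`` iterations breed n children by
    n/2 rounds of (tournament-select two parents, crossover, mutate both),
    replace the parents wholesale, evaluate the children. The returned
    archive holds the best solution over the entire run and is therefore
    non-decreasing per generation even though the population itself is
    non-elitist. ``fitness_fn`` is consulted once per distinct decoded
    genotype (cached).
    """
    rng = np.random.default_rng(config.seed)
    cache: dict[DecodedGenotype, float] = {}
    n_evals = 0

    def evaluate(g: MLPGenotype) -> EvaluatedSolution:
        nonlocal n_evals
        key = decode(g)
        if key not in cache:
            fit = float(fitness_fn(g))
            if not math.isfinite(fit):
                raise ValueError(
                    f"fitness_fn returned non-finite value {fit!r} for "
                    f"genotype {key}")
            cache[key] = fit
            n_evals += 1
        return EvaluatedSolution(genotype=g, fitness=cache[key])

    population = [evaluate(g) for g in random_population(config, rng)]
    best = max(population, key=lambda s: s.fitness)
    history: list[tuple[int, float, float]] = []

    for gen in range(1, config.generations + 1):
        children: list[MLPGenotype] = []
        for _ in range(config.population_size // 2):
            pa = tournament_select(population, config.tournament_k, rng)
            pb = tournament_select(population, config.tournament_k, rng)
            c1, c2 = single_point_crossover(
                pa.genotype, pb.genotype, config.crossover_prob, rng)
            children.append(mutate(c1, config.mutation_prob, rng))
            children.append(mutate(c2, config.mutation_prob, rng))
        population = [evaluate(c) for c in children]
        gen_best = max(population, key=lambda s: s.fitness)
        if gen_best.fitness > best.fitness:
            best = gen_best
        mean = float(np.mean([s.fitness for s in population]))
        history.append((gen, best.fitness, mean))

    return GARunResult(best=best, per_generation=history,
                       evaluations=n_evals, cache=cache)
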