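"""Genetic-algorithm search of the network's initial weights and thresholds.

Gradient training of the sigmoid network is sensitive to its starting point
and can stall in poor local minima.  The GA-BP hybrid runs a real-coded
genetic algorithm over the flattened 52-parameter vector first — fitness is
the reciprocal of the untrained network's mean squared error on the training
fold — and hands the best chromosome to backpropagation as the initial state.

Operators: roulette-wheel selection proportional to fitness, per-gene
arithmetic (blend) crossover, uniform-perturbation mutation whose amplitude
is self-adaptive (a multiple of the current per-gene population spread, so
exploration narrows as the population converges), and elitism copying the
best individuals unchanged.  All rates, sizes and gene bounds are package
choices exposed through :class:`GAConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from dvhpredict.network import (
    N_HIDDEN,
    N_INPUT,
    N_OUTPUT,
    NetworkParams,
    TrainConfig,
    TrainingState,
    mse,
    train,
)

logger = logging.getLogger(__name__)

_EPS = 1e-8


@dataclass
class Chromosome:
    """Flat real-coded encoding of a full parameter set, with its fitness."""

    genes: np.ndarray
    fitness: float = 0.0

    def decode(self, topology: tuple[int, int, int] = (N_INPUT, N_HIDDEN, N_OUTPUT)) -> NetworkParams:
        return NetworkParams.unflatten(self.genes, topology)

    @classmethod
    def encode(cls, params: NetworkParams) -> "Chromosome":
        return cls(genes=params.flatten())


@dataclass
class GAConfig:
    pop_size: int = 30
    generations: int = 50
    crossover_rate: float = 0.7
    mutation_rate: float = 0.05
    gene_bounds: tuple[float, float] = (-3.0, 3.0)
    elitism: int = 1
    #: Mutation amplitude as a multiple of the current per-gene population
    #: standard deviation (self-adaptive: exploration shrinks as the
    #: population converges).
    mutation_span: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be at least 2")
        if self.generations < 1:
            raise ValueError("generations must be at least 1")
        for name, rate in (("crossover_rate", self.crossover_rate),
                           ("mutation_rate", self.mutation_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.gene_bounds[0] < self.gene_bounds[1]:
            raise ValueError("gene_bounds must be an increasing interval")
        if not 0 <= self.elitism < self.pop_size:
            raise ValueError("elitism must be non-negative and below pop_size")
        if not self.mutation_span > 0:
            raise ValueError("mutation_span must be positive")


def fitness(chrom: Chromosome, X: np.ndarray, Y: np.ndarray) -> float:
    """1 / (MSE + eps) of the decoded, untrained network on (X, Y)."""
    return 1.0 / (mse(chrom.decode(), X, Y) + _EPS)


def _evaluate(genes: np.ndarray, objective: Callable[[np.ndarray], float]) -> float:
    return 1.0 / (objective(genes) + _EPS)


def evolve(
    X: np.ndarray,
    Y: np.ndarray,
    cfg: GAConfig,
    init_population: np.ndarray | None = None,
    objective: Callable[[np.ndarray], float] | None = None,
    history: list[dict] | None = None,
) -> Chromosome:
    """Run the genetic algorithm and return the best-ever chromosome.

    ``objective`` defaults to the untrained-network MSE on (X, Y); supplying a
    different callable turns the routine into a generic real-coded minimizer
    (used by the test-suite benchmark on a sphere function).  ``history``, if
    given, collects per-generation best/mean fitness dictionaries.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.gene_bounds
    if objective is None:
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        objective = lambda genes: mse(NetworkParams.unflatten(genes), X, Y)  # noqa: E731
        n_genes = (N_INPUT + 1) * N_HIDDEN + (N_HIDDEN + 1) * N_OUTPUT
    else:
        n_genes = init_population.shape[1] if init_population is not None else (
            (N_INPUT + 1) * N_HIDDEN + (N_HIDDEN + 1) * N_OUTPUT
        )

    if init_population is None:
        pop = rng.uniform(lo, hi, size=(cfg.pop_size, n_genes))
    else:
        pop = np.array(init_population, dtype=float)
        if pop.shape[0] != cfg.pop_size:
            raise ValueError("init_population size must equal cfg.pop_size")

    fits = np.array([_evaluate(g, objective) for g in pop])
    best_idx = int(np.argmax(fits))
    best = Chromosome(genes=pop[best_idx].copy(), fitness=float(fits[best_idx]))

    if np.ptp(pop, axis=0).max() == 0.0 and cfg.mutation_rate == 0.0:
        logger.info("degenerate population (zero variance, no mutation); returning as-is")
        return best

    for gen in range(cfg.generations):
        # roulette-wheel selection (fitness is strictly positive)
        probs = fits / fits.sum()
        parents = pop[rng.choice(cfg.pop_size, size=cfg.pop_size, p=probs)]

        # arithmetic blend crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, cfg.pop_size - 1, 2):
            if rng.random() < cfg.crossover_rate:
                u = rng.random(n_genes)
                a, b = parents[i], parents[i + 1]
                children[i] = u * a + (1.0 - u) * b
                children[i + 1] = u * b + (1.0 - u) * a

        # uniform perturbation mutation; amplitude tracks the per-gene spread
        # of the parent population, so exploration is coarse early and fine
        # once the population has contracted
        span = cfg.mutation_span * pop.std(axis=0)
        mask = rng.random(children.shape) < cfg.mutation_rate
        children = children + mask * rng.uniform(-1.0, 1.0, size=children.shape) * span
        np.clip(children, lo, hi, out=children)

        child_fits = np.array([_evaluate(g, objective) for g in children])

        # elitism: overwrite the worst children with the best previous individuals
        if cfg.elitism > 0:
            elite_idx = np.argsort(fits)[-cfg.elitism :]
            worst_idx = np.argsort(child_fits)[: cfg.elitism]
            children[worst_idx] = pop[elite_idx]
            child_fits[worst_idx] = fits[elite_idx]

        pop, fits = children, child_fits
        assert pop.min() >= lo and pop.max() <= hi, "gene bounds violated"

        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best.fitness:
            best = Chromosome(genes=pop[gen_best].copy(), fitness=float(fits[gen_best]))
        if history is not None:
            history.append(
                {"generation": gen, "best_fitness": float(fits[gen_best]),
                 "mean_fitness": float(fits.mean()), "best_ever": best.fitness}
            )
    return best


def ga_bp_train(
    X: np.ndarray, Y: np.ndarray, cfg: GAConfig, tcfg: TrainConfig
) -> tuple[NetworkParams, TrainingState]:
    """GA search of the initial state followed by backpropagation training."""
    best = evolve(X, Y, cfg)
    return train(best.decode(), X, Y, tcfg)
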