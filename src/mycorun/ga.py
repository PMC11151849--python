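"""Genetic-algorithm engine (maximization convention).

The same engine serves both uses in the analysis: integer search over the
hidden-neuron count of the surrogate network, and continuous search over
substrate composition (and running time) on a trained surrogate.

One generation = fitness evaluation → roulette-wheel (fitness-proportional)
parent selection → crossover → per-gene mutation → elitist replacement.
Defaults follow the study settings: population 50, 500 generations, crossover
rate 0.85, mutation rate 0.01.  Roulette selection needs nonnegative weights,
so fitnesses are shifted by (min − ε) within each generation; with at least
one elite individual the best-so-far trace is nondecreasing.

Operator forms (unspecified in the source method): arithmetic crossover and
clipped Gaussian mutation (σ = 10% of the gene range) for real genes;
single-point crossover and uniform redraw for integer genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["GAConfig", "OptimizationOutcome", "run_ga", "roulette_select", "reproduce"]


@dataclass(frozen=True)
class GAConfig:
    """Evolutionary-search settings; defaults are the study's four parameters."""

    bounds: tuple[tuple[float, float], ...] = ()
    population_size: int = 50
    generations: int = 500
    crossover_rate: float = 0.85
    mutation_rate: float = 0.01
    elitism_count: int = 1
    seed: int = 0
    encoding: str = "real"  # 'real' or 'integer'

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.encoding not in ("real", "integer"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if not self.bounds:
            raise ValueError("per-gene bounds are required")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid gene bounds ({lo}, {hi})")
        if self.elitism_count < 0 or self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")


@dataclass(frozen=True)
class OptimizationOutcome:
    """Best solution found plus the per-generation best-fitness trace."""

    best_chromosome: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness after each generation
    seed: int
    config: GAConfig


def _random_population(cfg: GAConfig, rng: np.random.Generator) -> np.ndarray:
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    if cfg.encoding == "integer":
        return rng.integers(lo, hi + 1, size=(cfg.population_size, len(cfg.bounds))).astype(float)
    return rng.uniform(lo, hi, size=(cfg.population_size, len(cfg.bounds)))


def roulette_select(fitnesses: np.ndarray, rng: np.random.Generator) -> int:
    """Fitness-proportional parent index after a min-shift to nonnegative weights."""
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("empty population")
    w = f - f.min() + 1e-12
    cum = np.cumsum(w)
    return int(np.searchsorted(cum, rng.uniform(0.0, cum[-1]), side="right").clip(0, f.size - 1))


def reproduce(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Crossover (with prob ``crossover_rate``) then per-gene mutation; in-bounds."""
    a = np.array(parent_a, dtype=float)
    b = np.array(parent_b, dtype=float)
    lo = np.array([x[0] for x in config.bounds])
    hi = np.array([x[1] for x in config.bounds])
    n = len(lo)

    if rng.uniform() < config.crossover_rate:
        if config.encoding == "real":
            alpha = rng.uniform()
            a, b = alpha * a + (1 - alpha) * b, alpha * b + (1 - alpha) * a
        elif n > 1:  # single-point; a 1-gene chromosome has no interior cut
            point = int(rng.integers(1, n))
            a, b = (
                np.concatenate([a[:point], b[point:]]),
                np.concatenate([b[:point], a[point:]]),
            )

    for child in (a, b):
        mutate = rng.uniform(size=n) < config.mutation_rate
        if config.encoding == "integer":
            redraw = rng.integers(lo, hi + 1, size=n).astype(float)
            child[mutate] = redraw[mutate]
        else:
            step = rng.normal(0.0, 0.1 * (hi - lo), size=n)
            child[mutate] += step[mutate]
        np.clip(child, lo, hi, out=child)
        if config.encoding == "integer":
            np.rint(child, out=child)
    return a, b


def run_ga(
    fitness_fn: Callable[[np.ndarray], float],
    config: GAConfig,
    initial_population: Optional[Sequence[np.ndarray]] = None,
) -> OptimizationOutcome:
    """Run the full evolutionary loop; deterministic given (seed, config).

    ``initial_population`` rows (already within bounds) replace the leading
    random individuals, e.g. to seed the search with design-grid points.
    """
    rng = np.random.default_rng(config.seed)
    pop = _random_population(config, rng)
    if initial_population is not None:
        seeds = np.atleast_2d(np.asarray(initial_population, dtype=float))[: config.population_size]
        pop[: len(seeds)] = seeds

    def evaluate(population: np.ndarray) -> np.ndarray:
        out = np.empty(len(population))
        for i, chrom in enumerate(population):
            val = float(fitness_fn(chrom))
            if not np.isfinite(val):
                raise ValueError(f"fitness not finite at chromosome {chrom.tolist()}")
            out[i] = val
        return out

    fit = evaluate(pop)
    best_i = int(fit.argmax())
    best_chrom, best_fit = pop[best_i].copy(), float(fit[best_i])
    trace = []

    for _ in range(config.generations):
        order = np.argsort(fit)[::-1]
        elites = pop[order[: config.elitism_count]].copy()
        children = []
        while len(children) < config.population_size - config.elitism_count:
            pa = pop[roulette_select(fit, rng)]
            pb = pop[roulette_select(fit, rng)]
            ca, cb = reproduce(pa, pb, config, rng)
            children.append(ca)
            if len(children) < config.population_size - config.elitism_count:
                children.append(cb)
        pop = np.vstack([elites, np.array(children)]) if len(elites) else np.array(children)
        fit = evaluate(pop)
        gen_best = int(fit.argmax())
        if fit[gen_best] > best_fit:
            best_fit = float(fit[gen_best])
            best_chrom = pop[gen_best].copy()
        trace.append(best_fit)

    return OptimizationOutcome(
        best_chromosome=best_chrom,
        best_fitness=best_fit,
        trace=np.array(trace),
        seed=config.seed,
        config=config,
    )
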