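"""Real-coded genetic algorithm: roulette selection, blend (blx-alpha)
crossover, non-uniform mutation, and elitism.

The algorithm minimizes a scalar objective over a box-bounded real
vector.  Each generation is assembled from three pools: the elite
fraction copied unchanged, a crossover fraction bred from roulette-
selected parents with blx-alpha, and a mutation fraction produced by
non-uniform mutation (whose amplitude decays as the generation counter
approaches the budget) of roulette-selected individuals.  A caller-
supplied seed solution can be injected into the initial population,
which — together with elitism — bounds the best objective from above by
the seed's value throughout the run.

All randomness flows through one ``numpy.random.Generator`` seeded from
``GAConfig.rng_seed``; objective evaluation is sequential, so runs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BoundsSet",
    "GAConfig",
    "GAResult",
    "init_population",
    "selection_probabilities",
    "crossover_blx",
    "mutate_nonuniform",
    "run",
]


@dataclass(frozen=True)
class BoundsSet:
    """Elementwise box bounds on the decision vector."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("bounds must be 1-D arrays of equal length")
        if np.any(lo > hi):
            raise ValueError("lower bound exceeds upper bound")

    @property
    def size(self) -> int:
        return self.lower.size

    def contains(self, x: np.ndarray, atol: float = 1e-12) -> bool:
        return bool(
            np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol)
        )


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 86
    generations: int = 100
    elite_fraction: float = 0.05
    crossover_fraction: float = 0.80
    mutation_fraction: float = 0.15
    blx_alpha: float = 0.5
    #: shape exponent of the non-uniform mutation decay schedule
    mutation_shape: float = 3.0
    #: per-component mutation probability; None means 1/n_components
    mutation_rate: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        total = (
            self.elite_fraction + self.crossover_fraction + self.mutation_fraction
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"elite, crossover and mutation fractions must sum to 1, got {total}"
            )

    def pool_sizes(self) -> tuple[int, int, int]:
        """(elite, crossover, mutation) counts; elite and crossover are
        rounded to the nearest integer, mutation fills the remainder.
        A positive elite fraction always keeps at least one elite, so the
        best-objective trace is non-increasing for any population size."""
        n = self.population_size
        n_elite = round(self.elite_fraction * n)
        if self.elite_fraction > 0.0 and n_elite == 0:
            n_elite = 1
        n_cross = round(self.crossover_fraction * n)
        if n_elite + n_cross > n:
            n_cross = n - n_elite
        n_mut = n - n_elite - n_cross
        if n_mut < 0:
            n_cross += n_mut
            n_mut = 0
        return n_elite, n_cross, n_mut


@dataclass(frozen=True)
class GAResult:
    best_vector: np.ndarray
    best_h: float
    best_trace: np.ndarray
    worst_trace: np.ndarray
    avg_trace: np.ndarray
    population: np.ndarray = field(repr=False)
    objectives: np.ndarray = field(repr=False)


def init_population(
    bounds: BoundsSet,
    config: GAConfig,
    injected: Sequence[float] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform random population within bounds, plus one injected seed
    solution (placed last) if provided."""
    n = config.population_size
    n_random = n if injected is None else n - 1
    pop = rng.uniform(
        bounds.lower, bounds.upper, size=(n_random, bounds.size)
    )
    if injected is not None:
        seed = np.asarray(injected, dtype=float)
        if not bounds.contains(seed):
            raise ValueError("injected solution lies outside the bounds")
        pop = np.vstack([pop, seed])
    return pop


def selection_probabilities(objectives: Sequence[float]) -> np.ndarray:
    """Roulette-wheel probabilities for a minimization problem.

    Raw objectives (which may be negative) are shifted to non-negative
    fitness against the population's worst value, with a small positive
    floor so the worst individual keeps a nonzero probability.
    """
    h = np.asarray(objectives, dtype=float)
    if h.size == 0:
        raise ValueError("empty objective list")
    h_worst = float(np.max(h))
    delta = 1e-9 * max(1.0, abs(h_worst))
    fitness = (h_worst - h) + delta
    return fitness / fitness.sum()


def crossover_blx(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    alpha: float,
    bounds: BoundsSet,
    rng: np.random.Generator,
) -> np.ndarray:
    """Blend crossover: each child component is sampled uniformly from the
    parents' interval extended by alpha times its width, then clipped."""
    lo = np.minimum(parent_a, parent_b)
    hi = np.maximum(parent_a, parent_b)
    span = hi - lo
    child = rng.uniform(lo - alpha * span, hi + alpha * span)
    return np.clip(child, bounds.lower, bounds.upper)


def mutate_nonuniform(
    x: np.ndarray,
    generation: int,
    total_generations: int,
    bounds: BoundsSet,
    shape: float,
    rng: np.random.Generator,
    rate: float | None = None,
) -> np.ndarray:
    """Non-uniform mutation with annealed amplitude.

    Each component is mutated independently with probability ``rate``
    (default 1/n).  A mutated component moves toward its upper or lower
    bound (equal probability) by y * (1 - r^((1 - t/T)^shape)) with
    y the headroom to that bound and r uniform on [0, 1]; the step
    shrinks to zero as t approaches T.
    """
    n = x.size
    p = 1.0 / n if rate is None else rate
    mask = rng.random(n) < p
    up = rng.random(n) < 0.5
    r = rng.random(n)
    frac = 1.0 - generation / total_generations
    step = 1.0 - r ** (frac**shape)
    delta_up = (bounds.upper - x) * step
    delta_down = (x - bounds.lower) * step
    out = np.where(up, x + delta_up, x - delta_down)
    out = np.where(mask, out, x)
    return np.clip(out, bounds.lower, bounds.upper)


def run(
    config: GAConfig,
    bounds: BoundsSet,
    objective_fn: Callable[[np.ndarray], float],
    injected: Sequence[float] | None = None,
) -> GAResult:
    """Run the genetic algorithm for a fixed number of generations.

    Traces have ``generations + 1`` entries: the initial population plus
    one entry per generation.  Elites carry their cached objective, so
    the best trace is non-increasing.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_elite, n_cross, n_mut = config.pool_sizes()
    pop = init_population(bounds, config, injected, rng)
    h = np.array([objective_fn(ind) for ind in pop], dtype=float)

    best_trace = [float(h.min())]
    worst_trace = [float(h.max())]
    avg_trace = [float(h.mean())]

    n = config.population_size
    for t in range(1, config.generations + 1):
        order = np.argsort(h, kind="stable")
        elites = pop[order[:n_elite]]
        elite_h = h[order[:n_elite]]
        probs = selection_probabilities(h)

        children = np.empty((n_cross, bounds.size))
        for i in range(n_cross):
            ia, ib = rng.choice(n, size=2, p=probs)
            children[i] = crossover_blx(
                pop[ia], pop[ib], config.blx_alpha, bounds, rng
            )
        mutants = np.empty((n_mut, bounds.size))
        for i in range(n_mut):
            j = int(rng.choice(n, p=probs))
            mutants[i] = mutate_nonuniform(
                pop[j],
                t,
                config.generations,
                bounds,
                config.mutation_shape,
                rng,
                config.mutation_rate,
            )

        pop = np.vstack([elites, children, mutants])
        h = np.concatenate(
            [
                elite_h,
                [objective_fn(ind) for ind in children],
                [objective_fn(ind) for ind in mutants],
            ]
        )
        best_trace.append(float(h.min()))
        worst_trace.append(float(h.max()))
        avg_trace.append(float(h.mean()))

    i_best = int(np.argmin(h))
    return GAResult(
        best_vector=pop[i_best].copy(),
        best_h=float(h[i_best]),
        best_trace=np.array(best_trace),
        worst_trace=np.array(worst_trace),
        avg_trace=np.array(avg_trace),
        population=pop,
        objectives=h,
    )
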