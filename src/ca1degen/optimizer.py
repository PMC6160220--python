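"""Multi-objective evolutionary search over bounded conductance spaces.

The search follows the standard recipe of evolutionary neuron-model fitting:
log-uniform initialization within bounds, simulated-binary crossover (SBX,
η=10, p=0.7) and bounded polynomial mutation (η=20, per-gene p=1/dim) on the
parameters' working scale, and an indicator-based (IBEA-style, additive-ε)
environmental selection over the per-objective z-score vectors, with an
elitist hall of fame ranked by total score.  Runs are fully reproducible from
their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .objectives import ScoreReport
from .parameters import ParameterSpace

__all__ = [
    "Individual",
    "EvolutionConfig",
    "OptimizationRun",
    "initialize_population",
    "evolve",
    "hall_of_fame",
    "convergence_generation",
]


@dataclass(eq=False)  # identity comparison: vectors make value-equality ambiguous
class Individual:
    params: dict[str, float]
    vector: np.ndarray  # raw scale
    score: ScoreReport | None = None
    generation: int = 0
    index: int = 0  # insertion order within the run

    @property
    def total(self) -> float:
        if self.score is None:
            raise ValueError("individual not evaluated")
        return self.score.total

    @property
    def acceptable(self) -> bool:
        return self.score is not None and self.score.acceptable


@dataclass
class EvolutionConfig:
    pop_size: int = 128
    generations: int = 60
    seed: int = 0
    cx_prob: float = 0.7
    cx_eta: float = 10.0
    mut_eta: float = 20.0
    mut_prob: float | None = None  # default 1/dim
    elitism: bool = True


@dataclass
class OptimizationRun:
    seed: int
    pop_size: int
    etype: str
    history: list[float]  # best total score in the population, per generation
    population: list[Individual]  # final population
    evaluated: list[Individual]  # every individual ever evaluated
    config: EvolutionConfig

    @property
    def best(self) -> Individual:
        return min(self.evaluated, key=_hall_key)

    def hall_of_fame(self, k: int = 10) -> list[Individual]:
        return hall_of_fame(self, k)

    def to_json(self, path: str | Path, hall_size: int = 10) -> None:
        doc = {
            "seed": self.seed,
            "pop_size": self.pop_size,
            "etype": self.etype,
            "generations": len(self.history),
            "history": self.history,
            "hall_of_fame": [
                {
                    "params": ind.params,
                    "total": ind.total,
                    "acceptable": ind.acceptable,
                    "generation": ind.generation,
                    "scores": {f"{k0}@{k1:+g}": v for (k0, k1), v in ind.score.scores.items()},
                }
                for ind in self.hall_of_fame(hall_size)
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def initialize_population(
    space: ParameterSpace, n: int, seed: int | np.random.Generator
) -> list[Individual]:
    """Sample ``n`` individuals uniformly on each entry's scale (log-uniform
    for conductances).  Deterministic given the seed."""
    if n < 2:
        raise ValueError("population size must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vectors = space.sample(n, rng)
    return [
        Individual(params=space.as_dict(v), vector=v, generation=0, index=i)
        for i, v in enumerate(vectors)
    ]


# ---------------------------------------------------------------------------
# Variation operators (on the internal/working scale)


def _sbx(rng, a, b, lo, hi, eta):
    """Simulated binary crossover with bounds (one child pair)."""
    c1, c2 = a.copy(), b.copy()
    for i in range(a.size):
        if rng.random() > 0.5 or abs(a[i] - b[i]) < 1e-14:
            continue
        x1, x2 = min(a[i], b[i]), max(a[i], b[i])
        rand = rng.random()
        beta = 1.0 + (2.0 * (x1 - lo[i]) / (x2 - x1))
        alpha = 2.0 - beta ** -(eta + 1.0)
        betaq = (
            (rand * alpha) ** (1.0 / (eta + 1.0))
            if rand <= 1.0 / alpha
            else (1.0 / (2.0 - rand * alpha)) ** (1.0 / (eta + 1.0))
        )
        ch1 = 0.5 * ((x1 + x2) - betaq * (x2 - x1))
        beta = 1.0 + (2.0 * (hi[i] - x2) / (x2 - x1))
        alpha = 2.0 - beta ** -(eta + 1.0)
        betaq = (
            (rand * alpha) ** (1.0 / (eta + 1.0))
            if rand <= 1.0 / alpha
            else (1.0 / (2.0 - rand * alpha)) ** (1.0 / (eta + 1.0))
        )
        ch2 = 0.5 * ((x1 + x2) + betaq * (x2 - x1))
        ch1, ch2 = np.clip(ch1, lo[i], hi[i]), np.clip(ch2, lo[i], hi[i])
        if rng.random() < 0.5:
            ch1, ch2 = ch2, ch1
        c1[i], c2[i] = ch1, ch2
    return c1, c2


def _polynomial_mutation(rng, x, lo, hi, eta, prob):
    y = x.copy()
    for i in range(x.size):
        if rng.random() >= prob:
            continue
        delta1 = (y[i] - lo[i]) / (hi[i] - lo[i])
        delta2 = (hi[i] - y[i]) / (hi[i] - lo[i])
        rand = rng.random()
        mut_pow = 1.0 / (eta + 1.0)
        if rand < 0.5:
            val = 2.0 * rand + (1.0 - 2.0 * rand) * (1.0 - delta1) ** (eta + 1.0)
            deltaq = val**mut_pow - 1.0
        else:
            val = 2.0 * (1.0 - rand) + 2.0 * (rand - 0.5) * (1.0 - delta2) ** (eta + 1.0)
            deltaq = 1.0 - val**mut_pow
        y[i] = np.clip(y[i] + deltaq * (hi[i] - lo[i]), lo[i], hi[i])
    return y


# ---------------------------------------------------------------------------
# IBEA-style selection


def _ibea_fitness(F: np.ndarray, kappa: float = 0.05) -> np.ndarray:
    """Additive-ε indicator fitness; larger is better."""
    n = F.shape[0]
    span = F.max(axis=0) - F.min(axis=0)
    span[span == 0] = 1.0
    Fn = (F - F.min(axis=0)) / span
    # eps[i, j] = min amount by which i must improve to weakly dominate j
    eps = np.empty((n, n))
    for i in range(n):
        eps[i] = np.max(Fn[i] - Fn, axis=1)
    c = np.abs(eps).max()
    if c == 0:
        c = 1.0
    expo = np.exp(-eps / (c * kappa))
    np.fill_diagonal(expo, 0.0)
    return -expo.sum(axis=0)


def _environmental_selection(pop: list[Individual], zvecs: np.ndarray, n: int) -> list[int]:
    """Iteratively drop the worst-fitness index until ``n`` remain."""
    alive = list(range(len(pop)))
    while len(alive) > n:
        fit = _ibea_fitness(zvecs[alive])
        worst = int(np.argmin(fit))
        alive.pop(worst)
    return alive


def _hall_key(ind: Individual):
    return (ind.total, ind.generation, ind.index)


def _zvec(report: ScoreReport, keys: list) -> np.ndarray:
    return np.array([report.scores[k] for k in keys])


def evolve(
    space: ParameterSpace,
    evaluator: Callable[[dict[str, float]], ScoreReport],
    config: EvolutionConfig | None = None,
    etype: str = "unknown",
) -> OptimizationRun:
    """Run a seeded (µ+λ) evolution and return its full history.

    ``evaluator`` maps a parameter dict to a :class:`ScoreReport`; evaluation
    failures must already be absorbed as penalty reports.  With elitism the
    per-generation best-total history is non-increasing.
    """
    cfg = config or EvolutionConfig()
    if cfg.pop_size < 4:
        raise ValueError("pop_size must be >= 4")
    if cfg.generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = space.internal_bounds()
    mut_prob = cfg.mut_prob if cfg.mut_prob is not None else 1.0 / space.dim

    counter = 0

    def make(vec_internal: np.ndarray, gen: int) -> Individual:
        nonlocal counter
        raw = space.from_internal(vec_internal)
        ind = Individual(params=space.as_dict(raw), vector=raw, generation=gen, index=counter)
        counter += 1
        return ind

    population = initialize_population(space, cfg.pop_size, rng)
    counter = len(population)
    evaluated: list[Individual] = []
    score_keys: list | None = None

    def eval_all(inds: list[Individual]) -> None:
        nonlocal score_keys
        for ind in inds:
            ind.score = evaluator(ind.params)
            if score_keys is None:
                score_keys = sorted(ind.score.scores.keys(), key=repr)
            evaluated.append(ind)

    eval_all(population)
    history = [min(ind.total for ind in population)]

    for gen in range(1, cfg.generations):
        # variation: random pairing of the current population
        order = rng.permutation(cfg.pop_size)
        offspring: list[Individual] = []
        for i in range(0, cfg.pop_size - 1, 2):
            p1 = space.to_internal(population[order[i]].vector)
            p2 = space.to_internal(population[order[i + 1]].vector)
            if rng.random() < cfg.cx_prob:
                c1, c2 = _sbx(rng, p1, p2, lo, hi, cfg.cx_eta)
            else:
                c1, c2 = p1.copy(), p2.copy()
            c1 = _polynomial_mutation(rng, c1, lo, hi, cfg.mut_eta, mut_prob)
            c2 = _polynomial_mutation(rng, c2, lo, hi, cfg.mut_eta, mut_prob)
            offspring.append(make(c1, gen))
            offspring.append(make(c2, gen))
        if len(offspring) < cfg.pop_size:  # odd pop size: mutate a random parent
            p = space.to_internal(population[int(rng.integers(cfg.pop_size))].vector)
            offspring.append(make(_polynomial_mutation(rng, p, lo, hi, cfg.mut_eta, mut_prob), gen))
        eval_all(offspring)

        pool = population + offspring
        zmat = np.vstack([_zvec(ind.score, score_keys) for ind in pool])
        keep = _environmental_selection(pool, zmat, cfg.pop_size)
        population = [pool[i] for i in keep]

        if cfg.elitism:
            best = min(evaluated, key=_hall_key)
            if best not in population:
                worst = max(range(len(population)), key=lambda i: _hall_key(population[i]))
                population[worst] = best
        history.append(min(ind.total for ind in population))

    return OptimizationRun(
        seed=cfg.seed,
        pop_size=cfg.pop_size,
        etype=etype,
        history=history,
        population=population,
        evaluated=evaluated,
        config=cfg,
    )


def convergence_generation(history: list[float], rel_tol: float = 0.05) -> int:
    """First generation (1-based) at which the best-score history enters
    within ``rel_tol`` of its final stable minimum and stays there."""
    h = np.asarray(history, dtype=float)
    final = h.min()
    within = h <= final * (1.0 + rel_tol)
    return int(np.argmax(within)) + 1


def hall_of_fame(run: OptimizationRun, k: int = 10) -> list[Individual]:
    """The k best-scoring individuals of a run, ascending by total score;
    ties broken by earlier generation, then insertion order."""
    pool = sorted(run.evaluated, key=_hall_key)
    if k > len(pool):
        import warnings

        warnings.warn(f"requested {k} individuals but only {len(pool)} evaluated")
        return pool
    return pool[:k]
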