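"""Manta Ray Foraging Optimization (MRFO).

A population metaheuristic with three position-update rules mimicking manta
ray feeding behaviour:

* chain foraging   — members move toward the best-known solution and the
  member ahead of them in the chain;
* cyclone foraging — spiral movement around the best solution (exploitation)
  or around a random reference point (exploration, favoured early);
* somersault foraging — a flip around the best solution scaled by the
  somersault factor S.

All positions live in the unit hypercube [0, 1]^D and are decoded to typed
hyperparameter values through a :class:`~retinopt.search_space.SearchSpace`.
Minimization is the internal convention; maximization objectives are negated
by the caller.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

from .search_space import SearchSpace

logger = logging.getLogger(__name__)

Objective = Callable[[dict[str, Any]], float]

_LOG_FLOOR = 1e-12  # floor for the uniform draw inside sqrt(|log r|)


@dataclass
class MRFOConfig:
    """Run settings: iteration budget, population size, somersault factor S."""

    max_iter: int = 50
    pop_size: int = 20
    somersault_factor: float = 2.0
    seed: int = 0
    minimize: bool = True
    canonical_chain: bool = False  # reuse one draw as both rn and r in chain foraging

    def __post_init__(self) -> None:
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.somersault_factor <= 0:
            raise ValueError("somersault_factor must be > 0")


@dataclass
class Candidate:
    """A manta ray: unit-cube position, decoded values, objective value."""

    position: np.ndarray
    typed_values: dict[str, Any]
    fitness: float | None = None

    @classmethod
    def from_position(cls, coords: np.ndarray, space: SearchSpace) -> "Candidate":
        coords = np.clip(np.asarray(coords, dtype=float), 0.0, 1.0)
        return cls(position=coords, typed_values=space.decode(coords))

    def copy(self) -> "Candidate":
        return Candidate(self.position.copy(), dict(self.typed_values), self.fitness)


@dataclass
class Population:
    members: list[Candidate]
    gbest: Candidate
    iteration: int = 0

    @property
    def size(self) -> int:
        return len(self.members)

    def refresh_gbest(self) -> None:
        for m in self.members:
            if m.fitness is not None and m.fitness < self.gbest.fitness:
                self.gbest = m.copy()


@dataclass
class OptResult:
    """Best candidate found, per-iteration best-fitness trace, bookkeeping."""

    best: Candidate
    history: list[float]
    evaluations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "best_values": {k: _jsonable(v) for k, v in self.best.typed_values.items()},
            "best_fitness": self.best.fitness,
            "history": list(self.history),
            "evaluations": self.evaluations,
            "seed": self.seed,
        }


def _jsonable(v: Any):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


# ---------------------------------------------------------------------------
# Pure position-update rules (random draws passed in, so each can be checked
# against hand-evaluated scalar cases).
# ---------------------------------------------------------------------------

def chain_step(
    p: np.ndarray,
    chain_prev: np.ndarray,
    gbest: np.ndarray,
    rn: float,
    r: float,
) -> np.ndarray:
    """Chain-foraging update.

    ``chain_prev`` is the member ahead in the chain (the best solution for
    the leading member).  ``r`` feeds the sqrt(|log r|) weight and must be
    positive; draws of exactly zero are floored upstream.
    """
    alpha = 2.0 * rn * np.sqrt(np.abs(np.log(r)))
    new = p + rn * (chain_prev - p) + alpha * (gbest - p)
    return np.clip(new, 0.0, 1.0)


def _spiral(rn: float, itr: int, max_itr: int) -> float:
    return 2.0 * np.exp(rn * (max_itr - itr + 1) / max_itr) * np.sin(2.0 * np.pi * rn)


def cyclone_step(
    p: np.ndarray,
    chain_prev: np.ndarray,
    gbest: np.ndarray,
    rn: float,
    itr: int,
    max_itr: int,
) -> np.ndarray:
    """Cyclone-foraging update spiralling around the best solution."""
    beta = _spiral(rn, itr, max_itr)
    new = gbest + rn * (chain_prev - p) + beta * (gbest - p)
    return np.clip(new, 0.0, 1.0)


def cyclone_explore_step(
    p: np.ndarray,
    chain_prev: np.ndarray,
    p_ref: np.ndarray,
    rn: float,
    itr: int,
    max_itr: int,
) -> np.ndarray:
    """Exploratory cyclone update anchored on a random reference point.

    ``p_ref`` is drawn uniformly in the unit cube (the internal image of
    LowerBound + rn * (UpperBound - LowerBound)).  The leading member passes
    ``chain_prev = p_ref`` so its chain term vanishes.
    """
    beta = _spiral(rn, itr, max_itr)
    new = p_ref + rn * (chain_prev - p) + beta * (p_ref - p)
    return np.clip(new, 0.0, 1.0)


def somersault_step(
    p: np.ndarray,
    gbest: np.ndarray,
    somersault_factor: float,
    rn1: float,
    rn2: float,
) -> np.ndarray:
    """Somersault update: flip around the best solution, scaled by S."""
    new = p + somersault_factor * (rn1 * gbest - rn2 * p)
    return np.clip(new, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Population-level machinery
# ---------------------------------------------------------------------------

def evaluate(cand: Candidate, objective: Objective, minimize: bool = True) -> bool:
    """Evaluate a candidate in place; returns False on a non-finite value."""
    val = objective(cand.typed_values)
    val = float(val) if minimize else -float(val)
    if not np.isfinite(val):
        warnings.warn("objective returned a non-finite value; candidate rejected")
        return False
    cand.fitness = val
    return True


def init_population(
    space: SearchSpace,
    objective: Objective,
    config: MRFOConfig,
    rng: np.random.Generator,
) -> tuple[Population, int]:
    """Plain uniform initialization; returns (population, evaluation count)."""
    members = []
    for _ in range(config.pop_size):
        cand = Candidate.from_position(rng.uniform(size=space.dimension), space)
        evaluate(cand, objective, config.minimize)
        members.append(cand)
    evals = len(members)
    best = min(
        (m for m in members if m.fitness is not None), key=lambda m: m.fitness
    ).copy()
    return Population(members, best, iteration=0), evals


def _draw_r(rng: np.random.Generator) -> float:
    r = rng.uniform()
    return max(r, _LOG_FLOOR)


def propose_position(
    pop: Population,
    k: int,
    config: MRFOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One foraging-phase proposal for member ``k`` (0-based index).

    With probability 0.5 cyclone foraging is used, taking the exploratory
    random-reference variant while itr/MaxItr < rand (early iterations),
    otherwise the spiral around the best solution; the other half of the
    time chain foraging is used.
    """
    p = pop.members[k].position
    gbest = pop.gbest.position
    chain_prev = gbest if k == 0 else pop.members[k - 1].position
    if rng.uniform() < 0.5:
        rn = rng.uniform()
        if pop.iteration / max(config.max_iter, 1) < rng.uniform():
            p_ref = rng.uniform(size=p.shape)
            prev = p_ref if k == 0 else chain_prev
            return cyclone_explore_step(p, prev, p_ref, rn, pop.iteration + 1, config.max_iter)
        return cyclone_step(p, chain_prev, gbest, rn, pop.iteration + 1, config.max_iter)
    rn = rng.uniform()
    r = rn if config.canonical_chain else _draw_r(rng)
    return chain_step(p, chain_prev, gbest, rn, r)


def _greedy_replace(
    pop: Population,
    k: int,
    new_pos: np.ndarray,
    space: SearchSpace,
    objective: Objective,
    config: MRFOConfig,
) -> int:
    """Evaluate a proposal and keep it only if it improves member k."""
    cand = Candidate.from_position(new_pos, space)
    ok = evaluate(cand, objective, config.minimize)
    current = pop.members[k].fitness
    if ok and (current is None or cand.fitness < current):
        pop.members[k] = cand
    return 1


def mrfo_iteration(
    pop: Population,
    space: SearchSpace,
    objective: Objective,
    config: MRFOConfig,
    rng: np.random.Generator,
) -> int:
    """One full MRFO generation; returns the number of objective calls.

    Foraging proposals with greedy acceptance, a best-solution refresh, then
    a somersault pass over all members with the same greedy acceptance.
    """
    evals = 0
    for k in range(pop.size):
        new_pos = propose_position(pop, k, config, rng)
        evals += _greedy_replace(pop, k, new_pos, space, objective, config)
    pop.refresh_gbest()
    for k in range(pop.size):
        rn1, rn2 = rng.uniform(), rng.uniform()
        new_pos = somersault_step(
            pop.members[k].position, pop.gbest.position, config.somersault_factor, rn1, rn2
        )
        evals += _greedy_replace(pop, k, new_pos, space, objective, config)
    pop.refresh_gbest()
    pop.iteration += 1
    return evals


def mrfo_run(
    space: SearchSpace,
    objective: Objective,
    config: MRFOConfig,
    rng: np.random.Generator | None = None,
) -> OptResult:
    """Run plain MRFO from uniform initialization."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pop, evals = init_population(space, objective, config, rng)
    history = [pop.gbest.fitness]
    for _ in range(config.max_iter):
        evals += mrfo_iteration(pop, space, objective, config, rng)
        history.append(pop.gbest.fitness)
    return OptResult(best=pop.gbest.copy(), history=history, evaluations=evals, seed=config.seed)
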