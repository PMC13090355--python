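"""Improved MRFO: MRFO with opposition-based initialization and partial
centroid opposition generation jumping.

The improvements over plain MRFO are two population-level moves:

* **opposition-based initialization** — sample N uniform candidates, add
  their centroid opposites, evaluate all 2N and keep the best N;
* **generation jumping** — with probability P_gj per iteration, replace the
  ordinary foraging generation by a diversification step: for every member
  compute its centroid opposite and several partial centroid opposites,
  then truncate the pooled candidates back to the best N.

Both moves use truncation selection, so the best-so-far fitness can never
worsen.
"""

from __future__ import annotations

import numpy as np

from .mrfo import (
    Candidate,
    MRFOConfig,
    Objective,
    OptResult,
    Population,
    evaluate,
    mrfo_iteration,
)
from .opposition import OppositionConfig, centroid_opposite, pcobl_opposites
from .search_space import SearchSpace


def _best_n(candidates: list[Candidate], n: int) -> list[Candidate]:
    """Truncation selection: stable sort by fitness, input order breaks ties."""
    valid = [c for c in candidates if c.fitness is not None]
    return sorted(valid, key=lambda c: c.fitness)[:n]


def opposition_init(
    space: SearchSpace,
    objective: Objective,
    config: MRFOConfig,
    rng: np.random.Generator,
) -> tuple[Population, int]:
    """Centroid-opposition-enriched initialization.

    Returns the truncated population of size N and the evaluation count (2N).
    """
    raw = [
        Candidate.from_position(rng.uniform(size=space.dimension), space)
        for _ in range(config.pop_size)
    ]
    positions = np.array([c.position for c in raw])
    opposites = [
        Candidate.from_position(centroid_opposite(positions, c.position), space)
        for c in raw
    ]
    pool = raw + opposites
    evals = 0
    for c in pool:
        evaluate(c, objective, config.minimize)
        evals += 1
    members = _best_n(pool, config.pop_size)
    best = members[0].copy()
    return Population(members, best, iteration=0), evals


def generation_jump(
    pop: Population,
    space: SearchSpace,
    objective: Objective,
    opp_cfg: OppositionConfig,
    config: MRFOConfig,
    rng: np.random.Generator,
) -> int:
    """One generation-jumping step; returns the number of objective calls.

    The candidate pool before truncation holds N originals, N centroid
    opposites and N * n_partial partial centroid opposites.
    """
    n = pop.size
    n_partial = opp_cfg.resolve_n_partial(space.dimension)
    positions = np.array([m.position for m in pop.members])
    pool: list[Candidate] = list(pop.members)
    evals = 0
    for m in pop.members:
        opp = Candidate.from_position(centroid_opposite(positions, m.position), space)
        evaluate(opp, objective, config.minimize)
        evals += 1
        pool.append(opp)
        for v in pcobl_opposites(positions, m.position, n_partial, rng):
            part = Candidate.from_position(v, space)
            evaluate(part, objective, config.minimize)
            evals += 1
            pool.append(part)
    pop.members = _best_n(pool, n)
    pop.refresh_gbest()
    pop.iteration += 1
    return evals


def imrfo_run(
    space: SearchSpace,
    objective: Objective,
    config: MRFOConfig,
    opp_cfg: OppositionConfig | None = None,
    rng: np.random.Generator | None = None,
) -> OptResult:
    """Full IMRFO loop: opposition init, then per iteration either a
    generation jump (probability P_gj) or a standard MRFO generation."""
    opp_cfg = OppositionConfig() if opp_cfg is None else opp_cfg
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pop, evals = opposition_init(space, objective, config, rng)
    history = [pop.gbest.fitness]
    for _ in range(config.max_iter):
        if rng.uniform() < opp_cfg.jump_probability:
            evals += generation_jump(pop, space, objective, opp_cfg, config, rng)
        else:
            evals += mrfo_iteration(pop, space, objective, config, rng)
        history.append(pop.gbest.fitness)
    return OptResult(best=pop.gbest.copy(), history=history, evaluations=evals, seed=config.seed)
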