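"""Opposition-based learning (OBL) and its centroid / partial variants.

Opposition schemes diversify a population by reflecting candidate solutions:

* OBL reflects a point through the midpoint of its box bounds,
  ``x_opp_i = a_i + b_i - x_i``;
* COBL reflects through the population centroid M, ``x_opp = 2M - x``;
* POBL keeps a subset of original coordinates and takes opposite values on
  the rest, producing a spectrum from exploitative (most coordinates kept)
  to exploratory (few kept);
* PCOBL combines the two: partial opposites whose flipped coordinates come
  from the centroid reflection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class OppositionConfig:
    """Generation-jumping probability and the partial-opposite budget."""

    jump_probability: float = 0.3
    n_partial: int | None = None  # default min(D, 5), resolved at run time
    retain_rule: str = "uniform-proper-subset"

    def __post_init__(self) -> None:
        if not 0.0 <= self.jump_probability <= 1.0:
            raise ValueError("jump_probability must be in [0, 1]")
        if self.n_partial is not None and self.n_partial < 1:
            raise ValueError("n_partial must be >= 1")

    def resolve_n_partial(self, dimension: int) -> int:
        return min(dimension, 5) if self.n_partial is None else self.n_partial


def obl_opposite(x: np.ndarray, lower: np.ndarray | float, upper: np.ndarray | float) -> np.ndarray:
    """Box-bound opposite: reflect each coordinate through (a_i + b_i) / 2."""
    x = np.asarray(x, dtype=float)
    lower = np.broadcast_to(np.asarray(lower, dtype=float), x.shape)
    upper = np.broadcast_to(np.asarray(upper, dtype=float), x.shape)
    if np.any(x < lower) or np.any(x > upper):
        raise ValueError("point outside its bounds")
    return lower + upper - x


def population_centroid(positions: np.ndarray) -> np.ndarray:
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("empty population")
    return positions.mean(axis=0)


def centroid_opposite(
    positions: np.ndarray,
    x: np.ndarray,
    lower: np.ndarray | float = 0.0,
    upper: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Centroid opposite 2M - x, clipped to the static search bounds."""
    m = population_centroid(positions)
    return np.clip(2.0 * m - np.asarray(x, dtype=float), lower, upper)


def partial_opposites(x: np.ndarray, x_opp: np.ndarray, degree: int = 1) -> list[np.ndarray]:
    """All partial opposites keeping exactly ``degree`` original coordinates.

    For degree 1 this is the D vectors each retaining one original
    coordinate and taking opposite values elsewhere; in general there are
    C(D, degree) of them.  ``degree >= D`` would return the original point
    and is rejected.
    """
    x = np.asarray(x, dtype=float)
    x_opp = np.asarray(x_opp, dtype=float)
    if x.shape != x_opp.shape:
        raise ValueError("point and opposite must share a dimension")
    d = x.shape[0]
    if not 1 <= degree < d:
        raise ValueError(f"degree must satisfy 1 <= degree < D={d}")
    out = []
    for keep in combinations(range(d), degree):
        v = x_opp.copy()
        v[list(keep)] = x[list(keep)]
        out.append(v)
    return out


def pcobl_opposites(
    positions: np.ndarray,
    x: np.ndarray,
    n_partial: int,
    rng: np.random.Generator,
    lower: np.ndarray | float = 0.0,
    upper: np.ndarray | float = 1.0,
) -> list[np.ndarray]:
    """Partial centroid opposites of ``x`` with respect to a population.

    Computes the full centroid opposite, then emits ``n_partial`` vectors,
    each retaining a uniformly sampled non-empty proper subset of the
    original coordinates and taking centroid-opposite values on the rest.
    A 1-D space degenerates to the full centroid opposite.
    """
    x = np.asarray(x, dtype=float)
    x_opp = centroid_opposite(positions, x, lower, upper)
    d = x.shape[0]
    if d == 1:
        logger.info("1-D space: partial centroid opposition degenerates to COBL")
        return [x_opp.copy()]
    out = []
    for _ in range(n_partial):
        size = int(rng.integers(1, d))  # non-empty proper subset
        keep = rng.choice(d, size=size, replace=False)
        v = x_opp.copy()
        v[keep] = x[keep]
        out.append(v)
    return out
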