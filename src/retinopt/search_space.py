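"""Mixed-variable search spaces and their unit-hypercube encoding.

The optimizer works internally on vectors in [0, 1]^D.  Each coordinate is
decoded to its typed value (continuous, integer, categorical or boolean)
through the affine / binning maps defined here, so the position-update
arithmetic never has to know about variable kinds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

VALID_KINDS = ("continuous", "integer", "categorical", "boolean")


@dataclass(frozen=True)
class ParamSpec:
    """One hyperparameter: its kind and domain.

    ``lower``/``upper`` are the bounds a_i, b_i for continuous and integer
    parameters; ``choices`` is the ordered label list for categoricals.
    Booleans have the implicit domain {False, True}.
    """

    name: str
    kind: str
    lower: float | None = None
    upper: float | None = None
    choices: tuple[Any, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind in ("continuous", "integer"):
            if self.lower is None or self.upper is None:
                raise ValueError(f"{self.name}: bounds required for {self.kind}")
            if not self.lower < self.upper:
                raise ValueError(f"{self.name}: need lower < upper")
        if self.kind == "categorical":
            if not self.choices:
                raise ValueError(f"{self.name}: categorical needs choices")
            if len(set(map(str, self.choices))) != len(self.choices):
                raise ValueError(f"{self.name}: duplicate choices")
            object.__setattr__(self, "choices", tuple(self.choices))

    def decode(self, c: float) -> Any:
        """Map a unit coordinate c in [0, 1] to this parameter's value."""
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"{self.name}: coordinate {c} outside [0, 1]")
        if self.kind == "continuous":
            return self.lower + c * (self.upper - self.lower)
        if self.kind == "integer":
            v = round(self.lower + c * (self.upper - self.lower))
            return int(min(max(v, self.lower), self.upper))
        if self.kind == "categorical":
            idx = min(int(c * len(self.choices)), len(self.choices) - 1)
            return self.choices[idx]
        return bool(c >= 0.5)


@dataclass(frozen=True)
class SearchSpace:
    """Ordered collection of ParamSpecs; order fixes the coordinate index."""

    params: tuple[ParamSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(self.params))
        if len(self.params) < 1:
            raise ValueError("search space needs at least one parameter")
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")

    @property
    def dimension(self) -> int:
        return len(self.params)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    def decode(self, coords: Sequence[float]) -> dict[str, Any]:
        """Decode a unit-hypercube position into a name -> value mapping."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.dimension,):
            raise ValueError(
                f"position has shape {coords.shape}, space dimension is {self.dimension}"
            )
        return {p.name: p.decode(c) for p, c in zip(self.params, coords)}

    @classmethod
    def from_dicts(cls, entries: Sequence[dict]) -> "SearchSpace":
        specs = []
        for e in entries:
            specs.append(
                ParamSpec(
                    name=e["name"],
                    kind=e["kind"],
                    lower=e.get("lower"),
                    upper=e.get("upper"),
                    choices=tuple(e["choices"]) if "choices" in e else None,
                )
            )
        return cls(tuple(specs))

    @classmethod
    def from_file(cls, path: str | Path) -> "SearchSpace":
        """Load a space from a YAML or JSON list of parameter entries."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dicts(data)


def default_search_space() -> SearchSpace:
    """The packaged hyperparameter space for fundus-classifier tuning.

    Covers the geometric-augmentation ranges, flip switches, optimizer
    choice, batch size, transfer-learning ratio and learning rate.
    """
    path = Path(__file__).parent / "data" / "search_space.yaml"
    return SearchSpace.from_file(path)
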