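"""Analytic benchmark objectives for exercising the optimizers.

Provides the classic sphere / Rastrigin / Rosenbrock test functions over a
configurable box, plus a smooth hyperparameter-proxy objective with a
planted optimum over the packaged tuning space, so optimizer behaviour can
be checked in milliseconds instead of through classifier training.
"""

from __future__ import annotations

from typing import Any, Callable

import numpy as np

from .search_space import ParamSpec, SearchSpace


def vector_space(dimension: int, lower: float = -5.0, upper: float = 5.0) -> SearchSpace:
    """A purely continuous box [lower, upper]^D."""
    return SearchSpace(
        tuple(
            ParamSpec(name=f"x{i}", kind="continuous", lower=lower, upper=upper)
            for i in range(dimension)
        )
    )


def _as_array(values: dict[str, Any]) -> np.ndarray:
    return np.array([values[k] for k in sorted(values, key=lambda s: int(s[1:]))])


def sphere(values: dict[str, Any]) -> float:
    """Sum of squares; global minimum 0 at the origin."""
    x = _as_array(values)
    return float(np.sum(x**2))


def rastrigin(values: dict[str, Any]) -> float:
    """Highly multimodal; global minimum 0 at the origin."""
    x = _as_array(values)
    return float(10 * x.size + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))


def rosenbrock(values: dict[str, Any]) -> float:
    """Banana valley; global minimum 0 at the all-ones point."""
    x = _as_array(values)
    return float(np.sum(100 * (x[1:] - x[:-1] ** 2) ** 2 + (1 - x[:-1]) ** 2))


# Planted optimum for the proxy objective over the packaged tuning space.
PROXY_OPTIMUM: dict[str, Any] = {
    "rotation": 15.0,
    "width_shift": 0.1,
    "height_shift": 0.1,
    "zoom": 0.05,
    "shear": 0.05,
    "h_flip": True,
    "v_flip": False,
    "optimizer": "Adam",
    "batch_size": 32,
    "tl_learn_ratio": 20.0,
    "learning_rate": 0.001,
}


def hyperparameter_proxy(values: dict[str, Any]) -> float:
    """Deterministic stand-in for a training-and-validate objective.

    A smooth quadratic bowl over the tuning space with its minimum (value 0)
    planted at :data:`PROXY_OPTIMUM`.  Continuous parameters contribute
    squared normalized distance; categoricals and booleans contribute a unit
    penalty when they miss the planted choice.  Learning rate is compared on
    a log scale, matching how its effect actually behaves.
    """
    cost = 0.0
    ranges = {
        "rotation": 30.0,
        "width_shift": 0.2,
        "height_shift": 0.2,
        "zoom": 0.2,
        "shear": 0.2,
        "tl_learn_ratio": 30.0,
    }
    for name, span in ranges.items():
        cost += ((values[name] - PROXY_OPTIMUM[name]) / span) ** 2
    lr = np.log10(values["learning_rate"]) - np.log10(PROXY_OPTIMUM["learning_rate"])
    cost += float(lr**2)
    for name in ("h_flip", "v_flip", "optimizer", "batch_size"):
        cost += 0.0 if values[name] == PROXY_OPTIMUM[name] else 1.0
    return cost


def objective_suite() -> dict[str, Callable[[dict[str, Any]], float]]:
    """Named objectives for optimizer tests."""
    return {
        "sphere": sphere,
        "rastrigin": rastrigin,
        "rosenbrock": rosenbrock,
        "hyperparameter_proxy": hyperparameter_proxy,
    }
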