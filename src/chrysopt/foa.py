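"""Fruit-fly optimization algorithm (FOA) over the 11 protocol factors.

FOA is a swarm metaheuristic modeled on fruit flies homing in on a smell:
each fly perturbs the swarm axis by a random flight offset, its distance to
the origin Dist_i = sqrt(X_i^2 + Y_i^2) yields a smell-concentration
decision value S_i = 1/Dist_i, the decision value is decoded into a
candidate protocol, and the candidate's objective value (the "smell") pulls
the swarm axis to the best fly.  The classic formulation is scalar; here
every decision variable keeps its own independent (x, y) pair — the
standard multi-dimensional extension — and each dimension's S decodes
through that variable's own bounds.

The incumbent best is retained (elitist update: the axis moves only when a
fly improves on it), so the best-smell trace is non-decreasing and the
objective is evaluated exactly maxgen x sizepop times per run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "FOAConfig",
    "SwarmState",
    "FOAResult",
    "init_swarm",
    "smell_decision_value",
    "decode_candidate",
    "step",
    "optimize",
]

_DIST_FLOOR = 1e-12


class BoundsError(ValueError):
    """Invalid decision-variable bounds."""


@dataclass(frozen=True)
class FOAConfig:
    """Swarm parameters; the defaults are the study configuration
    (maxgen 100, sizepop 10, flight range [-10, 10], axis init in [0, 1])."""

    maxgen: int = 100
    sizepop: int = 10
    fr: tuple[float, float] = (-10.0, 10.0)
    axis_init: tuple[float, float] = (0.0, 1.0)
    dimensions: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.maxgen < 1 or self.sizepop < 1 or self.dimensions < 1:
            raise ValueError("maxgen, sizepop and dimensions must be >= 1")
        if abs(self.fr[0] + self.fr[1]) > 1e-12:
            raise ValueError(f"flight range {self.fr} must be symmetric about 0")


@dataclass
class SwarmState:
    x: np.ndarray  # (sizepop, dims) fly x-coordinates
    y: np.ndarray  # (sizepop, dims)
    axis_x: np.ndarray  # (dims,) swarm axis
    axis_y: np.ndarray
    dist: np.ndarray | None = None  # (sizepop, dims)
    s: np.ndarray | None = None  # smell-concentration decision values
    smell: np.ndarray | None = None  # (sizepop,) fitness
    best_smell: float = -np.inf
    best_index: int | None = None
    best_candidate: np.ndarray | None = None
    generation: int = 0
    evaluations: int = 0


@dataclass
class FOAResult:
    best_inputs: np.ndarray
    best_predicted_efficiency: float
    history: list[float]
    evaluations: int


def init_swarm(config: FOAConfig, rng: np.random.Generator) -> SwarmState:
    """Draw the initial per-dimension axis uniformly from ``axis_init``;
    no fitness is evaluated yet."""
    lo, hi = config.axis_init
    axis_x = rng.uniform(lo, hi, size=config.dimensions)
    axis_y = rng.uniform(lo, hi, size=config.dimensions)
    return SwarmState(
        x=np.tile(axis_x, (config.sizepop, 1)),
        y=np.tile(axis_y, (config.sizepop, 1)),
        axis_x=axis_x,
        axis_y=axis_y,
        dist=None,
        s=None,
        smell=np.full(config.sizepop, -np.inf),
        generation=0,
    )


def smell_decision_value(x_coord: np.ndarray, y_coord: np.ndarray) -> np.ndarray:
    """S = 1/Dist with Dist = sqrt(x^2 + y^2), floored at 1e-12 so a fly at
    the origin never yields an infinite decision value."""
    dist = np.sqrt(np.asarray(x_coord, float) ** 2 + np.asarray(y_coord, float) ** 2)
    dist = np.maximum(dist, _DIST_FLOOR)
    return 1.0 / dist


def decode_candidate(
    s: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    categorical_spec: Mapping[int, int] | None = None,
) -> np.ndarray:
    """Map per-dimension decision values to a candidate input vector.

    Continuous dimension j: low + clamp01(s_j) * (high - low), i.e. the
    decision value is read against the magnitude at unit distance (s_ref=1)
    and clamped into the box.  A categorical dimension (the strain) is then
    rounded to the nearest valid integer code.
    """
    s = np.atleast_2d(np.asarray(s, dtype=float))
    out = np.empty_like(s)
    for j, (lo, hi) in enumerate(bounds):
        if lo > hi:
            raise BoundsError(f"dimension {j}: low {lo} > high {hi}")
        out[:, j] = lo + np.clip(s[:, j], 0.0, 1.0) * (hi - lo)
    for j, n_codes in (categorical_spec or {}).items():
        lo, hi = bounds[j]
        out[:, j] = np.clip(np.rint(out[:, j]), max(lo, 0), min(hi, n_codes - 1))
    return out


def step(
    swarm: SwarmState,
    objective: Callable[[np.ndarray], np.ndarray],
    bounds: Sequence[tuple[float, float]],
    config: FOAConfig,
    rng: np.random.Generator,
    categorical_spec: Mapping[int, int] | None = None,
) -> SwarmState:
    """One generation: random flights, decode, evaluate, elitist axis update.

    ``objective`` receives the (sizepop, dims) matrix of decoded candidates
    and returns one fitness per fly; non-finite fitnesses are excluded from
    the argmax.  Ties at the argmax resolve to the lowest fly index.
    """
    lo, hi = config.fr
    shape = (config.sizepop, config.dimensions)
    swarm.x = swarm.axis_x + rng.uniform(lo, hi, size=shape)
    swarm.y = swarm.axis_y + rng.uniform(lo, hi, size=shape)
    swarm.dist = np.sqrt(swarm.x**2 + swarm.y**2)
    swarm.s = smell_decision_value(swarm.x, swarm.y)
    candidates = decode_candidate(swarm.s, bounds, categorical_spec)
    smell = np.asarray(objective(candidates), dtype=float).ravel()
    swarm.evaluations += config.sizepop
    smell = np.where(np.isfinite(smell), smell, -np.inf)
    swarm.smell = smell
    best_index = int(np.argmax(smell))
    if smell[best_index] > swarm.best_smell:
        swarm.best_smell = float(smell[best_index])
        swarm.best_index = best_index
        swarm.best_candidate = candidates[best_index].copy()
        swarm.axis_x = swarm.x[best_index].copy()
        swarm.axis_y = swarm.y[best_index].copy()
    swarm.generation += 1
    return swarm


def optimize(
    objective: Callable[[np.ndarray], np.ndarray],
    bounds: Sequence[tuple[float, float]],
    categorical_spec: Mapping[int, int] | None = None,
    config: FOAConfig = FOAConfig(),
    rng: np.random.Generator | int | None = None,
) -> FOAResult:
    """Run init + maxgen generations; returns the best decoded candidate,
    its objective value and the per-generation best-smell history."""
    if len(bounds) != config.dimensions:
        raise BoundsError(
            f"{len(bounds)} bounds for {config.dimensions} dimensions"
        )
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    swarm = init_swarm(config, rng)
    history: list[float] = []
    for _ in range(config.maxgen):
        swarm = step(swarm, objective, bounds, config, rng, categorical_spec)
        history.append(swarm.best_smell)
    return FOAResult(
        best_inputs=swarm.best_candidate,
        best_predicted_efficiency=swarm.best_smell,
        history=history,
        evaluations=swarm.evaluations,
    )
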