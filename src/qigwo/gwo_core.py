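"""Continuous grey wolf optimizer (GWO) and its binary flag variant (BGWO).

The grey wolf optimizer is a population metaheuristic in which the three
best solutions found so far in the pack -- the alpha, beta and delta wolves
-- steer the remaining (omega) wolves.  Each wolf moves to the average of
three "encircling" steps, one per leader::

    K_l = |C_l * X_l - X|         C_l = 2 r2        (r2 ~ U[0,1]^d)
    X_l'= X_l - A_l * K_l         A_l = 2 a r1 - a  (r1 ~ U[0,1]^d)
    X(t+1) = (X_a' + X_b' + X_d') / 3

with the exploration coefficient ``a`` decaying linearly from 2 to 0 over
the run.  The binary variant keeps the continuous dynamics and decodes a
position into bits only at evaluation time: component j maps to 1 iff it is
strictly greater than 0.5 (the "flag" rule).

Conventions
-----------
* Minimization throughout; objectives return one finite real.
* Out-of-bounds positions are clamped to the configured box.
* Leaders are the three best solutions found so far, re-ranked after every
  iteration (no archive beyond the three); ties are broken by lower wolf
  index / earlier discovery so runs are bit-reproducible under a seed.
* The reported trajectory is the best fitness over everything evaluated so
  far, hence non-increasing.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GwoConfig",
    "Pack",
    "CoefficientSet",
    "OptimizationResult",
    "ObjectiveError",
    "unit_bounds",
    "load_config",
    "coefficient_schedule",
    "encircle_update",
    "flag_binarize",
    "gwo_minimize",
    "bgwo_minimize",
]

Objective = Callable[[np.ndarray], float]


class ObjectiveError(ValueError):
    """Raised when an objective returns a non-finite value."""


@dataclass(frozen=True)
class GwoConfig:
    """Run configuration shared by all wolf-pack optimizers.

    Parameters
    ----------
    population_size:
        Number of wolves; at least 3 so the three leaders exist.
    max_iterations:
        Number of position-update iterations after the initial evaluation.
    bounds:
        Per-dimension ``(lower, upper)`` pairs defining the search box.
    seed:
        Seed for the pseudo-random stream; identical seed + config gives
        bit-identical results.
    """

    population_size: int = 10
    max_iterations: int = 200
    bounds: tuple[tuple[float, float], ...] = ((0.0, 1.0),)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 3:
            raise ValueError("population_size must be >= 3 (alpha, beta, delta)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        for lo, hi in bounds:
            if not lo < hi:
                raise ValueError(f"invalid bounds ({lo}, {hi}): lower must be < upper")
        object.__setattr__(self, "bounds", bounds)

    @property
    def dimension(self) -> int:
        return len(self.bounds)

    def lower(self) -> np.ndarray:
        return np.array([lo for lo, _ in self.bounds])

    def upper(self) -> np.ndarray:
        return np.array([hi for _, hi in self.bounds])


def unit_bounds(dimension: int) -> tuple[tuple[float, float], ...]:
    """Unit box [0,1]^d, the conventional search box for binary decodings."""
    return tuple((0.0, 1.0) for _ in range(dimension))


def load_config(path: str | Path, cls: type = GwoConfig):
    """Read an optimizer config from a ``key = value`` text file.

    Values are Python literals (ints, floats, tuples); ``#`` starts a
    comment.  Keys must be fields of ``cls`` (GwoConfig or a subclass).
    """
    values: dict = {}
    known = {f.name for f in fields(cls)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in known:
            raise ValueError(f"line {lineno}: unknown config key {key!r}")
        values[key] = ast.literal_eval(value.strip())
    return cls(**values)


@dataclass
class Pack:
    """Population state: continuous positions, fitness, ranked leaders."""

    positions: np.ndarray  # (wolves, dimensions)
    fitness: np.ndarray  # (wolves,)
    leader_indices: tuple[int, int, int]  # (alpha, beta, delta)

    @staticmethod
    def rank_leaders(fitness: np.ndarray) -> tuple[int, int, int]:
        # stable sort: equal fitness resolved by lower wolf index
        order = np.argsort(fitness, kind="stable")
        return int(order[0]), int(order[1]), int(order[2])


@dataclass(frozen=True)
class CoefficientSet:
    """One draw of the encircling coefficients for a single leader."""

    a: float
    r1: np.ndarray
    r2: np.ndarray
    A: np.ndarray = field(init=False)
    C: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "A", 2.0 * self.a * self.r1 - self.a)
        object.__setattr__(self, "C", 2.0 * self.r2)


@dataclass
class OptimizationResult:
    """Outcome of one optimizer run.

    ``trajectory[t]`` is the best fitness over all evaluations up to and
    including iteration ``t`` (iteration 0 is the initial population), so it
    is non-increasing and its last entry equals ``best_fitness``.
    ``optimal_iteration`` is the first iteration attaining ``best_fitness``.
    """

    best_position: np.ndarray
    best_fitness: float
    trajectory: np.ndarray
    optimal_iteration: int

    @property
    def evaluations(self) -> int:
        return len(self.trajectory)


def coefficient_schedule(t: int, T: int) -> float:
    """Exploration coefficient ``a`` at iteration ``t`` of ``T``.

    Decays linearly from 2 (full exploration) at t=0 to 0 (pure
    exploitation) at t=T.
    """
    if T < 1:
        raise ValueError("max iterations T must be >= 1")
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, {T}]")
    return 2.0 * (1.0 - t / T)


def encircle_update(
    position: np.ndarray,
    leaders: Sequence[np.ndarray],
    a: float,
    rng: np.random.Generator,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Move one wolf toward the consensus of the three leaders.

    Draw order is fixed: for each leader in (alpha, beta, delta) order, r1
    then r2, each a fresh uniform vector.  The result is clamped to
    ``bounds=(lower, upper)`` when given.
    """
    position = np.asarray(position, dtype=float)
    steps = np.empty((3, position.size))
    for i, leader in enumerate(leaders):
        leader = np.asarray(leader, dtype=float)
        coeff = CoefficientSet(a=a, r1=rng.random(position.size), r2=rng.random(position.size))
        k = np.abs(coeff.C * leader - position)
        steps[i] = leader - coeff.A * k
    new = steps.mean(axis=0)
    if bounds is not None:
        new = np.clip(new, bounds[0], bounds[1])
    return new


def flag_binarize(position: np.ndarray) -> np.ndarray:
    """Flag decoding: bit j is 1 iff position component j is strictly > 0.5."""
    return (np.asarray(position, dtype=float) > 0.5).astype(np.int8)


def _evaluate(objective: Objective, position: np.ndarray, decoded: np.ndarray) -> float:
    value = float(objective(decoded))
    if not np.isfinite(value):
        raise ObjectiveError(
            f"objective returned non-finite value {value!r} at position {decoded.tolist()}"
        )
    return value


def _pack_minimize(
    objective: Objective,
    config: GwoConfig,
    decode: Callable[[np.ndarray], np.ndarray],
    binary: bool = False,
) -> OptimizationResult:
    """Shared GWO loop; ``decode`` maps a continuous position to what the
    objective sees (identity for GWO, flag bits for BGWO).

    On the binary path a wolf whose decoded pattern duplicates one of the
    current leaders' patterns is re-initialized uniformly in the box before
    evaluation: a duplicate contributes no information (the pattern's
    fitness is already held by the leader set), and without the guard the
    pack's decode collapses onto the leader consensus once the exploration
    coefficient ``a`` is small, freezing the search on plateaus of the
    piecewise-constant decoded objective.  Elitism in the leader set keeps
    the best pattern regardless.
    """
    rng = np.random.default_rng(config.seed)
    lower, upper = config.lower(), config.upper()
    n, d = config.population_size, config.dimension

    positions = rng.uniform(lower, upper, size=(n, d))
    fitness = np.empty(n)
    decoded = [decode(positions[i]) for i in range(n)]
    for i in range(n):
        fitness[i] = _evaluate(objective, positions[i], decoded[i])

    # leaders = three best solutions seen so far (elitist), stored as
    # continuous positions; earlier discovery wins ties
    order = Pack.rank_leaders(fitness)
    leader_positions = positions[list(order)].copy()
    leader_fitness = fitness[list(order)].copy()

    best_fitness = float(leader_fitness[0])
    best_position = decoded[order[0]].copy()
    trajectory = [best_fitness]

    for t in range(config.max_iterations):
        a = coefficient_schedule(t, config.max_iterations)
        current_leaders = [leader_positions[i].copy() for i in range(3)]
        if binary:
            leader_patterns = {tuple(decode(p).tolist()) for p in current_leaders}
        for i in range(n):
            positions[i] = encircle_update(
                positions[i], current_leaders, a, rng, bounds=(lower, upper)
            )
            decoded_i = decode(positions[i])
            if binary and tuple(decoded_i.tolist()) in leader_patterns:
                positions[i] = rng.uniform(lower, upper)
                decoded_i = decode(positions[i])
            fitness[i] = _evaluate(objective, positions[i], decoded_i)
            if fitness[i] < best_fitness:
                best_fitness = float(fitness[i])
                best_position = decoded_i.copy()
        # merge the pack into the leader set: keep the three best overall,
        # with incumbents winning ties (stable under equal fitness)
        merged_fit = np.concatenate([leader_fitness, fitness])
        merged_pos = np.vstack([leader_positions, positions])
        keep = np.argsort(merged_fit, kind="stable")[:3]
        leader_fitness = merged_fit[keep].copy()
        leader_positions = merged_pos[keep].copy()
        trajectory.append(best_fitness)

    trajectory = np.asarray(trajectory)
    optimal_iteration = int(np.argmax(trajectory == best_fitness))
    return OptimizationResult(
        best_position=best_position,
        best_fitness=best_fitness,
        trajectory=trajectory,
        optimal_iteration=optimal_iteration,
    )


def gwo_minimize(objective: Objective, config: GwoConfig) -> OptimizationResult:
    """Minimize a continuous objective over the configured box with GWO."""
    return _pack_minimize(objective, config, decode=lambda x: x)


def bgwo_minimize(objective: Objective, config: GwoConfig) -> OptimizationResult:
    """Minimize a binary objective with BGWO.

    Internally positions stay continuous inside the box (use
    :func:`unit_bounds` for the conventional [0,1]^d box); the objective is
    evaluated on the flag decoding, and ``best_position`` is binary.
    """
    return _pack_minimize(objective, config, decode=flag_binarize, binary=True)
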