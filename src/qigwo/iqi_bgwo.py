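"""Improved quantum-inspired binary grey wolf optimizer (IQI-BGWO).

Every wolf carries, per dimension, a qubit amplitude pair (x, y) with
x^2 + y^2 = 1; y^2 is the probability of reading bit 1.  Each iteration the
three pack leaders induce a rotation angle for every wolf,

    theta_L = zeta_L * gamma_L * sum_d(X_L_d - X_d) * 2*pi,
    zeta_L  = lambda_L * pi,      lambda_L, gamma_L ~ U[0,1],

the wolf's qubits are rotated by a y-axis rotation gate through theta_alpha,
theta_beta, theta_delta in sequence, and its continuous position contracts
multiplicatively by the new y^2.  Positions decode to bits by thresholding
against each leader's y^2, majority-voting the three bit vectors, and
finally gating through a sigmoid transfer with threshold ``s``.

Numerical choices
-----------------
* Amplitudes initialize to 1/sqrt(2) each (equal superposition, y^2 = 0.5);
  the literal value 1/2 per amplitude is accepted via ``amplitude_init`` but
  violates normalization and is renormalized with a warning.
* The multiplicative position update has an absorbing state at 0; any
  component falling below ``reseed_epsilon`` is re-seeded uniformly on
  [0, 1] to preserve exploration.
* The search always lives on the unit box [0,1]^d regardless of the bounds
  recorded in the config (the decode is scale-free in [0,1]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .gwo_core import (
    GwoConfig,
    ObjectiveError,
    OptimizationResult,
    Pack,
    unit_bounds,
)

__all__ = [
    "QubitVector",
    "RotationAngleState",
    "IqiConfig",
    "x_rotation_gate",
    "z_rotation_gate",
    "y_rotation_matrix",
    "leader_theta",
    "rotate_leader_qubit",
    "position_update",
    "threshold_binary",
    "majority_vote",
    "sigmoid",
    "sigmoid_binarize",
    "iqi_minimize",
]

_NORM_TOL = 1e-9


def y_rotation_matrix(theta: float) -> np.ndarray:
    """Real 2x2 y-axis rotation gate [[cos, -sin], [sin, cos]].

    Orthonormal, hence norm-preserving; composing two gates is the gate of
    the summed angle.
    """
    if not np.isfinite(theta):
        raise ValueError("rotation angle must be finite")
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def x_rotation_gate(theta: float) -> np.ndarray:
    """Complex x-axis rotation gate; provided for completeness, the
    optimizer dynamics use only the (real) y gate."""
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -1j * s], [s, c]])


def z_rotation_gate(theta: float) -> np.ndarray:
    """Complex z-axis rotation gate; unused by the optimizer dynamics."""
    return np.array([[np.exp(-1j * theta), 0.0], [0.0, np.exp(1j * theta)]])


@dataclass
class QubitVector:
    """Per-dimension amplitude pairs (x, y) with unit norm per dimension."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape:
            raise ValueError("amplitude arrays must have the same shape")
        norms = self.x**2 + self.y**2
        if np.any(np.abs(norms - 1.0) > _NORM_TOL):
            raise ValueError("qubit amplitudes must satisfy x^2 + y^2 = 1")

    @property
    def y_squared(self) -> np.ndarray:
        """Probability of reading bit 1 in each dimension."""
        return self.y**2

    def rotate(self, theta: float) -> "QubitVector":
        """Rotate every dimension's amplitude pair by the same angle."""
        c, s = np.cos(theta), np.sin(theta)
        return QubitVector(x=c * self.x - s * self.y, y=s * self.x + c * self.y)


@dataclass(frozen=True)
class RotationAngleState:
    """One iteration's random rotation state shared across the pack.

    ``zeta[i] = lambda_draws[i] * pi`` for leaders in (alpha, beta, delta)
    order; ``gamma`` are fresh uniforms per leader.
    """

    lambda_draws: tuple[float, float, float]
    gamma: tuple[float, float, float]

    @property
    def zeta(self) -> tuple[float, float, float]:
        return tuple(lam * np.pi for lam in self.lambda_draws)


@dataclass(frozen=True)
class IqiConfig(GwoConfig):
    """Configuration for the quantum-inspired binary optimizer.

    ``s_threshold`` is the sigmoid transfer cut in [0, 1]; ``amplitude_init``
    the initial (x, y) amplitude pair; ``reseed_epsilon`` the floor below
    which a position component is re-seeded uniformly.
    """

    s_threshold: float = 0.4
    amplitude_init: tuple[float, float] = (2.0**-0.5, 2.0**-0.5)
    reseed_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0.0 <= self.s_threshold <= 1.0:
            raise ValueError("s_threshold must lie in [0, 1]")
        x0, y0 = self.amplitude_init
        norm = x0**2 + y0**2
        if abs(norm - 1.0) > _NORM_TOL:
            warnings.warn(
                "amplitude_init is not normalized; renormalizing to unit length",
                stacklevel=2,
            )
            scale = norm**-0.5
            object.__setattr__(self, "amplitude_init", (x0 * scale, y0 * scale))

    @classmethod
    def binary(cls, dimension: int, **kwargs) -> "IqiConfig":
        return cls(bounds=unit_bounds(dimension), **kwargs)


def leader_theta(
    leader_position: np.ndarray,
    wolf_position: np.ndarray,
    zeta: float,
    gamma: float,
) -> float:
    """Rotation angle induced by one leader on one wolf.

    theta = zeta * gamma * sum_d(leader_d - wolf_d) * 2*pi.
    """
    leader_position = np.asarray(leader_position, dtype=float)
    wolf_position = np.asarray(wolf_position, dtype=float)
    if leader_position.shape != wolf_position.shape:
        raise ValueError("leader and wolf positions must have the same dimension")
    return float(zeta * gamma * np.sum(leader_position - wolf_position) * 2.0 * np.pi)


def rotate_leader_qubit(qubit: np.ndarray, theta: float) -> np.ndarray:
    """Apply the y-axis rotation gate to a single (x, y) amplitude pair."""
    qubit = np.asarray(qubit, dtype=float)
    if qubit.shape != (2,):
        raise ValueError("qubit must be a single (x, y) amplitude pair")
    if abs(qubit @ qubit - 1.0) > _NORM_TOL:
        raise ValueError("qubit amplitude pair is not normalized")
    return y_rotation_matrix(theta) @ qubit


def position_update(position: np.ndarray, y_squared: np.ndarray) -> np.ndarray:
    """Contract each position component by the qubit's bit-1 probability."""
    return np.asarray(position, dtype=float) * np.asarray(y_squared, dtype=float)


def threshold_binary(position_component, y_squared) -> np.ndarray:
    """Bit = 1 iff the position component is >= y^2 (inclusive)."""
    return (np.asarray(position_component, dtype=float) >= np.asarray(y_squared, dtype=float)).astype(
        np.int8
    )


def majority_vote(
    alpha_bits: np.ndarray, beta_bits: np.ndarray, delta_bits: np.ndarray
) -> np.ndarray:
    """Per-position majority of the three leaders' bit vectors."""
    a = np.asarray(alpha_bits)
    b = np.asarray(beta_bits)
    d = np.asarray(delta_bits)
    if not (a.shape == b.shape == d.shape):
        raise ValueError("bit vectors must have equal length")
    return ((a.astype(int) + b.astype(int) + d.astype(int)) >= 2).astype(np.int8)


def sigmoid(p):
    """Logistic transfer 1 / (1 + exp(-p))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(p, dtype=float)))


def sigmoid_binarize(position: np.ndarray, s: float) -> np.ndarray:
    """Bit = 1 iff sigmoid(position component) >= s, for s in [0, 1]."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("sigmoid threshold s must lie in [0, 1]")
    return (sigmoid(position) >= s).astype(np.int8)


def _decode_population(
    positions: np.ndarray,
    leader_y_squared: tuple[np.ndarray, np.ndarray, np.ndarray],
    s_threshold: float,
) -> np.ndarray:
    """Decode every wolf: per-leader threshold -> majority -> sigmoid gate.

    The sigmoid gate compares the wolf's own continuous component through
    the logistic transfer against ``s``; positions live in [0, 1], so any
    s <= 0.5 leaves the majority vote untouched while larger thresholds
    sparsify the decode.
    """
    votes = np.zeros(positions.shape, dtype=int)
    for y_sq in leader_y_squared:
        votes += positions >= y_sq[None, :]
    maj = (votes >= 2).astype(np.int8)
    gate = sigmoid(positions) >= s_threshold
    return (maj & gate.astype(np.int8)).astype(np.int8)


def _evaluate_bits(objective, bits: np.ndarray) -> float:
    value = float(objective(bits))
    if not np.isfinite(value):
        raise ObjectiveError(
            f"objective returned non-finite value {value!r} at position {bits.tolist()}"
        )
    return value


def iqi_minimize(objective: Callable[[np.ndarray], float], config: IqiConfig) -> OptimizationResult:
    """Minimize a binary objective with the quantum-inspired pack.

    Besides the wolves, each iteration evaluates three extra candidates
    built from an elite archive of the three best distinct bit vectors seen
    so far:

    * the majority vote of the elites (the voting step of the decode
      pipeline applied as a recombination operator),
    * their unanimity (strict vote: bits all three elites agree on), which
      prunes components not universally supported, and
    * a backward-elimination probe of the incumbent best (one active bit
      cleared at random) -- the scout role assigned to an omega wolf.

    The best bit vector over everything ever evaluated is reported, so the
    trajectory is non-increasing.  The probe uses a dedicated random
    stream so the pack dynamics are unaffected by its draws.
    """
    rng = np.random.default_rng(config.seed)
    probe_rng = np.random.default_rng((int(config.seed), 1))
    n, d = config.population_size, config.dimension
    x0, y0 = config.amplitude_init

    positions = rng.random((n, d))
    qx = np.full((n, d), x0)
    qy = np.full((n, d), y0)

    # initial decode: all thresholds equal the shared initial y^2
    y_sq = qy**2
    decoded = _decode_population(positions, (y_sq[0], y_sq[0], y_sq[0]), config.s_threshold)
    fitness = np.array([_evaluate_bits(objective, decoded[i]) for i in range(n)])

    # elite archive: bit vectors + fitness of the three best solutions seen
    # so far, used for the consensus recombination step
    order = list(Pack.rank_leaders(fitness))
    elite_bits = decoded[order].copy()
    elite_fitness = fitness[order].copy()

    best_fitness = float(elite_fitness[0])
    best_position = elite_bits[0].copy()
    trajectory = [best_fitness]

    for _t in range(config.max_iterations):
        # live pack leaders drive the quantum dynamics (rotation pull and
        # decode thresholds); the elite archive only recombines
        leaders = Pack.rank_leaders(fitness)
        leader_positions = positions[list(leaders)].copy()

        state = RotationAngleState(
            lambda_draws=tuple(rng.random(3)), gamma=tuple(rng.random(3))
        )
        zetas = state.zeta

        # per-wolf total rotation angle: sequential gates compose additively
        leader_sums = leader_positions.sum(axis=1)
        wolf_sums = positions.sum(axis=1)
        theta = np.zeros(n)
        for zeta_l, gamma_l, s_l in zip(zetas, state.gamma, leader_sums):
            theta += zeta_l * gamma_l * (s_l - wolf_sums) * 2.0 * np.pi

        c, s = np.cos(theta)[:, None], np.sin(theta)[:, None]
        qx, qy = c * qx - s * qy, s * qx + c * qy
        y_sq = qy**2

        positions = position_update(positions, y_sq)
        reseed = positions < config.reseed_epsilon
        if np.any(reseed):
            positions[reseed] = rng.random(int(reseed.sum()))

        leader_y_sq = tuple(y_sq[i] for i in leaders)
        decoded = _decode_population(positions, leader_y_sq, config.s_threshold)
        # duplicate guard: a wolf decoding onto an elite pattern adds no
        # information; re-seed its position to keep sampling fresh patterns
        elite_patterns = {tuple(b.tolist()) for b in elite_bits}
        for i in range(n):
            if tuple(decoded[i].tolist()) in elite_patterns:
                positions[i] = rng.random(d)
                decoded[i] = _decode_population(
                    positions[i][None, :], leader_y_sq, config.s_threshold
                )[0]
            fitness[i] = _evaluate_bits(objective, decoded[i])
            if fitness[i] < best_fitness:
                best_fitness = float(fitness[i])
                best_position = decoded[i].copy()

        # recombination candidates from the elite archive
        consensus = majority_vote(*elite_bits)
        unanimity = (elite_bits.sum(axis=0) == 3).astype(np.int8)
        consensus_fit = _evaluate_bits(objective, consensus)
        unanimity_fit = _evaluate_bits(objective, unanimity)
        for bits_c, fit_c in ((consensus, consensus_fit), (unanimity, unanimity_fit)):
            if fit_c < best_fitness:
                best_fitness = float(fit_c)
                best_position = bits_c.copy()

        # backward-elimination probe of the incumbent best (not archived)
        active = np.flatnonzero(best_position)
        if active.size > 1:
            probe = best_position.copy()
            probe[active[int(probe_rng.integers(active.size))]] = 0
            probe_fit = _evaluate_bits(objective, probe)
            if probe_fit < best_fitness:
                best_fitness = float(probe_fit)
                best_position = probe

        # merge, keeping the three best *distinct* patterns: distinct elites
        # make the majority consensus a real recombination operator instead
        # of an identity on a single converged pattern
        merged_fit = np.concatenate(
            [elite_fitness, fitness, [consensus_fit, unanimity_fit]]
        )
        merged_bits = np.vstack(
            [elite_bits, decoded, consensus[None, :], unanimity[None, :]]
        )
        keep: list[int] = []
        seen_patterns: set[tuple] = set()
        for idx in np.argsort(merged_fit, kind="stable"):
            pat = tuple(merged_bits[idx].tolist())
            if pat in seen_patterns:
                continue
            seen_patterns.add(pat)
            keep.append(int(idx))
            if len(keep) == 3:
                break
        while len(keep) < 3:  # fewer than 3 distinct patterns ever seen
            keep.append(keep[-1])
        elite_fitness = merged_fit[keep].copy()
        elite_bits = merged_bits[keep].copy()

        trajectory.append(best_fitness)

    trajectory = np.asarray(trajectory)
    optimal_iteration = int(np.argmax(trajectory == best_fitness))
    return OptimizationResult(
        best_position=best_position,
        best_fitness=best_fitness,
        trajectory=trajectory,
        optimal_iteration=optimal_iteration,
    )
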