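"""Benchmark functions F1-F10 and the optimizer comparison harness.

The function set is the canonical grey-wolf benchmark battery: five
unimodal functions (Sphere, Schwefel 2.22, Schwefel 1.2, Schwefel 2.21,
Rosenbrock) and five multimodal ones (generalized Schwefel, Rastrigin,
Ackley, Griewank, generalized penalized no. 1), each with its standard
symmetric box and known optimum.

``run_trials`` repeats an optimizer over deterministic per-repetition seeds
(base seed + r) and reduces the final best-fitness values to
best/worst/mean/std/variance rows; ``compare_algorithms`` runs the
statistical battery (paired Wilcoxon signed-rank, Cohen's d with pooled
standard deviation, one-way ANOVA, Tukey HSD post hoc).

Binary optimizers evaluate the continuous functions through the shared
fixed-point bit encoding (16 bits per dimension by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import gwo_core, iqi_bgwo
from .gwo_core import GwoConfig, OptimizationResult, unit_bounds
from .iqi_bgwo import IqiConfig
from .svm_rbf import decode_bits_to_reals

__all__ = [
    "BenchmarkFunction",
    "BENCHMARKS",
    "StatsRow",
    "ComparisonReport",
    "evaluate_benchmark",
    "get_benchmark",
    "random_search",
    "run_optimizer",
    "run_trials",
    "compare_algorithms",
    "report_grid",
]


@dataclass(frozen=True)
class BenchmarkFunction:
    id: str
    name: str
    bounds_halfwidth: float
    func: Callable[[np.ndarray], float]
    optimum_location: Callable[[int], np.ndarray]
    known_optimum: Callable[[int], float]

    def bounds(self, dimension: int) -> tuple[tuple[float, float], ...]:
        h = self.bounds_halfwidth
        return tuple((-h, h) for _ in range(dimension))


def _sphere(x):
    return float(np.sum(x**2))


def _schwefel_222(x):
    ax = np.abs(x)
    return float(np.sum(ax) + np.prod(ax))


def _schwefel_12(x):
    return float(np.sum(np.cumsum(x) ** 2))


def _schwefel_221(x):
    return float(np.max(np.abs(x)))


def _rosenbrock(x):
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2))


def _schwefel(x):
    return float(-np.sum(x * np.sin(np.sqrt(np.abs(x)))))


def _rastrigin(x):
    return float(np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x) + 10.0))


def _ackley(x):
    d = x.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x**2) / d))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / d)
        + 20.0
        + np.e
    )


def _griewank(x):
    d = x.size
    return float(
        np.sum(x**2) / 4000.0 - np.prod(np.cos(x / np.sqrt(np.arange(1, d + 1)))) + 1.0
    )


def _penalty_u(x, a=10.0, k=100.0, m=4.0):
    out = np.zeros_like(x)
    over, under = x > a, x < -a
    out[over] = k * (x[over] - a) ** m
    out[under] = k * (-x[under] - a) ** m
    return out


def _penalized1(x):
    d = x.size
    y = 1.0 + (x + 1.0) / 4.0
    core = (
        10.0 * np.sin(np.pi * y[0]) ** 2
        + np.sum((y[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[1:]) ** 2))
        + (y[-1] - 1.0) ** 2
    )
    return float(np.pi / d * core + np.sum(_penalty_u(x)))


_SCHWEFEL_OPT = 420.968746
_SCHWEFEL_MIN_PER_DIM = -418.9828872724338

BENCHMARKS: dict[str, BenchmarkFunction] = {
    "F1": BenchmarkFunction("F1", "Sphere", 100.0, _sphere, lambda d: np.zeros(d), lambda d: 0.0),
    "F2": BenchmarkFunction("F2", "Schwefel 2.22", 10.0, _schwefel_222, lambda d: np.zeros(d), lambda d: 0.0),
    "F3": BenchmarkFunction("F3", "Schwefel 1.2", 100.0, _schwefel_12, lambda d: np.zeros(d), lambda d: 0.0),
    "F4": BenchmarkFunction("F4", "Schwefel 2.21", 100.0, _schwefel_221, lambda d: np.zeros(d), lambda d: 0.0),
    "F5": BenchmarkFunction("F5", "Rosenbrock", 30.0, _rosenbrock, lambda d: np.ones(d), lambda d: 0.0),
    "F6": BenchmarkFunction(
        "F6", "Generalized Schwefel", 500.0, _schwefel,
        lambda d: np.full(d, _SCHWEFEL_OPT), lambda d: _SCHWEFEL_MIN_PER_DIM * d,
    ),
    "F7": BenchmarkFunction("F7", "Rastrigin", 5.12, _rastrigin, lambda d: np.zeros(d), lambda d: 0.0),
    "F8": BenchmarkFunction("F8", "Ackley", 32.0, _ackley, lambda d: np.zeros(d), lambda d: 0.0),
    "F9": BenchmarkFunction("F9", "Griewank", 600.0, _griewank, lambda d: np.zeros(d), lambda d: 0.0),
    "F10": BenchmarkFunction("F10", "Generalized Penalized 1", 50.0, _penalized1, lambda d: -np.ones(d), lambda d: 0.0),
}


def get_benchmark(id: str) -> BenchmarkFunction:
    try:
        return BENCHMARKS[id.upper()]
    except KeyError:
        raise KeyError(f"unknown benchmark id {id!r}; expected F1..F10") from None


def evaluate_benchmark(id: str, x: np.ndarray) -> float:
    """Evaluate a benchmark at ``x``; rejects points outside the box."""
    bench = get_benchmark(id)
    x = np.asarray(x, dtype=float)
    h = bench.bounds_halfwidth
    if np.any(np.abs(x) > h):
        raise ValueError(f"{bench.id} input outside its box [-{h}, {h}]")
    return bench.func(x)


def random_search(
    objective: Callable[[np.ndarray], float], config: GwoConfig
) -> OptimizationResult:
    """Uniform random sampling baseline with the pack's evaluation budget.

    Matches the pack optimizers' budget of population_size evaluations per
    iteration plus the initial population.
    """
    rng = np.random.default_rng(config.seed)
    lower, upper = config.lower(), config.upper()
    best_fitness = np.inf
    best_position = None
    trajectory = []
    for _t in range(config.max_iterations + 1):
        for _i in range(config.population_size):
            x = rng.uniform(lower, upper)
            v = float(objective(x))
            if v < best_fitness:
                best_fitness, best_position = v, x
        trajectory.append(best_fitness)
    trajectory = np.asarray(trajectory)
    return OptimizationResult(
        best_position=best_position,
        best_fitness=best_fitness,
        trajectory=trajectory,
        optimal_iteration=int(np.argmax(trajectory == best_fitness)),
    )


_BINARY_ALGOS = ("bgwo", "iqi")


def run_optimizer(
    algorithm: str,
    function_id: str,
    dimension: int,
    seed: int,
    population_size: int = 10,
    max_iterations: int = 200,
    bits_per_dimension: int = 16,
) -> OptimizationResult:
    """One optimizer run on one benchmark.

    Binary optimizers see the function through the fixed-point encoding of
    the box; continuous ones search the box directly.
    """
    bench = get_benchmark(function_id)

    if algorithm in _BINARY_ALGOS:
        lows = np.full(dimension, -bench.bounds_halfwidth)
        highs = np.full(dimension, bench.bounds_halfwidth)

        def objective(bits):
            return bench.func(decode_bits_to_reals(bits, lows, highs, bits_per_dimension))

        dim = dimension * bits_per_dimension
        if algorithm == "iqi":
            config = IqiConfig(
                population_size=population_size, max_iterations=max_iterations,
                bounds=unit_bounds(dim), seed=seed,
            )
            return iqi_bgwo.iqi_minimize(objective, config)
        config = GwoConfig(
            population_size=population_size, max_iterations=max_iterations,
            bounds=unit_bounds(dim), seed=seed,
        )
        return gwo_core.bgwo_minimize(objective, config)

    config = GwoConfig(
        population_size=population_size, max_iterations=max_iterations,
        bounds=bench.bounds(dimension), seed=seed,
    )
    if algorithm == "gwo":
        return gwo_core.gwo_minimize(bench.func, config)
    if algorithm == "random":
        return random_search(bench.func, config)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected gwo|bgwo|iqi|random")


@dataclass(frozen=True)
class StatsRow:
    """Summary of repeated final best-fitness values for one (algo, func)."""

    algorithm: str
    function: str
    best: float
    worst: float
    mean: float
    std: float
    variance: float
    finals: tuple[float, ...]
    trajectories: tuple[tuple[float, ...], ...]


def run_trials(
    algorithm: str,
    function_id: str,
    repetitions: int,
    dimension: int = 30,
    base_seed: int = 0,
    population_size: int = 10,
    max_iterations: int = 200,
    bits_per_dimension: int = 16,
) -> StatsRow:
    """Repeat an optimizer run with seeds base_seed + r and summarize.

    Std/variance use the sample (ddof=1) convention; a single repetition
    reports 0 for both.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    finals, trajectories = [], []
    for r in range(repetitions):
        result = run_optimizer(
            algorithm, function_id, dimension, base_seed + r,
            population_size, max_iterations, bits_per_dimension,
        )
        finals.append(result.best_fitness)
        trajectories.append(tuple(result.trajectory))
    arr = np.asarray(finals)
    std = float(arr.std(ddof=1)) if repetitions > 1 else 0.0
    return StatsRow(
        algorithm=algorithm,
        function=function_id,
        best=float(arr.min()),
        worst=float(arr.max()),
        mean=float(arr.mean()),
        std=std,
        variance=std**2,
        finals=tuple(finals),
        trajectories=tuple(trajectories),
    )


@dataclass
class ComparisonReport:
    """Pairwise and omnibus statistics over per-algorithm fitness samples."""

    pairwise: pd.DataFrame  # algo_a, algo_b, wilcoxon_stat, p_value, cohens_d, degenerate
    anova_f: float
    anova_p: float
    posthoc: pd.DataFrame | None  # Tukey HSD pairwise decisions


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Mean difference over the pooled standard deviation; 0 for identical samples."""
    diff = a.mean() - b.mean()
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0.0:
        return 0.0
    return float(diff / np.sqrt(pooled_var))


def compare_algorithms(
    samples: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> ComparisonReport:
    """Statistical battery over equal-length per-algorithm fitness vectors.

    Wilcoxon signed-rank on each algorithm pair's paired differences (a
    pair with all-zero differences is flagged degenerate and given d = 0),
    one-way ANOVA across all algorithms, and Tukey HSD post hoc when the
    omnibus test is significant at ``alpha``.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least two algorithms to compare")
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    sizes = {a.size for a in arrays.values()}
    if len(sizes) != 1:
        raise ValueError("paired tests require equal repetition counts")

    rows = []
    for a, b in combinations(names, 2):
        xa, xb = arrays[a], arrays[b]
        diffs = xa - xb
        if np.all(diffs == 0.0):
            rows.append(
                dict(algo_a=a, algo_b=b, wilcoxon_stat=np.nan, p_value=np.nan,
                     cohens_d=0.0, degenerate=True)
            )
            continue
        stat, p = stats.wilcoxon(xa, xb)
        rows.append(
            dict(algo_a=a, algo_b=b, wilcoxon_stat=float(stat), p_value=float(p),
                 cohens_d=_cohens_d(xa, xb), degenerate=False)
        )
    pairwise = pd.DataFrame(rows)

    f_stat, f_p = stats.f_oneway(*arrays.values())
    posthoc = None
    if np.isfinite(f_p) and f_p < alpha:
        res = stats.tukey_hsd(*arrays.values())
        ph_rows = []
        for i, j in combinations(range(len(names)), 2):
            ph_rows.append(
                dict(
                    algo_a=names[i], algo_b=names[j],
                    statistic=float(res.statistic[i, j]),
                    p_value=float(res.pvalue[i, j]),
                    significant=bool(res.pvalue[i, j] < alpha),
                )
            )
        posthoc = pd.DataFrame(ph_rows)
    return ComparisonReport(
        pairwise=pairwise, anova_f=float(f_stat), anova_p=float(f_p), posthoc=posthoc
    )


def report_grid(rows: Sequence[StatsRow]) -> pd.DataFrame:
    """Arrange StatsRows into a (function x metric) by algorithm grid."""
    records = []
    for row in rows:
        for metric in ("best", "worst", "mean", "std", "variance"):
            records.append(
                dict(function=row.function, metric=metric,
                     algorithm=row.algorithm, value=getattr(row, metric))
            )
    df = pd.DataFrame(records)
    return df.pivot_table(
        index=["function", "metric"], columns="algorithm", values="value", sort=False
    )
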