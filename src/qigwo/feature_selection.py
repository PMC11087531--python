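"""Wrapper feature selection driven by the binary pack optimizers.

A candidate feature subset (a 0/1 mask) is scored by the fitness

    fitness = q * Pr(M) + e * |R| / |C|,        e = 1 - q,

where Pr(M) is the cross-validated error rate of the wrapper classifier
trained on the masked features, |R| the subset size and |C| the total
feature count.  With the defaults q = 0.99, e = 0.01 the classifier error
dominates and the size term breaks ties toward smaller subsets.  Empty
masks are infeasible: they receive the sentinel fitness 1 + e, strictly
worse than any feasible value, and are never returned.

The wrapper classifier is the scaled-RBF one-vs-all SVM with fixed
mid-range parameters (penalty 1, sigma = sqrt(selected feature count),
lambda 1) so each fitness evaluation costs one cross-validation; nested
hyperparameter optimization can be enabled per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import gwo_core, iqi_bgwo
from .gwo_core import GwoConfig, OptimizationResult, unit_bounds
from .iqi_bgwo import IqiConfig
from .svm_rbf import KernelParams, cv_accuracy

__all__ = [
    "FsFitnessSpec",
    "SelectionResult",
    "TrialSummary",
    "fs_fitness",
    "select_features",
    "summarize_trials",
]


@dataclass(frozen=True)
class FsFitnessSpec:
    """Weights and wrapper settings for the selection fitness.

    ``q`` weights the classifier error rate; ``e = 1 - q`` weights the
    relative subset size.  ``classifier_params=None`` uses the fixed
    mid-range wrapper parameters; "optimize" enables nested tuning.
    """

    q: float = 0.99
    classifier_cv: int = 10
    classifier_params: KernelParams | Literal["optimize"] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must lie in [0, 1]")

    @property
    def e(self) -> float:
        return 1.0 - self.q


def fs_fitness(
    error_rate: float, subset_size: int, total_features: int, spec: FsFitnessSpec
) -> float:
    """q * error_rate + e * subset_size / total_features (minimization)."""
    if total_features < 1:
        raise ValueError("total_features must be >= 1")
    if not 0 < subset_size <= total_features:
        raise ValueError("subset_size must be in [1, total_features]")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    return spec.q * error_rate + spec.e * subset_size / total_features


@dataclass
class SelectionResult:
    """Selected mask plus the bookkeeping needed to audit the fitness."""

    selected_mask: np.ndarray
    fitness: float
    error_rate: float
    eliminated_count: int
    optimal_iteration: int
    trajectory: np.ndarray

    @property
    def selected_count(self) -> int:
        return int(np.sum(self.selected_mask))


def _wrapper_params(n_selected: int, spec: FsFitnessSpec) -> KernelParams:
    if isinstance(spec.classifier_params, KernelParams):
        return spec.classifier_params
    return KernelParams(sigma=float(np.sqrt(max(n_selected, 1))), penalty=1.0)


def select_features(
    features: np.ndarray,
    labels: np.ndarray,
    optimizer: Literal["bgwo", "iqi"] = "iqi",
    spec: FsFitnessSpec | None = None,
    config: GwoConfig | IqiConfig | None = None,
) -> SelectionResult:
    """Optimize a feature mask against the wrapper fitness.

    The CV fold split of the wrapper is fixed once per run (derived from
    the optimizer seed) so every mask is scored on the same surface, and
    mask scores are cached -- the decode revisits patterns frequently.
    """
    spec = spec or FsFitnessSpec()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    total = features.shape[1]

    if config is None:
        cls = IqiConfig if optimizer == "iqi" else GwoConfig
        config = cls(population_size=8, max_iterations=100, bounds=unit_bounds(total), seed=0)
    if config.dimension != total:
        raise ValueError(
            f"config dimension {config.dimension} != feature count {total}"
        )

    cv_seed = int(np.random.default_rng(config.seed).integers(2**31 - 1))
    sentinel = 1.0 + spec.e
    cache: dict[tuple, tuple[float, float]] = {}

    def score(mask: np.ndarray) -> tuple[float, float]:
        key = tuple(int(b) for b in mask)
        if key not in cache:
            n_sel = int(sum(key))
            if n_sel == 0:
                cache[key] = (sentinel, 1.0)
            else:
                cols = np.flatnonzero(np.asarray(key))
                if spec.classifier_params == "optimize":
                    from .svm_rbf import optimize_hyperparams

                    _, _, trace = optimize_hyperparams(
                        features[:, cols], labels, optimizer="gwo", cv_k=spec.classifier_cv
                    )
                    err = float(trace.best_fitness)
                else:
                    params = _wrapper_params(n_sel, spec)
                    err = 1.0 - cv_accuracy(
                        features[:, cols], labels, params, k=spec.classifier_cv, seed=cv_seed
                    )
                cache[key] = (fs_fitness(err, n_sel, total, spec), err)
        return cache[key]

    minimize = gwo_core.bgwo_minimize if optimizer == "bgwo" else iqi_bgwo.iqi_minimize
    result: OptimizationResult = minimize(lambda bits: score(bits)[0], config)

    mask = np.asarray(result.best_position).astype(int)
    if mask.sum() == 0:  # only possible if every candidate was empty
        raise RuntimeError("selection returned an empty mask")
    fitness, error_rate = score(mask)
    return SelectionResult(
        selected_mask=mask,
        fitness=float(fitness),
        error_rate=float(error_rate),
        eliminated_count=int(total - mask.sum()),
        optimal_iteration=result.optimal_iteration,
        trajectory=result.trajectory,
    )


@dataclass
class TrialSummary:
    """Per-trial hyperparameter/outcome rows plus exact column means."""

    table: pd.DataFrame
    means: pd.Series


def summarize_trials(
    rows: Sequence[dict],
    numeric_columns: Sequence[str] = (
        "theta_alpha",
        "optimal_iteration",
        "best_fitness",
        "s",
    ),
) -> TrialSummary:
    """Tabulate selection trials and compute exact column means.

    Means are arithmetic means of the stored values; any rounding happens
    only at serialization time.
    """
    if len(rows) == 0:
        raise ValueError("need at least one trial")
    table = pd.DataFrame(rows)
    cols = [c for c in numeric_columns if c in table.columns]
    means = table[cols].mean()
    return TrialSummary(table=table, means=means)
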