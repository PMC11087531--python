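"""Scaled RBF-kernel SVM: one-vs-all training, CV fitness, hyperparameter search.

The kernel is the Gaussian radial basis function with an explicit
multiplicative scale,

    k(a, b) = exp(-||a - b||^2 / sigma^2) * lambda,

so ``lambda = 1`` recovers the standard Gaussian kernel and any other value
rescales the whole Gram matrix linearly (it stays symmetric positive
semi-definite for lambda > 0).  The soft-margin quadratic program is not
reimplemented: the kernel is injected into scikit-learn's SVC as a
precomputed Gram matrix, one binary classifier per class (one-vs-all), and
prediction takes the class with the largest decision value.

Hyperparameter search minimizes ``1 - cv_accuracy`` over (penalty, sigma)
-- by default on log scales over the conventional RBF grid ranges -- using
any of the pack optimizers.  Binary optimizers drive the continuous
parameters through a fixed-point bit encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.svm import SVC

from . import gwo_core, iqi_bgwo
from .evaluation import stratified_kfold
from .gwo_core import GwoConfig, OptimizationResult, unit_bounds
from .iqi_bgwo import IqiConfig

__all__ = [
    "KernelParams",
    "SearchSpace",
    "TrainedModel",
    "rbf_kernel",
    "gram_matrix",
    "train_one_vs_all",
    "cv_accuracy",
    "decode_bits_to_reals",
    "decode_params",
    "optimize_hyperparams",
]


@dataclass(frozen=True)
class KernelParams:
    """Kernel width ``sigma``, Gram scale ``lambda_scale``, SVM penalty C."""

    sigma: float = 1.0
    lambda_scale: float = 1.0
    penalty: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.lambda_scale <= 0 or self.penalty <= 0:
            raise ValueError("sigma, lambda_scale and penalty must all be positive")


@dataclass(frozen=True)
class SearchSpace:
    """Box over kernel parameters searched by an optimizer.

    ``parameters`` maps a KernelParams field name to (low, high, scale)
    where scale is "linear" or "log"; ``bits_per_parameter`` controls the
    fixed-point resolution used by binary optimizers.
    """

    parameters: tuple[tuple[str, float, float, str], ...] = (
        ("penalty", 2.0**-5, 2.0**15, "log"),
        ("sigma", 2.0**-8, 2.0**8, "log"),
    )
    bits_per_parameter: int = 16

    def __post_init__(self) -> None:
        if self.bits_per_parameter < 2:
            raise ValueError("bits_per_parameter must be >= 2")
        for name, low, high, scale in self.parameters:
            if not low < high:
                raise ValueError(f"{name}: low must be < high")
            if scale not in ("linear", "log"):
                raise ValueError(f"{name}: scale must be 'linear' or 'log'")
            if scale == "log" and low <= 0:
                raise ValueError(f"{name}: log scale requires positive bounds")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.parameters)

    def from_fractions(self, fractions: np.ndarray) -> KernelParams:
        """Map values in [0,1]^P onto the box, respecting each scale."""
        values = {}
        for frac, (name, low, high, scale) in zip(fractions, self.parameters):
            frac = float(np.clip(frac, 0.0, 1.0))
            if scale == "log":
                values[name] = float(np.exp(np.log(low) + frac * (np.log(high) - np.log(low))))
            else:
                values[name] = float(low + frac * (high - low))
        return KernelParams(**values)


def rbf_kernel(a: np.ndarray, b: np.ndarray, params: KernelParams) -> float:
    """Scaled Gaussian similarity between two vectors; symmetric in (a, b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("inputs must have equal length")
    sq = float(np.sum((a - b) ** 2))
    return float(np.exp(-sq / params.sigma**2) * params.lambda_scale)


def gram_matrix(A: np.ndarray, B: np.ndarray, params: KernelParams) -> np.ndarray:
    """Pairwise kernel matrix K[i, j] = k(A[i], B[j])."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    sq = (
        np.sum(A**2, axis=1)[:, None]
        - 2.0 * A @ B.T
        + np.sum(B**2, axis=1)[None, :]
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / params.sigma**2) * params.lambda_scale


@dataclass
class TrainedModel:
    """One-vs-all kernel SVM: one binary margin classifier per class."""

    classes: np.ndarray
    classifiers: list[SVC]
    train_features: np.ndarray
    params: KernelParams

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        """(n_samples, n_classes) decision values against each class."""
        K = gram_matrix(np.atleast_2d(features), self.train_features, self.params)
        return np.column_stack([clf.decision_function(K) for clf in self.classifiers])

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Class with the largest one-vs-all decision value."""
        scores = self.decision_values(features)
        return self.classes[np.argmax(scores, axis=1)]

    @property
    def support_counts(self) -> list[int]:
        return [int(clf.n_support_.sum()) for clf in self.classifiers]


def train_one_vs_all(
    features: np.ndarray, labels: np.ndarray, params: KernelParams
) -> TrainedModel:
    """Fit one binary soft-margin classifier per class on the scaled kernel."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("one-vs-all training requires at least two classes")
    K = gram_matrix(features, features, params)
    classifiers = []
    for cls in classes:
        y = (labels == cls).astype(int)
        clf = SVC(kernel="precomputed", C=params.penalty)
        clf.fit(K, y)
        classifiers.append(clf)
    return TrainedModel(
        classes=classes, classifiers=classifiers, train_features=features, params=params
    )


def cv_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    params: KernelParams,
    k: int = 10,
    seed: int = 0,
) -> float:
    """Mean held-out accuracy over seed-reproducible stratified k folds.

    Rows are canonicalized (lexicographic sort on label then feature values)
    before fold assignment, so the score is invariant to row permutation of
    the dataset.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    order = np.lexsort(tuple(features.T) + (labels,))
    features, labels = features[order], labels[order]

    folds = stratified_kfold(labels, k, seed)
    accuracies = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        model = train_one_vs_all(features[train], labels[train], params)
        pred = model.predict(features[test])
        accuracies.append(float(np.mean(pred == labels[test])))
    return float(np.mean(accuracies))


def decode_bits_to_reals(
    bits: np.ndarray,
    lows: np.ndarray,
    highs: np.ndarray,
    bits_per_dim: int,
    scale: str = "linear",
) -> np.ndarray:
    """Fixed-point decode of a concatenated bit vector into real values.

    Each block of ``bits_per_dim`` bits is read most-significant-first as an
    integer v; the value is low + v / (2^bits - 1) * (high - low) on the
    requested scale (log scale interpolates the logarithms).
    """
    bits = np.asarray(bits).astype(int).ravel()
    lows = np.atleast_1d(np.asarray(lows, dtype=float))
    highs = np.atleast_1d(np.asarray(highs, dtype=float))
    n = lows.size
    if bits.size != n * bits_per_dim:
        raise ValueError(
            f"bit vector of length {bits.size} does not split into "
            f"{n} blocks of {bits_per_dim}"
        )
    weights = 2.0 ** np.arange(bits_per_dim - 1, -1, -1)
    ints = bits.reshape(n, bits_per_dim) @ weights
    frac = ints / (2.0**bits_per_dim - 1.0)
    if scale == "log":
        return np.exp(np.log(lows) + frac * (np.log(highs) - np.log(lows)))
    return lows + frac * (highs - lows)


def decode_params(bits: np.ndarray, space: SearchSpace) -> KernelParams:
    """Decode a binary position into kernel parameters over ``space``."""
    bits = np.asarray(bits).astype(int).ravel()
    n = len(space.parameters)
    if bits.size != n * space.bits_per_parameter:
        raise ValueError(
            f"expected {n * space.bits_per_parameter} bits, got {bits.size}"
        )
    weights = 2.0 ** np.arange(space.bits_per_parameter - 1, -1, -1)
    ints = bits.reshape(n, space.bits_per_parameter) @ weights
    fractions = ints / (2.0**space.bits_per_parameter - 1.0)
    return space.from_fractions(fractions)


OptimizerName = Literal["gwo", "bgwo", "iqi"]


def optimize_hyperparams(
    features: np.ndarray,
    labels: np.ndarray,
    optimizer: OptimizerName = "gwo",
    space: SearchSpace | None = None,
    cv_k: int = 10,
    config: GwoConfig | IqiConfig | None = None,
) -> tuple[KernelParams, TrainedModel, OptimizationResult]:
    """Search kernel parameters minimizing the CV error rate.

    The fitness of a candidate is ``1 - cv_accuracy`` under a fold split
    fixed once per search (derived from the config seed), so the search
    surface is deterministic.  Returns the best parameters, a model
    retrained on the full data with them, and the optimizer trace.
    """
    space = space or SearchSpace()
    n_params = len(space.parameters)
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)

    if optimizer == "gwo":
        if config is None:
            config = GwoConfig(
                population_size=10, max_iterations=20, bounds=unit_bounds(n_params), seed=0
            )
        to_params = space.from_fractions
    else:
        dim = n_params * space.bits_per_parameter
        if config is None:
            cls = IqiConfig if optimizer == "iqi" else GwoConfig
            config = cls(
                population_size=10, max_iterations=20, bounds=unit_bounds(dim), seed=0
            )
        to_params = lambda bits: decode_params(bits, space)  # noqa: E731

    cv_seed = int(np.random.default_rng(config.seed).integers(2**31 - 1))
    cache: dict[tuple, float] = {}

    def objective(position: np.ndarray) -> float:
        key = tuple(np.round(np.asarray(position, dtype=float), 12))
        if key not in cache:
            params = to_params(np.asarray(position))
            cache[key] = 1.0 - cv_accuracy(features, labels, params, k=cv_k, seed=cv_seed)
        return cache[key]

    minimize = {
        "gwo": gwo_core.gwo_minimize,
        "bgwo": gwo_core.bgwo_minimize,
        "iqi": iqi_bgwo.iqi_minimize,
    }[optimizer]
    result = minimize(objective, config)

    best_params = to_params(np.asarray(result.best_position))
    model = train_one_vs_all(features, labels, best_params)
    return best_params, model, result
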