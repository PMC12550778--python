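"""Soft-voting fusion of two probability classifiers with SOA-tuned weights.

The ensemble decision is ``P = w1 * P1 + w2 * P2`` with nonnegative weights
on the simplex (``w2 = 1 - w1``); since the argmax of a nonnegative
combination depends only on the ratio ``w1:w2``, the one-dimensional
simplex search is lossless.  The weights maximize the classification
fitness — the fraction of samples whose fused argmax equals the true label
— on a held-out (validation) split.  A brute-force grid search over ``w1``
is provided as an exhaustive oracle: the fitness is piecewise-constant in
``w1``, so a fine grid is effectively exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .soa import SOAConfig, soa_optimize

__all__ = [
    "EnsembleWeights",
    "fuse_probabilities",
    "classification_fitness",
    "optimize_weights",
    "brute_force_weights",
    "SOAWeightedEnsemble",
]


@dataclass(frozen=True)
class EnsembleWeights:
    omega1: float
    omega2: float

    def __post_init__(self):
        if self.omega1 < 0 or self.omega2 < 0:
            raise ValueError("ensemble weights must be nonnegative")
        if abs(self.omega1 + self.omega2 - 1.0) > 1e-9:
            raise ValueError(
                f"weights must sum to 1, got {self.omega1} + {self.omega2}"
            )


def _check_probs(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2:
        raise ValueError(f"{name} must be a 2-D (N, K) probability matrix")
    if np.any(p < -1e-9):
        raise ValueError(f"{name} contains negative entries")
    rowsum = p.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-6):
        raise ValueError(f"{name} rows must sum to 1 (max deviation {np.max(np.abs(rowsum - 1)):.2e})")
    return p


def fuse_probabilities(p1: np.ndarray, p2: np.ndarray, w: EnsembleWeights) -> np.ndarray:
    """Row-wise convex combination ``w1*P1 + w2*P2``."""
    p1 = _check_probs(p1, "p1")
    p2 = _check_probs(p2, "p2")
    if p1.shape != p2.shape:
        raise ValueError(f"shape mismatch: {p1.shape} vs {p2.shape}")
    return w.omega1 * p1 + w.omega2 * p2


def classification_fitness(p_ensemble: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of rows whose argmax (ties -> lowest class index) is the label."""
    p = np.asarray(p_ensemble, dtype=float)
    labels = np.asarray(labels)
    if len(p) != len(labels) or len(p) == 0:
        raise ValueError("p_ensemble and labels must have equal, nonzero length")
    k = p.shape[1]
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must be in 0..{k - 1}, got range "
                         f"[{labels.min()}, {labels.max()}]")
    pred = p.argmax(axis=1)  # numpy argmax ties -> lowest index
    return float((pred == labels).mean())


def _fitness_of_w1(w1: float, p1, p2, labels) -> float:
    w = EnsembleWeights(float(w1), 1.0 - float(w1))
    return classification_fitness(w.omega1 * p1 + w.omega2 * p2, labels)


def optimize_weights(
    p1: np.ndarray,
    p2: np.ndarray,
    labels: np.ndarray,
    soa_config: SOAConfig | None = None,
    simplex: bool = True,
):
    """SOA search for the fusion weights; returns (weights, fitness, history).

    By default the search is the scalar ``w1 in [0, 1]`` with
    ``w2 = 1 - w1`` — lossless, because the fused argmax depends only on
    the ratio of two nonnegative weights.  ``simplex=False`` searches the
    unconstrained box ``(w1, w2) in [0, 1]^2`` instead (for fidelity
    experiments); the returned weights are normalized to the simplex.
    Should be run on a held-out validation split, never on test data.
    """
    p1 = _check_probs(p1, "p1")
    p2 = _check_probs(p2, "p2")
    if p1.shape != p2.shape:
        raise ValueError(f"shape mismatch: {p1.shape} vs {p2.shape}")
    if soa_config is None:
        soa_config = SOAConfig()
    bounds = ((0.0, 1.0),) if simplex else ((0.0, 1.0), (0.0, 1.0))
    if soa_config.bounds != bounds:
        soa_config = SOAConfig(**{**soa_config.__dict__, "bounds": bounds})
    if simplex:
        pos, fit, history = soa_optimize(
            lambda x: _fitness_of_w1(x[0], p1, p2, labels), soa_config
        )
        w1 = float(np.clip(pos[0], 0.0, 1.0))
        return EnsembleWeights(w1, 1.0 - w1), fit, history

    def objective(x):
        # argmax is scale-invariant, so un-normalized mixing is well-defined
        mixed = x[0] * p1 + x[1] * p2
        pred = mixed.argmax(axis=1)
        return float((pred == np.asarray(labels)).mean())

    pos, fit, history = soa_optimize(objective, soa_config)
    total = pos.sum()
    w1 = float(pos[0] / total) if total > 0 else 0.5
    return EnsembleWeights(w1, 1.0 - w1), fit, history


def brute_force_weights(
    p1: np.ndarray, p2: np.ndarray, labels: np.ndarray, grid_step: float = 0.001
):
    """Exhaustive grid over ``w1``; ties resolved toward the smallest ``w1``."""
    if not 0 < grid_step <= 0.5:
        raise ValueError(f"grid_step must be in (0, 0.5], got {grid_step}")
    p1 = _check_probs(p1, "p1")
    p2 = _check_probs(p2, "p2")
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    grid = np.clip(grid, 0.0, 1.0)
    best_w1, best_fit = 0.0, -1.0
    for w1 in grid:
        f = _fitness_of_w1(w1, p1, p2, labels)
        if f > best_fit:  # strict: keeps the smallest maximizing w1
            best_w1, best_fit = float(w1), f
    return EnsembleWeights(best_w1, 1.0 - best_w1), best_fit


class SOAWeightedEnsemble(BaseEstimator):
    """sklearn-style wrapper: fit the fusion weight on validation outputs.

    ``fit(P, y)`` takes ``P`` of shape (N, 2, K) — the stacked probability
    outputs of the two branches — or a tuple ``(P1, P2)``.  Fitted
    attributes: ``weights_``, ``fitness_``, ``history_``.
    """

    def __init__(self, soa_config: SOAConfig | None = None):
        self.soa_config = soa_config

    @staticmethod
    def _unstack(P):
        if isinstance(P, (tuple, list)):
            p1, p2 = P
        else:
            P = np.asarray(P, dtype=float)
            if P.ndim != 3 or P.shape[1] != 2:
                raise ValueError("P must be (N, 2, K) or a (P1, P2) tuple")
            p1, p2 = P[:, 0, :], P[:, 1, :]
        return p1, p2

    def fit(self, P, y):
        p1, p2 = self._unstack(P)
        self.weights_, self.fitness_, self.history_ = optimize_weights(
            p1, p2, np.asarray(y), self.soa_config
        )
        return self

    def predict_proba(self, P) -> np.ndarray:
        p1, p2 = self._unstack(P)
        return fuse_probabilities(p1, p2, self.weights_)

    def predict(self, P) -> np.ndarray:
        return self.predict_proba(P).argmax(axis=1)
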