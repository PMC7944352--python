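"""Algorithmic regularization and algorithmic-probability sample weighting.

Both are estimator-agnostic cost transforms: regularization adds
lambda * K(model) to any cost; weighting scales each sample's loss by a
bracket weight chosen from the sample's complexity rank *within its own
class*.  The canonical bracket scheme down-weights the most complex
(most likely corrupted or incidental) samples:

    weight = 0.01 if K(x) is in the top quartile of its class,
             0.5  if in the upper half,
             2    otherwise.

A salting operator (random within-image pixel shuffling of a random
subset of samples) reproduces the corruption regime under which the
weighting mechanism is expected to help.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from ._bits import as_bits

__all__ = [
    "WeightingScheme",
    "EQ_BRACKETS",
    "algorithmic_weights",
    "weighted_cost",
    "regularized_cost",
    "salt_samples",
    "nearest_rank_percentile",
]

EQ_BRACKETS = ((75.0, 0.01), (50.0, 0.5), (0.0, 2.0))


@dataclass(frozen=True)
class WeightingScheme:
    """Ordered (phi percentile, gamma weight) brackets, scanned from the
    largest phi: a sample takes the gamma of the first bracket whose
    class-internal phi-th percentile its complexity reaches."""

    brackets: tuple = EQ_BRACKETS

    def __post_init__(self):
        phis = [p for p, _ in self.brackets]
        if any(b >= a for a, b in zip(phis, phis[1:])):
            raise ValueError("phi values must be strictly decreasing")
        if any(g <= 0 for _, g in self.brackets):
            raise ValueError("gamma weights must be positive")

    def weight_for(self, value: float, thresholds: Sequence[float]) -> float:
        for (phi, gamma), thr in zip(self.brackets, thresholds):
            if value >= thr:
                return gamma
        return 1.0  # no bracket matched (schemes without a phi=0 catch-all)


def nearest_rank_percentile(values: Sequence[float], phi: float) -> float:
    """Nearest-rank percentile; phi = 0 maps to -inf so a zero bracket
    catches every sample."""
    if phi <= 0:
        return -math.inf
    ordered = sorted(values)
    rank = max(1, math.ceil(phi / 100.0 * len(ordered)))
    return ordered[rank - 1]


def algorithmic_weights(samples: Sequence, labels: Sequence,
                        complexity_fn: Callable,
                        scheme: WeightingScheme = WeightingScheme()) -> np.ndarray:
    """Per-sample weights from within-class complexity quantiles.

    Weights depend only on each sample's complexity *rank* inside its
    class, so any monotone rescaling of ``complexity_fn`` yields the
    same weights.
    """
    if len(samples) != len(labels):
        raise ValueError("samples and labels must align")
    values = np.array([complexity_fn(x) for x in samples], dtype=float)
    by_class: dict = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    weights = np.empty(len(samples))
    for lab, idx in by_class.items():
        if not idx:
            raise ValueError(f"empty class {lab!r}")
        class_vals = values[idx]
        thresholds = [nearest_rank_percentile(class_vals, phi)
                      for phi, _ in scheme.brackets]
        for i in idx:
            weights[i] = scheme.weight_for(values[i], thresholds)
    return weights


def weighted_cost(per_sample_losses: Sequence[float], weights: Sequence[float],
                  aggregator: Callable = sum) -> float:
    """Aggregate of elementwise weight * loss (default: sum)."""
    losses = np.asarray(per_sample_losses, dtype=float)
    w = np.asarray(weights, dtype=float)
    if losses.shape != w.shape:
        raise ValueError("losses and weights must have equal length")
    return aggregator(w * losses)


def regularized_cost(J_value: float, lam: float, model_complexity: float) -> float:
    """J + lambda * K(model): penalize algorithmically complex models."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return J_value + lam * model_complexity


def salt_samples(images: Sequence, sample_fraction: float, pixel_fraction: float,
                 rng: np.random.Generator):
    """Corrupt a random ``sample_fraction`` of the images by permuting a
    random ``pixel_fraction`` of their pixel positions among themselves
    (the per-image pixel-value multiset is preserved).  Returns the
    corrupted copies and the boolean salted mask."""
    if not (0 <= sample_fraction <= 1 and 0 <= pixel_fraction <= 1):
        raise ValueError("fractions must be within [0, 1]")
    n = len(images)
    n_salt = int(round(sample_fraction * n))
    salted = np.zeros(n, dtype=bool)
    if n_salt:
        salted[rng.choice(n, size=n_salt, replace=False)] = True
    out = []
    for i, img in enumerate(images):
        arr = as_bits(img).copy()
        if salted[i]:
            flat = arr.ravel()
            k = int(round(pixel_fraction * flat.size))
            if k:
                pos = rng.choice(flat.size, size=k, replace=False)
                flat[pos] = flat[pos[rng.permutation(k)]]
        out.append(arr)
    return out, salted
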