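"""Graded response model (GRM) mathematics.

Samejima's graded response model for an item with discrimination ``a`` and
ordered thresholds ``b_1 < ... < b_{K-1}`` defines cumulative category curves

    P*_k(theta) = 1 / (1 + exp(-a (theta - b_k))),   k = 1 .. K-1,

the probability of responding in category ``k`` or above. Category
probabilities are adjacent differences, with boundaries P*_0 = 1, P*_K = 0:

    P_k(theta) = P*_k(theta) - P*_{k+1}(theta),      k = 0 .. K-1.

Fisher information for one item is

    I(theta) = sum_k (P*'_k - P*'_{k+1})^2 / P_k,
    P*'_k    = a * P*_k * (1 - P*_k),

additive across items under local independence, and the model-implied
standard error of measurement is SEM = 1 / sqrt(I).

The logistic metric uses scaling constant D = 1 (no 1.7 factor), the
dominant convention in CAT engines. Parameters calibrated on the normal
metric (D = 1.7) must be rescaled (multiply ``a`` by 1.7) before use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .item_bank import Item

__all__ = [
    "ThetaGrid",
    "PROBABILITY_FLOOR",
    "cumulative_probability",
    "category_probabilities",
    "item_information",
    "test_information",
    "information_sem",
]

# Floors category probabilities inside information sums; prevents division
# blow-up in extreme tails without affecting reported precision.
PROBABILITY_FLOOR = 1e-10


@dataclass(frozen=True)
class ThetaGrid:
    """Quadrature support for the latent trait: abscissae and prior weights.

    Weights are normalized to sum to 1 on construction. ``prior_mean`` and
    ``prior_sd`` record the closed-form moments of the prior the weights
    discretize; the empty-pattern posterior is the prior, so estimation
    reports these exactly rather than their quadrature approximations.
    """

    points: np.ndarray
    weights: np.ndarray
    prior_mean: float = 0.0
    prior_sd: float = 1.0

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if points.ndim != 1 or points.size < 2:
            raise ValueError("grid needs at least 2 points")
        if np.any(np.diff(points) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if weights.shape != points.shape:
            raise ValueError("weights must match points in shape")
        if np.any(weights <= 0):
            raise ValueError("weights must be positive")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "weights", weights / weights.sum())
        # per-item quadrature tables, filled lazily by the estimator
        object.__setattr__(self, "_cache", {})

    @classmethod
    def standard_normal(
        cls, n_points: int = 61, bound: float = 4.5
    ) -> "ThetaGrid":
        """Equally spaced grid over [-bound, bound] with N(0, 1) density weights.

        Endpoints carry half weight (trapezoid rule): with raw density
        weights the quadrature error decays only linearly in the spacing
        when the posterior has visible mass near the bounds.
        """
        points = np.linspace(-bound, bound, n_points)
        trapezoid = np.ones(n_points)
        trapezoid[[0, -1]] = 0.5
        return cls(points=points, weights=norm.pdf(points) * trapezoid)


def cumulative_probability(item: Item, k: int, theta) -> float | np.ndarray:
    """P*_k(theta): probability of responding in category >= k (k = 1..K-1)."""
    if not 1 <= k <= len(item.thresholds):
        raise IndexError(
            f"cumulative category index k={k} out of range 1..{len(item.thresholds)} "
            f"for item {item.item_id!r}"
        )
    return expit(item.discrimination * (np.asarray(theta, dtype=float) - item.thresholds[k - 1]))


def _cumulatives(item: Item, theta) -> np.ndarray:
    """P*_0..P*_K at each theta, shape (K+1,) + theta.shape. Boundaries 1 and 0."""
    theta = np.asarray(theta, dtype=float)
    b = np.array(item.thresholds, dtype=float)
    inner = expit(item.discrimination * (theta[..., None] - b))  # (..., K-1)
    inner = np.moveaxis(inner, -1, 0)
    ones = np.ones((1,) + theta.shape)
    return np.concatenate([ones, inner, np.zeros_like(ones)], axis=0)


def category_probabilities(item: Item, theta) -> np.ndarray:
    """Vector of the K category probabilities P_k(theta), k = 0..K-1.

    Entries are nonnegative and sum to 1. Vectorized over theta: for an array
    of shape S the result has shape (K,) + S.
    """
    pstar = _cumulatives(item, theta)
    return -np.diff(pstar, axis=0)


def item_information(item: Item, theta) -> float | np.ndarray:
    """GRM Fisher information of one item at theta. Nonnegative; -> 0 in the tails."""
    pstar = _cumulatives(item, theta)
    dpstar = item.discrimination * pstar * (1.0 - pstar)  # boundary derivs are 0
    probs = np.maximum(-np.diff(pstar, axis=0), PROBABILITY_FLOOR)
    info = (np.diff(dpstar, axis=0) ** 2 / probs).sum(axis=0)
    return info if info.ndim else float(info)


def test_information(items: Iterable[Item], theta) -> float | np.ndarray:
    """Sum of item informations over a subset (local independence); empty -> 0."""
    total = np.zeros(np.shape(np.asarray(theta, dtype=float)))
    for item in items:
        total = total + item_information(item, theta)
    return total if total.ndim else float(total)


def information_sem(information: float) -> float:
    """Model-implied SEM = 1/sqrt(I) for maximum-likelihood scoring.

    Raises
    ------
    ValueError
        If information is 0 (no information: SEM undefined) or negative.
    """
    if information < 0:
        raise ValueError(f"information must be nonnegative, got {information}")
    if information == 0:
        raise ValueError("no information: SEM is undefined at I = 0")
    return 1.0 / np.sqrt(information)
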