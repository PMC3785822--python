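"""Shannon information quantities, exact and plug-in, in bits.

All logarithms are base 2: the entropy of a distribution is the expected
number of yes/no questions needed to pin down an outcome, and the mutual
information ``I(X;Y) = H(X) - H(X|Y)`` is the number of such questions
about X answered by observing Y.

The sample-based estimators are the plug-in (maximum-likelihood)
estimators computed from empirical frequencies.  Plug-in entropy is biased
downward by about ``(K - 1) / (2 n ln 2)`` bits for K observed outcomes,
which makes plug-in MI biased upward; the optional Miller-Madow correction
subtracts that first-order term explicitly.  No correction is ever applied
silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from scipy.special import xlogy

__all__ = [
    "DiscreteDistribution",
    "JointDistribution",
    "entropy",
    "mutual_information",
    "entropy_from_samples",
    "plugin_estimates",
    "PluginEstimates",
    "binary_entropy",
]

_PROB_TOL = 1e-12
_LN2 = np.log(2.0)


def _check_probs(probs: np.ndarray, name: str) -> np.ndarray:
    probs = np.asarray(probs, dtype=np.float64)
    if np.any(probs < -_PROB_TOL):
        raise ValueError(f"{name}: negative probability")
    total = probs.sum()
    if abs(total - 1.0) > _PROB_TOL:
        raise ValueError(f"{name}: probabilities sum to {total!r}, not 1")
    return np.clip(probs, 0.0, None)


@dataclass(frozen=True)
class DiscreteDistribution:
    """Finite distribution: outcome labels and their probabilities."""

    outcomes: tuple
    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        probs = _check_probs(self.probs, "DiscreteDistribution")
        if len(self.outcomes) != probs.size:
            raise ValueError("outcomes and probs must have equal length")
        object.__setattr__(self, "probs", probs)

    @classmethod
    def uniform(cls, outcomes: Sequence[Hashable]) -> "DiscreteDistribution":
        n = len(outcomes)
        return cls(tuple(outcomes), np.full(n, 1.0 / n))


@dataclass(frozen=True)
class JointDistribution:
    """Joint distribution of an (X, Y) pair as a probability matrix.

    ``probs[i, j]`` is P(X = x_outcomes[i], Y = y_outcomes[j]).
    """

    x_outcomes: tuple
    y_outcomes: tuple
    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_outcomes", tuple(self.x_outcomes))
        object.__setattr__(self, "y_outcomes", tuple(self.y_outcomes))
        probs = np.asarray(self.probs, dtype=np.float64)
        if probs.shape != (len(self.x_outcomes), len(self.y_outcomes)):
            raise ValueError("probs matrix shape does not match outcome labels")
        _check_probs(probs.ravel(), "JointDistribution")
        object.__setattr__(self, "probs", np.clip(probs, 0.0, None))

    def marginal_x(self) -> DiscreteDistribution:
        return DiscreteDistribution(self.x_outcomes, self.probs.sum(axis=1))

    def marginal_y(self) -> DiscreteDistribution:
        return DiscreteDistribution(self.y_outcomes, self.probs.sum(axis=0))

    def swapped(self) -> "JointDistribution":
        return JointDistribution(self.y_outcomes, self.x_outcomes, self.probs.T)


def _entropy_bits(probs: np.ndarray) -> float:
    # -sum p log2 p with 0 log 0 = 0
    return float(-xlogy(probs, probs).sum() / _LN2)


def entropy(d: DiscreteDistribution | np.ndarray) -> float:
    """Shannon entropy H = -sum_i p_i log2 p_i, in bits."""
    if isinstance(d, DiscreteDistribution):
        return _entropy_bits(d.probs)
    return _entropy_bits(_check_probs(np.asarray(d), "entropy"))


def binary_entropy(p: float | np.ndarray) -> float | np.ndarray:
    """Entropy of a Bernoulli(p) variable in bits (vectorized)."""
    p = np.asarray(p, dtype=np.float64)
    out = -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)) / _LN2
    return float(out) if out.ndim == 0 else out


def mutual_information(j: JointDistribution) -> float:
    """Mutual information I(X;Y) = H(X) + H(Y) - H(X,Y), in bits.

    Symmetric in its arguments and non-negative (up to rounding, which is
    clipped at zero).
    """
    h_x = _entropy_bits(j.probs.sum(axis=1))
    h_y = _entropy_bits(j.probs.sum(axis=0))
    h_xy = _entropy_bits(j.probs.ravel())
    return max(0.0, h_x + h_y - h_xy)


def _counts(samples: np.ndarray) -> np.ndarray:
    _, counts = np.unique(samples, return_counts=True)
    return counts


def entropy_from_samples(samples, miller_madow: bool = False) -> float:
    """Plug-in entropy of a label sequence, in bits.

    With ``miller_madow=True`` the first-order bias correction
    ``(K - 1) / (2 n ln 2)`` is added, K being the number of observed
    outcomes.
    """
    samples = np.asarray(samples)
    if samples.size == 0:
        raise ValueError("empty sample")
    counts = _counts(samples)
    n = samples.size
    h = _entropy_bits(counts / n)
    if miller_madow:
        h += (counts.size - 1) / (2.0 * n * _LN2)
    return h


@dataclass(frozen=True)
class PluginEstimates:
    """Plug-in information estimates and the sample size they rest on."""

    entropy_x_bits: float
    entropy_y_bits: float
    mi_bits: float
    n: int
    miller_madow: bool = False


def plugin_estimates(
    samples_x, samples_y, miller_madow: bool = False
) -> PluginEstimates:
    """Plug-in entropy and MI from aligned label sequences.

    The reported ``n`` lets callers judge the bias of the estimates
    (plug-in MI is biased upward by O(K/n)).  The Miller-Madow variant
    corrects each entropy term, hence the MI, to first order.
    """
    x = np.asarray(samples_x)
    y = np.asarray(samples_y)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("samples_x and samples_y must be equal-length 1-D sequences")
    n = x.size
    cx = _counts(x)
    cy = _counts(y)
    # joint counts via pairing of factorized codes
    _, inv_x = np.unique(x, return_inverse=True)
    _, inv_y = np.unique(y, return_inverse=True)
    joint_codes = inv_x * cy.size + inv_y
    cxy = _counts(joint_codes)
    h_x = _entropy_bits(cx / n)
    h_y = _entropy_bits(cy / n)
    h_xy = _entropy_bits(cxy / n)
    if miller_madow:
        h_x += (cx.size - 1) / (2.0 * n * _LN2)
        h_y += (cy.size - 1) / (2.0 * n * _LN2)
        h_xy += (cxy.size - 1) / (2.0 * n * _LN2)
    mi = h_x + h_y - h_xy
    if not miller_madow:
        mi = max(0.0, mi)
    return PluginEstimates(h_x, h_y, mi, n, miller_madow)
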