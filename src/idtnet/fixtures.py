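"""Toy networks and exact small-system oracles.

Everything here is exhaustively computable: Boltzmann tables by 2^N
enumeration and single-flip transition matrices for the random-site
schedule.  These are the independent references the simulation kernels
are validated against.
"""

from __future__ import annotations

import numpy as np

from .netgen import InteractionNetwork
from .spin_dynamics import DynamicsParams

__all__ = [
    "star_network",
    "path_network",
    "triangle_network",
    "random_simple_network",
    "two_spin_chain",
    "all_states",
    "state_index",
    "enumerate_gibbs",
    "single_update_transition_matrix",
    "total_variation",
]


def star_network(n_leaves: int = 5) -> InteractionNetwork:
    """Hub (unit 0) connected to ``n_leaves`` leaves."""
    return InteractionNetwork(n_leaves + 1, [(0, i) for i in range(1, n_leaves + 1)])


def path_network(n: int = 5) -> InteractionNetwork:
    """Open chain of n units."""
    return InteractionNetwork(n, [(i, i + 1) for i in range(n - 1)])


def triangle_network() -> InteractionNetwork:
    return InteractionNetwork(3, [(0, 1), (1, 2), (0, 2)])


def two_spin_chain() -> InteractionNetwork:
    return InteractionNetwork(2, [(0, 1)])


def random_simple_network(
    n: int = 8, n_edges: int = 12, seed: int = 7
) -> InteractionNetwork:
    """Erdos-Renyi-style simple graph with exactly ``n_edges`` edges."""
    rng = np.random.default_rng(seed)
    possible = [(i, j) for i in range(n) for j in range(i + 1, n)]
    chosen = rng.choice(len(possible), size=n_edges, replace=False)
    return InteractionNetwork(n, [possible[c] for c in chosen])


def all_states(n: int) -> np.ndarray:
    """All 2^n spin configurations; bit i of the row index maps to unit i."""
    idx = np.arange(2**n)
    return np.where((idx[:, None] >> np.arange(n)) & 1 == 1, 1, -1).astype(np.int8)


def state_index(states: np.ndarray) -> int:
    """Bitmask index of a configuration (inverse of :func:`all_states`)."""
    bits = (np.asarray(states) == 1).astype(np.int64)
    return int((bits << np.arange(bits.size)).sum())


def enumerate_gibbs(
    network: InteractionNetwork, params: DynamicsParams
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Gibbs distribution over all 2^N states.

    Returns (states, probs): Boltzmann weights of the ferromagnetic
    Hamiltonian E(S) = -J sum_edges s_i s_j at temperature T, normalized.
    """
    n = network.n_units
    if n > 20:
        raise ValueError("enumeration limited to N <= 20")
    states = all_states(n)
    energy = np.zeros(2**n)
    for u, v in network.edges:
        energy -= params.coupling * states[:, u] * states[:, v]
    logw = -energy / params.temperature
    logw -= logw.max()
    w = np.exp(logw)
    return states, w / w.sum()


def single_update_transition_matrix(
    network: InteractionNetwork, params: DynamicsParams
) -> np.ndarray:
    """Markov matrix of one random-site single-update step, P[a, b] = P(a -> b).

    The updated site is uniform over units; the site's new state follows
    the selected rule (Glauber heat bath or Metropolis).  Row-stochastic.
    """
    n = network.n_units
    if n > 12:
        raise ValueError("transition matrix limited to N <= 12")
    states = all_states(n)
    m = np.zeros((2**n, 2**n))
    for a in range(2**n):
        s = states[a]
        for i in range(n):
            h = int(s[network.neighbors(i)].sum())
            p_up = 1.0 / (1.0 + np.exp(-2.0 * params.beta_j * h))
            if params.rule == "glauber":
                p_new_up, p_new_down = p_up, 1.0 - p_up
            else:  # metropolis: flip accepted with min(1, exp(-dE/T))
                de_over_t = 2.0 * params.beta_j * s[i] * h
                p_flip = min(1.0, np.exp(-de_over_t))
                if s[i] == 1:
                    p_new_up, p_new_down = 1.0 - p_flip, p_flip
                else:
                    p_new_up, p_new_down = p_flip, 1.0 - p_flip
            b_flip = a ^ (1 << i)
            if s[i] == 1:
                m[a, a] += p_new_up / n
                m[a, b_flip] += p_new_down / n
            else:
                m[a, a] += p_new_down / n
                m[a, b_flip] += p_new_up / n
    return m


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """TV distance between two distributions on the same support."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())
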