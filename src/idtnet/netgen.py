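"""Degree distributions and configuration-model interaction networks.

The random-graph ensemble studied throughout the package is the
configuration model: a simple undirected graph drawn (approximately)
uniformly among graphs realizing a prescribed degree sequence.  With a
maximum degree that grows sublinearly in the network size the ensemble is
locally tree-like, which is the structural assumption behind the analytic
dissipation calculus in :mod:`idtnet.idt_analytic`.

Degree sequences are sampled i.i.d. from a truncated power law
``p(k) ~ k**(-gamma)`` on ``[k_min, k_max]``; heavy tails (``gamma < 2``)
are the regime of interest, where hubs coexist with many leaves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DegreeDistribution",
    "InteractionNetwork",
    "power_law_distribution",
    "sample_power_law_degrees",
    "build_configuration_graph",
    "excess_degree_distribution",
]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class DegreeDistribution:
    """Probability table ``p(k)`` over integer degrees.

    The same container holds ordinary degree distributions (support >= 1)
    and excess degree distributions ``q(m)`` (support >= 0).

    Parameters
    ----------
    support
        Strictly increasing non-negative integer degrees.
    probs
        Probability per degree; must sum to one within 1e-12.
    gamma
        Power-law exponent, when the table was built from one.
    """

    support: np.ndarray
    probs: np.ndarray
    gamma: float | None = None

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=np.int64)
        probs = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", probs)
        if support.ndim != 1 or probs.shape != support.shape:
            raise ValueError("support and probs must be 1-D arrays of equal length")
        if support.size == 0:
            raise ValueError("empty support")
        if np.any(support < 0):
            raise ValueError("degrees must be non-negative integers")
        if np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly increasing")
        if np.any(probs < -_PROB_TOL):
            raise ValueError("probabilities must be non-negative")
        total = probs.sum()
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities sum to {total!r}, not 1")

    @property
    def k_min(self) -> int:
        return int(self.support[0])

    @property
    def k_max(self) -> int:
        return int(self.support[-1])

    @property
    def mean_degree(self) -> float:
        """First moment <k>."""
        return float(np.dot(self.support, self.probs))

    def pmf(self, k: int) -> float:
        idx = np.searchsorted(self.support, k)
        if idx < self.support.size and self.support[idx] == k:
            return float(self.probs[idx])
        return 0.0

    def to_csv(self, path: str | Path) -> None:
        """Write the two-column ``k,probability`` table."""
        pd.DataFrame({"k": self.support, "probability": self.probs}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DegreeDistribution":
        df = pd.read_csv(path)
        return cls(df["k"].to_numpy(), df["probability"].to_numpy())


def power_law_distribution(
    gamma: float, k_min: int = 1, k_max: int = 100
) -> DegreeDistribution:
    """Normalized truncated power law ``p(k) ~ k**(-gamma)`` on [k_min, k_max]."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if not (1 <= k_min <= k_max):
        raise ValueError("need 1 <= k_min <= k_max")
    k = np.arange(k_min, k_max + 1, dtype=np.int64)
    w = k.astype(np.float64) ** (-float(gamma))
    return DegreeDistribution(k, w / w.sum(), gamma=float(gamma))


def sample_power_law_degrees(
    n: int,
    gamma: float,
    k_min: int = 1,
    k_max: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. degrees from a truncated power law, with even sum.

    ``k_max`` defaults to ``floor(sqrt(n))``, a sublinear cutoff that keeps
    the configuration model locally tree-like.  If the sampled degree sum is
    odd (the handshake lemma forbids realizing it), the last entry is
    resampled until the sum is even; the adjustment is logged.
    """
    if int(n) != n or n < 2:
        raise ValueError("n must be an integer >= 2")
    n = int(n)
    if k_max is None:
        k_max = int(np.floor(np.sqrt(n)))
    if not (1 <= k_min <= k_max):
        raise ValueError("need 1 <= k_min <= k_max")
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be < n={n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    dist = power_law_distribution(gamma, k_min, k_max)
    degrees = rng.choice(dist.support, size=n, p=dist.probs)
    n_resampled = 0
    while degrees.sum() % 2 != 0:
        degrees[-1] = rng.choice(dist.support, p=dist.probs)
        n_resampled += 1
    if n_resampled:
        logger.info(
            "odd degree sum: resampled last entry %d time(s) to restore parity",
            n_resampled,
        )
    return degrees.astype(np.int64)


class InteractionNetwork:
    """Simple undirected interaction graph over 0-based contiguous unit ids.

    Invariants enforced at construction: no self-loops, no parallel edges,
    and the stored degrees recount exactly from the edge set.  Internally
    keeps a CSR adjacency (``indptr``/``indices``) for the simulation
    kernels.
    """

    def __init__(self, n_units: int, edges: Iterable[tuple[int, int]]):
        if n_units < 1:
            raise ValueError("n_units must be >= 1")
        self.n_units = int(n_units)
        edge_set: set[tuple[int, int]] = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                raise ValueError(f"self-loop at unit {u}")
            if not (0 <= u < n_units and 0 <= v < n_units):
                raise ValueError(f"edge ({u},{v}) outside unit range")
            key = (u, v) if u < v else (v, u)
            if key in edge_set:
                raise ValueError(f"duplicate edge {key}")
            edge_set.add(key)
        self.edges: np.ndarray = (
            np.array(sorted(edge_set), dtype=np.int64)
            if edge_set
            else np.empty((0, 2), dtype=np.int64)
        )
        deg = np.zeros(self.n_units, dtype=np.int64)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        self.degree_of = deg
        # CSR adjacency
        indptr = np.zeros(self.n_units + 1, dtype=np.int64)
        np.cumsum(deg, out=indptr[1:])
        indices = np.empty(int(deg.sum()), dtype=np.int64)
        cursor = indptr[:-1].copy()
        for u, v in self.edges:
            indices[cursor[u]] = v
            cursor[u] += 1
            indices[cursor[v]] = u
            cursor[v] += 1
        self.indptr = indptr
        self.indices = indices

    def neighbors(self, unit: int) -> np.ndarray:
        return self.indices[self.indptr[unit] : self.indptr[unit + 1]]

    @property
    def degree_sequence(self) -> np.ndarray:
        return self.degree_of.copy()

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_units))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def write_edge_list(self, path: str | Path) -> None:
        """Two whitespace-separated 0-based columns, smaller id first."""
        with open(path, "w") as fh:
            for u, v in self.edges:
                fh.write(f"{u} {v}\n")

    @classmethod
    def read_edge_list(
        cls, path: str | Path, n_units: int | None = None
    ) -> "InteractionNetwork":
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                u, v = line.split()
                pairs.append((int(u), int(v)))
        if n_units is None:
            n_units = 1 + max(max(p) for p in pairs) if pairs else 1
        return cls(n_units, pairs)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"InteractionNetwork(n_units={self.n_units}, "
            f"n_edges={len(self.edges)})"
        )


def build_configuration_graph(
    degrees: np.ndarray | Iterable[int],
    seed: int | None = None,
    max_retries: int = 100,
    rng: np.random.Generator | None = None,
) -> InteractionNetwork:
    """Realize a degree sequence as a simple graph via stub matching + repair.

    Stub matching (``networkx.configuration_model``) may create self-loops
    and parallel edges; these defects are removed by double-edge swaps that
    preserve every degree.  If the repair stalls, the matching is redrawn,
    up to ``max_retries`` times.  Whole-graph rejection sampling is avoided
    on purpose: for heavy-tailed sequences it essentially never succeeds.
    """
    degrees = np.asarray(list(degrees), dtype=np.int64)
    n = degrees.size
    if n < 2:
        raise ValueError("need at least two units")
    if degrees.sum() % 2 != 0:
        raise ValueError(f"odd degree sum {int(degrees.sum())}: not realizable")
    if degrees.max(initial=0) >= n:
        raise ValueError("max degree must be < number of units")
    if np.any(degrees < 0):
        raise ValueError("degrees must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)

    for attempt in range(max_retries):
        multi = nx.configuration_model(
            degrees.tolist(), seed=int(rng.integers(0, 2**31))
        )
        edges = _repair_to_simple(multi, rng)
        if edges is not None:
            net = InteractionNetwork(n, edges)
            if not np.array_equal(net.degree_of, degrees):
                raise AssertionError("degree sequence not preserved by repair")
            if attempt:
                logger.info("configuration graph built after %d redraw(s)", attempt)
            return net
    raise RuntimeError(
        f"could not realize degree sequence as a simple graph after "
        f"{max_retries} attempts (n={n}, k_max={int(degrees.max())})"
    )


def _repair_to_simple(
    multi: nx.MultiGraph, rng: np.random.Generator, max_swaps_factor: int = 200
) -> list[tuple[int, int]] | None:
    """Double-edge-swap repair of a stub-matched multigraph.

    Returns the simple edge list, or None if the repair stalls.  A swap
    replaces a defective edge (u,v) and a random good edge (x,y) with
    (u,x) and (v,y), which keeps all four degrees.
    """
    edge_list: list[tuple[int, int]] = [(int(u), int(v)) for u, v, _ in multi.edges]
    m = len(edge_list)
    if m == 0:
        return []

    def canon(e: tuple[int, int]) -> tuple[int, int]:
        return e if e[0] <= e[1] else (e[1], e[0])

    def is_bad(e: tuple[int, int]) -> bool:
        return e[0] == e[1] or counts[canon(e)] > 1

    counts: dict[tuple[int, int], int] = {}
    for e in edge_list:
        counts[canon(e)] = counts.get(canon(e), 0) + 1
    bad: set[int] = {i for i, e in enumerate(edge_list) if is_bad(e)}

    budget = max_swaps_factor * max(1, len(bad)) + 10 * m
    while bad and budget > 0:
        budget -= 1
        i = next(iter(bad))
        if not is_bad(edge_list[i]):  # stale: its duplicate twin was rewired
            bad.discard(i)
            continue
        j = int(rng.integers(0, m))
        if j == i:
            continue
        u, v = edge_list[i]
        x, y = edge_list[j]
        if rng.random() < 0.5:
            x, y = y, x
        new_i, new_j = (u, x), (v, y)
        if new_i[0] == new_i[1] or new_j[0] == new_j[1]:
            continue
        ci, cj = canon(new_i), canon(new_j)
        # tentatively remove the two old edges, then require both new slots free
        for old in ((u, v), (x, y)):
            counts[canon(old)] -= 1
        if ci != cj and counts.get(ci, 0) == 0 and counts.get(cj, 0) == 0:
            edge_list[i], edge_list[j] = new_i, new_j
            counts[ci] = counts.get(ci, 0) + 1
            counts[cj] = counts.get(cj, 0) + 1
            bad.discard(i)
            bad.discard(j)
        else:  # revert
            for old in ((u, v), (x, y)):
                counts[canon(old)] += 1
    counts = {c: n for c, n in counts.items() if n}
    if any(is_bad(e) for e in edge_list):
        return None
    return [canon(e) for e in edge_list]


def excess_degree_distribution(p: DegreeDistribution) -> DegreeDistribution:
    """Excess degree distribution ``q(m) = (m+1) p(m+1) / <k>`` over m >= 0.

    ``q(m)`` is the distribution of the number of *additional* edges of the
    unit found at the end of a uniformly random edge; it governs how
    information spreads beyond the first hop in a locally tree-like graph.
    """
    mean = p.mean_degree
    if mean <= 0:
        raise ValueError("degree distribution has zero mean degree")
    mask = p.support >= 1
    m = p.support[mask] - 1
    q = p.support[mask] * p.probs[mask] / mean
    q = q / q.sum()  # remove residual rounding
    return DegreeDistribution(m, q)
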