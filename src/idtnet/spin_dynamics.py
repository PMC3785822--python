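"""Discrete-time Markov-network dynamics of binary ferromagnetic spins.

Each unit carries a state in {-1, +1} and, when updated, quasi-equilibrates
to the instantaneous interaction potential of its neighbours (local
thermodynamic equilibrium): the transition law is the Gibbs measure

    P(r | neighbours)  ~  exp(-E(r | neighbours) / T),

with local energy ``E(r) = -J r * sum(neighbour states)``.  Two standard
single-site realizations of this law are provided: Glauber (heat-bath)
updates, which draw the new state directly from the conditional Gibbs
distribution, and Metropolis-Hastings updates, which always accept
energy-lowering flips and accept energy-raising ones with probability
``exp(-dE/T)``.  Both satisfy detailed balance with respect to the global
Gibbs distribution of the zero-field ferromagnetic Ising Hamiltonian
``E(S) = -J sum_{(i,j) in E} s_i s_j``.

Time is measured in sweeps: one sweep equals N single-site updates, so the
lag axis of downstream information measures does not depend on the network
size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import _kernels
from .netgen import InteractionNetwork

__all__ = [
    "DynamicsParams",
    "Trajectory",
    "random_spins",
    "local_energy",
    "gibbs_transition_probs",
    "glauber_step",
    "metropolis_step",
    "run_chain",
]

_RULES = {"glauber": _kernels.RULE_GLAUBER, "metropolis": _kernels.RULE_METROPOLIS}
_SCHEDULES = {
    "random-site": _kernels.SCHEDULE_RANDOM_SITE,
    "sweep": _kernels.SCHEDULE_SWEEP,
}


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of the heat-bath spin dynamics.

    temperature
        Heat-bath temperature T > 0, in units of the coupling J.
    coupling
        Ferromagnetic coupling J > 0.
    rule
        Update rule, ``"glauber"`` or ``"metropolis"``.
    seed
        Default seed for chains run with these parameters.
    """

    temperature: float
    coupling: float = 1.0
    rule: Literal["glauber", "metropolis"] = "glauber"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.coupling <= 0:
            raise ValueError("coupling must be > 0")
        if self.rule not in _RULES:
            raise ValueError(f"unknown rule {self.rule!r}")

    @property
    def beta_j(self) -> float:
        """J / T, the only combination the update rules depend on."""
        return self.coupling / self.temperature


@dataclass
class Trajectory:
    """Recorded time evolution of a spin configuration.

    ``snapshots[r]`` is the configuration after ``(r + 1) * record_stride``
    sweeps from the initial state.
    """

    snapshots: np.ndarray  # (n_records, n_units) int8
    record_stride: int  # sweeps between snapshots
    schedule: str
    n_sweeps: int
    seed: int | None = None

    @property
    def n_units(self) -> int:
        return self.snapshots.shape[1]

    def magnetization(self) -> np.ndarray:
        """Mean spin per snapshot."""
        return self.snapshots.mean(axis=1)


def random_spins(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random configuration of n spins."""
    return np.where(rng.random(n) < 0.5, -1, 1).astype(np.int8)


def _validate_config(states: np.ndarray, n_units: int) -> np.ndarray:
    states = np.asarray(states)
    if states.shape != (n_units,):
        raise ValueError(f"configuration length {states.shape} != ({n_units},)")
    if not np.all(np.abs(states) == 1):
        raise ValueError("spin states must be in {-1, +1}")
    return states.astype(np.int8)


def local_energy(state: int, neighbor_states, coupling: float = 1.0) -> float:
    """Interaction energy ``-J * state * sum(neighbour states)``.

    Depends on the neighbour states only through their sum, i.e. on the
    distribution of neighbour states, not on which neighbour holds which
    state.  An empty neighbourhood gives a flat landscape (energy 0).
    """
    if state not in (-1, 1):
        raise ValueError("state must be -1 or +1")
    return -coupling * state * float(np.sum(np.asarray(neighbor_states)))


def gibbs_transition_probs(neighbor_states, params: DynamicsParams) -> np.ndarray:
    """Conditional Gibbs distribution over {-1, +1} given the neighbour states.

    Returns ``[P(-1), P(+1)]`` with ``P(r) ~ exp(-E(r)/T)``.  With no
    neighbours (or in the infinite-temperature limit) both states are
    equally likely.
    """
    h = float(np.sum(np.asarray(neighbor_states)))
    x = 2.0 * params.beta_j * h
    # both tails via the large-denominator logistic form: no cancellation
    return np.array([1.0 / (1.0 + np.exp(x)), 1.0 / (1.0 + np.exp(-x))])


def _single_site_update(
    config: np.ndarray,
    site: int,
    network: InteractionNetwork,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> np.ndarray:
    states = _validate_config(config, network.n_units).copy()
    if not (0 <= site < network.n_units):
        raise ValueError(f"invalid site id {site}")
    _kernels._update_site(
        states,
        int(site),
        network.indptr,
        network.indices,
        params.beta_j,
        _RULES[params.rule],
        rng,
    )
    return states


def glauber_step(
    config: np.ndarray,
    site: int,
    network: InteractionNetwork,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Heat-bath update of one site; all other states unchanged."""
    p = DynamicsParams(params.temperature, params.coupling, "glauber", params.seed)
    return _single_site_update(config, site, network, p, rng)


def metropolis_step(
    config: np.ndarray,
    site: int,
    network: InteractionNetwork,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Metropolis-Hastings update of one site; all other states unchanged."""
    p = DynamicsParams(params.temperature, params.coupling, "metropolis", params.seed)
    return _single_site_update(config, site, network, p, rng)


def run_chain(
    network: InteractionNetwork,
    params: DynamicsParams,
    n_sweeps: int,
    init: np.ndarray | str = "random",
    schedule: Literal["random-site", "sweep"] = "random-site",
    record_stride: int = 1,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Run the single-site dynamics for ``n_sweeps`` sweeps.

    Snapshots are recorded every ``record_stride`` sweeps.  Reproducible:
    the same seed (via ``params.seed`` or an explicit ``rng``) yields a
    bit-identical trajectory.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if record_stride < 1:
        raise ValueError("record_stride must be >= 1")
    if schedule not in _SCHEDULES:
        raise ValueError(f"unknown schedule {schedule!r}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if isinstance(init, str):
        if init != "random":
            raise ValueError("init must be a configuration or 'random'")
        states = random_spins(network.n_units, rng)
    else:
        states = _validate_config(init, network.n_units).copy()
    n_records = n_sweeps // record_stride
    out = np.empty((n_records, network.n_units), dtype=np.int8)
    _kernels.run_sweeps_record(
        states,
        network.indptr,
        network.indices,
        params.beta_j,
        int(n_sweeps),
        _RULES[params.rule],
        _SCHEDULES[schedule],
        int(record_stride),
        out,
        rng,
    )
    return Trajectory(
        snapshots=out,
        record_stride=int(record_stride),
        schedule=schedule,
        n_sweeps=int(n_sweeps),
        seed=params.seed,
    )
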