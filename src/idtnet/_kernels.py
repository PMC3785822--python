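"""Numba kernels for single-site spin updates.

All kernels share the same update rules and consume the supplied
``numpy.random.Generator`` in a fixed order, so trajectories are
bit-reproducible for a given seed.

Conventions
-----------
* States are int8 in {-1, +1}; the local field ``h`` is the integer sum of
  neighbour states (CSR adjacency ``indptr``/``indices``).
* ``j_over_t = J / T`` (ferromagnetic coupling over heat-bath temperature).
* Glauber (heat bath): the new state is drawn from the conditional Gibbs
  distribution ``P(+1|h) = 1 / (1 + exp(-2 J h / T))``.  The decision rule
  is written sign-symmetrically (branch on the sign of ``h``) so that a
  global spin flip of the initial state, replayed against the same random
  stream, yields the exactly negated trajectory whenever no zero-field
  update occurs.
* Metropolis: propose flipping the site; accept with probability
  ``min(1, exp(-dE/T))`` where ``dE = 2 J s h``.  A uniform draw is
  consumed only when ``dE > 0``, which preserves the flip symmetry of the
  random stream unconditionally.
* One sweep = N single-site updates.  Schedule 0 picks a uniformly random
  site per update; schedule 1 runs a fresh random permutation per sweep.
"""

import numpy as np
from numba import njit

RULE_GLAUBER = 0
RULE_METROPOLIS = 1
SCHEDULE_RANDOM_SITE = 0
SCHEDULE_SWEEP = 1


@njit(cache=True)
def _update_site(states, i, indptr, indices, j_over_t, rule, rng):
    h = 0
    for e in range(indptr[i], indptr[i + 1]):
        h += states[indices[e]]
    if rule == RULE_GLAUBER:
        if h > 0:
            p_up = 1.0 / (1.0 + np.exp(-2.0 * j_over_t * h))
            states[i] = 1 if rng.random() < p_up else -1
        elif h < 0:
            p_down = 1.0 / (1.0 + np.exp(2.0 * j_over_t * h))
            states[i] = -1 if rng.random() < p_down else 1
        else:
            states[i] = 1 if rng.random() < 0.5 else -1
    else:  # Metropolis
        de_over_t = 2.0 * j_over_t * states[i] * h
        if de_over_t <= 0.0:
            states[i] = -states[i]
        elif rng.random() < np.exp(-de_over_t):
            states[i] = -states[i]


@njit(cache=True)
def _permutation_inplace(perm, rng):
    # Fisher-Yates; Generator.permutation is not available in nopython mode
    n = perm.shape[0]
    for t in range(n - 1, 0, -1):
        j = rng.integers(0, t + 1)
        tmp = perm[t]
        perm[t] = perm[j]
        perm[j] = tmp


@njit(cache=True)
def run_sweeps(states, indptr, indices, j_over_t, n_sweeps, rule, schedule, rng):
    """Advance ``states`` in place by ``n_sweeps`` full sweeps."""
    n = states.shape[0]
    perm = np.arange(n)
    for _ in range(n_sweeps):
        if schedule == SCHEDULE_SWEEP:
            _permutation_inplace(perm, rng)
            for idx in range(n):
                _update_site(states, perm[idx], indptr, indices, j_over_t, rule, rng)
        else:
            for _ in range(n):
                i = rng.integers(0, n)
                _update_site(states, i, indptr, indices, j_over_t, rule, rng)


@njit(cache=True)
def run_sweeps_record(
    states, indptr, indices, j_over_t, n_sweeps, rule, schedule, record_stride, out, rng
):
    """Like :func:`run_sweeps` but store a snapshot every ``record_stride`` sweeps.

    ``out`` must have shape (n_sweeps // record_stride, n).
    """
    n = states.shape[0]
    perm = np.arange(n)
    row = 0
    for sweep in range(n_sweeps):
        if schedule == SCHEDULE_SWEEP:
            _permutation_inplace(perm, rng)
            for idx in range(n):
                _update_site(states, perm[idx], indptr, indices, j_over_t, rule, rng)
        else:
            for _ in range(n):
                i = rng.integers(0, n)
                _update_site(states, i, indptr, indices, j_over_t, rule, rng)
        if (sweep + 1) % record_stride == 0:
            out[row, :] = states
            row += 1


@njit(cache=True)
def run_updates_count(
    states, indptr, indices, j_over_t, n_updates, rule, rng, counts
):
    """Single-site updates accumulating visit counts of the bitmask-encoded state.

    For exact-enumeration cross-checks on small systems (N <= ~20):
    ``counts`` has length 2**N; one count is recorded after every update.
    Bit i of the index is 1 when unit i is in state +1.
    """
    n = states.shape[0]
    idx = 0
    for i in range(n):
        if states[i] == 1:
            idx |= 1 << i
    for _ in range(n_updates):
        i = rng.integers(0, n)
        old = states[i]
        _update_site(states, i, indptr, indices, j_over_t, rule, rng)
        if states[i] != old:
            idx ^= 1 << i
        counts[idx] += 1


@njit(cache=True)
def conditioned_runs(
    ref_state, indptr, indices, j_over_t, rule, schedule, n_series, tau_max, out, rng
):
    """Independent forward runs from a common reference state.

    ``out`` has shape (n_series, tau_max + 1, n); lag 0 stores the reference
    state itself, lag tau the state after tau sweeps.
    """
    n = ref_state.shape[0]
    for s in range(n_series):
        states = ref_state.copy()
        out[s, 0, :] = states
        perm = np.arange(n)
        for tau in range(1, tau_max + 1):
            if schedule == SCHEDULE_SWEEP:
                _permutation_inplace(perm, rng)
                for idx in range(n):
                    _update_site(
                        states, perm[idx], indptr, indices, j_over_t, rule, rng
                    )
            else:
                for _ in range(n):
                    i = rng.integers(0, n)
                    _update_site(states, i, indptr, indices, j_over_t, rule, rng)
            out[s, tau, :] = states
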