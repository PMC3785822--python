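# Methods

## Model

A system of `N` binary units `s_i ∈ {−1, +1}` interacts through a simple
undirected graph.  Dynamics are discrete-time Markov-network dynamics
under local thermodynamic equilibrium: when a unit updates, its new state
is drawn from the conditional Gibbs distribution induced by the current
states of its neighbours,

    P(r | ∂s) ∝ exp(−E(r | ∂s) / T),   E(r | ∂s) = −J r Σ_{j∈∂s} s_j,

with ferromagnetic coupling `J > 0` and heat-bath temperature `T > 0`.
This is the zero-field ferromagnetic Ising model; the global Gibbs
distribution `π(S) ∝ exp(J Σ_{(i,j)∈E} s_i s_j / T)` is stationary for
both implemented update rules, which satisfy detailed balance:

* **Glauber (heat bath)** — the site's new state is drawn directly from
  `P(r | ∂s)`; used for the analytic pipeline.
* **Metropolis–Hastings** — a flip is proposed and accepted with
  probability `min(1, exp(−ΔE/T))`; used for the simulation pipeline to
  show the results do not depend on the particular realization of the
  Gibbs measure.

Time is measured in **sweeps** (N single-site updates), so lag axes are
independent of system size.  The update schedule is a uniformly random
site per update by default; a random-permutation sweep schedule is
available.  `J = 1` throughout, so temperatures are in units of the
coupling.

Networks are configuration-model graphs over a prescribed degree
sequence: stub matching followed by degree-preserving double-edge swaps
that remove self-loops and parallel edges (whole-graph rejection is
hopeless for heavy tails).  Degree sequences are i.i.d. draws from a
truncated power law `p(k) ∝ k^−γ` on `[k_min, k_max]`; an odd degree sum
is repaired by resampling the last entry (logged).  With `k_max` sublinear
in `N` the graphs are locally tree-like, the structural assumption behind
the analytic calculus.  Default `k_max = floor(sqrt(N))` for generic use;
see "Scaling" below for when this default is the wrong choice.

## Analytic IDT

The per-edge transmission `T(k) = I(s_i^t ; s_j^{t+1})` for a neighbour
`j` of degree `k` is computed exactly: the source has a uniform prior, the
`k−1` residual inputs are i.i.d. spins with mean `m` (the *neighbour
magnetization*), and the 2×2 joint is obtained by summing the logistic
transition law over the binomial residual-field distribution — `O(k)`
instead of the `O(2^k)` brute-force enumeration it is tested against.

The degree-`k` unit's one-step information is `I_k(1) = U(k)·k·⟨T⟩_q`
capped at the unit's marginal entropy `H(s)`, with `⟨T⟩_q` the
excess-degree average and `U(k) ∈ [0,1]` a uniqueness (non-overlap)
factor, 1 in the implemented upper bound (any other constant only rescales
the curve).  The cap is essential physics, not bookkeeping: information
about a state can never exceed the entropy of that state, and in the
ordered phase the marginal entropy of a degree-`k` unit,
`H(s) = H_b((1 + m_k)/2)` with `m_k = E[tanh(J h/T)]` over the binomial
field of `k` magnetized neighbours, collapses rapidly with `k`.  The
linear growth `k·⟨T⟩_q` against the collapsing cap is what produces the
interior maximum of the IDT and the decline for hubs.  In the symmetric
phase (`m = 0`) the cap equals 1 bit for every degree and the curve is
monotone non-decreasing — the hub effect is a property of the ordered
phase.

The dissipation ratio `r = c_eff · min(1, ⟨m·T(m+1)⟩_q / H(s))` (with
`H(s) = 1` bit, the maximum-entropy reference unit) is the per-step
fraction of information retained as it spreads beyond the first hop; it is
degree-independent because the excess-degree environment of every unit is
the same in an uncorrelated random graph.  The IDT is the affine-log
transform `D(k) = [log₂ I_k(1) − log₂ ε]/(−log₂ r)`, which preserves the
degree-ordering of `I_k(1)`.  Degrees with `I_k(1) ≤ ε` get `D = 0`;
`r` numerically indistinguishable from 0 (below 1e-15, e.g. at effectively
infinite temperature) or equal to 1 raises instead of producing
infinities.

The neighbour magnetization defaults to 0 (the maximum-entropy prior).
For a *specific* ensemble and temperature the physically consistent value
is the stationary cavity magnetization, the fixed point of the
message-passing recursion `m̂ = Σ_m q(m) E_{h}[tanh(J h/T)]` with `h` the
field of `m` i.i.d. `m̂`-magnetized spins; `stationary_cavity_magnetization`
computes it (iteration from 0.999, tolerance 1e-12) and
`with_stationary_magnetization` applies it.  All six studied temperatures
(2.0–14.0) lie below the transition of the `γ = 1.6`, `k_max = 77`
ensemble (the fixed point is non-zero up to `T ≈ 26`), so the headline
curves are evaluated in the ordered phase.

`T(k) − T(k_ref)` profiles use the largest computed degree as the limit
estimate rather than an asymptotic fit; the implemented checks are the
bound structure (non-negative, non-increasing decrements — transmission
converges downward), not a specific rate constant.

## Empirical IDT

The estimator mirrors the analytic definition without assuming tree
structure.  Per realization: equilibrate (default 1000 sweeps), take the
current state as the reference `S*`, and sample `n_series` independent
forward chains from `S*` for `tau_max` sweeps.  Because the stationary
chain is reversible, these forward runs are distributed as time-reversed
histories *ending* at `S*`; lag `τ` is read as "`τ` sweeps before the
end".  The construction is validated on exhaustively enumerable chains
against transition-matrix powers, which bypasses the reversibility
argument entirely.

Per unit, `info(τ) = H_prior(s_i) − H(s_i at lag τ | S*)`, both plug-in
entropies — the conditional one over the ensemble, the prior over an
unconditioned equilibrium run (default 2000 samples, stride 2 sweeps).
Negative estimates are floored at zero and the flooring recorded.  The
per-unit noise floor is the 97.5th percentile of the spurious entropy drop
under the no-information null (binomial resampling of the conditional
counts at the prior marginal), i.e. the scale of plug-in bias; the default
ε of 0.01 bits exceeds the floor of symmetric units at the default
`n_series = 5000`.

`d_i` is the ε-crossing of a least-squares fit of `log₂ info(τ)` against
`τ`, restricted to the *contiguous initial* run of lags above the noise
floor: once the curve has sunk into the noise band, later excursions above
the floor are bias, and including them flattens the slope (measured
overestimates above 10× for fast-decaying leaves).  Degenerate cases are
handled explicitly rather than silently:

* curve never above ε → `d_i = 0` (information already dissipated);
* fewer than 3 lags above the floor (decay faster than the lag
  resolution) → log-linear interpolation across the crossing, flagged
  unreliable;
* non-decaying fit, or a fitted crossing beyond 5× the observation window
  (right-censored — the data cannot support the extrapolation) → flagged
  unreliable, excluded from aggregation.

Per-unit IDTs are pooled over realizations (each with its own network and
reference state; default 6) and aggregated by degree: exact bins up to
degree 20, log-spaced bins (4 per decade) above, SEM reported only for
bins with at least two units.

## Scaling of the simulation experiment

The reference simulation uses 6000 spins and 90 000 conditioned series per
realization; the package's test-scale experiment uses 500 spins and 5000
series × 6 realizations (about a minute on one CPU).  Scaling down `N`
has one trap: the ordering temperature of a heavy-tailed ensemble is set
by `⟨k²⟩/⟨k⟩`, so shrinking the degree cutoff along with `N` (the generic
`sqrt(N)` default) pushes the transition below the studied temperatures
and destroys the ordered phase the hub effect lives in.  The scaled
experiment therefore keeps the full-scale degree table (`γ = 1.6`,
`k_max = 77`, still well below `N = 500`) and scales only the unit count —
preserving the phase is what makes the scaled run a faithful reproduction.
At `T = 9` the scaled run shows the full effect: top-decile-degree hubs
are frozen (near-zero prior entropy, IDT at the floor) while
intermediate-degree units peak.

## What the synthetic data does and does not emulate

The generator reproduces the studied ensemble: power-law degree sequences
without self-loops, parallel edges, degree–degree correlations or
community structure, and binary spins with a single coupling constant.
Real interaction networks violate most of these idealizations (clustering,
assortativity, heterogeneous couplings, non-binary states), so passing
tests demonstrate correctness of the framework on its stated model class,
not that any particular real system has diminishing-hub dynamics.  The
empirical estimator also conditions on single reference states rather
than estimating information against the full joint system state (which is
intractable), and no correction is applied for information flowing back
to the source unit.

## Numerical choices

* Logarithms base 2 everywhere; information in bits.
* Gibbs probabilities always evaluated through the large-denominator
  logistic form (`1/(1+e^x)` per tail), avoiding cancellation in the small
  tail; detailed balance then holds to 1e-12 at every field value.
* The Glauber decision rule branches on the sign of the local field so
  that a global spin flip replayed against the same random stream yields
  the exactly negated trajectory whenever no zero-field update occurs;
  Metropolis has this symmetry unconditionally.
* Simulation kernels are numba-compiled and consume a
  `numpy.random.Generator` in a fixed order: trajectories are
  bit-reproducible from the seed.
* Distribution tables are validated to sum to 1 within 1e-12; degenerate
  inputs (odd degree sums, zero mean degree, infeasible ε, zero
  dissipation ratio, empty samples) raise informative errors.

## Known limitations

* `U(k)` is implemented only as its `U = 1` upper bound (plus user-supplied
  tables); no closed form for the information overlap between neighbours
  is attempted.
* The large-`k` transmission limit is estimated at the largest computed
  degree, not by asymptotic fit.
* The cavity magnetization assumes the locally tree-like ensemble; on a
  single small realized graph the true marginals fluctuate around it.
* Near the ordering transition the conditioned-ensemble estimator needs
  window lengths and series counts beyond the defaults; estimates there
  are dominated by the censoring rules and should be treated as
  qualitative.
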