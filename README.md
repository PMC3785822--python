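# idtnet — information dissipation time in Markov networks

`idtnet` quantifies the *dynamical* importance of individual units in a
network of interacting stochastic units: not how well connected a unit is,
but how long the rest of the system remembers its instantaneous state.  It
is aimed at researchers studying collective dynamics on heterogeneous
networks — spin systems, simple models of gene-regulatory, neural or social
dynamics — who want a non-perturbative, information-theoretic alternative
to knock-out experiments and topology-only centrality measures.

## The measure

Units carry binary states `s_i ∈ {−1, +1}` and update by the Gibbs measure:
a unit in the instantaneous potential of its neighbours picks its next
state with probability `P(r | ∂s) ∝ exp(−E(r | ∂s)/T)`, where
`E(r | ∂s) = −J·r·Σ_{j∈∂s} s_j` is the ferromagnetic interaction energy and
`T` the heat-bath temperature (local thermodynamic equilibrium).  The
information the system retains at time `t` about a unit's state at time
`t₀` is the mutual information `I(s_i^{t₀}; S^t)`; the **information
dissipation time** (IDT) of the unit is the time until that information
falls below a floor ε.

On a locally tree-like random graph with degree distribution `p(k)` the
IDT of a degree-`k` unit has the closed form

    D(k) = [log I_k(1) − log ε] / [−log r],

where

* `T(k) = I(s_i^t ; s_j^{t+1})` is the per-edge transmission into a
  degree-`k` neighbour, computed exactly by summing the Gibbs transition
  law over the binomial residual-field distribution;
* `I_k(1) = U(k)·k·⟨T⟩_q`, the excess-degree average `⟨T⟩_q = Σ_m q(m)
  T(m+1)` with `q(m) ∝ (m+1)p(m+1)`, capped at the unit's marginal entropy
  `H(s)`;
* `r = c_eff · min(1, ⟨m·T(m+1)⟩_q / H(s))` is the constant per-step
  fraction of information retained as it spreads hop by hop.

Below the ferromagnetic transition the neighbourhood of a hub is
magnetized, the hub's own state is nearly frozen, and its marginal entropy
`H(s)` collapses — so `D(k)` *peaks at intermediate degree and declines for
hubs*: the most connected units are the ones the system forgets fastest.
The package's second pipeline checks this without any tree-likeness
assumption, by simulating Metropolis–Hastings spin dynamics, sampling
trajectory ensembles conditioned on a common reference state (valid by
detailed balance), and regressing per-unit information decay curves to
their ε-crossing.

## Worked example

```python
import numpy as np
from idtnet import *

dist = power_law_distribution(1.6, 1, 77)           # p(k) ∝ k^−1.6
dyn = DynamicsParams(temperature=2.5)               # J = 1
m_hat = stationary_cavity_magnetization(dist, dyn)  # ordered phase?
params = AnalyticIDTParams(dynamics=dyn, degree_distribution=dist,
                           epsilon_bits=1e-3, neighbor_magnetization=m_hat)
print(f"cavity magnetization m_hat = {m_hat:.4f}")
print(f"expected transmission <T>_q = {expected_transmission(params):.5f} bits")
print(f"dissipation ratio r = {dissipation_ratio(params):.5f}")
curve = idt_curve(np.arange(1, 78), params)
for k in (1, 3, 7, 20, 40, 77):
    row = curve.to_frame().set_index("k").loc[k]
    print(f"k={k:3d}  I_k(1)={row['I_k1_bits']:.3e} bits  D(k)={row['D_k_steps']:.3f} steps")
print("peak degree:", curve.argmax_degree)
```

prints

```
cavity magnetization m_hat = 0.8414
expected transmission <T>_q = 0.01963 bits
dissipation ratio r = 0.02550
k=  1  I_k(1)=1.963e-02 bits  D(k)=0.811 steps
k=  3  I_k(1)=5.888e-02 bits  D(k)=1.111 steps
k=  7  I_k(1)=1.374e-01 bits  D(k)=1.342 steps
k= 20  I_k(1)=4.189e-04 bits  D(k)=0.000 steps
k= 40  I_k(1)=2.186e-08 bits  D(k)=0.000 steps
k= 77  I_k(1)=0.000e+00 bits  D(k)=0.000 steps
peak degree: 7
```

At `T = 2.5` the heavy-tailed ensemble is deeply ordered
(`m_hat = 0.84`): a leaf injects about 0.02 bits into its single
neighbour, a degree-7 unit maximizes the retained information, and units
with 20 or more neighbours are so strongly magnetized that their state
carries essentially no information to dissipate — their IDT is already at
the floor.  `D(k)` is in units of update steps of the dissipation cascade.

The same pipelines are available from the shell:

```bash
idtnet generate-network --seed 1 --out net_out     # edge list + degree table
idtnet analytic-curve   --seed 1 --out curve_out   # D(k) CSV + parameter sidecar
idtnet empirical-idt    --seed 1 --out emp_out     # per-unit / per-degree IDTs
idtnet make-fixtures    --seed 1 --out fix_out     # toy nets + exact Gibbs tables
```

Every command accepts `--config config.yaml` (flat key-value; see
`idtnet.config.DEFAULTS`) and writes its resolved configuration and a JSON
run log next to the outputs.

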