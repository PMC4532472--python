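# chainabridge

Model reduction ("abridgment") for linear chain reaction systems in
stochastic chemical kinetics, with the tooling to decide *when* the
reduction is trustworthy and to verify it by exact simulation.

Many biochemical models contain a reversible chain

```
S1 <=[f1,b1]=> S2 <=[f2,b2]=> ... <=[f_{n-1},b_{n-1}]=> Sn --f_n--> S_{n+1}
```

in which the chain hops are fast and the exit reaction is slow — multisite
phosphorylation of a cell-cycle regulator is the motivating example.  An
SSA simulation spends nearly all of its effort on the fast back-and-forth
hops, so one wants to collapse the chain into a single effective reaction
`S1 -> S_{n+1}` with rate `c`.  This package implements the spectral theory
behind that collapse:

* The single-particle occupation probabilities solve the chemical master
  equation `dP/dt = A P` with a tridiagonal generator `A`; dropping the exit
  term gives the fast-subsystem generator `B`.
* The fast chain forgets perturbations on the **relaxation time**
  `T_relax = 1/|λ̂_{n-1}|`, the reciprocal of B's smallest-magnitude nonzero
  eigenvalue.
* The abridgment is valid when the **validity ratio** `ρ = f_n · T_relax`
  is ≪ 1, i.e. the chain relaxes much faster than the slow reaction's mean
  firing time `1/f_n`.
* The reduced rate is the dominant eigenvalue `|λ_n|` of `A`, approximated
  by `γ = −f_n · π_u` (the exit rate weighted by the fast-equilibrium
  occupancy of the exit state) with relative error `O(ρ)`; `m` independent
  particles exit at rate `m·|λ_n|`.

The theory is verified end to end on a multisite-phosphorylation bistable
switch (Cdh1/Clb2 mutual inhibition): the package simulates the full
11-species model and its two-species abridged form with an exact
direct-method SSA (compiled with numba for 10⁶-time-unit horizons) and
compares the stationary Clb2 distributions.

## Worked example

```python
import numpy as np
from chainabridge import (ChainSpec, spectral_report, SwitchParams,
                          reproduce_switch_comparison)

# a fast symmetric 5-state chain with a slow exit
chain = ChainSpec(n=5, forward=(10.0,)*4, backward=(10.0,)*4, exit_rate=0.05)
rep = spectral_report(chain)
print(f"T_relax = {rep.T_relax:.4f}  rho = {rep.rho:.5f}  valid = {rep.valid}")
print(f"|lambda_n| = {rep.c_single:.6f}  gamma = {rep.gamma:.6f}")

# full vs reduced bistable switch at chain scale k = 0.5
res = reproduce_switch_comparison(SwitchParams(k=0.5), t_end=2e5, seed=1)
print(f"density error = {res.error_pct:.2f}%")
```

prints

```
T_relax = 0.2618  rho = 0.01309  valid = True
|lambda_n| = 0.009940  gamma = -0.010000
density error = 17.39%
```

The chain relaxes in ~0.26 time units while the exit fires every 20, so
`ρ ≈ 0.013` clears the default threshold 0.1 and the chain may be abridged;
the equilibrium rate `γ = f_n/n = 0.01` overshoots the exact `|λ_n|` by
about `ρ`, as the theory predicts.  The switch comparison at `k = 0.5` (a
marginal regime) leaves a visible but moderate mismatch between the full
and reduced stationary distributions of Clb2; at `k = 5` the mismatch drops
to a few percent, while at `k = 0.01` the two models disagree about the
number of stable states and the error exceeds 100%.

A command-line interface mirrors the library:

```bash
chainabridge analyze-chain chain.yaml          # JSON spectral report
chainabridge exit-time chain.yaml --out s.tsv  # survival curve + diagnostic
chainabridge simulate model.yaml --t-end 100 --seed 1 --species S
chainabridge reproduce switch --k 0.05 --t-end 1e6 --seed 1
chainabridge gen-fixtures --count 10 --seed 0
chainabridge run experiment.yaml               # declarative config
```

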