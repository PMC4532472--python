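# Methods

## The abridgment problem

The object of study is a reversible linear chain with a slow exit,

    S1 <=[f1,b1]=> S2 <=> ... <=> Sn --f_n--> S_{n+1},

where the `f_i`, `b_i` may depend on other (slow) species but not on the
chain occupancies themselves.  For one particle started in `S1`, the vector
`P(t)` of occupation probabilities solves the chemical master equation
`dP/dt = A P` with the tridiagonal generator

    A[i,i]   = -(b_{i-1} + f_i)      (b_0 = 0; f_n enters the exit row)
    A[i+1,i] = f_i,   A[i,i+1] = b_i,

and the exit survival function is `Prob(T >= t) = 1^T exp(At) e_1`.  `A`
has `n` strictly negative eigenvalues `λ_1 <= ... <= λ_n < 0`.  When the
dominant eigenvalue is well separated, `|λ_n| << |λ_i|` for `i < n`, the
exit time is effectively exponential and the whole chain may be replaced by
the single reaction `S1 -> S_{n+1}` with rate `c = |λ_n|` (`m` independent
particles: `c = m|λ_n|`, since the earliest of `m` exit times has survival
equal to the m-th power of the single-particle survival).

Removing the exit term gives the fast-subsystem generator `B = A + f_n
e_u e_u^T` (exit state `u`, default `n`).  `B` conserves probability, has
one zero eigenvalue, and rank-one perturbation theory gives the entry-wise
interlacing `0 <= λ̂_i − λ_i <= f_n`.  Two consequences drive everything
else:

* **Validity.**  `|λ_n| <= f_n`, and the gap condition holds whenever
  `f_n << |λ̂_{n-1}|`, i.e. `ρ = f_n · T_relax << 1` with
  `T_relax = 1/|λ̂_{n-1}|` the relaxation time of the fast chain.
* **Rate.**  The equilibrium `π` of the fast chain (unique for irreducible
  chains) gives `γ = −f_n π_u`, which approximates `λ_n` with relative
  error `O(ρ)`.

`spectral_report` computes all of these and asserts the interlacing and
rate bounds on every call.

## Parameters that matter

| parameter | meaning | default |
|---|---|---|
| `exit_index u` | chain state the slow reaction leaves from | `n` |
| validity threshold | cutoff on `ρ = f_n·T_relax` | 0.1 |
| `particles m` | independent chain particles | 1 |

The threshold 0.1 operationalizes "`ρ` much smaller than 1": by the `O(ρ)`
bound it corresponds to roughly a 10% error in the reduced rate.  It is a
reporting convention, always overridable, not a physical constant.

## The bistable switch testbed

The verification model couples the chain to two slow reactions.  Cdh1 has
`L = 10` phosphoforms `Cdh1P_0..Cdh1P_9` (weights `L − i`, so
unphosphorylated Cdh1 degrades Clb2 most strongly):

* phosphorylation `Cdh1P_i -> Cdh1P_{i+1}` with propensity `k·Clb2·X_i`
  (Clb2-catalyzed, elementary rate law),
* dephosphorylation at `k·k_p·X_{i+1}`,
* synthesis `∅ -> Clb2` at `k_s`,
* degradation `Clb2 -> ∅` with propensity `k_a·(Σ_i (L−i)·X_i)·X_Clb2`.

Reference parameterization: `k_p = 8.0`, `k_a = 5.5e-4`, `k_s = 350·k_a`,
`m = 10` Cdh1 particles, initial Clb2 = 10 with all Cdh1 unphosphorylated.
The scale `k` multiplies only the chain rates and moves the system between
the valid (`k` large) and invalid (`k` small) regimes.  The two attractors
sit near Clb2 ≈ 4 (chain unphosphorylated, strong degradation) and
Clb2 ≈ 35 (chain phosphorylated, weak degradation).

The abridged model keeps only Clb2: synthesis at `k_s` and degradation with
propensity `k_a·m·w̄(Clb2)·X_Clb2`, where `w̄(c) = Σ (L−i) π_i(c)` is the
expectation of the weighted Cdh1 sum under the frozen-chain equilibrium —
a truncated geometric with ratio `c/k_p` (closed form; cross-checked in
tests against the linear solve).  `w̄` runs from `L` at `c = 0` down to 1
as `c → ∞` and equals `(L+1)/2 = 5.5` at `c = k_p`.  The rate is
re-evaluated at the current Clb2 before every firing; since the model is
one-dimensional this is implemented as a propensity lookup table over Clb2
copy numbers.

The comparison metric is the percent L1 distance
`100·Σ_x |p(x) − q(x)|` between time-fraction distributions over raw
integer copy numbers (no binning), range 0–200.  This is the natural
"density error" whose range admits values above 100% when the two models
disagree about the number of stable states.

### Relaxation-time vs slow-interval curves

For diagnosing the regimes across Clb2 levels,
`relaxation_vs_firing_curve` compares `T_relax` of the frozen chain with
the mean waiting time between slow firings.  The slow interval is evaluated
with the degradation weight at its maximum `L·m` (all Cdh1
unphosphorylated):

    mean_slow_interval(c) = 1 / (k_s + k_a·L·m·c).

This is the *shortest* slow interval the system can realize, hence the
conservative choice for a validity diagnostic: if the chain relaxes faster
than even this interval, it relaxes faster than the actual one.  With it,
the `k = 5` relaxation curve lies below the interval curve for all
Clb2 in 1..35, the `k = 0.05` and `k = 0.01` curves lie above everywhere,
and the `k = 0.5` curve crosses near Clb2 ≈ 5 and ≈ 15 — exactly the
regimes in which the simulated density errors are small, catastrophic, and
intermediate respectively.  The QSS-averaged alternative
`1/(k_s + k_a·m·w̄(c)·c)` is exposed alongside (`qss_slow_interval`); it
compresses the invalid window and was not adopted as the headline curve.

## Simulation engine

`simulate_ssa` is the exact direct method: per step two uniforms in fixed
order, `τ = ln(1/r1)/a0`, channel = smallest `j` with cumulative propensity
strictly exceeding `r2·a0` (an exact tie selects the next channel — a
measure-zero convention fixed for determinism).  Trajectories record every
jump and are bit-reproducible given `(network, init, t_end, seed)`.

Long-horizon stationary estimates use `simulate_time_fractions`: the same
direct method with the dwell-time histogram of one species accumulated
online (O(1) memory for any horizon).  Networks whose propensities are all
mass-action, mass-action × linear form, or tabulated run in a
numba-compiled kernel with an embedded PCG32 stream; custom Python
propensities fall back to an equivalent interpreted loop.  The kernel was
validated against an exact sparse CME stationary solve on a downscaled
switch (2 particles, 3 levels, truncated Clb2 axis): the L1 distance decays
to the Monte-Carlo floor (~1.5% at 5×10⁶ time units).

Burn-in for stationary estimates defaults to 1% of the horizon; at 10⁶
time units the initial transient is orders of magnitude shorter than the
discarded window.

## Numerical choices

* Eigenvalues come from a dense nonsymmetric solver (`n` is at most a few
  hundred).  Birth–death generators are similar to symmetric tridiagonal
  matrices, so genuinely complex spectra are impossible; imaginary parts
  below `1e-9` of the spectral radius are truncated, anything larger is a
  hard error.
* The fast equilibrium solves the reduced nonsingular system
  `B̃β + y = 0` (substituting `π_n = 1 − Σβ`) by LU with one sweep of
  iterative refinement; strongly biased chains otherwise lose relative
  accuracy in occupancies near 1e-10.  Agreement with the detailed-balance
  closed form is at machine-absolute level (< 1e-10) — *relative* accuracy
  of occupancies at the underflow edge is intrinsically limited to about
  `eps/π_i`.
* A dense eigensolver resolves eigenvalues to absolute accuracy
  ~eps·‖A‖.  When the exit is many orders slower than the chain,
  `|λ_n|` falls below that floor; `reduced_rate` then refines the dominant
  eigenvalue by extended-precision Sturm bisection on the symmetric
  tridiagonal matrix that `A` is similar to under detailed-balance scaling,
  restoring relative accuracy (to ~1e-8) for the rate and its gap to `γ`.
* Survival curves use the eigen-expansion `Σ c_i (1^T ξ_i) e^{λ_i t}` when
  the eigenvector matrix has condition number below 1e8, otherwise
  scaling-and-squaring matrix exponentials per grid point.
* Zero-rate edges make a chain reducible: `equilibrium_distribution`
  refuses rather than regularizes.  `relaxation_time` only requires a
  simple zero eigenvalue, so a dephosphorylation-only chain (Clb2 = 0) is
  still diagnosable and is flagged.
* Degenerate `n = 1`: `T_relax = 0`, `γ = −f_1` exactly.

## Synthetic fixtures and what the tests show

Random chain fixtures draw log-uniform rates over `10^[−2, 2]` with sizes
2–12; the optional `rho_target` rescales the exit rate so that
`f_n·T_relax` hits a prescribed validity ratio exactly.  These fixtures
exercise the spectral claims (signs, interlacing, `|λ_n| ≤ f_n`, the
`O(ρ)` rate gap) across the parameter space, but they are idealized:
rates are state-independent, chains are irreducible, and there is no
coupling to other species.  Passing them certifies the linear-algebraic
machinery, not the behavior of any particular biological network; the
switch experiments cover the coupled, state-dependent case.

Statistical tests (Poisson counts, exponential holding times, KS
comparisons against analytic survival curves) use fixed seeds and
3-standard-error or p > 1e-3 bands, so they are deterministic in CI while
still being genuine distributional checks.

## Known limitations

* Only the direct method is implemented — no tau-leaping or next-reaction
  variants, and no spatial simulation.
* The abridgment theory covers linear chains (state-dependent rates enter
  only through slow variables); nonlinear or branched fast subsystems are
  out of scope.
* Exit-time analysis reports the survival curve and its exponential
  deviation, not higher moments or phase-type fits.
* At chain scale `k = 0.01` the full-vs-reduced density error converges to
  ≈ 110–115%; the qualitative regime claim (full model unimodal, reduced
  bimodal) holds there, and the error ordering across `k` is strictly
  decreasing in `k` as expected.
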