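"""First-exit-time distributions for chain systems, analytic and empirical.

For a single particle started in state ``init_index`` of the chain, the exit
time T (first arrival in S_{n+1}) has survival function

    Prob(T >= t) = 1^T exp(A t) e_init,

with A the single-particle generator including the exit term.  When the
spectral gap condition |lambda_n| << |lambda_i| (i < n) holds, this survival
is close to the single exponential exp(lambda_n t) and the chain may be
abridged into one reaction.  The module quantifies that closeness and
provides SSA-based empirical samples for verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .chain_spectral import ChainSpec, build_generator_A, _real_eigvals
from .reaction_network import Reaction, ReactionNetwork, simulate_ssa

__all__ = [
    "SurvivalCurve",
    "survival_function",
    "exponential_deviation",
    "m_particle_survival",
    "empirical_exit_times",
    "chain_reaction_network",
]

# eigen-expansion is preferred (cheap on dense t grids) unless the
# eigenvector matrix is ill-conditioned, where expm is the robust path
_EIG_COND_LIMIT = 1e8


@dataclass
class SurvivalCurve:
    """Prob(T >= t) sampled on a grid; survival(0) = 1, non-increasing."""

    t_grid: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        self.t_grid = np.asarray(self.t_grid, dtype=np.float64)
        self.survival = np.asarray(self.survival, dtype=np.float64)
        if self.t_grid.shape != self.survival.shape or self.t_grid.ndim != 1:
            raise ValueError("t_grid and survival must be 1-D of equal length")
        if self.t_grid[0] != 0.0 or np.any(np.diff(self.t_grid) <= 0):
            raise ValueError("t_grid must start at 0 and increase strictly")
        if np.any(self.survival < -1e-12) or np.any(self.survival > 1.0 + 1e-12):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-9):
            raise ValueError("survival must be non-increasing")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time\tsurvival\n")
            for t, s in zip(self.t_grid, self.survival):
                fh.write(f"{t:.17g}\t{s:.17g}\n")


def survival_function(
    chain: ChainSpec, t_grid, init_index: int = 1
) -> SurvivalCurve:
    """Analytic survival 1^T exp(A t) e_init on the given grid.

    Uses the eigen-expansion sum_i c_i (1^T xi_i) exp(lambda_i t) when A is
    comfortably diagonalizable, otherwise falls back to scaling-and-squaring
    matrix exponentials per grid point.
    """
    t_grid = np.asarray(t_grid, dtype=np.float64)
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    a_mat = build_generator_A(chain)
    n = chain.n
    e0 = np.zeros(n)
    e0[init_index - 1] = 1.0

    vals, vecs = scipy.linalg.eig(a_mat)
    use_eig = np.linalg.cond(vecs) < _EIG_COND_LIMIT
    if use_eig:
        coeff = np.linalg.solve(vecs, e0)  # c_i from the initial condition
        ones_v = np.ones(n) @ vecs  # 1^T xi_i
        surv = np.real(
            (coeff * ones_v)[None, :] * np.exp(np.outer(t_grid, vals))
        ).sum(axis=1)
    else:
        surv = np.empty_like(t_grid)
        for i, t in enumerate(t_grid):
            surv[i] = np.ones(n) @ (scipy.linalg.expm(a_mat * t) @ e0)
    surv = np.clip(surv, 0.0, 1.0)
    surv = np.minimum.accumulate(surv)  # remove sub-1e-12 roundoff wiggles
    return SurvivalCurve(t_grid, surv)


def exponential_deviation(
    chain: ChainSpec, t_max_multiples: float = 10.0, num: int = 2001
) -> float:
    """Sup-norm distance between the exit survival and exp(lambda_n t).

    The grid spans [0, t_max_multiples / |lambda_n|], i.e. several mean
    lifetimes of the dominant mode.  A small value certifies that the exit
    time is effectively exponential and the abridgment faithful.
    """
    vals = _real_eigvals(build_generator_A(chain))
    lam_n = vals[-1]
    if chain.n == 1:
        return 0.0
    if lam_n >= 0:
        raise ValueError("chain has no exit (f_n = 0); deviation undefined")
    t_max = t_max_multiples / abs(lam_n)
    grid = np.linspace(0.0, t_max, num)
    curve = survival_function(chain, grid)
    return float(np.abs(curve.survival - np.exp(lam_n * grid)).max())


def m_particle_survival(single: SurvivalCurve, m: int) -> SurvivalCurve:
    """Survival of the earliest of m independent exit times: S(t)^m.

    In the exponential regime exp(lambda_n t)^m = exp(m lambda_n t), the
    reduced rate for m particles.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    return SurvivalCurve(single.t_grid, single.survival**m)


def chain_reaction_network(chain: ChainSpec) -> ReactionNetwork:
    """The chain as an explicit reaction network with exit species S_{n+1}."""
    n = chain.n
    names = [f"S{i + 1}" for i in range(n)] + [f"S{n + 1}"]
    reactions = []
    for i in range(n - 1):
        fwd = np.zeros(n + 1, dtype=int)
        fwd[i], fwd[i + 1] = -1, 1
        reactions.append(
            Reaction.mass_action(f"S{i + 1}->S{i + 2}", fwd, chain.forward[i], {i: 1})
        )
        bwd = np.zeros(n + 1, dtype=int)
        bwd[i + 1], bwd[i] = -1, 1
        reactions.append(
            Reaction.mass_action(f"S{i + 2}->S{i + 1}", bwd, chain.backward[i], {i + 1: 1})
        )
    u = chain.exit_index - 1
    exitv = np.zeros(n + 1, dtype=int)
    exitv[u], exitv[n] = -1, 1
    reactions.append(
        Reaction.mass_action(f"S{u + 1}->S{n + 1}", exitv, chain.exit_rate, {u: 1})
    )
    return ReactionNetwork(names, reactions)


def empirical_exit_times(
    chain: ChainSpec, replicates: int, seed: int, init_index: int = 1
) -> np.ndarray:
    """SSA first-passage times of one particle from S_init to S_{n+1}."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if chain.exit_rate <= 0:
        raise ValueError("exit_rate must be positive to sample exit times")
    network = chain_reaction_network(chain)
    n = chain.n
    init = np.zeros(n + 1, dtype=int)
    init[init_index - 1] = 1
    child_seeds = np.random.SeedSequence(seed).generate_state(replicates)
    out = np.empty(replicates)
    for r in range(replicates):
        traj = simulate_ssa(
            network,
            init,
            t_end=np.inf,
            seed=int(child_seeds[r]),
            stop_predicate=lambda x: x[n] >= 1,
        )
        if not traj.stopped_early:
            raise RuntimeError("exit never reached (unexpected for f_n > 0)")
        out[r] = traj.final_time
    return out
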