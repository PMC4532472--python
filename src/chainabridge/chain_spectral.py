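"""Spectral abridgment theory for linear chain reaction systems.

The object of study is the reversible chain with a slow exit reaction,

    S_1 <=> S_2 <=> ... <=> S_n --(f_n)--> S_{n+1},

with forward rates f_1..f_{n-1}, backward rates b_1..b_{n-1}.  For a single
particle the occupation probabilities solve dP/dt = A P with A the
tridiagonal generator including the exit term; dropping the exit gives the
fast-subsystem generator B.  The module computes:

* the generators A and B (and the reduced nonsingular system B~ used to
  solve for the fast equilibrium),
* the relaxation time T_relax = 1/|lambda_hat_{n-1}| of the fast subsystem,
* the fast equilibrium distribution pi (linear solve, cross-checkable
  against the detailed-balance closed form),
* the reduced (abridged) reaction rate: the dominant eigenvalue lambda_n of
  A and its equilibrium approximation gamma = -f_n * pi_u, with the
  m-particle rate m*|lambda_n|,
* the validity ratio rho = f_n * T_relax; the abridgment of the chain into
  the single reaction S_1 -> S_{n+1} is accurate when rho << 1, i.e. when
  the fast chain relaxes much faster than the slow reaction's mean firing
  time 1/f_n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "ChainSpec",
    "SpectralReport",
    "build_generator_A",
    "build_generator_B",
    "build_reduced_B",
    "chain_eigenvalues",
    "relaxation_time",
    "equilibrium_distribution",
    "detailed_balance_equilibrium",
    "ReducedRate",
    "reduced_rate",
    "validity_check",
    "spectral_report",
    "DEFAULT_VALIDITY_THRESHOLD",
]

#: rho = f_n * T_relax below this is treated as "much smaller than 1";
#: the O(rho) error bound then allows roughly 10% rate error.
DEFAULT_VALIDITY_THRESHOLD = 0.1

# imaginary parts below this fraction of the spectral radius are solver noise
_IMAG_TOL = 1e-9


@dataclass(frozen=True)
class ChainSpec:
    """A linear chain S_1..S_n with an exit reaction of rate ``exit_rate``.

    Parameters
    ----------
    n : number of chain states.
    forward, backward : rate vectors of length n-1 (f_i is the S_i -> S_{i+1}
        rate, b_i the S_{i+1} -> S_i rate).
    exit_rate : rate f_n of the slow exit reaction.
    exit_index : 1-based state the exit leaves from (default n).
    particles : number m of independent particles in the chain.
    """

    n: int
    forward: tuple[float, ...]
    backward: tuple[float, ...]
    exit_rate: float
    exit_index: int | None = None
    particles: int = 1

    def __post_init__(self):
        object.__setattr__(self, "forward", tuple(float(v) for v in self.forward))
        object.__setattr__(self, "backward", tuple(float(v) for v in self.backward))
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(self.forward) != self.n - 1 or len(self.backward) != self.n - 1:
            raise ValueError("forward/backward must have length n-1")
        rates = (*self.forward, *self.backward, self.exit_rate)
        if not all(np.isfinite(r) and r >= 0 for r in rates):
            raise ValueError("all rates must be finite and non-negative")
        if self.exit_index is None:
            object.__setattr__(self, "exit_index", self.n)
        if not 1 <= self.exit_index <= self.n:
            raise ValueError("exit_index must lie in 1..n")
        if self.particles < 1:
            raise ValueError("particles must be >= 1")

    @property
    def irreducible(self) -> bool:
        return all(f > 0 for f in self.forward) and all(b > 0 for b in self.backward)


def build_generator_B(chain: ChainSpec) -> np.ndarray:
    """Tridiagonal CME generator of the fast subsystem (no exit reaction).

    Every column sums to zero: probability is conserved within the chain.
    """
    n = chain.n
    b_mat = np.zeros((n, n))
    for i in range(n - 1):
        f, b = chain.forward[i], chain.backward[i]
        b_mat[i, i] -= f
        b_mat[i + 1, i] += f
        b_mat[i + 1, i + 1] -= b
        b_mat[i, i + 1] += b
    return b_mat


def build_generator_A(chain: ChainSpec) -> np.ndarray:
    """Full single-particle generator: B with -f_n on the exit diagonal entry."""
    a = build_generator_B(chain)
    u = chain.exit_index - 1
    a[u, u] -= chain.exit_rate
    return a


def build_reduced_B(chain: ChainSpec) -> tuple[np.ndarray, np.ndarray]:
    """Nonsingular (n-1)x(n-1) system for the fast equilibrium.

    Substituting p_n = 1 - sum(p_1..p_{n-1}) into dP/dt = B P yields
    dP'/dt = B~ P' + y with y = b_{n-1} e_{n-1}; the equilibrium beta solves
    B~ beta + y = 0.
    """
    if chain.n < 2:
        raise ValueError("reduced system requires n >= 2")
    b_mat = build_generator_B(chain)
    n = chain.n
    bt = b_mat[: n - 1, : n - 1].copy()
    bt[n - 2, :] -= chain.backward[n - 2]
    y = np.zeros(n - 1)
    y[n - 2] = chain.backward[n - 2]
    return bt, y


def _real_eigvals(mat: np.ndarray) -> np.ndarray:
    """Sorted real eigenvalues; complains if the spectrum is not real.

    Birth-death generators are similar to symmetric matrices, so genuine
    imaginary parts indicate a malformed input rather than roundoff.
    """
    vals = scipy.linalg.eigvals(mat)
    radius = max(np.abs(vals).max(), 1e-300)
    if np.abs(vals.imag).max() > _IMAG_TOL * radius:
        raise ValueError("generator spectrum has non-negligible imaginary parts")
    return np.sort(vals.real)


def chain_eigenvalues(chain: ChainSpec) -> tuple[np.ndarray, np.ndarray]:
    """(eigenvalues of A ascending, eigenvalues of B ascending)."""
    return _real_eigvals(build_generator_A(chain)), _real_eigvals(
        build_generator_B(chain)
    )


def relaxation_time(chain: ChainSpec) -> float:
    """T_relax = 1/|lambda_hat_{n-1}|, the slowest nonzero mode of B.

    The fast chain forgets a perturbation on this timescale.  A chain with
    n = 1 has no internal dynamics; its relaxation time is 0 by convention.
    """
    if chain.n == 1:
        return 0.0
    vals = _real_eigvals(build_generator_B(chain))
    radius = max(np.abs(vals).max(), 1e-300)
    second = vals[-2]  # largest nonzero eigenvalue (vals[-1] ~ 0)
    if abs(second) <= 1e-12 * radius or radius < 1e-290:
        raise ValueError(
            "fast subsystem has a repeated zero eigenvalue (disconnected chain: "
            "some f_i = b_i = 0); relaxation time undefined"
        )
    return 1.0 / abs(second)


def equilibrium_distribution(chain: ChainSpec) -> np.ndarray:
    """Fast-subsystem equilibrium pi from the reduced linear solve.

    Solves B~ beta + y = 0 and appends pi_n = 1 - sum(beta).  Requires an
    irreducible chain (all f_i, b_i > 0); a reducible chain makes the reduced
    matrix singular and is refused rather than regularized.
    """
    if chain.n == 1:
        return np.array([1.0])
    if not chain.irreducible:
        raise ValueError("equilibrium requires all f_i, b_i > 0 (irreducible chain)")
    bt, y = build_reduced_B(chain)
    lu = scipy.linalg.lu_factor(bt)
    beta = scipy.linalg.lu_solve(lu, -y)
    # one sweep of iterative refinement: tiny occupancies of strongly biased
    # chains otherwise lose relative accuracy in the direct solve
    residual = bt @ beta + y
    beta -= scipy.linalg.lu_solve(lu, residual)
    pi = np.append(beta, 1.0 - beta.sum())
    if pi.min() < -1e-10:
        raise RuntimeError("equilibrium solve produced negative probabilities")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def detailed_balance_equilibrium(chain: ChainSpec) -> np.ndarray:
    """Closed-form equilibrium pi_{i+1}/pi_i = f_i/b_i (truncated geometric
    for uniform rate ratios).  Independent of the linear solve; used as a
    cross-check and as the fast path for quasi-steady-state rate evaluation."""
    if chain.n == 1:
        return np.array([1.0])
    if not all(b > 0 for b in chain.backward):
        raise ValueError("detailed balance form requires all b_i > 0")
    log_pi = np.zeros(chain.n)
    for i in range(chain.n - 1):
        if chain.forward[i] == 0.0:
            log_pi[i + 1] = -np.inf
        else:
            log_pi[i + 1] = log_pi[i] + np.log(chain.forward[i]) - np.log(
                chain.backward[i]
            )
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    return pi / pi.sum()


def _sturm_count(diag, off2, x):
    """Number of eigenvalues of the symmetric tridiagonal below x (LDL^T)."""
    tiny = np.finfo(np.longdouble).tiny
    count = 0
    q = diag[0] - x
    if q < 0:
        count += 1
    for i in range(1, diag.shape[0]):
        if q == 0:
            q = tiny
        q = (diag[i] - x) - off2[i - 1] / q
        if q < 0:
            count += 1
    return count


def dominant_eigenvalue(chain: ChainSpec) -> float:
    """The dominant (smallest-magnitude) eigenvalue lambda_n of A.

    A dense solve has absolute accuracy ~eps * ||A||; when the exit is many
    orders slower than the chain, |lambda_n| falls below that floor and the
    dense value is pure noise.  In that regime the eigenvalue is refined by
    extended-precision Sturm bisection on the symmetric tridiagonal that A
    is similar to under the detailed-balance diagonal scaling (requires an
    irreducible chain).
    """
    a_mat = build_generator_A(chain)
    vals = _real_eigvals(a_mat)
    lam = vals[-1]
    radius = np.abs(vals).max()
    if abs(lam) > 1e-10 * radius or not chain.irreducible or chain.n == 1:
        return float(lam)
    f = np.asarray(chain.forward, dtype=np.longdouble)
    b = np.asarray(chain.backward, dtype=np.longdouble)
    diag = -(np.concatenate(([0.0], b)) + np.concatenate((f, [0.0])))
    diag = diag.astype(np.longdouble)
    diag[chain.exit_index - 1] -= np.longdouble(chain.exit_rate)
    off2 = f * b
    # all eigenvalues are < 0; bisect for the n-th (largest) one
    lo = -np.longdouble(abs(lam) * 4 + 1e-13 * radius)
    n = chain.n
    while _sturm_count(diag, off2, lo) == n:
        lo *= 2
    hi = np.longdouble(0.0)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sturm_count(diag, off2, mid) == n:
            hi = mid  # all eigenvalues below mid: lambda_n < mid
        else:
            lo = mid
        if hi < 0 and (hi - lo) < 1e-8 * abs(hi):
            break
    return float(0.5 * (lo + hi))


@dataclass(frozen=True)
class ReducedRate:
    gamma: float  # equilibrium approximation -f_n * pi_u (negative)
    c_single: float  # |lambda_n|: exact single-particle exit rate
    c_m: float  # m * |lambda_n|: m-particle reduced rate
    relative_gap: float  # |lambda_n - gamma| / |lambda_n|


def reduced_rate(chain: ChainSpec) -> ReducedRate:
    """Reaction rate for the abridged system S_1 -> S_{n+1}.

    ``gamma = -f_n * pi_u`` evaluates the slow exit at the fast equilibrium;
    it approximates the dominant eigenvalue lambda_n of A with relative error
    O(f_n * T_relax).  The m-particle system (earliest of m independent exit
    times) reduces to rate m*|lambda_n|.
    """
    if chain.n == 1:
        gamma = -chain.exit_rate
        c = chain.exit_rate
        return ReducedRate(gamma, c, chain.particles * c, 0.0)
    pi = equilibrium_distribution(chain)
    gamma = -chain.exit_rate * pi[chain.exit_index - 1]
    lam_n = dominant_eigenvalue(chain)
    c_single = abs(lam_n)
    gap = abs(lam_n - gamma) / c_single if c_single > 0 else 0.0
    return ReducedRate(gamma, c_single, chain.particles * c_single, gap)


def validity_check(
    chain: ChainSpec, threshold: float = DEFAULT_VALIDITY_THRESHOLD
) -> tuple[float, bool]:
    """rho = f_n * T_relax and whether it clears the separation threshold.

    rho compares the fast chain's relaxation time against the slow reaction's
    mean firing time 1/f_n; the abridgment requires rho << 1.
    """
    if chain.exit_rate == 0.0:
        return 0.0, True
    rho = chain.exit_rate * relaxation_time(chain)
    return rho, bool(rho < threshold)


@dataclass(frozen=True)
class SpectralReport:
    chain: ChainSpec
    eigenvalues_A: np.ndarray
    eigenvalues_B: np.ndarray
    T_relax: float
    equilibrium: np.ndarray
    gamma: float
    c_single: float
    c_m: float
    relative_gap: float
    rho: float
    valid: bool

    def to_dict(self) -> dict:
        return {
            "n": self.chain.n,
            "particles": self.chain.particles,
            "eigenvalues_A": list(self.eigenvalues_A),
            "eigenvalues_B": list(self.eigenvalues_B),
            "T_relax": self.T_relax,
            "equilibrium": list(self.equilibrium),
            "gamma": self.gamma,
            "c_single": self.c_single,
            "c_m": self.c_m,
            "relative_gap": self.relative_gap,
            "rho": self.rho,
            "valid": self.valid,
        }


def spectral_report(
    chain: ChainSpec, threshold: float = DEFAULT_VALIDITY_THRESHOLD
) -> SpectralReport:
    """Full spectral analysis with internal consistency checks.

    Verifies the rank-one interlacing bound 0 <= lambda_hat_i - lambda_i <=
    f_n entry-wise and |lambda_n| <= f_n before returning.
    """
    vals_a, vals_b = chain_eigenvalues(chain)
    t_relax = relaxation_time(chain) if chain.n >= 2 else 0.0
    pi = equilibrium_distribution(chain)
    rr = reduced_rate(chain)
    rho, valid = (
        validity_check(chain, threshold)
        if chain.n >= 2
        else (0.0, True)
    )
    scale = max(np.abs(vals_b).max(), chain.exit_rate, 1.0)
    diff = vals_b - vals_a
    tol = 1e-8 * scale
    if np.any(diff < -tol) or np.any(diff > chain.exit_rate + tol):
        raise RuntimeError("interlacing bound 0 <= lhat_i - l_i <= f_n violated")
    if abs(vals_a[-1]) > chain.exit_rate + tol:
        raise RuntimeError("|lambda_n| <= f_n violated")
    return SpectralReport(
        chain=chain,
        eigenvalues_A=vals_a,
        eigenvalues_B=vals_b,
        T_relax=t_relax,
        equilibrium=pi,
        gamma=rr.gamma,
        c_single=rr.c_single,
        c_m=rr.c_m,
        relative_gap=rr.relative_gap,
        rho=rho,
        valid=valid,
    )
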