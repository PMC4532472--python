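"""Concrete reaction systems: the three-species chain, the enzyme chain, and
the multisite-phosphorylation bistable switch with its abridged form.

The bistable switch couples a fast reversible phosphorylation chain to two
slow reactions.  Cdh1 carries ``levels`` phosphoforms Cdh1P_0..Cdh1P_{L-1};
Clb2 catalyzes phosphorylation (rate k*Clb2 per Cdh1 molecule per step) and
phosphatase action returns each step at rate k*k_p.  Clb2 is synthesized at
constant rate k_s and degraded with propensity

    k_a * (sum_i (L - i) * Cdh1P_i) * Clb2,

so unphosphorylated Cdh1 (weight L) degrades Clb2 most strongly — mutual
inhibition, hence bistability.  The scale k multiplies only the chain rates:
large k separates timescales and licenses the abridgment into a two-species
birth-death model whose degradation rate constant is the quasi-steady-state
expectation of the weighted Cdh1 sum at the current Clb2 level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chain_spectral import (
    ChainSpec,
    detailed_balance_equilibrium,
    reduced_rate,
    relaxation_time,
)
from .reaction_network import Reaction, ReactionNetwork

__all__ = [
    "SwitchParams",
    "DEFAULT_SWITCH",
    "build_three_species",
    "build_bistable_switch",
    "build_reduced_switch",
    "build_enzyme_chain",
    "switch_chain",
    "mean_phospho_weight",
    "reduced_degradation_table",
    "relaxation_vs_firing_curve",
]


@dataclass(frozen=True)
class SwitchParams:
    """Parameters of the multisite-phosphorylation bistable switch.

    Defaults are the reference parameterization used throughout:
    k_p = 8.0, k_a = 5.5e-4, k_s = 350*k_a, 10 Cdh1 particles, 10
    phospho-levels; ``k`` scales only the chain reactions and is the knob
    that moves the system between the valid (k large) and invalid (k small)
    abridgment regimes.
    """

    k: float
    k_p: float = 8.0
    k_a: float = 5.5e-4
    k_s: float = 350 * 5.5e-4
    m: int = 10
    levels: int = 10
    clb2_init: int = 10

    def __post_init__(self):
        if min(self.k, self.k_p, self.k_a, self.k_s) <= 0:
            raise ValueError("all rate parameters must be positive")
        if self.m < 1 or self.levels < 2:
            raise ValueError("need m >= 1 and levels >= 2")

    @property
    def weights(self) -> np.ndarray:
        """Degradation weight of phospho-level i is levels - i."""
        return np.arange(self.levels, 0, -1, dtype=np.float64)


DEFAULT_SWITCH = SwitchParams(k=5.0)


# ---------------------------------------------------------------------------
# Three-species system S1 <=> S2 -> S3 and its abridgment S1 -> S3
# ---------------------------------------------------------------------------


def build_three_species(
    c1: float, c2: float, c3: float
) -> tuple[ReactionNetwork, ReactionNetwork, ChainSpec]:
    """The classic reducible system S1 <=(c2)=(c1)=> S2 --(c3)--> S3.

    Returns (full network, abridged network S1 -> S3 at rate |gamma|, chain
    spec).  The abridged rate |gamma| = c1*c3/(c1+c2) evaluates the exit at
    the fast equilibrium occupancy of S2.
    """
    chain = ChainSpec(n=2, forward=(c1,), backward=(c2,), exit_rate=c3)
    full = ReactionNetwork(
        ["S1", "S2", "S3"],
        [
            Reaction.mass_action("S1->S2", [-1, 1, 0], c1, {0: 1}),
            Reaction.mass_action("S2->S1", [1, -1, 0], c2, {1: 1}),
            Reaction.mass_action("S2->S3", [0, -1, 1], c3, {1: 1}),
        ],
    )
    c = abs(reduced_rate(chain).gamma)
    reduced = ReactionNetwork(
        ["S1", "S3"],
        [Reaction.mass_action("S1->S3", [-1, 1], c, {0: 1})],
    )
    return full, reduced, chain


# ---------------------------------------------------------------------------
# Bistable switch (full and reduced)
# ---------------------------------------------------------------------------


def build_bistable_switch(p: SwitchParams) -> ReactionNetwork:
    """Full switch: phospho-chain of Cdh1 plus Clb2 synthesis/degradation.

    Species are Cdh1P_0..Cdh1P_{L-1} (indices 0..L-1) and Clb2 (index L).
    Total Cdh1 is conserved at m by construction.
    """
    levels = p.levels
    clb2 = levels
    names = [f"Cdh1P{i}" for i in range(levels)] + ["Clb2"]
    nsp = levels + 1
    reactions = []
    for i in range(levels - 1):
        phos = np.zeros(nsp, dtype=int)
        phos[i], phos[i + 1] = -1, 1
        reactions.append(
            Reaction.mass_action(
                f"Cdh1P{i}->Cdh1P{i + 1}", phos, p.k, {i: 1, clb2: 1}
            )
        )
        dephos = np.zeros(nsp, dtype=int)
        dephos[i + 1], dephos[i] = -1, 1
        reactions.append(
            Reaction.mass_action(
                f"Cdh1P{i + 1}->Cdh1P{i}", dephos, p.k * p.k_p, {i + 1: 1}
            )
        )
    synth = np.zeros(nsp, dtype=int)
    synth[clb2] = 1
    reactions.append(Reaction.mass_action("0->Clb2", synth, p.k_s))
    degr = np.zeros(nsp, dtype=int)
    degr[clb2] = -1
    w = np.zeros(nsp)
    w[:levels] = p.weights
    reactions.append(
        Reaction.weighted_mass_action("Clb2->0", degr, p.k_a, {clb2: 1}, w)
    )
    return ReactionNetwork(names, reactions)


def switch_initial_state(p: SwitchParams) -> np.ndarray:
    """All Cdh1 unphosphorylated, Clb2 at its initial copy number."""
    x = np.zeros(p.levels + 1, dtype=np.int64)
    x[0] = p.m
    x[p.levels] = p.clb2_init
    return x


def switch_chain(p: SwitchParams, clb2: float) -> ChainSpec:
    """The Cdh1 phospho-chain with Clb2 frozen: f_i = k*Clb2, b_i = k*k_p."""
    return ChainSpec(
        n=p.levels,
        forward=(p.k * clb2,) * (p.levels - 1),
        backward=(p.k * p.k_p,) * (p.levels - 1),
        exit_rate=0.0,
        particles=p.m,
    )


def mean_phospho_weight(p: SwitchParams, clb2: float) -> float:
    """QSS expectation of sum_i (L - i) pi_i at frozen Clb2.

    pi is the truncated-geometric equilibrium of the frozen chain with ratio
    r = Clb2/k_p.  Ranges from L (Clb2 -> 0, all unphosphorylated) down to 1
    (Clb2 -> inf, all fully phosphorylated); equals (L+1)/2 at Clb2 = k_p.
    """
    if clb2 == 0.0:
        return float(p.levels)
    pi = detailed_balance_equilibrium(switch_chain(p, clb2))
    return float(p.weights @ pi)


def reduced_degradation_table(p: SwitchParams, size: int = 4096) -> np.ndarray:
    """table[x] = k_a * m * mean_weight(x) * x: full degradation propensity
    of the reduced model at Clb2 = x."""
    xs = np.arange(size)
    return np.array(
        [p.k_a * p.m * mean_phospho_weight(p, float(x)) * x for x in xs]
    )


def build_reduced_switch(p: SwitchParams, table_size: int = 4096) -> ReactionNetwork:
    """Abridged switch: Clb2 alone, with QSS-averaged degradation.

    Synthesis stays 0 -> Clb2 at k_s; degradation fires with propensity
    k_a * m * E[weighted Cdh1 sum | Clb2] * Clb2, the frozen-chain
    expectation re-evaluated at the current Clb2 before every firing
    (implemented as a lookup table over Clb2 copy numbers).
    """
    table = reduced_degradation_table(p, table_size)
    return ReactionNetwork(
        ["Clb2"],
        [
            Reaction.mass_action("0->Clb2", [1], p.k_s),
            Reaction.tabulated("Clb2->0", [-1], 0, table),
        ],
    )


# ---------------------------------------------------------------------------
# Enzyme chain: fast uniform chain catalyzed by E, slow degradation of E
# ---------------------------------------------------------------------------


def build_enzyme_chain(
    k0: float, e_synthesis: float, ku: float, u: int, n: int, m: int
) -> ReactionNetwork:
    """Chain S_1 <=> ... <=> S_n with both directions at rate k0*E, plus
    constant E synthesis and slow degradation E -> 0 at rate ku*X_u*E.

    E is a catalyst: chain reactions leave E unchanged, and the enzymic
    degradation leaves the chain species unchanged.
    """
    if not 1 <= u <= n:
        raise ValueError("u must lie in 1..n")
    names = [f"S{i + 1}" for i in range(n)] + ["E"]
    e_idx = n
    nsp = n + 1
    reactions = []
    for i in range(n - 1):
        fwd = np.zeros(nsp, dtype=int)
        fwd[i], fwd[i + 1] = -1, 1
        reactions.append(
            Reaction.mass_action(f"S{i + 1}->S{i + 2}", fwd, k0, {i: 1, e_idx: 1})
        )
        bwd = np.zeros(nsp, dtype=int)
        bwd[i + 1], bwd[i] = -1, 1
        reactions.append(
            Reaction.mass_action(f"S{i + 2}->S{i + 1}", bwd, k0, {i + 1: 1, e_idx: 1})
        )
    synth = np.zeros(nsp, dtype=int)
    synth[e_idx] = 1
    reactions.append(Reaction.mass_action("0->E", synth, e_synthesis))
    degr = np.zeros(nsp, dtype=int)
    degr[e_idx] = -1
    reactions.append(
        Reaction.mass_action("E->0", degr, ku, {u - 1: 1, e_idx: 1})
    )
    return ReactionNetwork(names, reactions)


# ---------------------------------------------------------------------------
# Timescale diagnostics across Clb2 levels
# ---------------------------------------------------------------------------


def relaxation_vs_firing_curve(p: SwitchParams, clb2_values) -> pd.DataFrame:
    """Chain relaxation time vs mean slow-reaction interval per Clb2 level.

    For each frozen Clb2: T_relax of the phospho-chain, and the mean waiting
    time between slow firings.  The interval uses the shortest (most
    conservative) slow timescale, with the degradation weight at its maximum
    L*m (all Cdh1 unphosphorylated):

        mean_slow_interval = 1 / (k_s + k_a * L * m * Clb2).

    The QSS-averaged alternative 1/(k_s + k_a*m*E[weight]*Clb2) is reported
    alongside as ``qss_slow_interval``.  Where the T_relax curve lies below
    the interval curve, the timescale-separation condition holds and the
    abridgment is trustworthy.

    Clb2 = 0 makes the chain forward-reducible (pure dephosphorylation); its
    relaxation time is still computed from the surviving modes and flagged.
    """
    rows = []
    for clb2 in clb2_values:
        if clb2 < 0:
            raise ValueError("Clb2 values must be >= 0")
        chain = switch_chain(p, float(clb2))
        t_relax = relaxation_time(chain)
        w = mean_phospho_weight(p, float(clb2))
        slow_rate = p.k_s + p.k_a * (p.levels * p.m) * float(clb2)
        qss_rate = p.k_s + p.k_a * p.m * w * float(clb2)
        rows.append(
            {
                "clb2": clb2,
                "t_relax": t_relax,
                "mean_slow_interval": 1.0 / slow_rate,
                "qss_slow_interval": 1.0 / qss_rate,
                "chain_reducible": not chain.irreducible,
            }
        )
    return pd.DataFrame(rows)
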