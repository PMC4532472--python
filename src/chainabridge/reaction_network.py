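"""Discrete-state stochastic reaction networks and the Gillespie direct method.

A :class:`ReactionNetwork` is the usual well-stirred jump-process picture: N
species with integer copy numbers, M reaction channels, each channel j
carrying a state-change vector nu_j and a propensity function a_j(x) such
that a_j(x)dt is the probability of one R_j firing in [t, t+dt).

Two simulation entry points are provided:

* :func:`simulate_ssa` — the exact direct method, recording every jump in a
  :class:`Trajectory`; suitable for short runs and first-passage sampling.
* :func:`simulate_time_fractions` — the same direct method with online
  accumulation of the time-weighted copy-number distribution of one species,
  dispatching to a compiled kernel when every propensity is in encodable form;
  this is the path used for 1e6-time-unit stationary-distribution experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from . import _kernel

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "Trajectory",
    "DistributionEstimate",
    "simulate_ssa",
    "simulate_time_fractions",
    "time_fraction_distribution",
    "write_trajectory",
    "read_trajectory",
]


# ---------------------------------------------------------------------------
# Propensity encodings
# ---------------------------------------------------------------------------

_KIND_MASS_ACTION = 0
_KIND_WEIGHTED = 1
_KIND_TABULATED = 2
_KIND_CUSTOM = -1


def _falling_factorial(x: int, order: int) -> float:
    out = 1.0
    for r in range(order):
        out *= x - r
    return out


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: change vector nu_j plus a propensity rule.

    Build instances through the classmethods; they attach the metadata the
    compiled kernel needs.  ``custom`` reactions carry an arbitrary
    state -> rate callable and force the pure-Python simulation path.
    """

    name: str
    change: np.ndarray
    propensity: Callable[[np.ndarray], float]
    kind: int = _KIND_CUSTOM
    rate: float = 0.0
    reactants: tuple[tuple[int, int], ...] = ()  # (species index, order)
    weights: np.ndarray | None = None
    table: np.ndarray | None = None
    table_species: int = -1

    @classmethod
    def mass_action(
        cls,
        name: str,
        change: Sequence[int],
        rate: float,
        reactants: Mapping[int, int] | None = None,
    ) -> "Reaction":
        """a(x) = rate * prod_s x_s (x_s - 1) ... (x_s - order + 1)."""
        if rate < 0:
            raise ValueError(f"reaction {name!r}: rate must be >= 0, got {rate}")
        pairs = tuple(sorted((reactants or {}).items()))

        def _prop(x: np.ndarray, _rate=rate, _pairs=pairs) -> float:
            a = _rate
            for s, order in _pairs:
                a *= _falling_factorial(int(x[s]), order)
            return a

        return cls(
            name=name,
            change=np.asarray(change, dtype=np.int64),
            propensity=_prop,
            kind=_KIND_MASS_ACTION,
            rate=float(rate),
            reactants=pairs,
        )

    @classmethod
    def weighted_mass_action(
        cls,
        name: str,
        change: Sequence[int],
        rate: float,
        reactants: Mapping[int, int],
        weights: Sequence[float],
    ) -> "Reaction":
        """a(x) = rate * (w . x) * falling-factorial part.

        The linear form expresses state-dependent rate "constants", e.g. a
        degradation channel whose rate is proportional to a weighted sum of
        phosphoform populations.
        """
        if rate < 0:
            raise ValueError(f"reaction {name!r}: rate must be >= 0, got {rate}")
        w = np.asarray(weights, dtype=np.float64)
        pairs = tuple(sorted(reactants.items()))

        def _prop(x: np.ndarray, _rate=rate, _pairs=pairs, _w=w) -> float:
            a = _rate * float(_w @ x)
            for s, order in _pairs:
                a *= _falling_factorial(int(x[s]), order)
            return a

        return cls(
            name=name,
            change=np.asarray(change, dtype=np.int64),
            propensity=_prop,
            kind=_KIND_WEIGHTED,
            rate=float(rate),
            reactants=pairs,
            weights=w,
        )

    @classmethod
    def tabulated(
        cls,
        name: str,
        change: Sequence[int],
        species: int,
        table: Sequence[float],
    ) -> "Reaction":
        """a(x) = table[x[species]]; the table is the entire propensity."""
        tab = np.asarray(table, dtype=np.float64)
        if np.any(tab < 0):
            raise ValueError(f"reaction {name!r}: table contains negative entries")

        def _prop(x: np.ndarray, _tab=tab, _s=species) -> float:
            xv = int(x[_s])
            if xv >= _tab.shape[0]:
                raise RuntimeError(
                    f"reaction {name!r}: copy number {xv} beyond table "
                    f"length {_tab.shape[0]}"
                )
            return float(_tab[xv])

        return cls(
            name=name,
            change=np.asarray(change, dtype=np.int64),
            propensity=_prop,
            kind=_KIND_TABULATED,
            reactants=((species, 0),),
            table=tab,
            table_species=species,
        )

    @classmethod
    def custom(
        cls, name: str, change: Sequence[int], fn: Callable[[np.ndarray], float]
    ) -> "Reaction":
        return cls(
            name=name, change=np.asarray(change, dtype=np.int64), propensity=fn
        )


@dataclass(frozen=True)
class ReactionNetwork:
    """Species names plus reaction channels; validates shapes on creation."""

    species_names: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    def __init__(self, species_names: Sequence[str], reactions: Sequence[Reaction]):
        object.__setattr__(self, "species_names", tuple(species_names))
        object.__setattr__(self, "reactions", tuple(reactions))
        n = len(self.species_names)
        if len(set(self.species_names)) != n:
            raise ValueError("duplicate species names")
        for rxn in self.reactions:
            if rxn.change.shape != (n,):
                raise ValueError(
                    f"reaction {rxn.name!r}: change vector has length "
                    f"{rxn.change.shape[0]}, expected {n}"
                )

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def propensities(self, x: np.ndarray) -> np.ndarray:
        a = np.empty(len(self.reactions))
        for j, rxn in enumerate(self.reactions):
            aj = rxn.propensity(x)
            if aj < 0:
                raise ValueError(
                    f"negative propensity {aj} for reaction {rxn.name!r} at state {x}"
                )
            a[j] = aj
        return a

    @property
    def jit_compatible(self) -> bool:
        return all(r.kind != _KIND_CUSTOM for r in self.reactions)

    def _encode(self):
        """Pack reactions into the flat arrays the compiled kernel consumes."""
        m, n = len(self.reactions), self.n_species
        nu = np.zeros((m, n), dtype=np.int64)
        kind = np.zeros(m, dtype=np.int8)
        rate = np.zeros(m, dtype=np.float64)
        kmax = max((len(r.reactants) for r in self.reactions), default=1) or 1
        react_sp = np.full((m, kmax), -1, dtype=np.int64)
        react_ord = np.zeros((m, kmax), dtype=np.int64)
        lin_w = np.zeros((m, n), dtype=np.float64)
        tab_idx = np.full(m, -1, dtype=np.int64)
        tabs = [r.table for r in self.reactions if r.table is not None]
        tlen = max((t.shape[0] for t in tabs), default=1)
        tables = np.zeros((max(len(tabs), 1), tlen), dtype=np.float64)
        ti = 0
        for j, r in enumerate(self.reactions):
            if r.kind == _KIND_CUSTOM:
                raise ValueError(
                    f"reaction {r.name!r} has a custom propensity; "
                    "no compiled encoding"
                )
            nu[j] = r.change
            kind[j] = r.kind
            rate[j] = r.rate
            for q, (s, order) in enumerate(r.reactants):
                react_sp[j, q] = s
                react_ord[j, q] = order
            if r.kind == _KIND_WEIGHTED:
                lin_w[j] = r.weights
            if r.kind == _KIND_TABULATED:
                tables[ti, : r.table.shape[0]] = r.table
                tab_idx[j] = ti
                react_sp[j, 0] = r.table_species
                ti += 1
        return nu, kind, rate, react_sp, react_ord, lin_w, tab_idx, tables


# ---------------------------------------------------------------------------
# Trajectories and time-fraction distributions
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Piecewise-constant SSA path: state[i] holds on [times[i], times[i+1])."""

    times: np.ndarray
    states: np.ndarray
    final_time: float
    stopped_early: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.times.ndim != 1 or self.states.shape[0] != self.times.shape[0]:
            raise ValueError("times and states must have matching leading length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[-1] > self.final_time + 1e-12:
            raise ValueError("last recorded time exceeds final_time")


@dataclass
class DistributionEstimate:
    """Probability mass over integer copy numbers (time-fraction estimate)."""

    support: np.ndarray
    mass: np.ndarray

    def __post_init__(self):
        self.support = np.asarray(self.support, dtype=np.int64)
        self.mass = np.asarray(self.mass, dtype=np.float64)
        if self.support.shape != self.mass.shape or self.support.ndim != 1:
            raise ValueError("support and mass must be 1-D and equal length")
        if np.any(self.mass < -1e-15):
            raise ValueError("negative probability mass")
        total = self.mass.sum()
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"mass sums to {total}, expected 1 within 1e-12")
        if np.any(np.diff(self.support) <= 0):
            raise ValueError("support must be strictly increasing")

    @classmethod
    def from_weights(cls, support, weights) -> "DistributionEstimate":
        w = np.asarray(weights, dtype=np.float64)
        total = w.sum()
        if total <= 0:
            raise ValueError("total weight must be positive")
        keep = w > 0
        return cls(np.asarray(support)[keep], w[keep] / total)

    def as_dict(self) -> dict[int, float]:
        return {int(s): float(m) for s, m in zip(self.support, self.mass)}

    def mean(self) -> float:
        return float(self.support @ self.mass)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("copy_number\tprobability\n")
            for s, m in zip(self.support, self.mass):
                fh.write(f"{int(s)}\t{m:.17g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistributionEstimate":
        data = np.loadtxt(path, skiprows=1, ndmin=2)
        return cls(data[:, 0].astype(np.int64), data[:, 1])


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_ssa(
    network: ReactionNetwork,
    init_state: Sequence[int],
    t_end: float,
    seed,
    stop_predicate: Callable[[np.ndarray], bool] | None = None,
    max_steps: int | None = None,
) -> Trajectory:
    """Exact direct-method SSA, recording every jump.

    Each step draws two uniforms in fixed order: r1 sets the waiting time
    tau = ln(1/r1)/a0, r2 selects the channel as the smallest j with
    cumulative propensity strictly exceeding r2*a0.  The run ends at
    ``t_end``, when the total propensity vanishes, or when
    ``stop_predicate(state)`` first holds (the stopping time is recorded as
    the trajectory's final time).
    """
    x = np.asarray(init_state, dtype=np.int64).copy()
    if np.any(x < 0):
        raise ValueError("initial state must be non-negative")
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    rng = _as_rng(seed)

    times = [0.0]
    states = [x.copy()]
    t = 0.0
    if stop_predicate is not None and stop_predicate(x):
        return Trajectory(np.array(times), np.array(states), 0.0, stopped_early=True)

    steps = 0
    while True:
        a = network.propensities(x)
        a0 = a.sum()
        if a0 <= 0.0:
            return Trajectory(np.array(times), np.array(states), t_end)
        r1 = rng.random()
        r2 = rng.random()
        tau = np.log(1.0 / r1) / a0
        if t + tau >= t_end:
            return Trajectory(np.array(times), np.array(states), t_end)
        t += tau
        # strict inequality: a partial sum exactly equal to the target
        # selects the next channel
        j = int(np.searchsorted(np.cumsum(a), r2 * a0, side="right"))
        x = x + network.reactions[j].change
        if np.any(x < 0):
            raise RuntimeError(
                f"reaction {network.reactions[j].name!r} drove the state negative"
            )
        times.append(t)
        states.append(x.copy())
        if stop_predicate is not None and stop_predicate(x):
            return Trajectory(np.array(times), np.array(states), t, stopped_early=True)
        steps += 1
        if max_steps is not None and steps >= max_steps:
            raise RuntimeError(f"exceeded max_steps={max_steps} before t_end")


def time_fraction_distribution(
    traj: Trajectory, species_index: int, burn_in: float = 0.0
) -> DistributionEstimate:
    """Fraction of simulated time a species spends at each copy number.

    mass(x) = (time spent at copy number x after burn_in) / (final_time - burn_in).
    """
    if burn_in >= traj.final_time:
        raise ValueError("burn_in must be smaller than the trajectory final time")
    edges = np.append(traj.times, traj.final_time)
    lo = np.maximum(edges[:-1], burn_in)
    hi = np.minimum(edges[1:], traj.final_time)
    dwell = np.maximum(hi - lo, 0.0)
    values = traj.states[:, species_index]
    support = np.unique(values)
    weights = np.zeros(support.shape[0])
    idx = np.searchsorted(support, values)
    np.add.at(weights, idx, dwell)
    return DistributionEstimate.from_weights(support, weights)


def simulate_time_fractions(
    network: ReactionNetwork,
    init_state: Sequence[int],
    t_end: float,
    seed,
    species_index: int,
    burn_in: float = 0.0,
    hist_size: int = 4096,
) -> DistributionEstimate:
    """Long-run SSA returning only the time-fraction distribution of one species.

    Dwell times are accumulated online, so arbitrarily long horizons need O(1)
    memory.  Networks whose propensities are all mass-action / weighted /
    tabulated run in the compiled kernel; custom propensities fall back to a
    Python loop (same estimator, different RNG stream).
    """
    x = np.asarray(init_state, dtype=np.int64).copy()
    if np.any(x < 0):
        raise ValueError("initial state must be non-negative")
    if not 0 <= burn_in < t_end:
        raise ValueError("need 0 <= burn_in < t_end")

    if network.jit_compatible:
        nu, kind, rate, react_sp, react_ord, lin_w, tab_idx, tables = network._encode()
        hist = np.zeros(hist_size, dtype=np.float64)
        state, inc = _kernel.pcg_init(int(seed))
        t, n_steps, status, _ = _kernel.ssa_time_fraction(
            x, nu, kind, rate, react_sp, react_ord, lin_w, tab_idx, tables,
            float(t_end), float(burn_in), int(species_index), hist, state, inc,
        )
        if status == _kernel.ERR_NEGATIVE_PROPENSITY:
            raise RuntimeError("negative propensity encountered in compiled SSA")
        if status == _kernel.ERR_TABLE_OVERFLOW:
            raise RuntimeError("tabulated propensity: copy number beyond table")
        if status == _kernel.ERR_HIST_OVERFLOW:
            raise RuntimeError(
                f"histogram overflow: raise hist_size (currently {hist_size})"
            )
        return DistributionEstimate.from_weights(np.arange(hist_size), hist)

    # python fallback with online accumulation
    rng = _as_rng(seed)
    hist: dict[int, float] = {}
    t = 0.0
    while True:
        a = network.propensities(x)
        a0 = a.sum()
        if a0 <= 0.0:
            seg = t_end - max(t, burn_in)
            if seg > 0:
                xv = int(x[species_index])
                hist[xv] = hist.get(xv, 0.0) + seg
            break
        r1 = rng.random()
        tau = np.log(1.0 / r1) / a0
        seg0 = max(t, burn_in)
        seg1 = min(t + tau, t_end)
        if seg1 > seg0:
            xv = int(x[species_index])
            hist[xv] = hist.get(xv, 0.0) + (seg1 - seg0)
        if t + tau >= t_end:
            break
        t += tau
        r2 = rng.random()
        j = int(np.searchsorted(np.cumsum(a), r2 * a0, side="right"))
        x = x + network.reactions[j].change
    support = np.array(sorted(hist))
    return DistributionEstimate.from_weights(support, [hist[s] for s in support])


# ---------------------------------------------------------------------------
# Trajectory I/O: TSV + JSON sidecar
# ---------------------------------------------------------------------------


def write_trajectory(
    traj: Trajectory,
    network: ReactionNetwork,
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time\t" + "\t".join(network.species_names) + "\n")
        for t, row in zip(traj.times, traj.states):
            fh.write(f"{t:.17g}\t" + "\t".join(str(int(v)) for v in row) + "\n")
    sidecar = {
        "species": list(network.species_names),
        "final_time": traj.final_time,
        "stopped_early": traj.stopped_early,
    }
    sidecar.update(metadata or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Trajectory(
        data[:, 0],
        data[:, 1:].astype(np.int64),
        float(meta["final_time"]),
        stopped_early=bool(meta.get("stopped_early", False)),
    )
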