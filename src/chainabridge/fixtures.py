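"""Random chain fixtures and declarative experiment configs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .chain_spectral import (
    ChainSpec,
    relaxation_time,
    spectral_report,
)
from .exit_time import exponential_deviation, survival_function
from .metrics import reproduce_switch_comparison
from .models import SwitchParams
from .reaction_network import (
    Reaction,
    ReactionNetwork,
    simulate_ssa,
    time_fraction_distribution,
    write_trajectory,
)

__all__ = [
    "FixtureConfig",
    "generate_random_chains",
    "run_config",
    "network_from_dict",
    "chain_from_dict",
]

logger = logging.getLogger("chainabridge")


@dataclass(frozen=True)
class FixtureConfig:
    """Recipe for reproducible random chains with log-uniform rates.

    ``rho_target`` rescales each chain's exit rate so that
    f_n * T_relax hits the requested validity ratio exactly.
    """

    count: int
    seed: int
    n_range: tuple[int, int] = (2, 12)
    rate_log10_range: tuple[float, float] = (-2.0, 2.0)
    rho_target: float | None = None

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.n_range[0] < 2 or self.n_range[1] < self.n_range[0]:
            raise ValueError("n_range must be non-empty with lower bound >= 2")
        if self.rate_log10_range[1] < self.rate_log10_range[0]:
            raise ValueError("rate_log10_range must be non-empty")


def generate_random_chains(cfg: FixtureConfig) -> list[ChainSpec]:
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.rate_log10_range
    chains = []
    for _ in range(cfg.count):
        n = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        forward = 10.0 ** rng.uniform(lo, hi, size=n - 1)
        backward = 10.0 ** rng.uniform(lo, hi, size=n - 1)
        exit_rate = 10.0 ** rng.uniform(lo, hi)
        chain = ChainSpec(
            n=n, forward=tuple(forward), backward=tuple(backward),
            exit_rate=float(exit_rate),
        )
        if cfg.rho_target is not None:
            t_relax = relaxation_time(chain)
            chain = ChainSpec(
                n=n, forward=tuple(forward), backward=tuple(backward),
                exit_rate=float(cfg.rho_target / t_relax),
            )
        chains.append(chain)
    return chains


# ---------------------------------------------------------------------------
# Declarative model / chain schemas (YAML)
# ---------------------------------------------------------------------------


def _fail(path: str, msg: str):
    raise ValueError(f"config error at {path}: {msg}")


def chain_from_dict(d: dict, path: str = "chain") -> ChainSpec:
    for key in ("n", "forward", "backward", "exit_rate"):
        if key not in d:
            _fail(f"{path}.{key}", "missing required field")
    for key in ("forward", "backward"):
        if any(v < 0 for v in d[key]):
            _fail(f"{path}.{key}", "rates must be non-negative")
    if d["exit_rate"] < 0:
        _fail(f"{path}.exit_rate", "rates must be non-negative")
    try:
        return ChainSpec(
            n=int(d["n"]),
            forward=tuple(d["forward"]),
            backward=tuple(d["backward"]),
            exit_rate=float(d["exit_rate"]),
            exit_index=d.get("exit_index"),
            particles=int(d.get("particles", 1)),
        )
    except ValueError as exc:
        _fail(path, str(exc))


def network_from_dict(d: dict, path: str = "model") -> ReactionNetwork:
    """Declarative network: species list plus mass-action/weighted/tabulated
    reactions keyed by species name."""
    if "species" not in d or "reactions" not in d:
        _fail(path, "must declare 'species' and 'reactions'")
    species = list(d["species"])
    index = {s: i for i, s in enumerate(species)}
    reactions = []
    for rnum, rd in enumerate(d["reactions"]):
        rpath = f"{path}.reactions[{rnum}]"
        if "change" not in rd:
            _fail(rpath + ".change", "missing required field")
        change = np.zeros(len(species), dtype=int)
        for name, delta in rd["change"].items():
            if name not in index:
                _fail(rpath + ".change", f"unknown species {name!r}")
            change[index[name]] = int(delta)
        rname = rd.get("name", f"R{rnum}")
        if "table" in rd:
            if "table_species" not in rd:
                _fail(rpath + ".table_species", "required with 'table'")
            reactions.append(
                Reaction.tabulated(
                    rname, change, index[rd["table_species"]], rd["table"]
                )
            )
            continue
        if "rate" not in rd:
            _fail(rpath + ".rate", "missing required field")
        if rd["rate"] < 0:
            _fail(rpath + ".rate", "must be >= 0")
        reactants = {
            index[name]: int(order)
            for name, order in rd.get("reactants", {}).items()
        }
        if "weights" in rd:
            w = np.zeros(len(species))
            for name, wv in rd["weights"].items():
                if name not in index:
                    _fail(rpath + ".weights", f"unknown species {name!r}")
                w[index[name]] = float(wv)
            reactions.append(
                Reaction.weighted_mass_action(
                    rname, change, float(rd["rate"]), reactants, w
                )
            )
        else:
            reactions.append(
                Reaction.mass_action(rname, change, float(rd["rate"]), reactants)
            )
    return ReactionNetwork(species, reactions)


def run_config(path: str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute a declared experiment from a YAML file.

    Supported tasks: ``analyze-chain``, ``exit-time``, ``simulate``,
    ``switch-compare``, ``gen-fixtures``.  Returns a summary dict and writes
    any requested artifacts under ``out_dir`` (default: alongside the
    config).
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict) or "task" not in cfg:
        _fail("task", "config must be a mapping with a 'task' field")
    out_dir = Path(out_dir) if out_dir is not None else path.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    task = cfg["task"]
    seed = int(cfg.get("seed", 0))
    logger.info("run_config task=%s seed=%d config=%s", task, seed, path)

    if task == "analyze-chain":
        chain = chain_from_dict(cfg.get("chain", {}))
        report = spectral_report(chain).to_dict()
        if "out" in cfg:
            (out_dir / cfg["out"]).write_text(json.dumps(report, indent=2))
        return report

    if task == "exit-time":
        chain = chain_from_dict(cfg.get("chain", {}))
        t_max = float(cfg.get("t_max", 10.0))
        num = int(cfg.get("num_points", 401))
        rep = spectral_report(chain)
        grid = np.linspace(0.0, t_max / rep.c_single, num)
        curve = survival_function(chain, grid)
        result = {
            "deviation": exponential_deviation(chain),
            "c_single": rep.c_single,
        }
        if "out" in cfg:
            curve.to_tsv(out_dir / cfg["out"])
            (out_dir / (cfg["out"] + ".json")).write_text(
                json.dumps(result, indent=2)
            )
        return result

    if task == "simulate":
        network = network_from_dict(cfg.get("model", {}))
        init = np.array(
            [int(cfg.get("init", {}).get(s, 0)) for s in network.species_names]
        )
        t_end = float(cfg.get("t_end", 1.0))
        traj = simulate_ssa(network, init, t_end, seed)
        summary = {"n_jumps": int(traj.times.shape[0] - 1), "t_end": t_end}
        if "out" in cfg:
            write_trajectory(traj, network, out_dir / cfg["out"], {"seed": seed})
        if cfg.get("distribution_species") is not None:
            sp = network.species_index(cfg["distribution_species"])
            burn = float(cfg.get("burn_in", 0.0))
            dist = time_fraction_distribution(traj, sp, burn)
            if "distribution_out" in cfg:
                dist.to_tsv(out_dir / cfg["distribution_out"])
            summary["distribution_mean"] = dist.mean()
        return summary

    if task == "switch-compare":
        params = SwitchParams(
            k=float(cfg["k"]),
            **{
                key: cfg[key]
                for key in ("k_p", "k_a", "k_s", "m", "levels", "clb2_init")
                if key in cfg
            },
        )
        t_end = float(cfg.get("t_end", 1e6))
        res = reproduce_switch_comparison(params, t_end, seed)
        summary = {"error_pct": res.error_pct, "k": params.k, "t_end": t_end}
        if "out" in cfg:
            stem = out_dir / cfg["out"]
            res.dist_full.to_tsv(str(stem) + ".full.tsv")
            res.dist_reduced.to_tsv(str(stem) + ".reduced.tsv")
            Path(str(stem) + ".json").write_text(json.dumps(summary, indent=2))
        return summary

    if task == "gen-fixtures":
        fcfg = FixtureConfig(
            count=int(cfg.get("count", 10)),
            seed=seed,
            n_range=tuple(cfg.get("n_range", (2, 12))),
            rate_log10_range=tuple(cfg.get("rate_log10_range", (-2.0, 2.0))),
            rho_target=cfg.get("rho_target"),
        )
        chains = generate_random_chains(fcfg)
        payload = [
            {
                "n": c.n,
                "forward": list(c.forward),
                "backward": list(c.backward),
                "exit_rate": c.exit_rate,
            }
            for c in chains
        ]
        if "out" in cfg:
            (out_dir / cfg["out"]).write_text(json.dumps(payload, indent=2))
        return {"count": len(chains)}

    _fail("task", f"unknown task {task!r}")
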