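"""Paired-ensemble experiment harness.

The central design throughout is the *paired ensemble*: for each run a fresh
landscape realization is drawn, and a recombining (fraction ``r``) and a
non-recombining (``r = 0``) population evolve on that same realization from
the same monomorphic start, with independent demographic noise.  Averaging
the per-pair differences over runs isolates the effect of recombination from
landscape-to-landscape variability.

Reproducibility rests on a counter-based seed schedule: a master seed plus a
run index deterministically yields four independent streams (landscape,
recombining dynamics, non-recombining dynamics, environment), so ensembles
can be extended or distributed without replaying earlier runs, and parameter
sweeps reuse the same landscape seed for run ``k`` at every swept value.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .finite_dynamics import INFINITE, DynamicsParams, run_finite
from .infinite_dynamics import run_infinite
from .landscapes import FitnessLandscape, LandscapeParams, generate_landscape
from .observables import (
    AdvantageSummary,
    TrapEvent,
    advantage_summary,
    detect_trap_escape,
)
from .seascape import SeascapeParams, run_seascape

__all__ = [
    "ExperimentConfig",
    "PairedEnsembleResult",
    "run_seeds",
    "paired_ensemble",
    "sweep",
    "make_fixture",
    "FIXTURE_NAMES",
    "save_delta_tsv",
]

#: sweepable parameter name -> (section, field)
SWEEPABLE = {
    "r": ("dynamics", "r"),
    "mu": ("dynamics", "mu"),
    "N": ("dynamics", "N"),
    "lam": ("landscape", "lam"),
    "c": ("landscape", "c"),
    "L": ("landscape", "L"),
    "p_reset": ("seascape", "p_reset"),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce a paired ensemble."""

    landscape: LandscapeParams
    dynamics: DynamicsParams
    t_max: int
    n_runs: int
    master_seed: int
    seascape: "SeascapeParams | None" = None
    sweep: "tuple[str, tuple] | None" = None
    engine: str = "finite"
    start: "int | None" = None
    precision: "int | None" = None

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.t_max < 0:
            raise ValueError("t_max must be >= 0")
        if self.engine not in ("finite", "infinite"):
            raise ValueError("engine must be 'finite' or 'infinite'")
        if self.sweep is not None and self.sweep[0] not in SWEEPABLE:
            raise ValueError(
                f"unknown sweep parameter {self.sweep[0]!r}; "
                f"choose from {sorted(SWEEPABLE)}"
            )

    def to_dict(self) -> dict:
        d = {
            "landscape": self.landscape.to_dict(),
            "dynamics": dataclasses.asdict(self.dynamics),
            "t_max": self.t_max,
            "n_runs": self.n_runs,
            "master_seed": self.master_seed,
            "engine": self.engine,
            "start": self.start,
            "precision": self.precision,
        }
        if self.seascape is not None:
            d["seascape"] = {
                "p_reset": self.seascape.p_reset,
                "mode": self.seascape.mode,
                "base": self.seascape.base.to_dict(),
            }
        if self.sweep is not None:
            d["sweep"] = {"param": self.sweep[0], "values": list(self.sweep[1])}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        land = LandscapeParams.from_dict(d.pop("landscape"))
        dyn = DynamicsParams(**d.pop("dynamics"))
        sea = None
        if "seascape" in d and d["seascape"] is not None:
            s = d.pop("seascape")
            sea = SeascapeParams(
                p_reset=s["p_reset"],
                mode=s["mode"],
                base=LandscapeParams.from_dict(s.get("base", land.to_dict())),
            )
        else:
            d.pop("seascape", None)
        sw = None
        if "sweep" in d and d["sweep"] is not None:
            s = d.pop("sweep")
            sw = (s["param"], tuple(s["values"]))
        else:
            d.pop("sweep", None)
        return cls(landscape=land, dynamics=dyn, seascape=sea, sweep=sw, **d)

    @classmethod
    def from_file(cls, path: "str | Path") -> "ExperimentConfig":
        path = Path(path)
        with open(path) as fh:
            d = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls.from_dict(d)


def run_seeds(master_seed: int, run_idx: int) -> "dict[str, np.random.SeedSequence]":
    """Derive the four per-run RNG streams from the master seed.

    Counter-based: stream ``j`` of run ``k`` is
    ``SeedSequence(master_seed, spawn_key=(k, j))``, so any run of any
    ensemble extension is reachable without drawing intermediate state.
    """
    names = ("landscape", "dyn_r", "dyn_nr", "env")
    return {
        name: np.random.SeedSequence(master_seed, spawn_key=(run_idx, j))
        for j, name in enumerate(names)
    }


@dataclass
class PairedEnsembleResult:
    """Run-averaged difference series plus per-run bookkeeping.

    ``per_run`` maps ``'F_r', 'F_nr', 'S_r', 'S_nr', 'Fmax_r', 'Fmax_nr'``
    to ``(n_runs, t_max + 1)`` arrays, so standard errors of any windowed
    statistic can be computed across runs after the fact.
    """

    config: ExperimentConfig
    delta: pd.DataFrame
    summary: AdvantageSummary
    per_run: "dict[str, np.ndarray]"
    events_r: "list[list[TrapEvent]]"
    events_nr: "list[list[TrapEvent]]"
    landscape_seeds: "list[int]"
    trajectories: "list[tuple[list, list]] | None" = None

    def per_run_delta_F(self) -> np.ndarray:
        return self.per_run["F_r"] - self.per_run["F_nr"]


def _landscape_for_run(cfg: ExperimentConfig, seeds) -> FitnessLandscape:
    ss = seeds["landscape"]
    # record the derived integer seed in the params so the landscape can be
    # regenerated from its serialized sidecar alone
    lp = dc_replace(cfg.landscape, seed=int(ss.generate_state(1)[0]))
    return generate_landscape(lp)


def paired_ensemble(
    cfg: ExperimentConfig, keep_trajectories: bool = False
) -> PairedEnsembleResult:
    """Run the paired r-vs-0 ensemble described by ``cfg``.

    Each run draws its own landscape; the two arms share it (and, on a
    seascape, the whole environmental history) but use independent dynamics
    streams.  Fully reproducible from ``cfg.master_seed``.
    """
    n_t = cfg.t_max + 1
    per_run = {
        key: np.empty((cfg.n_runs, n_t))
        for key in ("F_r", "F_nr", "S_r", "S_nr", "Fmax_r", "Fmax_nr")
    }
    pairs = []
    events_r: "list[list[TrapEvent]]" = []
    events_nr: "list[list[TrapEvent]]" = []
    land_seeds: "list[int]" = []
    dp = cfg.dynamics
    dp_nr = dc_replace(dp, r=0.0)
    for k in range(cfg.n_runs):
        seeds = run_seeds(cfg.master_seed, k)
        land = _landscape_for_run(cfg, seeds)
        land_seeds.append(land.params.seed)
        start = cfg.start if cfg.start is not None else land.params.sigma_star
        if cfg.engine == "infinite":
            traj_r = run_infinite(
                land, dp.mu, dp.r, cfg.t_max, start=start,
                precision=cfg.precision, theta_trap=dp.theta_trap,
            )
            traj_nr = run_infinite(
                land, dp.mu, 0.0, cfg.t_max, start=start,
                precision=cfg.precision, theta_trap=dp.theta_trap,
            )
        elif cfg.seascape is not None:
            # both arms see the same environment: same env seed, fresh stream each
            traj_r = run_seascape(
                dp, cfg.seascape, cfg.t_max, start=start,
                dyn_rng=np.random.default_rng(seeds["dyn_r"]),
                env_rng=np.random.default_rng(seeds["env"]),
                land=land,
            )
            traj_nr = run_seascape(
                dp_nr, cfg.seascape, cfg.t_max, start=start,
                dyn_rng=np.random.default_rng(seeds["dyn_nr"]),
                env_rng=np.random.default_rng(seeds["env"]),
                land=land,
            )
        else:
            traj_r = run_finite(
                land, dp, cfg.t_max, start=start,
                rng=np.random.default_rng(seeds["dyn_r"]),
            )
            traj_nr = run_finite(
                land, dp_nr, cfg.t_max, start=start,
                rng=np.random.default_rng(seeds["dyn_nr"]),
            )
        for key, traj in (("r", traj_r), ("nr", traj_nr)):
            per_run[f"F_{key}"][k] = [rec.mean_fitness for rec in traj]
            per_run[f"S_{key}"][k] = [rec.entropy for rec in traj]
            per_run[f"Fmax_{key}"][k] = [rec.max_fitness for rec in traj]
        if cfg.seascape is None:
            events_r.append(
                detect_trap_escape(traj_r, land, dp.theta_trap, dp.theta_escape, start)
            )
            events_nr.append(
                detect_trap_escape(traj_nr, land, dp.theta_trap, dp.theta_escape, start)
            )
        else:
            events_r.append([])
            events_nr.append([])
        if keep_trajectories:
            pairs.append((traj_r, traj_nr))
    fr, fn = per_run["F_r"], per_run["F_nr"]
    delta = pd.DataFrame(
        {
            "t": np.arange(n_t),
            "delta_F": (fr - fn).mean(axis=0),
            "delta_S": (per_run["S_r"] - per_run["S_nr"]).mean(axis=0),
            "delta_Fmax": (per_run["Fmax_r"] - per_run["Fmax_nr"]).mean(axis=0),
            "P_plus": ((fr > fn) + 0.5 * (fr == fn)).mean(axis=0),
            "n_pairs": cfg.n_runs,
        }
    )
    summary = advantage_summary(delta["delta_F"].to_numpy())
    return PairedEnsembleResult(
        config=cfg,
        delta=delta,
        summary=summary,
        per_run=per_run,
        events_r=events_r,
        events_nr=events_nr,
        landscape_seeds=land_seeds,
        trajectories=pairs if keep_trajectories else None,
    )


def _with_param(cfg: ExperimentConfig, name: str, value) -> ExperimentConfig:
    section, field = SWEEPABLE[name]
    if section == "landscape":
        land = dc_replace(cfg.landscape, **{field: value})
        sea = cfg.seascape
        if sea is not None:
            sea = dc_replace(sea, base=dc_replace(sea.base, **{field: value}))
        return dc_replace(cfg, landscape=land, seascape=sea, sweep=None)
    if section == "dynamics":
        return dc_replace(cfg, dynamics=dc_replace(cfg.dynamics, **{field: value}), sweep=None)
    if cfg.seascape is None:
        raise ValueError("p_reset sweep requires a seascape section")
    return dc_replace(cfg, seascape=dc_replace(cfg.seascape, **{field: value}), sweep=None)


def sweep(cfg: ExperimentConfig, keep_trajectories: bool = False):
    """One paired ensemble per swept value, sharing the master seed schedule.

    Returns a dict keyed by parameter value.  Because run ``k`` reuses the
    same landscape seed at every value, differences across the sweep reflect
    only the swept parameter.
    """
    if cfg.sweep is None:
        raise ValueError("config has no sweep section")
    name, values = cfg.sweep
    return {
        v: paired_ensemble(_with_param(cfg, name, v), keep_trajectories)
        for v in values
    }


def save_delta_tsv(result: PairedEnsembleResult, path: "str | Path") -> None:
    """Difference series as TSV with the config echoed in '#' header lines."""
    with open(path, "w") as fh:
        for line in json.dumps(result.config.to_dict(), indent=1).splitlines():
            fh.write(f"# {line}\n")
        result.delta.to_csv(fh, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# deterministic tiny fixtures with hand-computed properties
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("two_locus_valley", "two_peak_L3", "additive_L3")


def make_fixture(name: str) -> "tuple[FitnessLandscape, dict]":
    """Tiny explicit landscapes for tests, with hand-computed expectations.

    ``two_locus_valley``: F = (1, 0.5, 0.5, 2) on L=2 — local maxima {00, 11},
    a fitness valley between them.
    ``two_peak_L3``: an L=3 landscape with exactly the two peaks {000, 111}.
    ``additive_L3``: c=1 additive landscape, single peak at 111.
    """
    if name == "two_locus_valley":
        params = LandscapeParams(L=2, model="hoc", c=0.0, lam=1.0, seed=0)
        F = np.array([1.0, 0.5, 0.5, 2.0])
        land = FitnessLandscape(params=params, F=F, eta=F.copy())
        expected = {
            "local_maxima": {0b00, 0b11},
            "global_maximum": 0b11,
            "uniform_entropy": 2 * np.log(2.0),
        }
        return land, expected
    if name == "two_peak_L3":
        params = LandscapeParams(L=3, model="hoc", c=0.0, lam=1.0, seed=0)
        # peaks at 000 and 111; every other genotype below both neighbours' peaks
        F = np.array([3.0, 1.0, 1.2, 2.0, 1.1, 1.9, 2.1, 4.0])
        land = FitnessLandscape(params=params, F=F, eta=F.copy())
        expected = {"local_maxima": {0b000, 0b111}, "global_maximum": 0b111}
        return land, expected
    if name == "additive_L3":
        params = LandscapeParams(L=3, model="additive", c=1.0, lam=0.0, seed=0)
        land = generate_landscape(params)
        expected = {
            "local_maxima": {0b111},
            "global_maximum": 0b111,
            "F": [0.0, 1.0, 1.0, 2.0, 1.0, 2.0, 2.0, 3.0],
        }
        return land, expected
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
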