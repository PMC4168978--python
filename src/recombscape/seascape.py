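"""Fitness seascapes: landscapes that are stochastically reset in time.

At each generation, with probability ``p_reset``, the environment changes:
every random fitness component is redrawn from its original law and the
reference sequence moves — to a uniformly chosen Hamming-1 neighbour
(*soft* reset, a small environmental shift) or to a uniformly random
genotype (*hard* reset, an abrupt one).  The slope ``c``, ruggedness ``lam``
and locus count ``L`` are conserved, so the statistical character of the
environment is stationary even though every epoch has fresh peaks.

Environmental randomness (reset times, new components, new reference) is
drawn from its own RNG stream so that a recombining and a non-recombining
population can be exposed to the *same* environment while keeping their
demographic noise independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .finite_dynamics import DynamicsParams, FinitePopulation, step_finite
from .landscapes import FitnessLandscape, LandscapeParams, generate_landscape
from .observables import TrajectoryRecord, make_record

__all__ = [
    "SeascapeParams",
    "reset_landscape",
    "run_seascape",
    "stationary_advantage",
]


@dataclass(frozen=True)
class SeascapeParams:
    """Reset law of a fitness seascape.

    ``p_reset`` is the per-generation reset probability, so epochs between
    resets are geometric with mean ``1 / p_reset`` generations; ``mode`` is
    ``'soft'`` or ``'hard'``; ``base`` gives the landscape family that every
    epoch is drawn from.
    """

    p_reset: float
    mode: str
    base: LandscapeParams

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_reset <= 1.0):
            raise ValueError("p_reset must lie in [0, 1]")
        if self.mode not in ("soft", "hard"):
            raise ValueError("mode must be 'soft' or 'hard'")
        if self.base.model == "nk":
            raise ValueError("seascape resets are defined for the RMF family only")

    @property
    def expected_epoch(self) -> float:
        return float("inf") if self.p_reset == 0 else 1.0 / self.p_reset


def reset_landscape(
    land: FitnessLandscape, mode: str, rng: np.random.Generator
) -> FitnessLandscape:
    """Redraw the random fitness components and move the reference sequence.

    The exponential components are redrawn i.i.d. with the original mean
    ``lam``; the new reference is a uniform Hamming-1 neighbour of the old
    one (``'soft'``) or uniform over all genotypes (``'hard'``).  ``c``,
    ``lam`` and ``L`` are unchanged.
    """
    params = land.params
    if params.model == "nk":
        raise ValueError("seascape resets are defined for the RMF family only")
    L = params.L
    if mode == "soft":
        new_star = params.sigma_star ^ (1 << int(rng.integers(0, L)))
    elif mode == "hard":
        new_star = int(rng.integers(0, 1 << L))
    else:
        raise ValueError("mode must be 'soft' or 'hard'")
    new_params = dc_replace(params, sigma_star=new_star)
    n = params.n_genotypes
    if params.lam > 0:
        eta = -params.lam * np.log1p(-rng.random(n))
    else:
        eta = np.zeros(n)
    g = np.arange(n, dtype=np.int64)
    d = np.bitwise_count(g ^ np.int64(new_star)).astype(np.float64)
    F = params.c * d + eta
    eta = F - params.c * d  # representable residual, as in fresh generation
    return FitnessLandscape(params=new_params, F=F, eta=eta)


def run_seascape(
    dp: DynamicsParams,
    sp: SeascapeParams,
    t_max: int,
    start: "int | None" = None,
    dyn_rng: "np.random.Generator | int | None" = None,
    env_rng: "np.random.Generator | int | None" = None,
    land: "FitnessLandscape | None" = None,
) -> "list[TrajectoryRecord]":
    """Finite-population trajectory on a resetting landscape.

    Identical to the static engine except that, before each generation's
    substeps, the landscape is replaced via :func:`reset_landscape` with
    probability ``p_reset``.  Reset decisions and redraws consume only
    ``env_rng``, demographic noise only ``dyn_rng`` — with ``p_reset = 0``
    the trajectory is bit-identical to a static run with the same dynamics
    seed.  Records carry ``reset_flag`` on reset generations.
    """
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    if not isinstance(dyn_rng, np.random.Generator):
        dyn_rng = np.random.default_rng(dyn_rng if dyn_rng is not None else dp.seed)
    if not isinstance(env_rng, np.random.Generator):
        env_rng = np.random.default_rng(env_rng)
    if land is None:
        land = generate_landscape(sp.base, env_rng)
    if start is None:
        start = land.params.sigma_star
    N = int(dp.N)
    pop = FinitePopulation.monomorphic(land.L, start, N)
    records = [
        make_record(0, pop.frequencies(), land, dp.theta_trap, presence=pop.counts > 0)
    ]
    for _ in range(t_max):
        reset = bool(env_rng.random() < sp.p_reset)
        if reset:
            land = reset_landscape(land, sp.mode, env_rng)
        pop = step_finite(pop, land, dp, dyn_rng)
        records.append(
            make_record(
                pop.t,
                pop.frequencies(),
                land,
                dp.theta_trap,
                reset_flag=reset,
                presence=pop.counts > 0,
            )
        )
    return records


def stationary_advantage(
    delta: "np.ndarray | list[float]", window: "tuple[int, int]" = (5000, 20000)
) -> float:
    """Mean of the advantage series over a late, stationary time window.

    ``delta[t]`` is indexed by generation; the closed window ``[t_lo, t_hi]``
    defaults to generations 5000-20000, late enough for the mean fitness
    difference on a seascape to have become stationary.
    """
    delta = np.asarray(delta, dtype=float)
    t_lo, t_hi = window
    if not (0 <= t_lo <= t_hi < delta.size):
        raise ValueError(
            f"window [{t_lo}, {t_hi}] outside the series range [0, {delta.size - 1}]"
        )
    return float(delta[t_lo : t_hi + 1].mean())
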