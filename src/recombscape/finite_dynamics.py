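"""Wright-Fisher dynamics with a recombining fraction, finite N.

One generation applies four substeps to a population of ``N`` haploid
individuals distributed over the ``2**L`` genotypes:

1. **Mutation** (deterministic flow on frequencies): a fraction ``mu`` of
   each genotype's carriers moves to its ``L`` single-mutant neighbours,
   ``mu / L`` to each.
2. **Selection** (deterministic): frequencies are reweighted by relative
   fitness, ``p'_g = p_g F_g / Fbar``.
3. **Random sampling**: each genotype count is drawn independently from a
   Poisson law with mean ``N p_g`` (faster than one multinomial and
   equivalent up to the total-size fluctuation), then the total is restored
   to exactly ``N``.
4. **Recombination**: ``k ~ Poisson(r N)`` individuals (all ``N`` when
   ``r = 1``) are replaced by uniform-crossover offspring of two parents
   drawn uniformly, with replacement, from the pre-replacement population.

The first two substeps act on real-valued frequencies; only sampling
re-integerizes, so all demographic noise lives in steps 3-4.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np

from .landscapes import FitnessLandscape, neighbor_table, genotype_bits
from .observables import TrajectoryRecord, make_record

__all__ = [
    "INFINITE",
    "DynamicsParams",
    "FinitePopulation",
    "mutation_step",
    "selection_step",
    "sampling_step",
    "uniform_crossover",
    "recombination_step",
    "step_finite",
    "run_finite",
    "write_trajectory_tsv",
]

#: sentinel population size selecting the deterministic engine
INFINITE = math.inf


@dataclass(frozen=True)
class DynamicsParams:
    """Population-dynamics parameters.

    ``N`` — population size (or :data:`INFINITE` for the deterministic
    engine); ``mu`` — genome-wide per-generation mutation probability;
    ``r`` — fraction of the population replaced by recombinants each
    generation; ``theta_trap`` / ``theta_escape`` — modal-frequency
    thresholds declaring trapping and escape at a local maximum.
    """

    N: "int | float"
    mu: float
    r: float
    theta_trap: float = 0.95
    theta_escape: float = 0.5
    seed: "int | None" = None

    def __post_init__(self) -> None:
        if self.N != INFINITE and (self.N < 1 or int(self.N) != self.N):
            raise ValueError("N must be a positive integer or INFINITE")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")
        if not (0.0 <= self.r <= 1.0):
            raise ValueError("r must lie in [0, 1]")
        if not (0 < self.theta_escape < self.theta_trap < 1):
            raise ValueError("need 0 < theta_escape < theta_trap < 1")

    @property
    def mutation_supply(self) -> float:
        """Expected number of new mutants per generation, N*mu."""
        return self.N * self.mu


@dataclass
class FinitePopulation:
    """Integer occupancy of the genotype space, summing to N."""

    counts: np.ndarray
    N: int
    t: int = 0

    @classmethod
    def monomorphic(cls, L: int, genotype: int, N: int) -> "FinitePopulation":
        counts = np.zeros(1 << L, dtype=np.int64)
        counts[genotype] = N
        return cls(counts=counts, N=N)

    def frequencies(self) -> np.ndarray:
        return self.counts / self.N

    def check(self) -> None:
        if self.counts.sum() != self.N or np.any(self.counts < 0):
            raise AssertionError("population counts corrupted")


def mutation_step(p: np.ndarray, mu: float, L: int) -> np.ndarray:
    """Deterministic single-mutation flow: ``p' = (1-mu) p + (mu/L) A p``."""
    if not (0.0 <= mu <= 1.0):
        raise ValueError("mu must lie in [0, 1]")
    p = np.asarray(p, dtype=float)
    if mu == 0.0:
        return p.copy()
    nbrs = neighbor_table(L)
    return (1.0 - mu) * p + (mu / L) * p[nbrs].sum(axis=1)


def selection_step(p: np.ndarray, land: FitnessLandscape) -> np.ndarray:
    """Multiplicative selection: ``p'_g = p_g F_g / Fbar``."""
    p = np.asarray(p, dtype=float)
    w = p * land.F
    s = w.sum()
    if s <= 0.0:
        raise ValueError("mean fitness is zero; selection undefined")
    return w / s


def sampling_step(
    p: np.ndarray, N: int, rng: np.random.Generator
) -> np.ndarray:
    """Poisson resampling of counts with the total forced back to N.

    Each count is Poisson(``N p_g``).  If the realized total exceeds N,
    surplus individuals are removed uniformly at random (multivariate
    hypergeometric draw); if it falls short, the deficit is refilled by
    sampling genotypes proportionally to the realized counts (or to ``p``
    if every count came out zero).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    counts = rng.poisson(N * np.asarray(p, dtype=float))
    total = int(counts.sum())
    if total > N:
        counts = rng.multivariate_hypergeometric(counts, N)
    elif total < N:
        if total > 0:
            extra = rng.multinomial(N - total, counts / total)
        else:
            extra = rng.multinomial(N, np.asarray(p, dtype=float))
        counts = counts + extra
    return counts.astype(np.int64)


def uniform_crossover(a: int, b: int, L: int, rng: np.random.Generator) -> int:
    """Offspring taking each locus from parent ``a`` or ``b`` with prob 1/2."""
    mask = int(rng.integers(0, 1 << L))
    return (a & mask) | (b & ~mask & ((1 << L) - 1))


def recombination_step(
    pop: FinitePopulation, r: float, rng: np.random.Generator
) -> FinitePopulation:
    """Replace ``k ~ Poisson(rN)`` individuals by recombinant offspring.

    ``k`` is truncated at N (and equals N deterministically when ``r = 1``).
    Replaced slots are chosen uniformly without replacement; each offspring's
    two parents are independent uniform draws from the pre-replacement
    population (self-pairing allowed).
    """
    if not (0.0 <= r <= 1.0):
        raise ValueError("r must lie in [0, 1]")
    N = pop.N
    if r == 0.0:
        return pop
    k = N if r == 1.0 else min(int(rng.poisson(r * N)), N)
    if k == 0:
        return pop
    counts = pop.counts
    n_geno = counts.shape[0]
    removed = rng.multivariate_hypergeometric(counts, k)
    # parents from the pre-replacement population
    cum = np.cumsum(counts)
    pa = np.searchsorted(cum, rng.integers(0, N, size=k), side="right")
    pb = np.searchsorted(cum, rng.integers(0, N, size=k), side="right")
    masks = rng.integers(0, n_geno, size=k)
    full = n_geno - 1
    children = (pa & masks) | (pb & ~masks & full)
    new_counts = counts - removed + np.bincount(children, minlength=n_geno)
    return FinitePopulation(counts=new_counts.astype(np.int64), N=N, t=pop.t)


def step_finite(
    pop: FinitePopulation,
    land: FitnessLandscape,
    dp: DynamicsParams,
    rng: np.random.Generator,
) -> FinitePopulation:
    """One full generation: mutation, selection, sampling, recombination."""
    p = mutation_step(pop.frequencies(), dp.mu, land.L)
    p = selection_step(p, land)
    counts = sampling_step(p, pop.N, rng)
    out = recombination_step(
        FinitePopulation(counts=counts, N=pop.N, t=pop.t), dp.r, rng
    )
    return replace(out, t=pop.t + 1)


def run_finite(
    land: FitnessLandscape,
    dp: DynamicsParams,
    t_max: int,
    start: "int | None" = None,
    rng: "np.random.Generator | int | None" = None,
) -> "list[TrajectoryRecord]":
    """Simulate ``t_max`` generations from a monomorphic start.

    Returns ``t_max + 1`` records (the initial state is record ``t = 0``).
    ``start`` defaults to the landscape's reference sequence, the
    poorly-adapted corner of an RMF landscape.
    """
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    if isinstance(rng, np.random.Generator):
        pass
    else:
        rng = np.random.default_rng(rng if rng is not None else dp.seed)
    if start is None:
        start = land.params.sigma_star
    N = int(dp.N)
    pop = FinitePopulation.monomorphic(land.L, start, N)
    records = [
        make_record(0, pop.frequencies(), land, dp.theta_trap, presence=pop.counts > 0)
    ]
    for _ in range(t_max):
        pop = step_finite(pop, land, dp, rng)
        records.append(
            make_record(
                pop.t, pop.frequencies(), land, dp.theta_trap, presence=pop.counts > 0
            )
        )
    return records


def write_trajectory_tsv(
    records: "list[TrajectoryRecord]",
    path,
    L: int,
    config: "dict | None" = None,
) -> None:
    """Write one row per generation; config echoed as '#'-prefixed JSON."""
    with open(path, "w") as fh:
        if config is not None:
            for line in json.dumps(config, indent=1).splitlines():
                fh.write(f"# {line}\n")
        fh.write(
            "t\tmean_fitness\tmax_fitness\tentropy\tadditive_variance\t"
            "modal_genotype_bits\tmodal_frequency\ttrapped_flag\treset_flag\n"
        )
        for r in records:
            fh.write(
                f"{r.t}\t{r.mean_fitness:.17g}\t{r.max_fitness:.17g}\t"
                f"{r.entropy:.17g}\t{r.additive_variance:.17g}\t"
                f"{genotype_bits(r.modal_genotype, L)}\t{r.modal_frequency:.17g}\t"
                f"{int(r.trapped)}\t{int(r.reset_flag)}\n"
            )
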