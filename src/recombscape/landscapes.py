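"""Fitness landscapes on the binary hypercube.

A genotype with ``L`` biallelic loci is encoded as an integer in
``[0, 2**L)``; bit ``i`` is the allele at locus ``i`` (0 = wild type,
1 = mutant).  A landscape assigns a non-negative fitness to each of the
``2**L`` genotypes.  Supported models:

``additive``
    ``F(s) = c * d(s, s*)`` where ``d`` is the Hamming distance to a
    reference genotype ``s*`` and ``c`` is the slope in fitness units per
    mutational step.  Smooth, single-peaked.
``rmf``
    Rough Mount Fuji: the additive ridge plus an i.i.d. exponential random
    component with mean ``lam`` at every genotype.  ``lam / c`` tunes the
    ruggedness, interpolating between the additive model (``lam = 0``) and
    an uncorrelated random landscape (``c = 0``).
``hoc``
    House of Cards: i.i.d. exponential fitness values, the maximally
    rugged limit (``rmf`` with ``c = 0``).
``nk``
    Kauffman's NK model: each locus contributes a lognormal random value
    that depends on its own allele and the alleles of its ``K`` circularly
    adjacent neighbours; the genotype fitness is the sum of the ``L``
    contributions.

All random draws come from a seeded :class:`numpy.random.Generator`;
exponential variates are produced by inverse-CDF transform of uniforms so
that a landscape is reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

import dataclasses
import functools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LandscapeParams",
    "FitnessLandscape",
    "hamming_distance",
    "generate_landscape",
    "local_maxima",
    "density_of_maxima",
    "neighbor_table",
    "genotype_bits",
    "bits_to_genotype",
    "save_landscape",
    "load_landscape",
]

MODELS = ("rmf", "additive", "hoc", "nk")


def _as_rng(rng: "np.random.Generator | int | None", seed: "int | None" = None) -> np.random.Generator:
    """Coerce ``rng`` (Generator, int seed or None) into a Generator.

    ``None`` falls back to ``seed`` (which may itself be None, giving OS
    entropy)."""
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        rng = seed
    return np.random.default_rng(rng)


def hamming_distance(a: int, b: int, L: int) -> int:
    """Number of loci at which genotypes ``a`` and ``b`` differ."""
    if not (0 <= a < (1 << L)) or not (0 <= b < (1 << L)):
        raise ValueError(f"genotype out of range for L={L}: a={a}, b={b}")
    return int(a ^ b).bit_count()


def genotype_bits(g: int, L: int) -> str:
    """Bit-string representation, locus 0 leftmost (e.g. L=4, g=1 -> '1000')."""
    return "".join("1" if (g >> i) & 1 else "0" for i in range(L))


def bits_to_genotype(bits: str) -> int:
    """Inverse of :func:`genotype_bits`."""
    return sum(1 << i for i, b in enumerate(bits) if b == "1")


@functools.lru_cache(maxsize=32)
def neighbor_table(L: int) -> np.ndarray:
    """(2**L, L) array: entry [g, i] is genotype g with locus i flipped."""
    if L < 1:
        raise ValueError("L must be >= 1")
    g = np.arange(1 << L, dtype=np.int64)[:, None]
    flips = (np.int64(1) << np.arange(L, dtype=np.int64))[None, :]
    return g ^ flips


@dataclass(frozen=True)
class LandscapeParams:
    """Generating parameters of a fitness landscape.

    Parameters
    ----------
    L : number of loci (>= 1); the genotype space has 2**L states.
    model : one of 'rmf', 'additive', 'hoc', 'nk'.
    c : additive slope (fitness units per Hamming step, >= 0).
    lam : mean of the exponential random component (>= 0).
    sigma_star : reference genotype (integer encoding); fitness grows, on
        average, with Hamming distance from it.
    nk_K : number of interacting neighbours per locus (NK only), in [0, L-1].
    nk_mu, nk_sigma : location and scale of the lognormal contribution
        distribution (NK only).
    seed : RNG seed used when no explicit generator is supplied.
    """

    L: int
    model: str = "rmf"
    c: float = 1.0
    lam: float = 1.0
    sigma_star: int = 0
    nk_K: "int | None" = None
    nk_mu: float = 0.0
    nk_sigma: float = 1.0
    seed: "int | None" = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.c < 0 or self.lam < 0:
            raise ValueError("c and lam must be non-negative")
        if not (0 <= self.sigma_star < (1 << self.L)):
            raise ValueError("sigma_star out of genotype range")
        if self.model == "additive":
            if self.lam != 0 or self.c <= 0:
                raise ValueError("additive model requires lam == 0 and c > 0")
        if self.model == "hoc":
            if self.c != 0 or self.lam <= 0:
                raise ValueError("hoc model requires c == 0 and lam > 0")
        if self.model == "nk":
            if self.nk_K is None or not (0 <= self.nk_K <= self.L - 1):
                raise ValueError("nk model requires nk_K in [0, L-1]")

    @property
    def n_genotypes(self) -> int:
        return 1 << self.L

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeParams":
        return cls(**d)


@dataclass
class FitnessLandscape:
    """A complete genotype -> fitness mapping plus its generating state.

    ``F[g]`` is the fitness of genotype ``g``.  For the RMF family ``eta``
    stores the realized exponential components so that ``F - c*d(., s*)``
    recovers them exactly; for the NK model ``nk_tables`` stores the per-locus
    contribution tables (shape ``(L, 2**(K+1))``) so the landscape can be
    re-randomized in a seascape or serialized.
    """

    params: LandscapeParams
    F: np.ndarray
    eta: "np.ndarray | None" = None
    nk_tables: "np.ndarray | None" = None
    _is_max: "np.ndarray | None" = field(default=None, repr=False, compare=False)
    _dist: "np.ndarray | None" = field(default=None, repr=False, compare=False)

    @property
    def L(self) -> int:
        return self.params.L

    @property
    def n_genotypes(self) -> int:
        return self.params.n_genotypes

    def distances(self) -> np.ndarray:
        """Hamming distance of every genotype to the reference sequence."""
        if self._dist is None:
            g = np.arange(self.n_genotypes, dtype=np.int64)
            self._dist = np.bitwise_count(g ^ np.int64(self.params.sigma_star)).astype(np.int64)
        return self._dist

    def is_local_max(self) -> np.ndarray:
        """Boolean mask of genotypes strictly fitter than all L neighbours."""
        if self._is_max is None:
            nbrs = neighbor_table(self.L)
            nbr_F = self.F[nbrs]
            if np.any(self.F[:, None] == nbr_F):
                raise ValueError(
                    "landscape has fitness ties between neighbours; "
                    "local maxima are defined only for tie-free landscapes"
                )
            self._is_max = np.all(self.F[:, None] > nbr_F, axis=1)
        return self._is_max

    def global_maximum(self) -> int:
        return int(np.argmax(self.F))


def generate_landscape(
    params: LandscapeParams, rng: "np.random.Generator | int | None" = None
) -> FitnessLandscape:
    """Draw one landscape realization.

    Deterministic given a seed: ``rng`` may be a Generator, an integer seed,
    or None (then ``params.seed`` is used).
    """
    rng = _as_rng(rng, params.seed)
    n = params.n_genotypes
    if params.model == "nk":
        K = params.nk_K
        # contribution of locus i depends on the alleles at loci
        # {i, i+1, ..., i+K} (circular); one lognormal value per pattern
        tables = np.exp(
            params.nk_mu + params.nk_sigma * rng.standard_normal((params.L, 1 << (K + 1)))
        )
        F = _nk_fitness(params.L, K, tables)
        return FitnessLandscape(params=params, F=F, nk_tables=tables)

    g = np.arange(n, dtype=np.int64)
    d = np.bitwise_count(g ^ np.int64(params.sigma_star)).astype(np.float64)
    if params.lam > 0:
        # inverse-CDF exponential keeps landscapes reproducible across platforms
        eta = -params.lam * np.log1p(-rng.random(n))
    else:
        eta = np.zeros(n)
    F = params.c * d + eta
    # store the representable residual so F - c*d recovers eta bit-exactly
    eta = F - params.c * d
    return FitnessLandscape(params=params, F=F, eta=eta)


def _nk_fitness(L: int, K: int, tables: np.ndarray) -> np.ndarray:
    """Sum the L locus contributions for every genotype."""
    g = np.arange(1 << L, dtype=np.int64)
    F = np.zeros(1 << L)
    for i in range(L):
        # pattern: bit j of the index is the allele at locus (i+j) mod L
        idx = np.zeros(1 << L, dtype=np.int64)
        for j in range(K + 1):
            locus = (i + j) % L
            idx |= ((g >> locus) & 1) << j
        F += tables[i, idx]
    return F


def local_maxima(land: FitnessLandscape) -> "set[int]":
    """Genotypes strictly fitter than all of their single-mutant neighbours.

    Raises ``ValueError`` on landscapes with neighbour fitness ties (the
    notion of a strict peak is then ill-defined).
    """
    return set(np.flatnonzero(land.is_local_max()).tolist())


def density_of_maxima(
    params: LandscapeParams,
    n_real: int,
    rng: "np.random.Generator | int | None" = None,
) -> "tuple[np.ndarray, float]":
    """Mean density of local maxima, per Hamming shell around the reference.

    Returns ``(per_shell, overall)`` where ``per_shell[d]`` is the fraction
    of genotypes at distance ``d`` from ``sigma_star`` that are local maxima,
    averaged over ``n_real`` independent landscape realizations, and
    ``overall`` is the average fraction over the whole hypercube.
    """
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    rng = _as_rng(rng, params.seed)
    L = params.L
    shell_counts = np.array([math.comb(L, d) for d in range(L + 1)], dtype=float)
    per_shell = np.zeros(L + 1)
    overall = 0.0
    for _ in range(n_real):
        land = generate_landscape(params, rng)
        mask = land.is_local_max()
        d = land.distances()
        per_shell += np.bincount(d[mask], minlength=L + 1) / shell_counts
        overall += mask.mean()
    return per_shell / n_real, overall / n_real


# ---------------------------------------------------------------------------
# serialization: TSV table + JSON sidecar with the generating parameters
# ---------------------------------------------------------------------------

def save_landscape(land: FitnessLandscape, path: "str | Path") -> None:
    """Write genotype_bits / fitness / eta as TSV; params to ``<path>.json``.

    Values are printed with 17 significant digits, so a round-trip through
    :func:`load_landscape` is lossless for doubles.
    """
    path = Path(path)
    L = land.L
    with open(path, "w") as fh:
        fh.write("genotype_bits\tfitness\teta\n")
        for g in range(land.n_genotypes):
            eta = land.eta[g] if land.eta is not None else float("nan")
            fh.write(f"{genotype_bits(g, L)}\t{land.F[g]:.17g}\t{eta:.17g}\n")
    sidecar = {"params": land.params.to_dict()}
    if land.nk_tables is not None:
        sidecar["nk_tables"] = [[f"{v:.17g}" for v in row] for row in land.nk_tables]
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_landscape(path: "str | Path") -> FitnessLandscape:
    """Inverse of :func:`save_landscape`."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    params = LandscapeParams.from_dict(sidecar["params"])
    n = params.n_genotypes
    F = np.empty(n)
    eta = np.empty(n)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["genotype_bits", "fitness", "eta"]:
            raise ValueError(f"unexpected landscape table header: {header}")
        for line in fh:
            bits, fv, ev = line.rstrip("\n").split("\t")
            g = bits_to_genotype(bits)
            F[g] = float(fv)
            eta[g] = float(ev)
    nk_tables = None
    if "nk_tables" in sidecar:
        nk_tables = np.array([[float(v) for v in row] for row in sidecar["nk_tables"]])
        return FitnessLandscape(params=params, F=F, nk_tables=nk_tables)
    if np.all(np.isnan(eta)):
        eta = None
    return FitnessLandscape(params=params, F=F, eta=eta)
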