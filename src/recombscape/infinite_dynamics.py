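"""Deterministic genotype-frequency dynamics in the infinite-N limit.

Mutation, selection and recombination become operators on the frequency
simplex over the ``2**L`` genotypes:

* mutation — a column-stochastic matrix built from the hypercube adjacency
  matrix ``A``: the single-step operator ``M1 = (1-mu) I + (mu/L) A``, or the
  all-orders operator ``Minf = (1-mu) (I - (mu/L) A)^{-1}`` obtained by
  summing the geometric series of higher-order mutation events (it converges
  since ``mu < 1``); finite-order truncations of the series are
  column-renormalized;
* selection — ``p'_g = p_g F_g / Fbar``;
* recombination — the quadratic uniform-crossover map
  ``Q(p)_g = sum_{a,b} T(g|a,b) p_a p_b``; a fraction ``r`` of the
  population is replaced by its image, ``p -> (1-r) p + r Q(p)``.

Because every genotype acquires positive frequency after one mutation step
and the distribution decays exponentially with Hamming distance from the
founder, double precision can silently flush distant genotypes to zero; the
``precision`` argument switches the state and all operators to ``mpmath``
arbitrary-precision reals (default 35 significant digits) so that no
genotype is ever lost to rounding.

Implementation note: all three operators are cheap in the Walsh basis.  The
Walsh functions diagonalize ``A`` (eigenvalue ``L - 2 w`` on parity
character ``k`` with ``w = popcount(k)``), hence every mutation operator is
diagonal there, and uniform crossover becomes the submask convolution
``qhat_k = 2^{-|k|} sum_{s subset k} phat_s phat_{k xor s}``, computable in
``O(3^L)`` instead of the naive ``O(8^L)``.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import mpmath
import numpy as np

from .landscapes import FitnessLandscape
from .observables import TrajectoryRecord, make_record

__all__ = [
    "INFINITE",
    "MutationOperator",
    "InfiniteState",
    "adjacency_matrix",
    "mutation_operator",
    "recombination_map",
    "step_infinite",
    "run_infinite",
    "fwht",
]

INFINITE = math.inf

#: default cap on L in arbitrary-precision mode (cost grows as 3^L per step)
HIGH_PRECISION_L_CAP = 12


def adjacency_matrix(L: int) -> np.ndarray:
    """Hypercube adjacency: ``A[a, b] = 1`` iff ``a`` and ``b`` differ at one locus."""
    if L < 1:
        raise ValueError("L must be >= 1")
    n = 1 << L
    g = np.arange(n, dtype=np.int64)
    d = np.bitwise_count(g[:, None] ^ g[None, :])
    return (d == 1).astype(np.int64)


def fwht(x: np.ndarray) -> np.ndarray:
    """In-place-style fast Walsh-Hadamard transform (unnormalized).

    Works for float arrays and for object arrays of ``mpmath.mpf``; the
    transform is an involution up to the factor ``2**L``.
    """
    x = x.copy()
    n = x.shape[0]
    h = 1
    while h < n:
        for start in range(0, n, 2 * h):
            a = x[start : start + h].copy()
            b = x[start + h : start + 2 * h].copy()
            x[start : start + h] = a + b
            x[start + h : start + 2 * h] = a - b
        h *= 2
    return x


@functools.lru_cache(maxsize=32)
def _popcounts(L: int) -> np.ndarray:
    return np.bitwise_count(np.arange(1 << L, dtype=np.int64)).astype(np.int64)


@functools.lru_cache(maxsize=16)
def _submask_index(L: int) -> "tuple[np.ndarray, np.ndarray, np.ndarray]":
    """Flattened (k, s, k^s) triples over all submasks s of every k.

    3**L triples in total; used to vectorize the recombination submask
    convolution.
    """
    ks, ss, cs = [], [], []
    for k in range(1 << L):
        s = k
        while True:
            ks.append(k)
            ss.append(s)
            cs.append(k ^ s)
            if s == 0:
                break
            s = (s - 1) & k
    return (
        np.array(ks, dtype=np.int64),
        np.array(ss, dtype=np.int64),
        np.array(cs, dtype=np.int64),
    )


def _mutation_eigenvalues(L: int, mu, order, one):
    """Walsh-basis eigenvalues of the mutation operator.

    ``one`` is 1.0 or ``mpmath.mpf(1)`` and fixes the arithmetic type.  The
    eigenvalue on the parity character with popcount ``w`` (adjacency
    eigenvalue ``x = L - 2w``) is:

    order 1:        1 - 2 mu w / L
    order INFINITE: (1 - mu) / (1 - mu x / L)
    order k >= 2:   sum_{m<=k} (mu x / L)^m / sum_{m<=k} mu^m
                    (truncated geometric series, column-renormalized)
    """
    w = np.arange(L + 1)
    x = L - 2 * w
    mu = one * mu
    if order == 1:
        vals = [one - 2 * mu * wi / L for wi in w]
    elif order == INFINITE:
        vals = [(one - mu) / (one - mu * xi / L) for xi in x]
    else:
        order = int(order)
        if order < 1:
            raise ValueError("order must be a positive integer or INFINITE")
        norm = sum((mu ** m for m in range(order + 1)), one * 0)
        vals = [
            sum(((mu * xi / L) ** m for m in range(order + 1)), one * 0) / norm
            for xi in x
        ]
    return vals


@dataclass
class MutationOperator:
    """Column-stochastic mutation operator, applied via the Walsh transform."""

    L: int
    mu: float
    order: "int | float"
    eigenvalues_by_popcount: list
    high_precision: bool = False

    def apply(self, p: np.ndarray) -> np.ndarray:
        w = _popcounts(self.L)
        eig = np.array(self.eigenvalues_by_popcount, dtype=object if self.high_precision else float)
        phat = fwht(p)
        phat = phat * eig[w]
        out = fwht(phat)
        if self.high_precision:
            scale = mpmath.mpf(1 << self.L)
            return np.array([v / scale for v in out], dtype=object)
        return out / (1 << self.L)

    @property
    def matrix(self) -> np.ndarray:
        """Materialized 2**L x 2**L matrix (float; intended for small L)."""
        n = 1 << self.L
        cols = []
        eye = np.eye(n)
        for j in range(n):
            col = self.apply(
                np.array([mpmath.mpf(v) for v in eye[:, j]], dtype=object)
                if self.high_precision
                else eye[:, j]
            )
            cols.append([float(v) for v in col])
        return np.array(cols).T


def mutation_operator(
    L: int, mu: float, order: "int | float" = INFINITE, precision: "int | None" = None
) -> MutationOperator:
    """Build the mutation operator of the given order.

    ``order=1`` is the single-step matrix ``(1-mu) I + (mu/L) A``;
    ``order=INFINITE`` the summed geometric series
    ``(1-mu)(I - (mu/L) A)^{-1}``; an integer ``k >= 2`` truncates the series
    at ``k`` terms and renormalizes the columns.  ``precision`` switches to
    ``mpmath`` arithmetic with that many significant digits.
    """
    if not (0.0 <= mu < 1.0):
        raise ValueError("mu must lie in [0, 1); the geometric series needs mu < 1")
    hp = precision is not None
    if hp:
        with mpmath.workdps(precision):
            one = mpmath.mpf(1)
            eig = _mutation_eigenvalues(L, mu, order, one)
    else:
        eig = _mutation_eigenvalues(L, mu, order, 1.0)
    return MutationOperator(
        L=L, mu=mu, order=order, eigenvalues_by_popcount=eig, high_precision=hp
    )


def recombination_map(p: np.ndarray, L: int) -> np.ndarray:
    """Uniform-crossover offspring distribution of random mating.

    ``Q(p)_g = sum_{a,b} p_a p_b prod_i [a_i = b_i ? 1{g_i = a_i} : 1/2]``.
    Computed as a submask convolution in the Walsh basis (see module notes).
    Fixes every point mass and every linkage-equilibrium product
    distribution, and preserves all single-locus marginals exactly.
    """
    hp = p.dtype == object
    ks, ss, cs = _submask_index(L)
    w = _popcounts(L)
    phat = fwht(p)
    if hp:
        half = mpmath.mpf(1) / 2
        qhat = np.array([mpmath.mpf(0)] * (1 << L), dtype=object)
        for k, s, c in zip(ks, ss, cs):
            qhat[k] += phat[s] * phat[c]
        qhat = np.array(
            [qhat[k] * half ** int(w[k]) for k in range(1 << L)], dtype=object
        )
        out = fwht(qhat)
        scale = mpmath.mpf(1 << L)
        return np.array([v / scale for v in out], dtype=object)
    qhat = np.zeros(1 << L)
    np.add.at(qhat, ks, phat[ss] * phat[cs])
    qhat *= 0.5 ** w
    return fwht(qhat) / (1 << L)


@dataclass
class InfiniteState:
    """Frequency vector (float64 or mpmath) plus a generation counter."""

    p: np.ndarray
    t: int = 0

    def as_float(self) -> np.ndarray:
        if self.p.dtype == object:
            return np.array([float(v) for v in self.p])
        return np.asarray(self.p, dtype=float)


def _select(p: np.ndarray, F) -> np.ndarray:
    w = p * F
    s = w.sum()
    if s <= 0:
        raise ValueError("mean fitness is zero; selection undefined")
    return w / s


def step_infinite(
    state: InfiniteState,
    land: FitnessLandscape,
    mu: float,
    r: float,
    mut_op: "MutationOperator | None" = None,
) -> InfiniteState:
    """One deterministic generation: mutation, selection, recombination."""
    hp = state.p.dtype == object
    if mut_op is None:
        mut_op = mutation_operator(land.L, mu, INFINITE, precision=mpmath.mp.dps if hp else None)
    F = land.F
    if hp:
        F = np.array([mpmath.mpf(v) for v in land.F], dtype=object)
    p = mut_op.apply(state.p)
    p = _select(p, F)
    if r > 0:
        q = recombination_map(p, land.L)
        p = (1 - r) * p + r * q
    p = p / p.sum()  # renormalize away accumulated round-off
    return InfiniteState(p=p, t=state.t + 1)


def run_infinite(
    land: FitnessLandscape,
    mu: float,
    r: float,
    t_max: int,
    start: "int | None" = None,
    precision: "int | None" = None,
    order: "int | float" = INFINITE,
    theta_trap: float = 0.95,
    L_cap: int = HIGH_PRECISION_L_CAP,
) -> "list[TrajectoryRecord]":
    """Deterministic trajectory from a monomorphic start.

    ``precision`` (significant digits, e.g. 35) enables arbitrary-precision
    arithmetic; it is required honest bookkeeping for long runs because the
    frequency of genotypes far from the founder decays below double
    precision.  High-precision runs are capped at ``L_cap`` loci.
    """
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    if precision is not None and land.L > L_cap:
        raise ValueError(
            f"L={land.L} exceeds the high-precision cap {L_cap}; "
            "raise L_cap explicitly if you mean it"
        )
    if start is None:
        start = land.params.sigma_star
    n = land.n_genotypes
    hp = precision is not None
    ctx = mpmath.workdps(precision) if hp else None
    if ctx is not None:
        ctx.__enter__()
    try:
        if hp:
            p = np.array([mpmath.mpf(0)] * n, dtype=object)
            p[start] = mpmath.mpf(1)
        else:
            p = np.zeros(n)
            p[start] = 1.0
        mut_op = mutation_operator(land.L, mu, order, precision=precision)
        state = InfiniteState(p=p, t=0)
        records = [make_record(0, state.as_float(), land, theta_trap)]
        for _ in range(t_max):
            state = step_infinite(state, land, mu, r, mut_op)
            records.append(make_record(state.t, state.as_float(), land, theta_trap))
        return records
    finally:
        if ctx is not None:
            ctx.__exit__(None, None, None)
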