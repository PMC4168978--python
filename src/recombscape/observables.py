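"""Summary statistics and event detectors for evolutionary trajectories.

The central objects are per-generation :class:`TrajectoryRecord` rows and the
paired-ensemble difference series: for a recombining (fraction ``r``) and a
non-recombining population evolving on the *same* landscape realization,

* ``delta_F(t)``  — ensemble mean of ``Fbar_r(t) - Fbar_nr(t)``,
* ``delta_S(t)``  — the analogous Shannon-entropy difference,
* ``delta_Fmax(t)`` — difference of the fittest-present-genotype fitness,
* ``P_plus(t)``   — fraction of pairs in which the recombining population has
  the strictly higher mean fitness (exact ties count 1/2).

Trapping bookkeeping follows the near-fixation picture: a population counts
as trapped when its modal genotype is a local fitness maximum carrying at
least a fraction ``theta_trap`` of the individuals, and it has escaped once
that genotype's share first falls below ``theta_escape`` (or the genotype
loses modality, which at the default ``theta_escape = 0.5`` is the same
loss-of-majority event).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscapes import FitnessLandscape, hamming_distance

__all__ = [
    "TrajectoryRecord",
    "TrapEvent",
    "AdvantageSummary",
    "entropy",
    "additive_variance",
    "distance_variance",
    "velocity",
    "detect_trap_escape",
    "escape_fraction",
    "first_trap_distance",
    "delta_series",
    "advantage_summary",
    "offpeak_cv",
    "make_record",
    "records_to_frame",
]

#: frequencies below this are treated as absent when locating the fittest
#: genotype present in a deterministic (infinite-population) state
PRESENCE_TOL = 1e-12


@dataclass(frozen=True, slots=True)
class TrajectoryRecord:
    """One generation of summary statistics."""

    t: int
    mean_fitness: float
    max_fitness: float
    entropy: float
    additive_variance: float
    modal_genotype: int
    modal_frequency: float
    trapped: bool
    reset_flag: bool = False


@dataclass(frozen=True)
class TrapEvent:
    """A trapping (and possibly escape) episode at a local fitness maximum."""

    genotype: int
    t_start: int
    t_end: "int | None"
    distance_from_start: int


@dataclass(frozen=True)
class AdvantageSummary:
    """Location and size of the maximal recombination advantage."""

    t_max: int
    delta_max: float
    t_zero: "int | None"


def entropy(p: np.ndarray) -> float:
    """Shannon entropy ``-sum p ln p`` (nats) of a genotype distribution.

    ``0 * ln 0`` is taken as 0; lies in ``[0, L ln 2]`` for ``2**L`` states.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("frequency vector has negative entries")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def distance_variance(p: np.ndarray, land: FitnessLandscape) -> float:
    """Population variance of the Hamming distance to the reference sequence."""
    if land.params.model == "nk":
        raise ValueError("additive variance needs a reference sequence (RMF family)")
    d = land.distances().astype(float)
    p = np.asarray(p, dtype=float)
    m = float(p @ d)
    return float(p @ (d - m) ** 2)


def additive_variance(p: np.ndarray, land: FitnessLandscape) -> float:
    """Additive genetic variance ``c**2 * Var_p[d(., s*)]`` in fitness^2 units.

    ``c * d`` is the heritable part of the RMF fitness, so the variance of the
    distance to the reference, scaled by ``c**2``, is the variance of the
    inherited fitness component.  Zero for House-of-Cards (``c = 0``).
    """
    return land.params.c ** 2 * distance_variance(p, land)


def velocity(mean_fitness: "np.ndarray | list[float]", window: int = 1) -> np.ndarray:
    """Per-generation fitness velocity ``v(t) = Fbar(t) - Fbar(t-1)``.

    ``window > 1`` applies a centered moving average of that width to the raw
    first differences.  Output length is ``len(input) - 1``.
    """
    f = np.asarray(mean_fitness, dtype=float)
    if f.size < 2:
        raise ValueError("need at least two generations to compute a velocity")
    if window < 1:
        raise ValueError("window must be >= 1")
    v = np.diff(f)
    if window > 1:
        kernel = np.ones(window) / window
        v = np.convolve(v, kernel, mode="same")
    return v


def make_record(
    t: int,
    p: np.ndarray,
    land: FitnessLandscape,
    theta_trap: float = 0.95,
    reset_flag: bool = False,
    presence: "np.ndarray | None" = None,
) -> TrajectoryRecord:
    """Build a TrajectoryRecord from a frequency vector.

    ``presence`` optionally marks which genotypes exist in the population
    (integer counts > 0 for the finite engine); by default any frequency
    above :data:`PRESENCE_TOL` counts as present.
    """
    p = np.asarray(p, dtype=float)
    if presence is None:
        presence = p > PRESENCE_TOL
    mean_fit = float(p @ land.F)
    present_F = land.F[presence]
    max_fit = float(present_F.max()) if present_F.size else float("nan")
    modal = int(np.argmax(p))
    modal_freq = float(p[modal])
    if land.params.model == "nk":
        va = float("nan")
    else:
        va = additive_variance(p, land)
    trapped = bool(land.is_local_max()[modal] and modal_freq >= theta_trap)
    return TrajectoryRecord(
        t=t,
        mean_fitness=mean_fit,
        max_fitness=max_fit,
        entropy=entropy(p),
        additive_variance=va,
        modal_genotype=modal,
        modal_frequency=modal_freq,
        trapped=trapped,
        reset_flag=reset_flag,
    )


def records_to_frame(records: "list[TrajectoryRecord]") -> pd.DataFrame:
    import dataclasses

    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def detect_trap_escape(
    traj: "list[TrajectoryRecord]",
    land: FitnessLandscape,
    theta_trap: float = 0.95,
    theta_escape: float = 0.5,
    start: "int | None" = None,
) -> "list[TrapEvent]":
    """Extract trapping/escape episodes from a trajectory.

    An event opens at the first generation where the modal genotype is a
    local maximum with frequency >= ``theta_trap``; it closes at the first
    later generation where that genotype's share drops below
    ``theta_escape`` — observed on the records as either the modal frequency
    falling below the threshold or the genotype losing modality.  Events are
    disjoint and chronological; an unresolved event has ``t_end = None``.
    """
    if not (0 < theta_escape < theta_trap < 1):
        raise ValueError("need 0 < theta_escape < theta_trap < 1")
    is_max = land.is_local_max()
    if start is None:
        start = land.params.sigma_star
    events: "list[TrapEvent]" = []
    current: "TrapEvent | None" = None
    for rec in traj:
        if current is None:
            if is_max[rec.modal_genotype] and rec.modal_frequency >= theta_trap:
                current = TrapEvent(
                    genotype=rec.modal_genotype,
                    t_start=rec.t,
                    t_end=None,
                    distance_from_start=hamming_distance(
                        rec.modal_genotype, start, land.L
                    ),
                )
        else:
            escaped = rec.modal_genotype != current.genotype or (
                rec.modal_frequency < theta_escape
            )
            if escaped:
                events.append(
                    TrapEvent(
                        genotype=current.genotype,
                        t_start=current.t_start,
                        t_end=rec.t,
                        distance_from_start=current.distance_from_start,
                    )
                )
                current = None
    if current is not None:
        events.append(current)
    return events


def escape_fraction(
    events: "list[TrapEvent]",
    horizon: "int | None" = None,
    baseline: "float | None" = None,
) -> float:
    """Fraction of trapping events that ended in an escape by ``horizon``.

    ``n_e / n_t`` with ``n_t`` counting events opened by the horizon and
    ``n_e`` those also closed by it.  ``baseline`` (e.g. the matched value of
    a non-recombining ensemble) divides the result when given.  Raises on an
    empty trapping count, where the ratio is undefined.
    """
    if horizon is None:
        horizon = max((e.t_start for e in events), default=-1)
    opened = [e for e in events if e.t_start <= horizon]
    if not opened:
        raise ValueError("no trapping events by the horizon; escape fraction undefined")
    closed = sum(1 for e in opened if e.t_end is not None and e.t_end <= horizon)
    frac = closed / len(opened)
    if baseline is not None:
        frac /= baseline
    return frac


def first_trap_distance(events: "list[TrapEvent]", start: int, L: int) -> "int | None":
    """Hamming distance from the starting genotype to the first trap."""
    if not events:
        return None
    first = min(events, key=lambda e: e.t_start)
    return hamming_distance(first.genotype, start, L)


def delta_series(
    pairs: "list[tuple[list[TrajectoryRecord], list[TrajectoryRecord]]]",
) -> pd.DataFrame:
    """Paired-ensemble difference series.

    ``pairs`` holds ``(recombining, non-recombining)`` trajectories of equal
    length, each pair from one shared landscape realization.  Returns a frame
    with columns ``t, delta_F, delta_S, delta_Fmax, P_plus, n_pairs``.
    """
    if not pairs:
        raise ValueError("need at least one trajectory pair")
    n_t = len(pairs[0][0])
    for tr, tn in pairs:
        if len(tr) != n_t or len(tn) != n_t:
            raise ValueError("paired trajectories must all have equal length")
    n_pairs = len(pairs)
    dF = np.zeros(n_t)
    dS = np.zeros(n_t)
    dFm = np.zeros(n_t)
    Pp = np.zeros(n_t)
    for tr, tn in pairs:
        fr = np.array([r.mean_fitness for r in tr])
        fn = np.array([r.mean_fitness for r in tn])
        dF += fr - fn
        dS += np.array([r.entropy for r in tr]) - np.array([r.entropy for r in tn])
        dFm += np.array([r.max_fitness for r in tr]) - np.array(
            [r.max_fitness for r in tn]
        )
        Pp += np.where(fr > fn, 1.0, 0.0) + np.where(fr == fn, 0.5, 0.0)
    return pd.DataFrame(
        {
            "t": np.arange(n_t),
            "delta_F": dF / n_pairs,
            "delta_S": dS / n_pairs,
            "delta_Fmax": dFm / n_pairs,
            "P_plus": Pp / n_pairs,
            "n_pairs": n_pairs,
        }
    )


def advantage_summary(
    delta: "np.ndarray | list[float]", horizon: "int | None" = None
) -> AdvantageSummary:
    """Maximal advantage and the first sign change after it.

    ``delta[t]`` is the advantage at generation ``t``.  ``t_max`` is the
    earliest argmax up to ``horizon`` (inclusive; default: whole series),
    ``t_zero`` the first later generation with ``delta <= 0`` (None if the
    advantage never vanishes).
    """
    delta = np.asarray(delta, dtype=float)
    if delta.size == 0:
        raise ValueError("empty series")
    if horizon is not None:
        delta = delta[: horizon + 1]
    t_max = int(np.argmax(delta))
    after = np.flatnonzero(delta[t_max + 1 :] <= 0)
    t_zero = int(t_max + 1 + after[0]) if after.size else None
    return AdvantageSummary(t_max=t_max, delta_max=float(delta[t_max]), t_zero=t_zero)


def offpeak_cv(
    trajectories: "list[list[TrajectoryRecord]]",
    land: FitnessLandscape,
    N: int,
) -> float:
    """Coefficient of variation of the off-peak population size.

    Over all (run, generation) pairs where the modal genotype is a local
    maximum, collect the number of individuals *not* on that genotype,
    ``N * (1 - modal_frequency)``, and return sample-sd / mean.  The
    off-peak cloud is the raw material for escapes, so its fluctuations
    indicate how bursty escape attempts are.
    """
    is_max = land.is_local_max()
    values = [
        N * (1.0 - rec.modal_frequency)
        for traj in trajectories
        for rec in traj
        if is_max[rec.modal_genotype]
    ]
    if not values:
        raise ValueError("no generations with the modal genotype on a local maximum")
    arr = np.asarray(values)
    mean = arr.mean()
    if mean == 0:
        return 0.0
    sd = arr.std(ddof=1) if arr.size > 1 else 0.0
    return float(sd / mean)
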