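"""Multi-type Moran model of the stem-cell compartment under strict homeostasis.

The stem pool holds exactly ``N`` cells in mutation classes 0, 1, 2.  Every
``tau/N`` weeks one replacement event occurs: a uniformly chosen resident
dies and one cell is born.  The born cell is either a (fitness-weighted)
copy of a resident, mutated along the forward cascade 0 -> 1 -> 2, or - with
probability ``d * chi`` - a dedifferentiated two-mutation progenitor filling
the niche opening, where ``chi`` is the two-mutation fraction of the
progenitor population.  Strict homeostasis means dedifferentiation competes
only for niche openings, which is why it acts like a selective advantage
rather than an absolute influx.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._rng import UniformStream, replicate_seed

__all__ = [
    "MoranParams",
    "MoranState",
    "FixationRecord",
    "mutation_matrix",
    "replacement_probabilities",
    "moran_event",
    "simulate_fixation",
    "simulate_two_type_absorption",
    "quasi_steady_chi",
]

_SCOPES = ("two_mutation_only", "all_mutants", "all_mutants_birth_weighted")


@dataclass(frozen=True)
class MoranParams:
    """Replacement-process parameters (hematopoietic defaults)."""

    N: int = 100
    stem_mutation_rate: float = 1e-5   # per replication
    dediff_weight: float = 0.0         # d in [0, 1]
    dediff_scope: str = "two_mutation_only"
    selection: float = 0.0             # advantage of two-mutation stem cells
    stem_cycle: float = 20.0           # tau, weeks per cell division
    exponential_intervals: bool = False

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be positive")
        if not 0.0 <= self.stem_mutation_rate <= 1.0:
            raise ValueError("stem_mutation_rate must lie in [0, 1]")
        if not 0.0 <= self.dediff_weight <= 1.0:
            raise ValueError("dediff_weight must lie in [0, 1]")
        if self.dediff_scope not in _SCOPES:
            raise ValueError(f"dediff_scope must be one of {_SCOPES}")
        if self.selection <= -1.0:
            raise ValueError("selection must exceed -1")
        if self.stem_cycle <= 0:
            raise ValueError("stem_cycle must be positive")

    @property
    def event_interval(self) -> float:
        return self.stem_cycle / self.N


@dataclass
class MoranState:
    """Counts per mutation class with fixed total N."""

    counts: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3,):
            raise ValueError("counts must have 3 mutation classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def N(self) -> int:
        return int(self.counts.sum())


@dataclass
class FixationRecord:
    """Outcome of one fixation replicate."""

    t_fix: float                 # weeks; nan if truncated
    t_emergence: float           # birth time of the surviving two-mutation
    #                            # lineage present at fixation (weeks)
    fixed_class: int
    truncated: bool
    n_events: int
    first_class2_origin: str | None = None   # "stem_mutation" | "dedifferentiation"
    seed: int | None = None


def mutation_matrix(u: float) -> np.ndarray:
    """Forward-cascade per-replication type-change probabilities (3x3)."""
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    return np.array(
        [
            [1.0 - u, u, 0.0],
            [0.0, 1.0 - u, u],
            [0.0, 0.0, 1.0],
        ]
    )


def _birth_distribution(
    counts: np.ndarray, chi, params: MoranParams
) -> np.ndarray:
    """Probability that the born cell has class j, given the state and chi.

    For scope ``two_mutation_only`` ``chi`` is the scalar two-mutation
    progenitor fraction; for the all-progenitor scopes ``chi`` is the
    length-3 progenitor class composition (birth-rate weighted for the
    weighted scope), and the total dedifferentiation weight is ``d``.
    """
    N = counts.sum()
    fitness = np.array([1.0, 1.0, 1.0 + params.selection])
    w = counts * fitness
    base = w @ mutation_matrix(params.stem_mutation_rate) / w.sum()
    d = params.dediff_weight
    if d == 0:
        return base
    if params.dediff_scope == "two_mutation_only":
        chi = float(chi)
        if not 0.0 <= chi <= 1.0:
            raise ValueError("chi must lie in [0, 1]")
        out = (1.0 - d * chi) * base
        out[2] += d * chi
    else:
        comp = np.asarray(chi, dtype=float)
        if comp.shape != (3,) or np.any(comp < 0):
            raise ValueError("progenitor composition must be 3 non-negative fractions")
        total = comp.sum()
        if total <= 0:
            return base
        out = (1.0 - d) * base + d * comp / total
    return out


def replacement_probabilities(
    state: MoranState, chi, params: MoranParams
) -> np.ndarray:
    """Joint probability P[i, j] of (death class i, birth class j).

    Death draw is uniform over residents; the birth draw is independent of
    it (the parent may be the dying cell), so the joint kernel is the outer
    product of the two marginals.
    """
    counts = state.counts
    N = counts.sum()
    if N != params.N:
        raise ValueError("state total does not match params.N")
    death = counts / N
    birth = _birth_distribution(counts, chi, params)
    P = np.outer(death, birth)
    if abs(P.sum() - 1.0) > 1e-12:
        raise RuntimeError("replacement kernel failed to normalize")
    return P


def moran_event(
    state: MoranState, chi, params: MoranParams, rng: np.random.Generator
) -> MoranState:
    """Sample one replacement event; total N is conserved, t advances."""
    P = replacement_probabilities(state, chi, params)
    flat = P.ravel()
    idx = rng.choice(9, p=flat)
    i, j = divmod(idx, 3)
    counts = state.counts.copy()
    counts[i] -= 1
    counts[j] += 1
    dt = params.event_interval
    if params.exponential_intervals:
        dt = rng.exponential(dt)
    return MoranState(counts=counts, t=state.t + dt)


def quasi_steady_chi(
    amplifications: Sequence[float] = (1.0, 1.0, 1.0),
) -> Callable[[float, int, int, int], float]:
    """chi-provider assuming the progenitor pool instantly mirrors the stems.

    With per-class amplification integrals ``I_k`` (progenitor progeny per
    unit stem influx), the adiabatic two-mutation fraction is
    ``chi = x2 I2 / sum_k x_k I_k``.  Equal amplifications give
    ``chi = x2 / N``, under which a dedifferentiation weight ``d`` is
    equivalent to a selection coefficient ``s = d`` for the two-mutation
    class.
    """
    I0, I1, I2 = (float(a) for a in amplifications)

    def chi(t: float, x0: int, x1: int, x2: int) -> float:
        denom = x0 * I0 + x1 * I1 + x2 * I2
        return (x2 * I2 / denom) if denom > 0 else 0.0

    return chi


def _resolve_chi(chi_provider):
    """Normalize a chi specification to (constant, callable) form."""
    if chi_provider is None:
        return 0.0, None
    if callable(chi_provider):
        return None, chi_provider
    return float(chi_provider), None


def simulate_fixation(
    params: MoranParams,
    chi_provider=None,
    seed: int | np.random.SeedSequence = 0,
    t_max: float = 2e6,
    initial: Sequence[int] | None = None,
    track_emergence: bool = True,
) -> FixationRecord:
    """Run replacement events until the two-mutation class fixes.

    ``chi_provider`` supplies the two-mutation progenitor fraction: ``None``
    (stem-only model, chi = 0), a constant, or a callable
    ``chi(t, x0, x1, x2)``.  Exceeding ``t_max`` sets the truncation flag
    rather than raising.  Fully reproducible for a given seed.

    Emergence bookkeeping carries one founding-time tag per living
    two-mutation cell (copies inherit the tag, new mutants and
    dedifferentiated entrants found new tags); at fixation ``t_emergence``
    is the earliest surviving founding time.
    """
    stream = UniformStream(seed)
    nxt = stream.next
    N = params.N
    u = params.stem_mutation_rate
    d = params.dediff_weight
    s = params.selection
    if params.dediff_scope != "two_mutation_only" and d > 0:
        raise NotImplementedError(
            "fast fixation runner supports scope 'two_mutation_only'; "
            "use the hybrid simulator for the all-progenitor variants"
        )
    dt = params.event_interval
    exp_dt = params.exponential_intervals
    chi_const, chi_fn = _resolve_chi(chi_provider)

    if initial is None:
        x0, x1, x2 = N, 0, 0
    else:
        x0, x1, x2 = (int(v) for v in initial)
        if x0 + x1 + x2 != N:
            raise ValueError("initial counts must sum to N")
    t = 0.0
    n_events = 0
    tags: list[float] = [0.0] * x2 if track_emergence else []
    first_origin = "initial" if x2 > 0 else None

    while x2 < N:
        if t >= t_max:
            return FixationRecord(
                t_fix=float("nan"),
                t_emergence=float("nan"),
                fixed_class=2 if x2 == N else (1 if x1 == N else 0),
                truncated=True,
                n_events=n_events,
                first_class2_origin=first_origin,
            )
        # death draw (uniform resident)
        r = nxt() * N
        if r < x0:
            die = 0
        elif r < x0 + x1:
            die = 1
        else:
            die = 2
        # birth draw
        born = -1
        parent = -1
        via_dediff = False
        if d > 0.0:
            chi = chi_fn(t, x0, x1, x2) if chi_fn is not None else chi_const
            if chi > 0.0 and nxt() < d * chi:
                born = 2
                via_dediff = True
        if born < 0:
            if s != 0.0:
                w2 = x2 * (1.0 + s)
                r2 = nxt() * (x0 + x1 + w2)
            else:
                r2 = nxt() * N
            if r2 < x0:
                parent = 0
            elif r2 < x0 + x1:
                parent = 1
            else:
                parent = 2
            born = parent
            if born < 2 and u > 0.0 and nxt() < u:
                born += 1
        # lineage tags (founding times of living class-2 cells); the parent
        # is drawn from the pre-event population, so inherit before removal
        if track_emergence:
            new_tag = None
            if born == 2:
                if parent == 2:
                    new_tag = tags[int(nxt() * x2)]
                else:
                    new_tag = t  # fresh mutation or dedifferentiated entrant
            if die == 2:
                k = int(nxt() * x2)
                tags[k] = tags[-1]
                tags.pop()
            if new_tag is not None:
                tags.append(new_tag)
        if die == 0:
            x0 -= 1
        elif die == 1:
            x1 -= 1
        else:
            x2 -= 1
        if born == 0:
            x0 += 1
        elif born == 1:
            x1 += 1
        else:
            x2 += 1
            if first_origin is None:
                first_origin = (
                    "dedifferentiation" if via_dediff else "stem_mutation"
                )
        t += (-np.log(nxt()) * dt) if exp_dt else dt
        n_events += 1

    t_emergence = min(tags) if (track_emergence and tags) else float("nan")
    return FixationRecord(
        t_fix=t,
        t_emergence=t_emergence,
        fixed_class=2,
        truncated=False,
        n_events=n_events,
        first_class2_origin=first_origin,
    )


def simulate_two_type_absorption(
    N: int,
    s: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    mutants: int = 1,
    tau: float = 20.0,
) -> tuple[bool, float]:
    """Run a mutation-free two-type Moran chain to absorption.

    Starts with ``mutants`` selection-``s`` mutants; returns (fixed, time in
    generations).  This is the direct Monte-Carlo counterpart of the exact
    tridiagonal-chain oracle.
    """
    if not 0 < mutants < N:
        raise ValueError("mutants must lie strictly between 0 and N")
    stream = UniformStream(seed)
    nxt = stream.next
    i = mutants
    events = 0
    if s == 0.0:
        while 0 < i < N:
            r = nxt() * N
            die_mut = r < i
            r2 = nxt() * N
            born_mut = r2 < i
            i += born_mut - die_mut
            events += 1
    else:
        while 0 < i < N:
            r = nxt() * N
            die_mut = r < i
            w = i * (1.0 + s)
            born_mut = nxt() * (N - i + w) < w
            i += born_mut - die_mut
            events += 1
    return i == N, events / N
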