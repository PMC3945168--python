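"""Density-dependent branching model of the stem compartment.

Homeostasis is maintained by cell-fate control rather than by coupling
births to deaths: every ``tau/S`` weeks a uniformly chosen stem cell
divides, producing 0, 1, or 2 stem offspring (the remainder differentiate
into progenitors).  The offspring-number probabilities depend on the total
population through a carrying capacity ``K``:

    p1 = q1,
    p2 = (1 - q1) / (1 + (S/K)^z),
    p0 = (1 - q1) - p2,

so the mean stem offspring per division ``m(S) = p1 + 2 p2`` equals one
exactly at ``S = K``, exceeds one below it and falls short above it.  The
asymmetric-division probability ``q1 -> 1`` recovers the Moran process for
every carrying capacity; the reversion strength ``z`` sets how hard the
population is pulled back to ``K`` and hence how large the quasi-stationary
fluctuations are.

Two-mutation progenitors dedifferentiate at rate ``eta`` per cell per week;
the mean number arriving between divisions is added to the two-mutation stem
count through a fractional accumulator before each division is carried out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import UniformStream

__all__ = [
    "HomeostasisParams",
    "BranchingState",
    "division_probabilities",
    "offspring_update",
    "dediff_influx",
    "branching_event",
    "simulate_branching_fixation",
]


@dataclass(frozen=True)
class HomeostasisParams:
    """Carrying-capacity stem-pool parameters (hematopoietic defaults)."""

    carrying_capacity: float = 100.0     # K, cells
    asym_prob: float = 0.5               # q1
    reversion_strength: float = 3.0      # z; larger = smaller fluctuations
    stem_cycle: float = 20.0             # tau, weeks per cell division
    stem_mutation_rate: float = 1e-5     # u, per stem offspring
    dediff_rate: float = 0.0             # eta, per 2-mutation progenitor/week
    per_class_capacity: bool = False     # use S_k/K_k instead of total S/K
    class_capacities: tuple[float, float, float] | None = None
    poisson_dediff: bool = False         # stochastic arrivals instead of mean
    #: differentiated offspring also mutate with probability u at the
    #: stem -> progenitor division
    mutate_differentiated: bool = True

    def __post_init__(self) -> None:
        if self.carrying_capacity < 1:
            raise ValueError("carrying_capacity must be at least 1")
        if not 0.0 <= self.asym_prob <= 1.0:
            raise ValueError("asym_prob must lie in [0, 1]")
        if self.reversion_strength < 0:
            raise ValueError("reversion_strength must be non-negative")
        if self.stem_cycle <= 0:
            raise ValueError("stem_cycle must be positive")
        if not 0.0 <= self.stem_mutation_rate <= 1.0:
            raise ValueError("stem_mutation_rate must lie in [0, 1]")
        if self.dediff_rate < 0:
            raise ValueError("dediff_rate must be non-negative")
        if self.class_capacities is not None and min(self.class_capacities) < 1:
            raise ValueError("class capacities must be at least 1")

    def capacity(self, k: int) -> float:
        if self.class_capacities is not None:
            return self.class_capacities[k]
        return self.carrying_capacity


@dataclass
class BranchingState:
    """Stem counts per class with a fractional dedifferentiation accumulator."""

    counts: np.ndarray
    t: float = 0.0
    dediff_accumulator: float = 0.0
    dediff_cumulative: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3,):
            raise ValueError("counts must have 3 mutation classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.dediff_accumulator < 1.0:
            raise ValueError("accumulator must lie in [0, 1)")

    @classmethod
    def at_capacity(cls, params: HomeostasisParams) -> "BranchingState":
        return cls(counts=np.array([int(round(params.capacity(0))), 0, 0]))

    @property
    def S(self) -> int:
        return int(self.counts.sum())


def division_probabilities(
    S: float, params: HomeostasisParams, k: int = 0, S_k: float | None = None
) -> tuple[float, float, float]:
    """(p0, p1, p2): probabilities of 0/1/2 stem offspring per division.

    Density dependence uses the total population ``S`` against the dividing
    class's carrying capacity by default; with ``per_class_capacity`` the
    class's own count ``S_k`` is used instead.
    """
    if S < 0:
        raise ValueError("S must be non-negative")
    q1 = params.asym_prob
    z = params.reversion_strength
    K = params.capacity(k)
    x = (S_k if params.per_class_capacity else S) / K
    if z == 0:
        frac = 0.5
    elif x == 0:
        frac = 1.0
    else:
        frac = 1.0 / (1.0 + x**z)
    p2 = (1.0 - q1) * frac
    p0 = (1.0 - q1) - p2
    p1 = q1
    if not (0 <= p0 <= 1 and 0 <= p2 <= 1):
        raise ValueError("division probabilities outside [0, 1]")
    return p0, p1, p2


def dediff_influx(eta: float, n2_prog: float, interval: float) -> float:
    """Mean number of cells dedifferentiating during ``interval`` weeks."""
    if eta < 0 or n2_prog < 0 or interval < 0:
        raise ValueError("arguments must be non-negative")
    return eta * n2_prog * interval


def offspring_update(
    state: BranchingState,
    k: int,
    params: HomeostasisParams,
    rng: UniformStream,
) -> np.ndarray:
    """Divide one class-``k`` stem cell in place; return progenitor emissions.

    The dividing cell is replaced by 0, 1, or 2 stem offspring according to
    :func:`division_probabilities` evaluated at the current total; each stem
    offspring independently mutates ``k -> k+1`` with probability ``u``.
    Non-stem offspring are emitted as newborn progenitors (count per class),
    feeding the age-structured compartment's boundary.
    """
    counts = state.counts
    if counts[k] < 1:
        raise ValueError(f"no class-{k} cell available to divide")
    S = int(counts.sum())
    p0, p1, p2 = division_probabilities(
        S, params, k, S_k=float(counts[k])
    )
    r = rng.next()
    n_stem = 0 if r < p0 else (1 if r < p0 + p1 else 2)
    n_prog = 2 - n_stem
    u = params.stem_mutation_rate
    counts[k] -= 1
    for _ in range(n_stem):
        kk = k
        if k < 2 and u > 0.0 and rng.next() < u:
            kk = k + 1
        counts[kk] += 1
    emissions = np.zeros(3, dtype=np.int64)
    for _ in range(n_prog):
        kk = k
        if params.mutate_differentiated and k < 2 and u > 0.0 and rng.next() < u:
            kk = k + 1
        emissions[kk] += 1
    return emissions


def branching_event(
    state: BranchingState,
    n2_prog,
    params: HomeostasisParams,
    rng: UniformStream,
) -> tuple[np.ndarray, bool, int]:
    """One full update cycle: dedifferentiation influx, then one division.

    ``n2_prog`` is the current number of two-mutation progenitors (a float
    or a callable of time).  Returns (progenitor emissions per class,
    extinct flag, dedifferentiated cells added this event).  Time advances
    by ``tau/S`` evaluated at the pre-event population.
    """
    S = state.S
    if S < 1:
        return np.zeros(3, dtype=np.int64), True, 0
    interval = params.stem_cycle / S
    n2 = n2_prog(state.t) if callable(n2_prog) else float(n2_prog)
    added = 0
    if params.dediff_rate > 0 and n2 > 0:
        mean = dediff_influx(params.dediff_rate, n2, interval)
        if params.poisson_dediff:
            # inverse-CDF Poisson draw from the uniform stream
            added = _poisson_draw(mean, rng)
        else:
            state.dediff_accumulator += mean
            added = int(state.dediff_accumulator)
            state.dediff_accumulator -= added
        if added:
            state.counts[2] += added
            state.dediff_cumulative += added
    # re-pick division after the population update
    S_new = state.S
    r = rng.next() * S_new
    if r < state.counts[0]:
        k = 0
    elif r < state.counts[0] + state.counts[1]:
        k = 1
    else:
        k = 2
    emissions = offspring_update(state, k, params, rng)
    state.t += interval
    return emissions, state.S == 0, added


def _poisson_draw(mean: float, rng: UniformStream) -> int:
    if mean <= 0:
        return 0
    L = np.exp(-mean)
    k = 0
    p = 1.0
    while True:
        p *= rng.next()
        if p <= L:
            return k
        k += 1


def simulate_branching_fixation(
    params: HomeostasisParams,
    seed: int | np.random.SeedSequence = 0,
    t_max: float = 2e6,
    n2_prog=0.0,
) -> dict:
    """Run divisions until the two-mutation class takes over (or extinction).

    Starts at carrying capacity with zero-mutation cells.  Returns a dict
    with keys ``fixed`` (bool), ``extinct`` (bool), ``truncated`` (bool),
    ``t_fix`` (weeks), ``n_events``.  Fixation means all living stem cells
    carry two mutations (conditioned-on-non-extinction analyses discard
    extinct replicates).
    """
    rng = UniformStream(seed)
    nxt = rng.next
    q1 = params.asym_prob
    z = params.reversion_strength
    u = params.stem_mutation_rate
    eta = params.dediff_rate
    tau = params.stem_cycle
    per_class = params.per_class_capacity
    if eta > 0 or callable(n2_prog):
        # general path through branching_event (dedifferentiation bookkeeping)
        state = BranchingState.at_capacity(params)
        n_events = 0
        while True:
            c = state.counts
            S = int(c[0] + c[1] + c[2])
            if S == 0:
                return {"fixed": False, "extinct": True, "truncated": False,
                        "t_fix": float("nan"), "n_events": n_events}
            if c[2] == S:
                return {"fixed": True, "extinct": False, "truncated": False,
                        "t_fix": state.t, "n_events": n_events}
            if state.t >= t_max:
                return {"fixed": False, "extinct": False, "truncated": True,
                        "t_fix": float("nan"), "n_events": n_events}
            branching_event(state, n2_prog, params, rng)
            n_events += 1
    # fast inline path (no dedifferentiation)
    c0 = int(round(params.capacity(0)))
    c1 = c2 = 0
    K0, K1, K2 = (params.capacity(k) for k in range(3))
    t = 0.0
    n_events = 0
    while True:
        S = c0 + c1 + c2
        if S == 0:
            return {"fixed": False, "extinct": True, "truncated": False,
                    "t_fix": float("nan"), "n_events": n_events}
        if c2 == S:
            return {"fixed": True, "extinct": False, "truncated": False,
                    "t_fix": t, "n_events": n_events}
        if t >= t_max:
            return {"fixed": False, "extinct": False, "truncated": True,
                    "t_fix": float("nan"), "n_events": n_events}
        r = nxt() * S
        if r < c0:
            k = 0; Sk = c0; K = K0
        elif r < c0 + c1:
            k = 1; Sk = c1; K = K1
        else:
            k = 2; Sk = c2; K = K2
        x = (Sk if per_class else S) / K
        if z == 0:
            frac = 0.5
        elif x == 0:
            frac = 1.0
        else:
            frac = 1.0 / (1.0 + x**z)
        p2 = (1.0 - q1) * frac
        p0 = (1.0 - q1) - p2
        r2 = nxt()
        n_stem = 0 if r2 < p0 else (1 if r2 < p0 + q1 else 2)
        if k == 0:
            c0 -= 1
        elif k == 1:
            c1 -= 1
        else:
            c2 -= 1
        for _ in range(n_stem):
            kk = k
            if k < 2 and u > 0.0 and nxt() < u:
                kk = k + 1
            if kk == 0:
                c0 += 1
            elif kk == 1:
                c1 += 1
            else:
                c2 += 1
        t += tau / S
        n_events += 1
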