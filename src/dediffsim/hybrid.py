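"""Hybrid runs: stochastic stem events coupled to the progenitor transport PDE.

The stem compartment (Moran or density-dependent branching) and the
age-structured progenitor compartment exchange information both ways:

* every stem division sheds newborn progenitors into the PDE boundary at
  age 0;
* the PDE's two-mutation progenitor pool feeds back as the
  dedifferentiation signal - the fraction ``chi`` (constant-size model,
  niche-opening competition) or the absolute count ``N2`` (variable-size
  model, additive influx).

Stem events are applied at their scheduled times between PDE steps; the
feedback signal is read at the most recent PDE step (lag at most one age
step, small against the stem event interval).  Runs are bit-reproducible
from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from ._rng import UniformStream, replicate_seed
from .branching import division_probabilities
from .config import SimConfig
from .moran import FixationRecord
from .progenitor import ProgenitorPDE, steady_state_profile

__all__ = [
    "Trajectory",
    "run_hybrid",
    "run_replicates",
    "fit_growth_rate",
    "growth_window",
    "time_to_threshold",
    "first_double_mutant_origin",
]


@dataclass
class Trajectory:
    """Sampled hybrid trajectory plus event provenance."""

    t: np.ndarray                      # weeks
    stem: np.ndarray                   # (n, 3) counts per class
    prog: np.ndarray                   # (n, 3) progenitor totals per class
    chi: np.ndarray
    extinct: bool = False
    truncated: bool = False
    fixation: FixationRecord | None = None
    first_class2_origin: str | None = None
    t_first_class2: float = float("nan")
    t_S2_threshold: float = float("nan")   # exact crossing time if requested
    S2_threshold: float | None = None
    dediff_cumulative: int = 0
    emitted_progenitors: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )
    influx_time_integral: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )
    seed: int | None = None

    @property
    def S_total(self) -> np.ndarray:
        return self.stem.sum(axis=1)


def _sampler(record_stride: int):
    t_l: list[float] = []
    stem_l: list[tuple] = []
    prog_l: list[tuple] = []
    chi_l: list[float] = []

    def record(step, t, x0, x1, x2, p0, p1, p2, chi, force=False):
        if force or step % record_stride == 0:
            t_l.append(t)
            stem_l.append((x0, x1, x2))
            prog_l.append((p0, p1, p2))
            chi_l.append(chi)

    def arrays():
        return (
            np.array(t_l),
            np.array(stem_l, dtype=float),
            np.array(prog_l, dtype=float),
            np.array(chi_l),
        )

    return record, arrays


def run_hybrid(
    config: SimConfig,
    replicate: int = 0,
    stop_on_fixation: bool = True,
    stop_at_S2: float | None = None,
    stop_at_S_total: float | None = None,
    stop_at_first_class2: bool = False,
) -> Trajectory:
    """Run one coupled replicate of the configured model.

    Optional early-stop conditions record exact crossing times: fixation of
    the two-mutation stem class, the two-mutation stem count reaching
    ``stop_at_S2`` (carcinogenesis threshold), the total stem count
    reaching ``stop_at_S_total`` (sustained growth), or the first
    two-mutation stem cell (origin studies).
    """
    if config.model == "constant_N":
        return _run_constant(
            config, replicate, stop_on_fixation, stop_at_S2, stop_at_first_class2
        )
    return _run_variable(
        config, replicate, stop_at_S2, stop_at_S_total, stop_at_first_class2
    )


def _run_constant(config, replicate, stop_on_fixation, stop_at_S2, stop_first2):
    mp = config.moran_params()
    pp = config.progenitor_params()
    pde = ProgenitorPDE(pp)
    da = pp.age_step
    N = mp.N
    tau = mp.stem_cycle
    event_dt = mp.event_interval
    ratio = event_dt / da
    if abs(ratio - round(ratio)) > 1e-9 and abs(1 / ratio - round(1 / ratio)) > 1e-9:
        raise ValueError(
            "age_step_weeks must divide (or be a multiple of) the event "
            f"interval tau/N = {event_dt}"
        )
    u = mp.stem_mutation_rate
    d = mp.dediff_weight
    s = mp.selection
    if mp.dediff_scope != "two_mutation_only" and d > 0:
        scope_all = True
    else:
        scope_all = False
    birth_weight = mp.dediff_scope == "all_mutants_birth_weighted"

    stream = UniformStream(replicate_seed(config.base_seed, replicate))
    nxt = stream.next

    # progenitor pool starts at the mutation-free steady state driven by an
    # all-class-0 stem pool; the v-driven mutant background builds within
    # about one progenitor lifespan
    try:
        state = steady_state_profile(pp, (N / tau, 0.0, 0.0))
        n = state.density.copy()
    except ValueError:
        n = np.zeros((3, pp.ages.size))
    quad_w = pde.quad_w
    if birth_weight:
        bw = pde.birth * quad_w  # (3, n_grid) birth-rate-weighted quadrature
    x0, x1, x2 = N, 0, 0
    t = 0.0
    next_event = event_dt
    step = 0
    t_max = config.t_max_weeks
    record, arrays = _sampler(config.record_stride)
    totals = n @ quad_w
    chi = float(totals[2] / totals.sum()) if totals.sum() > 0 else 0.0
    record(step, t, x0, x1, x2, *totals, chi, force=True)

    tags: list[float] = []
    first_origin = None
    t_first2 = float("nan")
    emitted = np.zeros(3)
    fix_rec = None
    truncated = False
    done = False

    while not done:
        if t >= t_max:
            truncated = True
            break
        t_next = t + da
        newborn0 = newborn1 = newborn2 = 0
        while next_event <= t_next + 1e-12:
            # --- one Moran replacement event ---
            r = nxt() * N
            die = 0 if r < x0 else (1 if r < x0 + x1 else 2)
            born = -1
            parent = -1
            via_dediff = False
            if d > 0.0:
                if scope_all:
                    comp = (n * (bw if birth_weight else quad_w)).sum(axis=1) \
                        if birth_weight else n @ quad_w
                    ctot = comp.sum()
                    if ctot > 0 and nxt() < d:
                        r3 = nxt() * ctot
                        born = 0 if r3 < comp[0] else (
                            1 if r3 < comp[0] + comp[1] else 2
                        )
                        via_dediff = True
                elif chi > 0.0 and nxt() < d * chi:
                    born = 2
                    via_dediff = True
            if born < 0:
                if s != 0.0:
                    w2 = x2 * (1.0 + s)
                    r2 = nxt() * (x0 + x1 + w2)
                else:
                    r2 = nxt() * N
                parent = 0 if r2 < x0 else (1 if r2 < x0 + x1 else 2)
                born = parent
                if born < 2 and u > 0.0 and nxt() < u:
                    born += 1
            # lineage tags for emergence bookkeeping
            new_tag = None
            if born == 2:
                if parent == 2 and x2 > 0:
                    new_tag = tags[int(nxt() * x2)]
                else:
                    new_tag = next_event
            if die == 2 and x2 > 0:
                k = int(nxt() * x2)
                tags[k] = tags[-1]
                tags.pop()
            if new_tag is not None:
                tags.append(new_tag)
            # the dividing parent sheds one differentiated sibling; a
            # dedifferentiated entrant is not a division
            if not via_dediff and parent >= 0:
                if parent == 0:
                    newborn0 += 1
                elif parent == 1:
                    newborn1 += 1
                else:
                    newborn2 += 1
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
                    t_first2 = next_event
                    if stop_first2:
                        done = True
            if stop_at_S2 is not None and x2 >= stop_at_S2:
                done = True
            if x2 == N and stop_on_fixation:
                fix_rec = FixationRecord(
                    t_fix=next_event,
                    t_emergence=min(tags) if tags else float("nan"),
                    fixed_class=2,
                    truncated=False,
                    n_events=step,
                    first_class2_origin=first_origin,
                )
                done = True
            next_event += event_dt
            if done:
                break
        influx = (newborn0 / da, newborn1 / da, newborn2 / da)
        emitted[0] += newborn0
        emitted[1] += newborn1
        emitted[2] += newborn2
        n = pde.step(n, influx)
        t = t_next
        step += 1
        totals = n @ quad_w
        tot = totals.sum()
        chi = float(totals[2] / tot) if tot > 0 else 0.0
        record(step, t, x0, x1, x2, *totals, chi, force=done)

    ts, stem, prog, chis = arrays()
    traj = Trajectory(
        t=ts, stem=stem, prog=prog, chi=chis,
        truncated=truncated, fixation=fix_rec,
        first_class2_origin=first_origin, t_first_class2=t_first2,
        emitted_progenitors=emitted, influx_time_integral=emitted.copy(),
        seed=replicate,
    )
    if stop_at_S2 is not None and stem[-1, 2] >= stop_at_S2:
        traj.t_S2_threshold = ts[-1]
        traj.S2_threshold = stop_at_S2
    return traj


def _run_variable(config, replicate, stop_at_S2, stop_at_S_total, stop_first2):
    hp = config.homeostasis_params()
    pp = config.progenitor_params()
    pde = ProgenitorPDE(pp)
    da = pp.age_step
    tau = hp.stem_cycle
    u = hp.stem_mutation_rate
    eta = hp.dediff_rate
    q1 = hp.asym_prob
    z = hp.reversion_strength
    K = hp.carrying_capacity
    per_class = hp.per_class_capacity
    mut_diff = hp.mutate_differentiated

    stream = UniformStream(replicate_seed(config.base_seed, replicate))
    nxt = stream.next

    c0 = int(round(K))
    c1 = c2 = 0
    # mean progenitor emissions per division at homeostasis: 2 p0 + p1
    p0h, p1h, _ = division_probabilities(c0, hp, 0, S_k=float(c0))
    mbar0 = 2.0 * p0h + p1h
    try:
        state = steady_state_profile(pp, (mbar0 * c0 / tau, 0.0, 0.0))
        n = state.density.copy()
    except ValueError:
        n = np.zeros((3, pp.ages.size))
    quad_w = pde.quad_w
    totals = n @ quad_w
    n2_prog = float(totals[2])

    t = 0.0
    acc = 0.0
    dediff_total = 0
    S = c0
    next_event = tau / S
    step = 0
    t_max = config.t_max_weeks
    record, arrays = _sampler(config.record_stride)
    chi = float(totals[2] / totals.sum()) if totals.sum() > 0 else 0.0
    record(step, t, c0, c1, c2, *totals, chi, force=True)

    first_origin = None
    t_first2 = float("nan")
    t_thresh = float("nan")
    emitted = np.zeros(3)
    extinct = False
    truncated = False
    done = False

    while not done:
        if t >= t_max:
            truncated = True
            break
        t_next = t + da
        newborn = [0, 0, 0]
        while next_event <= t_next + 1e-12 and not done:
            S = c0 + c1 + c2
            if S == 0:
                extinct = True
                done = True
                break
            interval = tau / S
            # dedifferentiation influx (mean arrivals via accumulator)
            if eta > 0.0 and n2_prog > 0.0:
                acc += eta * n2_prog * interval
                add = int(acc)
                if add:
                    acc -= add
                    c2 += add
                    dediff_total += add
                    if first_origin is None:
                        first_origin = "dedifferentiation"
                        t_first2 = next_event
                        if stop_first2:
                            done = True
            # division probabilities re-calculated at the updated total
            S = c0 + c1 + c2
            r = nxt() * S
            k = 0 if r < c0 else (1 if r < c0 + c1 else 2)
            Sk = (c0, c1, c2)[k]
            Kk = hp.capacity(k)
            xr = (Sk if per_class else S) / Kk
            if z == 0:
                frac = 0.5
            elif xr == 0:
                frac = 1.0
            else:
                frac = 1.0 / (1.0 + xr**z)
            p2 = (1.0 - q1) * frac
            p0 = (1.0 - q1) - p2
            r2 = nxt()
            n_stem = 0 if r2 < p0 else (1 if r2 < p0 + q1 else 2)
            # remove the divider, add its offspring
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
                    if first_origin is None:
                        first_origin = "stem_mutation"
                        t_first2 = next_event
                        if stop_first2:
                            done = True
            for _ in range(2 - n_stem):
                kk = k
                if mut_diff and k < 2 and u > 0.0 and nxt() < u:
                    kk = k + 1
                newborn[kk] += 1
            S = c0 + c1 + c2
            if S == 0:
                extinct = True
                done = True
                break
            if stop_at_S2 is not None and c2 >= stop_at_S2 and math.isnan(t_thresh):
                t_thresh = next_event
                done = True
            if stop_at_S_total is not None and S >= stop_at_S_total:
                done = True
            next_event += tau / S
        influx = (newborn[0] / da, newborn[1] / da, newborn[2] / da)
        emitted += newborn
        n = pde.step(n, influx)
        t = t_next
        step += 1
        totals = n @ quad_w
        tot = totals.sum()
        n2_prog = float(totals[2])
        chi = float(totals[2] / tot) if tot > 0 else 0.0
        record(step, t, c0, c1, c2, *totals, chi, force=done)

    ts, stem, prog, chis = arrays()
    traj = Trajectory(
        t=ts, stem=stem, prog=prog, chi=chis,
        extinct=extinct, truncated=truncated,
        first_class2_origin=first_origin, t_first_class2=t_first2,
        dediff_cumulative=dediff_total,
        emitted_progenitors=emitted, influx_time_integral=emitted.copy(),
        seed=replicate,
    )
    traj.t_S2_threshold = t_thresh
    traj.S2_threshold = stop_at_S2
    return traj


def run_replicates(config: SimConfig, **stop_kwargs) -> list[Trajectory]:
    """Run ``config.replicates`` independent replicates (deterministic seeds).

    Replicates are independent given their derived seeds; execution order
    cannot change results.
    """
    return [
        run_hybrid(config, replicate=i, **stop_kwargs)
        for i in range(config.replicates)
    ]


def fit_growth_rate(
    trajectory: Trajectory, window: tuple[float, float]
) -> tuple[float, float]:
    """Least-squares exponential growth rate of the total stem count.

    Fits ``log S(t)`` over ``window = (t_lo, t_hi)`` weeks; returns
    (rate per week, standard error).
    """
    t = trajectory.t
    S = trajectory.S_total
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 3:
        raise ValueError("window contains fewer than 3 samples")
    if np.any(S[mask] <= 0):
        raise ValueError("non-positive stem counts in fit window")
    res = _stats.linregress(t[mask], np.log(S[mask]))
    return float(res.slope), float(res.stderr)


def growth_window(
    trajectory: Trajectory, S_lo: float, S_hi: float
) -> tuple[float, float]:
    """Time window over which the total stem count first climbs S_lo -> S_hi."""
    t = trajectory.t
    S = trajectory.S_total
    above_lo = np.nonzero(S >= S_lo)[0]
    above_hi = np.nonzero(S >= S_hi)[0]
    if above_lo.size == 0 or above_hi.size == 0:
        raise ValueError("trajectory never reaches the requested sizes")
    return float(t[above_lo[0]]), float(t[above_hi[0]])


def time_to_threshold(trajectory: Trajectory, threshold: float) -> float:
    """First sampled time with the two-mutation stem count at the threshold.

    Returns nan (caller treats as truncation) if never reached.  Exact
    event-level crossing times recorded by ``stop_at_S2`` take precedence.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if (
        trajectory.S2_threshold is not None
        and trajectory.S2_threshold == threshold
        and not math.isnan(trajectory.t_S2_threshold)
    ):
        return trajectory.t_S2_threshold
    idx = np.nonzero(trajectory.stem[:, 2] >= threshold)[0]
    if idx.size == 0:
        return float("nan")
    return float(trajectory.t[idx[0]])


def first_double_mutant_origin(trajectories) -> dict:
    """Fraction of replicates whose first two-mutation stem cell arose by
    stem-compartment mutation (vs dedifferentiation), with a 95% binomial CI.
    """
    origins = [
        tr.first_class2_origin for tr in trajectories
        if tr.first_class2_origin is not None
    ]
    n = len(origins)
    if n == 0:
        raise ValueError("no replicate produced a two-mutation stem cell")
    k = sum(1 for o in origins if o == "stem_mutation")
    ci = _stats.binomtest(k, n).proportion_ci(confidence_level=0.95)
    return {
        "fraction_stem_mutation": k / n,
        "n": n,
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
    }
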