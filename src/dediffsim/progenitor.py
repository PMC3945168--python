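"""Age-structured deterministic dynamics of transit-amplifying progenitor cells.

Progenitor (transit-amplifying) cells are modeled as densities ``n_k(a, t)``
over a continuous maturity age ``a`` in [0, A], one density per mutation class
``k in {0, 1, 2}``.  Cells mature at unit speed, proliferate at an
age-dependent rate ``b_k(a)`` (a Hill-type "maturity switch" that turns
division off around age ``a_b``), die/are removed at rate ``d(a)``, and mutate
forward ``k -> k+1`` at rate ``v`` per cell per week (no back mutation; class
2 absorbs).  New cells enter at age 0 from stem-cell divisions, and cells
reaching the maximum lifespan ``A`` are removed.

The transport equation is solved along characteristics with a first-order
scheme whose time step equals the age step, so advection is exact and the
only discretization error is the explicit-Euler treatment of the reaction
(birth/death/mutation) terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ProgenitorParams",
    "AgeDensity",
    "NumericalStabilityError",
    "EmptyPopulationError",
    "birth_rate",
    "death_rate",
    "net_growth_rate",
    "advance",
    "steady_state_profile",
    "steady_state_cascade",
    "mutant_fraction",
    "subpopulation_total",
    "amplification_kernel",
    "chi_sweep",
    "ProgenitorPDE",
]

N_CLASSES = 3

#: Linear per-mutation proliferation advantage reproducing the default
#: maximal rates (1.5, 1.7, 1.9) per week: b_k = b_max * (1 + s*k).
DEFAULT_PROGENITOR_ADVANTAGE = 2.0 / 15.0

# Negative densities beyond this (relative) magnitude indicate a genuine
# stability failure rather than roundoff.
_NEGATIVE_TOL = 1e-12


class NumericalStabilityError(RuntimeError):
    """A step produced significantly negative densities."""


class EmptyPopulationError(ValueError):
    """A fraction was requested of an empty progenitor population."""


@dataclass(frozen=True)
class ProgenitorParams:
    """Parameters of the progenitor compartment (hematopoietic defaults).

    ``birth_max`` holds the maximal proliferation rate per mutation class
    (per week); the default (1.5, 1.7, 1.9) encodes a small proliferative
    advantage per mutation.  ``competition_mode`` selects how (if at all)
    crowding saturates proliferation: per-class logistic totals, a shared
    age-local density ceiling, or a shared global total.
    """

    max_age: float = 20.0              # weeks
    age_step: float = 0.05             # weeks
    birth_max: tuple[float, float, float] = (1.5, 1.7, 1.9)  # per week
    death_max: float = 1.0             # per week
    birth_switch_age: float = 10.0     # weeks
    death_switch_age: float = 0.0      # weeks
    birth_steepness: float = 2.0
    death_steepness: float = 2.0
    mutation_rate: float = 1e-5        # per cell per week
    competition_mode: str = "none"     # none | logistic | local | global
    carrying_capacity: float = 1e4     # cells (local mode: cells per unit age)
    #: weight the progenitor mutation clock by the local birth rate
    #: (mutations occur at division, so faster cycling mutates faster)
    birth_weighted_mutation: bool = False

    def __post_init__(self) -> None:
        if self.max_age <= 0:
            raise ValueError("max_age must be positive")
        if self.age_step <= 0:
            raise ValueError("age_step must be positive")
        n_bins = self.max_age / self.age_step
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("max_age must be an integral multiple of age_step")
        if len(self.birth_max) != N_CLASSES:
            raise ValueError("birth_max needs one rate per mutation class (3)")
        if min(self.birth_max) < 0 or self.death_max < 0:
            raise ValueError("rates must be non-negative")
        if self.birth_switch_age < 0 or self.death_switch_age < 0:
            raise ValueError("switch ages must be non-negative")
        if self.birth_steepness < 0 or self.death_steepness < 0:
            raise ValueError("steepness parameters must be non-negative")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be non-negative")
        if self.competition_mode not in ("none", "logistic", "local", "global"):
            raise ValueError(f"unknown competition_mode {self.competition_mode!r}")
        if self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be positive")

    @classmethod
    def with_selection(
        cls, s: float, b_max: float = 1.5, **kwargs
    ) -> "ProgenitorParams":
        """Parameters with per-mutation proliferative advantage ``s``.

        The class-``k`` maximal birth rate is ``b_max * (1 + s*k)``; the
        default advantage 2/15 reproduces (1.5, 1.7, 1.9).
        """
        if s < 0:
            raise ValueError("selection advantage must be non-negative")
        birth = tuple(b_max * (1.0 + s * k) for k in range(N_CLASSES))
        return cls(birth_max=birth, **kwargs)

    @property
    def n_bins(self) -> int:
        return int(round(self.max_age / self.age_step))

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.age_step


@dataclass
class AgeDensity:
    """Progenitor density per mutation class on a shared age grid.

    ``density[k, i]`` is cells per unit age of class ``k`` at age
    ``grid[i]``; integrals over age give cell counts.
    """

    grid: np.ndarray
    density: np.ndarray  # shape (3, len(grid))
    t: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (N_CLASSES, self.grid.size):
            raise ValueError("density must have shape (3, n_grid)")

    @classmethod
    def zero(cls, params: ProgenitorParams, t: float = 0.0) -> "AgeDensity":
        grid = params.ages
        return cls(grid=grid, density=np.zeros((N_CLASSES, grid.size)), t=t)

    @property
    def age_step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def totals(self) -> np.ndarray:
        """Cell count per class (trapezoidal quadrature)."""
        return np.trapezoid(self.density, dx=self.age_step, axis=1)


def _hill_decreasing(a: np.ndarray, switch_age: float, steepness: float) -> np.ndarray:
    """Hill switch, value 1 at a=0 decaying to 0, half-max at the switch age.

    ``steepness = 0`` gives the uniform half-max rate; ``switch_age = 0`` is
    the fully-switched limit (0 for a > 0) with the half-max value retained at
    exactly a = 0.
    """
    a = np.asarray(a, dtype=float)
    if steepness == 0:
        return np.full_like(a, 0.5)
    with np.errstate(divide="ignore", over="ignore"):
        if switch_age == 0:
            ratio = np.where(a > 0, np.inf, 1.0)
        else:
            ratio = (a / switch_age) ** steepness
        out = 1.0 / (1.0 + ratio)
    return out


def birth_rate(a, k: int, params: ProgenitorParams):
    """Age-dependent proliferation rate of class-``k`` progenitors (per week).

    Maximal at age 0, half-maximal at the proliferation switch age, and
    decreasing with maturity; a zero steepness yields a uniform rate.
    """
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr < 0):
        raise ValueError("age must be non-negative")
    if not 0 <= k < N_CLASSES:
        raise ValueError(f"mutation class must be 0..2, got {k}")
    out = params.birth_max[k] * _hill_decreasing(
        a_arr, params.birth_switch_age, params.birth_steepness
    )
    return out if isinstance(a, np.ndarray) else float(out)


def death_rate(a, params: ProgenitorParams):
    """Age-dependent death/removal rate (per week), increasing with maturity.

    Half-maximal at the death switch age; the default switch age 0 gives the
    constant maximal rate for all positive ages.
    """
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr < 0):
        raise ValueError("age must be non-negative")
    out = params.death_max * (1.0 - _hill_decreasing(
        a_arr, params.death_switch_age, params.death_steepness
    ))
    return out if isinstance(a, np.ndarray) else float(out)


def net_growth_rate(a, k: int, params: ProgenitorParams):
    """Net per-capita growth rate gamma_k(a) = b_k(a) - d(a), no competition."""
    return birth_rate(a, k, params) - death_rate(a, params)


class ProgenitorPDE:
    """Stepping engine for the progenitor transport equation.

    Caches the discretized rate arrays so that repeated :meth:`step` calls
    inside the hybrid simulator stay cheap.  ``step`` advances one age step
    (dt = age_step) given the boundary influx (cells per week) per class.
    """

    def __init__(self, params: ProgenitorParams) -> None:
        self.params = params
        self.dt = params.age_step
        ages = params.ages
        self.ages = ages
        self.birth = np.stack([birth_rate(ages, k, params) for k in range(N_CLASSES)])
        self.death = death_rate(ages, params)
        # trapezoid quadrature weights over age
        w = np.full(ages.size, self.dt)
        w[0] = w[-1] = 0.5 * self.dt
        self.quad_w = w
        if params.birth_weighted_mutation:
            # mutation clock proportional to local division activity,
            # normalized so the population-average clock is v at default rates
            mean_b = float(self.birth[0] @ w) / params.max_age
            self.mut_weight = self.birth[0] / mean_b if mean_b > 0 else np.ones_like(ages)
        else:
            self.mut_weight = np.ones_like(ages)

    def _birth_factor(self, n: np.ndarray) -> np.ndarray:
        """Competition factor multiplying the birth rate, shape (3, n_grid)."""
        mode = self.params.competition_mode
        if mode == "none":
            return np.ones((N_CLASSES, 1))
        K = self.params.carrying_capacity
        if mode == "logistic":
            totals = n @ self.quad_w
            return (1.0 - totals / K)[:, None]
        if mode == "local":
            local = n.sum(axis=0)
            return np.broadcast_to(1.0 - local / K, (N_CLASSES, local.size))
        # global
        total = float((n @ self.quad_w).sum())
        return np.full((N_CLASSES, 1), 1.0 - total / K)

    def step(self, n: np.ndarray, influx: Sequence[float]) -> np.ndarray:
        """One transport step; returns the new density array (3, n_grid)."""
        p = self.params
        dt = self.dt
        v = p.mutation_rate
        factor = self._birth_factor(n)
        growth = 1.0 + (self.birth * factor - self.death) * dt
        upd = n * growth
        if v > 0:
            m = v * dt * self.mut_weight
            flow01 = m * n[0]
            flow12 = m * n[1]
            upd[0] -= flow01
            upd[1] += flow01 - flow12
            upd[2] += flow12
        out = np.empty_like(n)
        out[:, 1:] = upd[:, :-1]
        out[:, 0] = np.asarray(influx, dtype=float)
        neg = out.min()
        if neg < 0:
            scale = max(float(np.abs(out).max()), 1.0)
            if neg < -_NEGATIVE_TOL * scale:
                raise NumericalStabilityError(
                    f"negative density {neg:.3e} after step (scale {scale:.3e}); "
                    "reduce the age step or check parameters"
                )
            np.clip(out, 0.0, None, out=out)
        return out


def advance(
    state: AgeDensity,
    influx: Sequence[float],
    dt: float,
    params: ProgenitorParams,
    pde: ProgenitorPDE | None = None,
) -> AgeDensity:
    """Advance the density one step along characteristics.

    ``influx`` is the newborn-cell flux (cells per week) per mutation class
    entering at age 0; ``dt`` must equal the age step (unit maturation speed).
    """
    if abs(dt - params.age_step) > 1e-12:
        raise ValueError("dt must equal the age step (advection along characteristics)")
    if np.any(np.asarray(influx, dtype=float) < 0):
        raise ValueError("influx must be non-negative")
    if pde is None:
        pde = ProgenitorPDE(params)
    new_density = pde.step(state.density, influx)
    return AgeDensity(grid=state.grid, density=new_density, t=state.t + dt)


def _cumulative_net_growth(params: ProgenitorParams, k: int) -> np.ndarray:
    """G_k(a) = int_0^a (b_k - d) ds on the age grid (trapezoid)."""
    ages = params.ages
    gamma = net_growth_rate(ages, k, params)
    out = np.zeros_like(ages)
    out[1:] = np.cumsum(0.5 * (gamma[1:] + gamma[:-1]) * np.diff(ages))
    return out


def steady_state_profile(
    params: ProgenitorParams, influx: Sequence[float]
) -> AgeDensity:
    """Closed-form steady wave profile per class (mutation neglected).

    Without competition the steady transport solution is
    ``n_k(a) = n_k(0) * exp(int_0^a (b_k - d) ds)`` with boundary density
    equal to the influx flux (unit maturation speed).  With logistic
    competition the per-class total saturates; the boundary-value problem is
    solved by a scalar fixed point on each class total.
    """
    influx = np.asarray(influx, dtype=float)
    if influx.shape != (N_CLASSES,):
        raise ValueError("influx needs one flux per mutation class")
    if np.any(influx < 0):
        raise ValueError("influx must be non-negative")
    ages = params.ages
    density = np.zeros((N_CLASSES, ages.size))
    if params.competition_mode == "none":
        for k in range(N_CLASSES):
            density[k] = influx[k] * np.exp(_cumulative_net_growth(params, k))
    elif params.competition_mode == "logistic":
        K = params.carrying_capacity
        d = death_rate(ages, params)
        dx = params.age_step
        for k in range(N_CLASSES):
            if influx[k] == 0:
                continue
            b = birth_rate(ages, k, params)

            def total_for(N_guess: float) -> float:
                gamma = b * (1.0 - N_guess / K) - d
                G = np.concatenate(
                    ([0.0], np.cumsum(0.5 * (gamma[1:] + gamma[:-1]) * dx))
                )
                prof = influx[k] * np.exp(G)
                return float(np.trapezoid(prof, dx=dx)), prof

            # fixed-point iteration with damping; totals are monotone in N
            N_cur = total_for(0.0)[0]
            for _ in range(200):
                N_new, prof = total_for(N_cur)
                if abs(N_new - N_cur) < 1e-10 * max(N_cur, 1.0):
                    break
                N_cur = 0.5 * (N_cur + N_new)
            density[k] = prof
    else:
        raise ValueError(
            "steady_state_profile supports competition_mode 'none' or 'logistic'"
        )
    return AgeDensity(grid=ages, density=density, t=0.0)


def steady_state_cascade(
    params: ProgenitorParams, influx: Sequence[float]
) -> AgeDensity:
    """Steady state of the full mutation cascade (v > 0), no competition.

    Solves, along age, ``n_k' = (gamma_k - v_loss) n_k + v n_{k-1}`` with
    integrating factors on the grid (class 2 has no mutational loss).
    """
    if params.competition_mode != "none":
        raise ValueError("cascade steady state requires competition_mode 'none'")
    influx = np.asarray(influx, dtype=float)
    ages = params.ages
    dx = params.age_step
    v = params.mutation_rate
    density = np.zeros((N_CLASSES, ages.size))
    G = []
    for k in range(N_CLASSES):
        loss = v if k < N_CLASSES - 1 else 0.0
        gamma = net_growth_rate(ages, k, params) - loss
        Gk = np.concatenate(([0.0], np.cumsum(0.5 * (gamma[1:] + gamma[:-1]) * dx)))
        G.append(Gk)
    density[0] = influx[0] * np.exp(G[0])
    for k in (1, 2):
        # n_k(a) = e^{G_k} [ n_k(0) + int_0^a v n_{k-1}(s) e^{-G_k(s)} ds ]
        src = v * density[k - 1] * np.exp(-G[k])
        integral = np.concatenate(
            ([0.0], np.cumsum(0.5 * (src[1:] + src[:-1]) * dx))
        )
        density[k] = np.exp(G[k]) * (influx[k] + integral)
    return AgeDensity(grid=ages, density=density, t=0.0)


def mutant_fraction(state: AgeDensity) -> float:
    """Proportion chi of two-mutation cells among all progenitors."""
    totals = state.totals()
    denom = float(totals.sum())
    if denom <= 0:
        raise EmptyPopulationError("mutant fraction undefined for empty population")
    return float(totals[2] / denom)


def subpopulation_total(state: AgeDensity, k: int) -> float:
    """Cell count of mutation class ``k`` (trapezoidal quadrature)."""
    if not 0 <= k < N_CLASSES:
        raise ValueError(f"mutation class must be 0..2, got {k}")
    return float(np.trapezoid(state.density[k], dx=state.age_step))


def amplification_kernel(
    params: ProgenitorParams,
    k: int = 2,
    kind: str = "exact",
    age_step: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Age-resolved amplification weight w_k(a) = (progeny per unit influx).

    ``kind='exact'`` evaluates ``exp(int_0^a gamma_k)``; ``kind='discrete'``
    evaluates the first-order Euler product the transport scheme realizes at
    step ``age_step``, for like-for-like comparison with simulations.
    Returns (ages, w).
    """
    if age_step is not None and age_step != params.age_step:
        params = replace(params, age_step=age_step)
    ages = params.ages
    if kind == "exact":
        w = np.exp(_cumulative_net_growth(params, k))
    elif kind == "discrete":
        gamma = net_growth_rate(ages, k, params)
        # the scheme applies the reaction factor at the pre-shift age
        factors = 1.0 + gamma[:-1] * params.age_step
        w = np.concatenate(([1.0], np.cumprod(factors)))
    else:
        raise ValueError("kind must be 'exact' or 'discrete'")
    return ages, w


def amplification_integral(
    params: ProgenitorParams,
    k: int = 2,
    kind: str = "exact",
    age_step: float | None = None,
) -> float:
    """I_k = int_0^A w_k(a) da: progenitor progeny per unit boundary influx."""
    ages, w = amplification_kernel(params, k, kind=kind, age_step=age_step)
    return float(np.trapezoid(w, x=ages))


def chi_sweep(
    v_values: Sequence[float],
    s_values: Sequence[float],
    influx0: float,
    base_params: ProgenitorParams | None = None,
) -> "pd.DataFrame":
    """Steady-state two-mutation fraction over a (v, s) grid.

    Stem influx is restricted to zero-mutation cells (flux ``influx0``), so
    any two-mutation progenitors arise purely from mutation and selection
    within the progenitor compartment.
    Returns a DataFrame with columns v, s, chi, total.
    """
    import pandas as pd

    if base_params is None:
        base_params = ProgenitorParams()
    rows = []
    for s in s_values:
        params = ProgenitorParams.with_selection(
            s,
            b_max=base_params.birth_max[0],
            max_age=base_params.max_age,
            age_step=base_params.age_step,
            death_max=base_params.death_max,
            birth_switch_age=base_params.birth_switch_age,
            death_switch_age=base_params.death_switch_age,
            birth_steepness=base_params.birth_steepness,
            death_steepness=base_params.death_steepness,
        )
        for v in v_values:
            p = replace(params, mutation_rate=float(v))
            state = steady_state_cascade(p, (influx0, 0.0, 0.0))
            totals = state.totals()
            rows.append(
                {
                    "v": float(v),
                    "s": float(s),
                    "chi": mutant_fraction(state),
                    "total": float(totals.sum()),
                }
            )
    return pd.DataFrame(rows)
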