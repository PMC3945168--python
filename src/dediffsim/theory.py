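"""Semi-analytic waiting-time, fixation, and growth-threshold theory.

This module collects the closed-form and numerically evaluated results used
both as user-facing calculators and as oracles for the stochastic
simulators:

* fixation probability of a mutant in a Moran population (exact birth-death
  chain form; 1/N under neutrality),
* the branching-process (stochastic-tunneling) density of the waiting time
  until a two-mutation cell destined to fix first appears,
* the conditional fixation-time density from the backward Kolmogorov
  (diffusion) equation, solved numerically,
* their convolution: the density of the total time to fixation of the
  two-mutation class,
* the self-consistent exponential growth rate of a dedifferentiation-driven
  stem-cell population and the critical dedifferentiation rate above which
  homeostasis fails.

Time for the stochastic-population densities is measured in stem-cell
generations (one generation = tau weeks = N replacement events) and converted
to weeks only at the interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from . import progenitor as _prog

__all__ = [
    "ApproximationWarning",
    "ResolutionError",
    "TimeDensity",
    "fixation_probability",
    "moran_chain_exact",
    "durrett_emergence_density",
    "emergence_mean",
    "emergence_speedup_factor",
    "kimura_fixation_time_density",
    "total_fixation_time_density",
    "growth_kernel",
    "alpha_growth_rate",
    "eta_critical",
]


class ApproximationWarning(UserWarning):
    """Parameters lie outside an approximation's stated validity regime."""


class ResolutionError(RuntimeError):
    """A numerical grid failed to conserve probability to tolerance."""


@dataclass
class TimeDensity:
    """Probability density of a waiting time on a uniform grid.

    ``units`` is ``"generations"`` or ``"weeks"``.
    """

    t: np.ndarray
    pdf: np.ndarray
    units: str = "generations"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pdf = np.asarray(self.pdf, dtype=float)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def mass(self) -> float:
        return float(np.trapezoid(self.pdf, x=self.t))

    def mean(self) -> float:
        return float(np.trapezoid(self.t * self.pdf, x=self.t) / self.mass())

    def cdf_values(self) -> np.ndarray:
        c = np.concatenate(
            ([0.0], np.cumsum(0.5 * (self.pdf[1:] + self.pdf[:-1]) * np.diff(self.t)))
        )
        return c / c[-1]

    def cdf(self, x) -> np.ndarray:
        """Interpolated CDF, for Kolmogorov-Smirnov comparisons."""
        return np.interp(x, self.t, self.cdf_values(), left=0.0, right=1.0)

    def quantile(self, q: float) -> float:
        c = self.cdf_values()
        return float(np.interp(q, c, self.t))

    def to_weeks(self, tau: float) -> "TimeDensity":
        if self.units == "weeks":
            return self
        return TimeDensity(t=self.t * tau, pdf=self.pdf / tau, units="weeks")


# ---------------------------------------------------------------------------
# Fixation probability and exact chain oracle
# ---------------------------------------------------------------------------

def fixation_probability(N: int, s: float = 0.0) -> float:
    """Probability that a single mutant with advantage ``s`` fixes.

    Uses the birth-death (Moran) chain form
    ``rho = (1 - 1/r) / (1 - r^-N)`` with ``r = 1 + s``, which is exact for
    the replacement process simulated here and reduces to 1/N under
    neutrality.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    if s <= -1:
        raise ValueError("s must exceed -1")
    if s == 0:
        return 1.0 / N
    r = 1.0 + s
    return float((1.0 - 1.0 / r) / (1.0 - r ** (-N)))


def moran_chain_exact(N: int, s: float = 0.0) -> dict:
    """Exact absorption analysis of the two-type Moran chain (no mutation).

    State ``i`` counts mutant cells; per replacement event the mutant count
    moves +1 with probability ``p_i = [i(1+s)/W] * (N-i)/N`` and -1 with
    ``q_i = [(N-i)/W] * i/N`` where ``W = N + i s`` (fitness-weighted birth
    draw, uniform death draw).  Returns fixation probabilities and mean
    absorption/fixation times (in generations, 1 generation = N events) from
    every starting state.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    i = np.arange(1, N, dtype=float)
    W = N + i * s
    p = (i * (1.0 + s) / W) * ((N - i) / N)
    q = ((N - i) / W) * (i / N)

    # fixation probability: constant ratio q/p = 1/(1+s)
    if s == 0:
        phi = np.arange(0, N + 1, dtype=float) / N
    else:
        r = 1.0 + s
        ii = np.arange(0, N + 1, dtype=float)
        phi = (1.0 - r ** (-ii)) / (1.0 - r ** (-N))

    # mean events to absorption: p_i (T_i - T_{i+1}) + q_i (T_i - T_{i-1}) = 1
    n = N - 1
    ab = np.zeros((3, n))
    ab[0, 1:] = -p[:-1]          # superdiagonal
    ab[1, :] = p + q             # diagonal
    ab[2, :-1] = -q[1:]          # subdiagonal
    T = solve_banded((1, 1), ab, np.ones(n))
    T_full = np.concatenate(([0.0], T, [0.0]))

    # conditional fixation time: solve for U_i = phi_i * T_i^fix
    rhs = phi[1:N].copy()
    U = solve_banded((1, 1), ab, rhs)
    U_full = np.concatenate(([0.0], U, [0.0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        T_fix = np.where(phi > 0, U_full / np.where(phi > 0, phi, 1.0), np.nan)
    T_fix[N] = 0.0

    return {
        "fixation_prob": phi,
        "mean_absorption_time": T_full / N,      # generations
        "mean_conditional_fixation_time": T_fix / N,  # generations
    }


# ---------------------------------------------------------------------------
# Emergence-time density (branching-process / stochastic-tunneling result)
# ---------------------------------------------------------------------------

def _emergence_rate_params(N, u1, u2, rho, s):
    if rho is None:
        rho = fixation_probability(N, s)
    if u2 is None:
        u2 = u1
    if not (0 < rho <= 1):
        raise ValueError("rho must lie in (0, 1]")
    if u1 < 0 or u2 < 0:
        raise ValueError("mutation rates must be non-negative")
    if N * u1 >= 1:
        warnings.warn(
            f"N*u1 = {N * u1:.3g} >= 1: outside the branching approximation's "
            "stated validity regime",
            ApproximationWarning,
            stacklevel=3,
        )
    R = np.sqrt(u2 * rho)
    return float(N * u1), float(R)


def durrett_emergence_density(
    t,
    N: int,
    u1: float,
    u2: float | None = None,
    rho: float | None = None,
    s: float = 0.0,
) -> np.ndarray:
    """Density of the first appearance of a two-mutation cell destined to fix.

    Single-mutant lineages arise at rate ``N u1`` per stem-cell generation
    and drift neutrally (critical branching); each lineage spawns a successful
    double mutant with time-dependent hazard ``R tanh(R t)``, ``R = sqrt(u2
    rho)`` with ``rho`` the double mutant's fixation probability.  The
    resulting density is

        f(t) = N u1 R tanh(R t) cosh(R t)^(-N u1),

    with ``t`` in stem-cell generations.  It integrates to one exactly and
    its mean scales as ``rho^(-1/2)``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    a, R = _emergence_rate_params(N, u1, u2, rho, s)
    if R == 0 or a == 0:
        return np.zeros_like(t)
    # stable evaluation: cosh^{-a} = exp(-a*logcosh)
    x = R * t
    logcosh = np.abs(x) + np.log1p(np.exp(-2 * np.abs(x))) - np.log(2.0)
    return a * R * np.tanh(x) * np.exp(-a * logcosh)


def emergence_survival(t, N, u1, u2=None, rho=None, s=0.0) -> np.ndarray:
    """P(no successful double mutant by t) = cosh(Rt)^(-N u1)."""
    t = np.asarray(t, dtype=float)
    a, R = _emergence_rate_params(N, u1, u2, rho, s)
    if R == 0 or a == 0:
        return np.ones_like(t)
    x = R * t
    logcosh = np.abs(x) + np.log1p(np.exp(-2 * np.abs(x))) - np.log(2.0)
    return np.exp(-a * logcosh)


def emergence_mean(
    N: int,
    u1: float,
    u2: float | None = None,
    rho: float | None = None,
    s: float = 0.0,
) -> float:
    """Mean emergence time in stem-cell generations (numerical quadrature)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ApproximationWarning)
        a, R = _emergence_rate_params(N, u1, u2, rho, s)
    if R == 0 or a == 0:
        return np.inf
    # E[T] = int_0^inf cosh(Rt)^(-a) dt = (1/R) * int_0^inf cosh(x)^(-a) dx
    val, _ = quad(lambda x: np.cosh(x) ** (-a) if x < 500 else 0.0, 0, np.inf)
    return float(val / R)


def emergence_speedup_factor(N: int, u1: float = 1e-5, u2: float | None = None) -> float:
    """Maximal emergence speed-up from raising fixation odds to certainty.

    Ratio of the mean emergence time with the neutral fixation probability
    ``rho = 1/N`` to the mean with ``rho = 1`` (the strongest advantage
    dedifferentiation can confer on an emergent double mutant).  The ratio is
    independent of the mutation rate and equals ``sqrt(N)``.
    """
    if N < 1:
        raise ValueError("N must be positive")
    if N == 1:
        return 1.0
    slow = emergence_mean(N, u1, u2, rho=1.0 / N)
    fast = emergence_mean(N, u1, u2, rho=1.0)
    return float(slow / fast)


# ---------------------------------------------------------------------------
# Conditional fixation-time density (backward Kolmogorov equation)
# ---------------------------------------------------------------------------

def _diffusion_fixation_prob(p0: float, N: int, s: float) -> float:
    if s == 0:
        return p0
    return float(np.expm1(-N * s * p0) / np.expm1(-N * s))

def kimura_fixation_time_density(
    p0: float,
    N: int,
    s: float = 0.0,
    n_p: int = 401,
    t_max: float | None = None,
    n_t: int = 2400,
) -> TimeDensity:
    """Density of the time to fixation, conditioned on fixation.

    Solves the backward Kolmogorov equation for the probability ``u(p, t)``
    that an allele at initial frequency ``p`` has fixed by time ``t``
    (generations),

        du/dt = s p(1-p) du/dp + (p(1-p)/N) d2u/dp2,

    with ``u(0, t) = 0`` and ``u(1, t) = 1``, by Crank-Nicolson time
    stepping; dividing ``u(p0, t)`` by the ultimate fixation probability and
    differentiating in ``t`` yields the conditional density.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly between 0 and 1")
    if N < 2:
        raise ValueError("N must be at least 2")
    if t_max is None:
        # neutral conditional fixation from p0 is O(N) generations; selection
        # only shortens it.  Scale generously and verify mass below.
        t_max = 14.0 * N / max(1.0, 1.0 + 0.5 * N * abs(s))
    p = np.linspace(0.0, 1.0, n_p)
    h = p[1] - p[0]
    dt = t_max / n_t
    pq = p * (1.0 - p)
    diff = pq / N
    adv = s * pq

    # interior operator A u = adv u_p + diff u_pp (central differences)
    lower = diff[1:-1] / h**2 - adv[1:-1] / (2 * h)
    upper = diff[1:-1] / h**2 + adv[1:-1] / (2 * h)
    main = -2.0 * diff[1:-1] / h**2

    n_int = n_p - 2
    # Crank-Nicolson: (I - dt/2 A) u+ = (I + dt/2 A) u- + dt * bc
    abL = np.zeros((3, n_int))
    abL[0, 1:] = -0.5 * dt * upper[:-1]
    abL[1, :] = 1.0 - 0.5 * dt * main
    abL[2, :-1] = -0.5 * dt * lower[1:]

    u = np.zeros(n_p)
    u[-1] = 1.0
    idx = np.searchsorted(p, p0)
    # linear interpolation weights for u(p0)
    i_lo = min(max(idx - 1, 0), n_p - 2)
    w_hi = (p0 - p[i_lo]) / h
    record = np.empty(n_t + 1)
    record[0] = 0.0
    bc = np.zeros(n_int)
    bc[-1] = upper[-1]  # u(1) = 1 boundary contribution
    for step in range(1, n_t + 1):
        ui = u[1:-1]
        rhs = ui + 0.5 * dt * (
            main * ui
            + np.concatenate((upper[:-1] * ui[1:], [0.0]))
            + np.concatenate(([0.0], lower[1:] * ui[:-1]))
        )
        rhs += dt * bc
        u[1:-1] = solve_banded((1, 1), abL, rhs)
        record[step] = (1.0 - w_hi) * u[i_lo] + w_hi * u[i_lo + 1]

    # normalize by the discrete operator's own stationary solution (the
    # ultimate fixation probability as this grid realizes it); it agrees
    # with the analytic diffusion value to O(h^2)
    ab0 = np.zeros((3, n_int))
    ab0[0, 1:] = upper[:-1]
    ab0[1, :] = main
    ab0[2, :-1] = lower[1:]
    u_inf = solve_banded((1, 1), ab0, -bc)
    rho = float((1.0 - w_hi) * np.concatenate(([0.0], u_inf, [1.0]))[i_lo]
                + w_hi * np.concatenate(([0.0], u_inf, [1.0]))[i_lo + 1])
    rho_analytic = _diffusion_fixation_prob(p0, N, s)
    if abs(rho - rho_analytic) > 5e-3 * rho_analytic + 1e-6:
        raise ResolutionError(
            f"discrete fixation probability {rho:.6g} deviates from the "
            f"diffusion value {rho_analytic:.6g}; refine the frequency grid"
        )
    F = record / rho
    if abs(F[-1] - 1.0) > 1e-4:
        raise ResolutionError(
            f"fixation probability not conserved: CDF reaches {F[-1]:.6f}; "
            "increase t_max or grid resolution"
        )
    F = np.clip(F, 0.0, None)
    t = np.linspace(0.0, t_max, n_t + 1)
    pdf = np.gradient(F, dt)
    pdf = np.clip(pdf, 0.0, None)
    mass = np.trapezoid(pdf, x=t)
    pdf /= mass
    return TimeDensity(t=t, pdf=pdf, units="generations")


# ---------------------------------------------------------------------------
# Total fixation-time density (emergence * fixation convolution)
# ---------------------------------------------------------------------------

def total_fixation_time_density(
    N: int,
    u: float,
    s: float = 0.0,
    tau: float | None = None,
    u2: float | None = None,
    p0: float | None = None,
) -> TimeDensity:
    """Density of the total waiting time to fixation of the two-mutation class.

    Convolution of the emergence-time density (first successful double
    mutant) and the conditional fixation-time density started from a single
    copy (``p0 = 1/N``), on a shared uniform grid in stem-cell generations.
    If ``tau`` (weeks per generation) is given the result is converted to
    weeks.
    """
    if p0 is None:
        p0 = 1.0 / N
    rho = fixation_probability(N, s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ApproximationWarning)
        mean_e = emergence_mean(N, u, u2, rho=rho)
    fix = kimura_fixation_time_density(p0, N, s)
    mean_f = fix.mean()
    dt = min(mean_e, mean_f) / 400.0
    t_max = 12.0 * (mean_e + mean_f)
    t = np.arange(0.0, t_max, dt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ApproximationWarning)
        f_e = durrett_emergence_density(t, N, u, u2, rho=rho)
    f_f = np.interp(t, fix.t, fix.pdf, right=0.0)
    f_f /= np.trapezoid(f_f, x=t)
    conv = np.convolve(f_e, f_f)[: t.size] * dt
    dens = TimeDensity(t=t, pdf=conv, units="generations")
    if tau is not None:
        dens = dens.to_weeks(tau)
    return dens


# ---------------------------------------------------------------------------
# Dedifferentiation-driven growth: self-consistent rate and threshold
# ---------------------------------------------------------------------------

def growth_kernel(
    params: _prog.ProgenitorParams | None = None,
    kind: str = "exact",
    age_step: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Amplification kernel w2(a) of two-mutation progenitors.

    ``w2(a) = exp(int_0^a gamma_2)`` converts the stem-driven boundary influx
    into the age-resolved progenitor density; its integral is the number of
    progenitor progeny alive per unit influx.  ``kind='discrete'`` evaluates
    the transport scheme's first-order product instead, for like-for-like
    comparison with simulated trajectories at the same age step.
    """
    if params is None:
        params = _prog.ProgenitorParams()
    return _prog.amplification_kernel(params, k=2, kind=kind, age_step=age_step)


def _influx_integral(alpha: float, ages: np.ndarray, w: np.ndarray) -> float:
    return float(np.trapezoid(w * np.exp(-alpha * ages), x=ages))


def alpha_growth_rate(
    eta: float,
    q1: float,
    tau: float = 20.0,
    kernel: tuple[np.ndarray, np.ndarray] | None = None,
    alpha_max: float = 50.0,
    tol: float = 1e-8,
) -> float:
    """Self-consistent exponential growth rate (per week) of the stem pool.

    During dedifferentiation-driven growth the symmetric self-renewal
    probability vanishes, so stem divisions lose cells at per-capita rate
    ``(1 - q1)/tau`` while each division sheds ``m_bar = 2 - q1`` progenitors.
    Exponential growth at rate ``alpha`` is self-consistent when

        alpha = -(1 - q1)/tau + (eta * m_bar / tau) * int_0^A e^{-alpha a} w2(a) da.

    Returns 0 for ``eta`` at or below the critical rate.
    """
    if eta < 0:
        raise ValueError("eta must be non-negative")
    if not 0 <= q1 <= 1:
        raise ValueError("q1 must lie in [0, 1]")
    if kernel is None:
        kernel = growth_kernel()
    ages, w = kernel
    m_bar = 2.0 - q1

    def g(alpha: float) -> float:
        return (
            -(1.0 - q1) / tau
            + (eta * m_bar / tau) * _influx_integral(alpha, ages, w)
            - alpha
        )

    if g(0.0) <= 0.0:
        return 0.0
    hi = 0.1
    while g(hi) > 0.0:
        hi *= 2.0
        if hi > alpha_max:
            raise RuntimeError(f"growth rate not bracketed within [0, {alpha_max}]")
    return float(brentq(g, 0.0, hi, xtol=tol))


def eta_critical(
    q1: float,
    tau: float = 20.0,
    kernel: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Critical dedifferentiation rate (per two-mutation progenitor per week).

    Setting the self-consistent growth rate to zero gives

        eta_c = (1 - q1) / [(2 - q1) * int_0^A w2(a) da];

    above it the dedifferentiation influx overwhelms division-based
    homeostasis and the stem pool grows exponentially.  Larger progenitor
    amplification (the integral) lowers the threshold.  ``q1 = 0`` (no
    asymmetric divisions) is a regular special case: eta_c = 1/(2 I2).
    Note the threshold is independent of tau: both the division-loss and
    influx terms scale with the division rate 1/tau.
    """
    if not 0 <= q1 <= 1:
        raise ValueError("q1 must lie in [0, 1]")
    if kernel is None:
        kernel = growth_kernel()
    ages, w = kernel
    I2 = float(np.trapezoid(w, x=ages))
    return (1.0 - q1) / ((2.0 - q1) * I2)
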