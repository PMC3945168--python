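# Methods

`dediffsim` models mutation accumulation in a hierarchically organized
tissue — a small, stochastic pool of self-renewing stem cells feeding a
large, short-lived population of transit-amplifying progenitors — and asks
how *dedifferentiation* (a mutant progenitor re-acquiring stem-like
self-renewal) changes the waiting time to carcinogenesis, defined here as
the takeover of the stem compartment by cells carrying two driver
mutations. Default parameters describe the human hematopoietic system:
about 100 actively dividing stem cells, each dividing once per `tau = 20`
weeks, progenitors living at most `A = 20` weeks.

## Progenitor compartment (deterministic, age-structured)

Progenitors of mutation class `k ∈ {0,1,2}` are densities `n_k(a,t)` over
maturity age `a ∈ [0, A]`, transported at unit speed and reacting through

    ∂t n_k + ∂a n_k = [b_k(a) − d(a)] n_k + v n_{k−1} − v·1{k<2} n_k,

with forward-only mutation at rate `v` per cell per week (class 2 absorbs)
and a boundary influx of newborn cells at `a = 0` supplied by stem
divisions. Proliferation and death follow Hill-type maturity switches

    b_k(a) = b_k,max / (1 + (a/a_b)^{m_b}),
    d(a)   = d_max (a/a_d)^{m_d} / (1 + (a/a_d)^{m_d}),

half-maximal at the switch ages; zero steepness gives a uniform (half-max)
rate, and the default `a_d = 0` gives the constant maximal death rate (the
value at exactly `a = 0` is fixed at `d_max/2`, the switch-age convention).
Per-mutation proliferative advantage enters linearly,
`b_k,max = b_max (1 + s k)`; the default `s = 2/15` with `b_max = 1.5`/week
gives maximal rates (1.5, 1.7, 1.9)/week. Without competition the steady
state is the wave profile `n_k(a) = n_k(0) exp(∫_0^a (b_k − d))`; optional
competition saturates the birth term logistically per class, by a shared
age-local density ceiling, or by the global total, all behind one
configuration key.

**Numerics.** First-order upwind along characteristics with `dt = Δa`
(advection exact; the reaction term is explicit Euler, so the scheme is
first-order and the long-time profile converges to the closed form with
error ∝ Δa — the error halves when the step halves). Default `Δa = 0.05`
weeks; the coupled experiments below use 0.1–0.2 weeks, which resolves all
distributions compared. Densities more negative than −1e−12 relative raise
an error; smaller negative round-off is clipped to zero.

A consequence of the Euler reaction step worth stating explicitly: the
discrete amplification `∏(1 + γΔa)` undershoots `exp(∫γ)` by a factor
`≈ exp(−(Δa/2)∫γ²)` (about 8% for class 2 at `Δa = 0.1`). The
growth-threshold calculators therefore accept an *amplification kernel*
argument: the continuous kernel is the default for pure-theory tables,
while comparisons against simulated trajectories evaluate the kernel with
the simulator's own discrete propagator at the same age step, so that
theory and simulation are solved on the same footing.

## Constant-size stem pool (Moran model with niche-opening dedifferentiation)

With strict homeostasis the stem pool holds exactly `N` cells. Every
`tau/N` weeks a uniformly chosen resident dies and one cell is born: with
probability `d·χ` a dedifferentiated two-mutation progenitor fills the
niche opening (`χ` = two-mutation fraction of the progenitor pool,
`d ∈ [0,1]` the dedifferentiation weight), otherwise a fitness-weighted
copy of a resident passed through the forward mutation cascade (`u` per
replication). Variant scopes allow all progenitor classes to
dedifferentiate, optionally weighted by the age-dependent birth rate.
Death and parent draws are independent (the parent may be the dying cell).
Stem fitness is neutral by default; a selection coefficient, when used,
multiplies the birth weight of two-mutation cells.

Each replacement event sheds one differentiated daughter of the parent's
class into the progenitor boundary; dedifferentiated entrants shed none
and are not removed from the progenitor density (the influx they represent
is negligible against progenitor turnover; a depletion switch exists).

**Emergence bookkeeping.** Every living two-mutation stem cell carries the
birth time of its founding event (new mutation or dedifferentiated
entrant); copies inherit the tag. At fixation the recorded emergence time
is the earliest surviving founding time. This is an observable proxy for
"first appearance of the lineage destined to fix"; at the mutation rates
used the two definitions differ at the few-percent level, checked against
the emergence-time density below.

## Theory

* **Fixation probability.** `ρ(N, s) = (1 − 1/(1+s)) / (1 − (1+s)^{−N})`,
  the exact absorption probability of the simulated birth–death chain;
  `ρ = 1/N` at neutrality.
* **Emergence-time density.** Single-mutant lineages arise at rate `N u1`
  per stem generation and drift critically; a lineage spawns a double
  mutant destined to fix with hazard `R tanh(R t)`, `R = √(u2 ρ)`
  (branching-process/stochastic-tunneling approximation), giving

      f(t) = N u1 R tanh(R t) cosh(R t)^{−N u1},

  exactly normalized, mean ∝ `ρ^{−1/2}`. Validity requires `N u1 < 1`
  (a warning is raised otherwise) and `N√(u2 ρ)` not small. The maximal
  dedifferentiation speed-up of emergence — raising `ρ` from `1/N` to 1 —
  is the ratio of the corresponding means, `√N` (10 at `N = 100`).
* **Conditional fixation time.** The backward Kolmogorov equation
  `∂t u = s p(1−p) ∂p u + (p(1−p)/N) ∂p² u` with `u(0,t)=0`, `u(1,t)=1`
  is solved by Crank–Nicolson on a uniform frequency grid (401 points,
  central differences); `u(p0,t)` is normalized by the *discrete*
  operator's stationary solution (which matches the analytic diffusion
  fixation probability to O(h²); a >0.5% discrepancy raises a resolution
  error) and differentiated in time. Probability conservation is enforced
  to 1e−4. At `N = 20`, `p0 = 1/N`, the neutral mean matches the exact
  chain (19 generations) within 2.5%.
* **Total fixation time.** Numerical convolution of the emergence and
  conditional fixation densities on a shared uniform grid in stem-cell
  generations (grid pitch: 1/400 of the smaller component mean; horizon:
  12× the sum of means), converted to weeks via `tau` at the interface.
* **Exact chain oracle.** Fixation probabilities, unconditional and
  conditional mean absorption times of the two-type Moran chain from
  banded linear solves; used to validate both the Monte-Carlo engines and
  the diffusion solver.

## Variable-size stem pool (density-dependent branching)

Birth and death decouple: every `tau/S` weeks one uniformly chosen cell
divides and is replaced by 0, 1, or 2 stem offspring (the complement
differentiates into progenitors):

    p1 = q1,   p2 = (1 − q1) / (1 + (S/K)^z),   p0 = (1 − q1) − p2,

so the mean offspring number `m(S) = p1 + 2p2` equals 1 exactly at the
carrying capacity `K`, exceeds 1 below and falls short above it. `q1` is
the asymmetric-division probability (`q1 → 1` freezes the population
size); the reversion strength `z` sets how hard `S` is pulled back to `K`
(quasi-stationary spread ∼ √(K/z)). Stem offspring mutate independently
with probability `u`; differentiated offspring likewise (switchable).
Two-mutation progenitors dedifferentiate at rate `eta` per cell per week;
the mean arrivals `eta · N2 · tau/S` per inter-division interval
accumulate fractionally and are added to the two-mutation stem count
before each division, after which the fate probabilities are re-evaluated
at the updated total (a Poisson-arrival option exists for sensitivity
analysis). `S = 0` terminates the replicate as extinct; fixation analyses
condition on non-extinction.

**Growth theory.** During dedifferentiation-driven growth (`S ≫ K`)
symmetric self-renewal vanishes: divisions lose stem cells at per-capita
rate `(1−q1)/tau` and shed `m̄ = 2 − q1` progenitors each. Writing the
two-mutation progenitor count as the influx convolved with the
amplification kernel `w2(a) = exp(∫_0^a γ2)`, the exponential ansatz
`S2 ∝ e^{αt}` is self-consistent when

    α = −(1 − q1)/tau + (eta · m̄ / tau) ∫_0^A e^{−α a} w2(a) da,

solved by bracketing root-finding (absolute tolerance 1e−8/week). Setting
`α = 0` gives the critical rate

    eta_c = (1 − q1) / [ (2 − q1) ∫_0^A w2(a) da ],

independent of `tau` (both the division-loss and influx terms scale with
the division rate) and decreasing in the progenitor amplification — a
faster-proliferating mutant lowers the threshold. `q1 = 0` is a regular
special case (`eta_c = 1/(2 I2)`). At the defaults `eta_c ≈ 3×10⁻⁴` per
cell per week. Fitted growth rates of simulated supercritical runs agree
with `α(eta)` to better than 1% when the kernel is evaluated with the
simulator's discretization, and are independent of the mutation rate.

## Hybrid coupling

The orchestrator interleaves stem events with transport steps: events are
applied at their scheduled times between PDE steps, reading the feedback
signal (`χ` for the constant-size model, the absolute two-mutation
progenitor count for the variable-size model) from the most recent PDE
step — a lag of at most one age step, small against both the event
interval and the progenitor response time. Event emissions accumulate into
the next step's boundary influx, so the time-integrated influx equals the
emission tally identically. The progenitor pool is initialized at the
mutation-free steady state driven by the initial (all class-0) stem pool;
the mutant background builds within about one progenitor lifespan, short
against every waiting time studied. Runs are bit-reproducible from
(configuration, base seed, replicate index); replicate seeds are spawned
from a `SeedSequence`, and all stochastic engines consume a single
block-buffered uniform stream per replicate.

For stem-only studies of the dedifferentiation-as-selection mapping the
package also provides an adiabatic χ-provider, `χ = x2 I2 / Σ_k x_k I_k`
with `I_k` the per-class amplification integrals: the limit in which the
progenitor pool instantly mirrors the stem composition. With equal
progenitor birth rates this reduces to `χ = x2/N`, under which the
niche-opening bias `d·χ` is, to O(d²), identical to a selection
coefficient `s = d` for the two-mutation class — the mapping used in the
threshold analyses (the threshold `d ≈ 1/N` is then the classic condition
that selection beat drift). With the default progenitor advantage the
class-2 amplification integral is ~15× the class-0 one, so `χ` overweights
two-mutation stems and the mapped coefficient is correspondingly larger;
the mapping studies therefore disable progenitor selection.

## Study conditions and problem sizes

Defaults are the hematopoietic values: `N = K = 100`, `tau = 20` weeks,
`A = 20` weeks, `b_k,max = 1.5 + 0.2k`/week, `d_max = 1`/week, `a_b = 10`
weeks, `a_d = 0`, `m_b = m_d = 2`, `u = v = 10⁻⁵` per division (the
standard driver-mutation figure), `s = 0` in the stem pool, `q1 = 0.5`,
`z = 3`, `d = eta = 0`. At the default mutation rate a successful double
mutant takes of order `1/(N u √(u ρ))` ≈ 10⁶ stem-cell generations to
emerge — the model's core negative result: without dedifferentiation or
selection, two-hit carcinogenesis in a 100-cell active pool is far slower
than a human lifespan.

Distribution-level validations must operate where fixation happens often
enough to sample: the theory-vs-simulation comparison runs at
`u = 1.5×10⁻²`, chosen so the mean emergence time and the mean
emergence-to-fixation time are comparable (~100 generations each), the
regime in which the convolution — rather than the emergence density
alone — is the informative object; the selection-mapping runs use
`u = 5×10⁻³` with `d = 0.05`, inside the approximations' validity
(`N u < 1`, `N√(u ρ) > 1`, `N d = 5` weak selection). Acceptance-scale
replicate counts are 500 per distribution (200 per sweep point, 20 seeds
per growth bracket, 2×10⁴ for the neutral oracle), sized for a single CPU;
growth-rate fits use the window where the total stem count climbs from
2 000 to 20 000 cells, past the point where the finite-`z` fate
probabilities have reached their growth-regime limits.

## What the generator does and does not emulate

The synthetic dynamics are the model itself — there is no external data.
Relative to real hematopoiesis the model ignores: quiescent–active stem
transitions (only ~100 active cells of ~10⁴ total are modeled); spatial
niche structure (well-mixed pools); feedback from progenitors onto stem
division rates or fates other than dedifferentiation; more than two driver
mutations; back mutation; double mutation in one division. Progenitor
counts are ~10²–10³ rather than the physiological ~10⁹ because the default
amplification integral is set by the birth/death switches, not calibrated
to absolute counts; all dedifferentiation thresholds are therefore
meaningful relative to the model's own progenitor numbers (`eta_c` scales
inversely with the amplification integral). Passing tests show internal
consistency between simulation and theory under these idealizations, not
calibration to clinical incidence data.

## Known limitations

* **Constant-vs-variable equivalence is approximate, not exact.** The
  division-fate branching model's per-division offspring variance
  `p0 + p2 ≤ 1` is structurally below the Moran replacement process's
  effective variance of 2 per generation (one birth plus one uncorrelated
  death per cell per generation). Genetic drift is therefore 2–4× weaker
  in the variable-size model, and without dedifferentiation its
  fixation-time distributions run 5–40% longer than the constant-size
  model's across the tested mutation rates, slowest at high `q1`. The
  distributions are qualitatively similar — same shape and scale — but a
  two-sample KS test at 500 replicates per arm resolves the difference;
  the corresponding acceptance check documents this honestly rather than
  asserting equivalence.
* The emergence-time density is an asymptotic approximation; with
  `u1 = u2 = u` the regimes `N u ≪ 1` and `N√(u ρ) ≫ 1` cannot hold
  simultaneously at neutrality, so quantitative agreement of the
  convolution with simulation is best in the intermediate window noted
  above and degrades outside it (sequential fixation at low `u`,
  recurrent-mutation sweep acceleration at high `u`).
* The diffusion fixation-time density underestimates the exact chain's
  conditional mean by ~`O(s)` at strong selection (−5.7% at `N s = 20`).
* The adiabatic χ-provider overestimates the progenitor response to
  short-lived stem lineages; the full PDE coupling is the reference
  implementation.
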