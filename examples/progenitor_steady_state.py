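"""Steady-state age distribution of the progenitor compartment.

A fixed pool of 100 unmutated stem cells (one division per 20 weeks, one
differentiated daughter per division) feeds the age-structured progenitor
population.  The closed-form steady wave profile n(a) = n(0) exp(int_0^a
(b - d)) is compared with the transport scheme run to convergence.
"""

import numpy as np

from dediffsim import ProgenitorParams, advance, steady_state_profile
from dediffsim.progenitor import AgeDensity, ProgenitorPDE

params = ProgenitorParams(age_step=0.1, mutation_rate=0.0)
influx = (100 / 20.0, 0.0, 0.0)  # N/tau = 5 newborn progenitors per week

exact = steady_state_profile(params, influx)
state = AgeDensity.zero(params)
pde = ProgenitorPDE(params)
for _ in range(int(2.5 * params.max_age / params.age_step)):
    state = advance(state, influx, params.age_step, params, pde=pde)

print(f"closed-form total progenitors: {exact.totals()[0]:.1f} cells")
print(f"simulated   total progenitors: {state.totals()[0]:.1f} cells")
peak = exact.grid[np.argmax(exact.density[0])]
print(f"age distribution peaks at {peak:.1f} weeks "
      f"(density {exact.density[0].max():.1f} cells/week of age)")
print("The pool expands while the maturity switch keeps b > d (roughly the "
      "first 7 weeks of age), then decays; each unit of boundary influx "
      "(one cell per week) maintains ~73 progenitors at the default rates.")
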