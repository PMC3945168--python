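"""Dedifferentiation under strict homeostasis acts like positive selection.

With a constant stem pool, a dedifferentiated progenitor can only enter
through a niche opening, with probability d * chi per replacement event.
When the progenitor pool mirrors the stem composition (chi = x2/N), this
bias is equivalent to a selection coefficient s = d for the two-mutation
class.  The example compares median fixation times across d with the
mapped-selection prediction.
"""

import warnings

import numpy as np

from dediffsim import (
    MoranParams,
    quasi_steady_chi,
    simulate_fixation,
    total_fixation_time_density,
)
from dediffsim._rng import replicate_seed
from dediffsim.theory import ApproximationWarning

N, u, tau = 100, 5e-3, 20.0
chi = quasi_steady_chi()

print(f"N = {N}, u = {u}; 60 replicates per point")
print(f"{'d':>6} {'median (weeks)':>15} {'theory mean s=d':>16}")
for d in (0.0, 0.005, 0.05, 0.2):
    params = MoranParams(N=N, stem_mutation_rate=u, dediff_weight=d)
    med = np.median([
        simulate_fixation(params, chi_provider=chi,
                          seed=replicate_seed(2, i), track_emergence=False).t_fix
        for i in range(60)
    ])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ApproximationWarning)
        mean_th = total_fixation_time_density(N, u, s=d, tau=tau).mean()
    print(f"{d:>6} {med:>15.0f} {mean_th:>16.0f}")
print("Below d = 1/N = 0.01 the medians are flat (selection weaker than "
      "drift); beyond it, dedifferentiation shortens fixation sharply.")
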