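"""Global multi-exponential fit of a synthetic dataset: recover the transition table.

Simulates the noiseless default GtACR1 FTIR dataset, fits six shared
exponentials by variable projection, and matches the fitted half-lives to the
named photocycle transitions by rank order.
"""

import numpy as np

from cyclefit import default_gtacr1_model, fit_global, simulate_dataset
from cyclefit.analysis import GTACR1_TRANSITION_REFERENCE, assign_transitions

ds = simulate_dataset(default_gtacr1_model())
fit = fit_global(ds, n_exponentials=6, n_starts=20, seed=1)

print(f"converged: {fit.converged}   minimized F = {fit.F:.3g}")
print(f"{'':4}{'fitted t1/2':>14}{'reference':>12}{'ratio':>8}   process")
for e in assign_transitions(fit, GTACR1_TRANSITION_REFERENCE):
    print(f"{e.name:<4}{e.fitted_halflife:>14.4g}{e.reference_halflife:>12.3g}"
          f"{e.ratio:>8.3f}   {e.label}")

# A ratio of 1.000 means the fitted half-life reproduces the generator's
# (printed-table) value; F near zero confirms the noiseless data lie exactly
# in the multi-exponential model class.
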