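"""Kinetic-topology discrimination: is the two-step channel opening resolvable?

Simulates data under the branched (parallel) L-topology at low noise and fits
three candidate schemes directly (populations x per-state spectra, spectra
solved linearly at every step).  BIC ranks the candidates; a top-two gap below
10 is reported as indistinguishable.
"""

import numpy as np

from cyclefit import default_gtacr1_model, discriminate_topologies, simulate_dataset
from cyclefit.kinetics import get_template

model = default_gtacr1_model()
axis = np.arange(1100.0, 1801.0, 8.0)
times = np.geomspace(1e-7, 20.0, 60)
clean = simulate_dataset(model, axis=axis, times=times)
sigma = 0.01 * float(np.abs(clean.values).max())
ds = simulate_dataset(model, axis=axis, times=times, noise_sigma=sigma, seed=7)

candidates = [get_template(n) for n in ("parallel", "parallel-exchange", "unbranched")]
ranking = discriminate_topologies(ds, candidates, n_starts=2, seed=0, tol=1e-8)

print(f"{'rank':<6}{'topology':<20}{'F':>10}{'BIC':>12}  params")
for i, r in enumerate(ranking.results, 1):
    print(f"{i:<6}{r.name:<20}{r.F:>10.3f}{r.bic:>12.1f}  {r.n_parameters}")
print(f"top-two dBIC = {ranking.delta_bic:.1f} "
      f"(indistinguishable: {ranking.indistinguishable})")

# At 1% noise the branched truth wins against the single-L reduced model;
# note that equal-size topologies (e.g. parallel vs sequential) span the same
# exponential space and can never be separated by fit quality alone.
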