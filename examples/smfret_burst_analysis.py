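"""Burst statistics of a simulated µsALEX measurement.

Simulates a photon stream of slowly exchanging open (E* ~ 0.51) and closed
(E* ~ 0.68) molecules, runs the all-photon burst search, fits the E*
populations with two Gaussians, and screens for within-burst dynamics with
burst variance analysis (BVA).
"""

import numpy as np

from bindkin.simulate import SimConfig, simulate_photon_stream
from bindkin.smfret import (
    all_photon_burst_search,
    bva,
    fit_population_gaussian,
)

cfg = SimConfig(seed=2, E1=0.51, E2=0.68, k_12=0.5, k_21=0.5)
stream = simulate_photon_stream(cfg, 60.0)
bursts = all_photon_burst_search(stream)
print(f"{len(stream)} photons -> {len(bursts)} bursts")

E = np.array([b.E_star for b in bursts])
S = np.array([b.S_star for b in bursts])
fret = (S > 0.3) & (S < 0.8)  # doubly-labeled species gate
fit = fit_population_gaussian(E[fret], 2)
for mu, sd, w in zip(fit.means, fit.sigmas, fit.weights):
    print(f"population: <E*> = {mu:.3f}, sigma = {sd:.3f}, weight = {w:.2f}")

res = bva(stream, bursts, n=5)
dev = res.sd_E - res.semicircle()
se = dev.std(ddof=1) / np.sqrt(dev.size)
print(f"BVA: mean sd(E*) - semicircle = {dev.mean():+.4f} ({dev.mean() / se:+.1f} SE)")

print(
    "\nTwo E* populations at the open and closed means with near-shot-noise\n"
    "BVA indicate distinct conformations exchanging slower than the burst\n"
    "duration; excess sd(E*) above sqrt(E(1-E)/n) would flag millisecond\n"
    "within-burst dynamics instead."
)
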