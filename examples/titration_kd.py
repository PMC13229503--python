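"""Ligand-binding affinity from a burst-counting titration.

Simulates the fraction of closed (high-FRET) molecules across a ligand
ladder and fits the Hill isotherm with n = 1, the valid model when the
protein concentration is far below K_d.
"""

import numpy as np

from bindkin.simulate import simulate_titration
from bindkin.smfret import hill_titration_fit

ladder = np.array([7.8, 15.6, 31.25, 62.5, 125, 250, 500, 1000]) * 1e-9
tser = simulate_titration(35e-9, ladder, n_bursts_per_point=500, seed=5)
for L, f in zip(tser.concentrations, tser.fraction_closed):
    print(f"[L] = {L * 1e9:7.2f} nM   fraction closed = {f:.3f}")

fit = hill_titration_fit(tser.concentrations, tser.fraction_closed)
print(
    f"\nHill (n=1) fit: K_d = {fit['K_d'] * 1e9:.1f} +- {fit['K_d_stderr'] * 1e9:.1f} nM"
    f"   (generator truth {tser.truth['K_d'] * 1e9:.0f} nM)"
)
print(
    "\nThe half-saturation point of the closed-state fraction is the\n"
    "dissociation constant; binomial counting noise at 500 bursts per point\n"
    "leaves it determined to within a few nanomolar."
)
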