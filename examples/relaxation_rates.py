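"""Dominant relaxation rates of the IF and CS binding pathways.

Builds one rate set per pathway and prints the exact relaxation rate (the
slowest nonzero eigenvalue of the three-state chain, in closed form) next to
the effective-rate approximation k_on [L] + k_off across a ligand ladder.
"""

import numpy as np

from bindkin.kinetics import (
    Pathway,
    PathwayRates,
    effective_rates_cs,
    effective_rates_if,
    equilibrium_kd,
    exact_relaxation_rate,
)

cs = PathwayRates(k_e=20.0, k_r=180.0, k_plus=3e8, k_minus=2.0, pathway=Pathway.CS)
if_ = PathwayRates(k_e=5.0, k_r=50.0, k_plus=1e8, k_minus=2.0, pathway=Pathway.IF)

for rates in (cs, if_):
    kd = equilibrium_kd(rates)
    print(f"\n{rates.pathway.value} pathway, equilibrium K_d = {kd * 1e9:.1f} nM")
    print(f"{'[L] (nM)':>10} {'exact k_obs':>12} {'k_on[L]+k_off':>14}")
    for L in np.array([0.5, 1, 5, 20, 100]) * kd:
        lam = exact_relaxation_rate(rates, L)
        eff = (
            effective_rates_cs(rates, L)
            if rates.pathway is Pathway.CS
            else effective_rates_if(rates)
        )
        approx = eff.k_on * L + eff.k_off
        print(f"{L * 1e9:10.1f} {lam:12.3f} {approx:14.3f}")

print(
    "\nThe approximation tracks the exact rate when the binding-competent\n"
    "conformation is weakly populated; the CS rate saturates at k_e, the IF\n"
    "rate at k_e + k_r — the concentration dependence is what a mixing\n"
    "experiment can use to tell the pathways apart."
)
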