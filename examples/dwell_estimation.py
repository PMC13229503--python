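"""Mean dwell time from right-censored first-passage observations.

Simulates a set of fixed-length trajectories of which only some exhibit the
closed-to-open transition within the observation window, then estimates the
mean closed-state dwell time with the censored-exponential MLE.
"""

import math

from bindkin.mechanism import dwell_mle_censored
from bindkin.simulate import simulate_dwells

horizon = 3e-6                      # per-trajectory observation window (s)
mean = horizon / math.log(1 / 0.45)  # chosen so ~55% of trajectories transition

data = simulate_dwells(mean, n_traj=20, horizon=horizon, seed=11)
print(
    f"{data.n_observed} of {data.n_observed + data.n_censored} trajectories "
    f"opened within {horizon * 1e6:.0f} us"
)

res = dwell_mle_censored(data)
lo, hi = res["ci"]
print(
    f"mean dwell = {res['mean_dwell'] * 1e6:.2f} us "
    f"(95% CI {lo * 1e6:.2f} - {hi * 1e6:.2f} us; truth {mean * 1e6:.2f} us)"
)
print(
    "\nTrajectories that never transition still carry information: their\n"
    "full length enters the exposure term of the exponential likelihood,\n"
    "so the estimate is unbiased despite ~45% censoring."
)
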