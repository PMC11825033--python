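"""Decompose daily hold-time distributions into untimed + timed processes.

Each day's hold times are fit with the two-process mixture
p(x) = w * Exp(x; kappa) + (1 - w) * N(x; mu, sigma^2). The exponential
weight w is the fraction of impulsive, untimed pulls: it falls as an
animal shifts to deliberate, requirement-tracking holds, and stays high
when that shift never happens.
"""

import numpy as np

from cagelever import SimConfig, hd_like_agent, simulate_cage, w_trajectory, wt_like_agent

N_DAYS = 20
cfg = SimConfig(
    n_days=N_DAYS,
    agents=[wt_like_agent("wt1", N_DAYS), hd_like_agent("hd1", N_DAYS)],
    seed=3,
    store_trajectories=False,  # mixture fits need only the hold times
)
log = simulate_cage(cfg)

for mouse in log.mouse_ids():
    series = [(d, w) for d, w in w_trajectory(log, mouse) if np.isfinite(w)]
    first = np.mean([w for _, w in series[:3]])
    last = np.mean([w for _, w in series[-3:]])
    print(f"{mouse} ({log.genotypes[mouse]}): fitted w "
          f"first days {first:.2f} -> last days {last:.2f}")
print("a falling w marks the shift from exploratory to timed lever pulls")
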