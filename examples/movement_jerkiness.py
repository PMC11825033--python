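"""Quantify movement jerkiness from lever trajectories.

Jerkiness is the SD of the >10 Hz component of a trial's lever trace
(zero-phase high-pass at 10 Hz, >=60 dB stopband). The two simulated
agents differ only in the trajectory noise they produce, mimicking the
smoother WT versus jerkier HD movement phenotype.
"""

import numpy as np

from cagelever import AgentParams, SimConfig, daily_jerkiness, simulate_cage
from cagelever.simulate import constant

agents = [
    AgentParams("smooth", jerk_sd=0.077, w_schedule=constant(0.5), entry_rate=2.0),
    AgentParams("jerky", jerk_sd=0.098, w_schedule=constant(0.5), entry_rate=2.0),
]
log = simulate_cage(SimConfig(n_days=5, agents=agents, seed=4))

for mouse in log.mouse_ids():
    series = daily_jerkiness(log, mouse)
    print(f"{mouse}: daily mean jerkiness "
          + " ".join(f"{v:.3f}" for v in series if np.isfinite(v))
          + f"  (overall {np.nanmean(series):.3f} deg)")
print("the generating noise SDs were 0.077 and 0.098 degrees; the daily "
      "means sit slightly below them (noise is suppressed near the goal "
      "boundary) but preserve the separation")
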