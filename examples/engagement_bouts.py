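"""Daily engagement metrics and the entry-bout-size distribution.

An entry bout is the run of trials performed within one chamber visit.
Bout sizes follow a roughly geometric (discrete exponential) distribution,
and success rate tends to rise with bout size.
"""

import numpy as np

from cagelever import SimConfig, daily_engagement, entry_bout_sizes, simulate_cage, wt_like_agent

N_DAYS = 10
log = simulate_cage(
    SimConfig(n_days=N_DAYS, agents=[wt_like_agent("m1", N_DAYS)], seed=8,
              store_trajectories=False)
)

days = daily_engagement(log, "m1", n_days=N_DAYS)
print("day  trials  entries  s/entry  trials/entry  success")
for d in days[:5]:
    print(f"{d.day:>3}  {d.n_trials:>6}  {d.n_entries:>7}  {d.mean_time_in_chamber_s:>7.0f}"
          f"  {d.trials_per_entry:>12.2f}  {d.success_rate:>7.2f}")

hist, sr = entry_bout_sizes(log, "m1")
print("\nbout size -> count (success rate):")
for size in sorted(hist):
    print(f"  {size:>2}: {hist[size]:>4}  ({sr[size]:.2f})")
mean_size = sum(s * c for s, c in hist.items()) / sum(hist.values())
print(f"mean bout size {mean_size:.2f} (generator used geometric p=0.25, mean 4)")
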