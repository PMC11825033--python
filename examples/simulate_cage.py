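"""Simulate a two-animal cage for a week and inspect the closed loop.

The WT-like agent's untimed weight declines day by day, so the nightly
scheduler keeps raising its required hold time; the HD-like agent stays
mostly untimed and its requirement stalls. The printed trace shows the
requirement each agent faced at the end of each day.
"""

import numpy as np

from cagelever import SimConfig, hd_like_agent, save_session, simulate_cage, wt_like_agent

N_DAYS = 7
cfg = SimConfig(
    n_days=N_DAYS,
    agents=[wt_like_agent("wt1", N_DAYS), hd_like_agent("hd1", N_DAYS)],
    seed=11,
)
log = simulate_cage(cfg)
save_session(log, "scratch_session", trajectory_format="hdf5")

print(f"simulated {len(log.trials)} trials, {len(log.entries)} entries, "
      f"{len(log.trajectories)} trajectories over {N_DAYS} days")
for mouse in log.mouse_ids():
    reqs = {}
    holds = {}
    for t in log.trials_for(mouse):
        d = log.day_of(t.t_start)
        reqs[d] = t.required_hold_time
        holds.setdefault(d, []).append(t.hold_time)
    trace = " ".join(f"{reqs.get(d, float('nan')):.2f}" for d in range(N_DAYS))
    mean_hold = np.mean([h for hs in holds.values() for h in hs])
    print(f"{mouse} ({log.genotypes[mouse]}): required hold by day [{trace}] s, "
          f"overall mean hold {mean_hold:.3f} s")
print("a rising requirement trace = the scheduler tracking real improvement")
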