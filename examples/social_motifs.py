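"""Detect follower-influencer motifs and matched solitary controls.

A motif is follower bout -> influencer bout -> follower bout, each of at
least 10 trials inside a 5-minute window with gaps of at most 5 minutes.
With a positive influence gain, the follower shifts toward timed pulls for
the bout after observing a better-performing peer, which shows up as a
larger relative success-rate change than in the gain-0 world.
"""

import numpy as np

from cagelever import AgentParams, SimConfig, find_controls, find_motifs, simulate_cage
from cagelever.simulate import constant


def sociable(mouse, gain):
    return AgentParams(
        mouse,
        w_schedule=constant(0.8 if mouse == "follower" else 0.05),
        entry_rate=4.0,
        bout_geom_p=0.12,
        trial_gap_range=(10.0, 25.0),
        influence_gain=gain,
    )


for gain in (0.0, 0.5):
    deltas = []
    for seed in range(4):
        cfg = SimConfig(
            n_days=6,
            agents=[sociable("follower", gain), sociable("peer", 0.0)],
            seed=seed,
            store_trajectories=False,
        )
        log = simulate_cage(cfg)
        motifs = find_motifs(log)
        deltas += [
            m.delta_success
            for m in motifs
            if m.follower_id == "follower" and m.influencer_class == "good"
            and m.sr_baseline > 0
        ]
    print(f"influence gain {gain}: {len(deltas)} good-influencer motifs, "
          f"mean delta_success {np.mean(deltas):+.2f}")
print("note: the relative-change statistic is positively biased even at "
      "gain 0 (ratio estimator); only the gain-0 vs gain>0 contrast is "
      "meaningful")
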