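#!/usr/bin/env python
"""Generate the synthetic sessions the downstream analyses run on.

Writes, under scratch/data/ (regenerated on demand): a free-movement session (3-axis accelerometer
trace, dF/F-like traces for 60 neurons of which 30% respond to movement
onset at a 4x rate gain, ROI centroids, ground truth) and a 42-trial
conditioning session event table with pseudo-random 10 s CS+/CS- cues.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from miniscape import io, synth

OUT = Path("scratch/data")
SEED = 20260928


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    p = synth.SynthParams(seed=SEED, duration_s=1800.0, n_neurons=60,
                          frac_responsive=0.3, frac_negative=0.1,
                          gain_pos=4.0, gain_neg=0.2, base_rate_hz=0.1)
    rec, bouts = synth.generate_kinematics(p)
    gt = synth.draw_recruitment(p, event_type="movement_onset")
    gt.bouts = bouts
    traces, gt = synth.generate_traces(p, bouts[:, 0], gt,
                                       event_type="movement_onset")
    fp = synth.generate_footprints(p)

    io.write_accelerometer(OUT / "free1_accelerometer.csv", rec)
    io.write_traces(OUT / "free1_traces.csv", traces)
    io.write_bouts(OUT / "free1_true_bouts.csv", bouts)
    io.write_ground_truth(OUT / "free1_ground_truth.json", gt)
    pd.DataFrame(fp.centroids_um, columns=["x_um", "y_um"]).to_csv(
        OUT / "free1_centroids.csv", index=False)

    cond = synth.SynthParams(seed=SEED + 1, duration_s=2700.0, n_neurons=60)
    events = synth.generate_conditioning_session(cond)
    io.write_events(OUT / "conditioning_events.csv", events)

    n_resp = len(gt.responsive_ids["movement_onset"])
    print(f"free-movement session: {p.n_neurons} neurons, {len(bouts)} movement "
          f"bouts, {n_resp} ground-truth responders "
          f"({sum(1 for s in gt.modulation_sign.values() if s < 0)} negative)")
    cues = events[events['type'].isin(['CS+', 'CS-'])]
    print(f"conditioning session: {len(cues)} cues, "
          f"{(events['type'] == 'reward').sum()} rewards")


if __name__ == "__main__":
    main()
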