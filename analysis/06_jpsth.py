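#!/usr/bin/env python
"""Population JPSTH diagonals: noise correlation around movement onset.

Three conditions with identical rate modulation (gain 4, 200 trials):
independent neurons; zero-lag coupling on half the trials ("large
acceleration change") only; full coupling.  For each, the shift-predictor-
corrected, bin-wise-normalized population JPSTH diagonal is compared with a
far-removed (>= 20 s shift) baseline band.  Writes results/jpsth/*.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from miniscape import jpsth as jp
from miniscape import synth

OUT = Path("results/jpsth")
SEED = 818


def simulate(seed, coact, mask=None):
    p = synth.SynthParams(seed=seed, duration_s=3600.0, n_neurons=12,
                          frac_responsive=1.0, gain_pos=4.0, base_rate_hz=0.1,
                          shared_coactivation_p=coact)
    rng = p.rng(1)
    events = synth.generate_event_times(p, 200, rng=rng)
    _, gt = synth.generate_traces(p, events, synth.draw_recruitment(p, rng=rng),
                                  rng=rng, coupled_trial_mask=mask)
    return gt.spike_frames, events, p.n_frames


def report(name, trains, events, n_frames, seed):
    st = jp.diagonal_analysis(trains, events, n_frames, seed=seed)
    z = (st.post_peak - st.baseline_mean) / st.baseline_sd
    pd.DataFrame({"lag_s": st.lags_s, "diagonal": st.diagonal}).to_csv(
        OUT / f"diagonal_{name}.csv", index=False)
    verdict = "exceeds" if z > 2 else "within"
    print(f"{name}: post-onset diagonal peak {st.post_peak:.4f}, baseline "
          f"{st.baseline_mean:.4f} +/- {st.baseline_sd:.4f} (z = {z:.1f}) "
          f"-> {verdict} the baseline band")
    return {"condition": name, "post_peak": st.post_peak,
            "baseline_mean": st.baseline_mean, "baseline_sd": st.baseline_sd,
            "z": z}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []

    trains, events, T = simulate(SEED, 0.0)
    rows.append(report("independent", trains, events, T, SEED + 1))

    trains, events, T = simulate(SEED + 10, 0.5)
    rows.append(report("coupled", trains, events, T, SEED + 11))

    mask = np.zeros(200, bool)
    mask[1::2] = True
    trains, events, T = simulate(SEED + 20, 0.5, mask=mask)
    rows.append(report("large_accel_trials", trains, events[mask], T, SEED + 21))
    rows.append(report("small_accel_trials", trains, events[~mask], T, SEED + 22))

    pd.DataFrame(rows).to_csv(OUT / "summary.csv", index=False)
    print("noise correlation appears only where zero-lag coupling was injected, "
          "and only on the trial subset carrying it")


if __name__ == "__main__":
    main()
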