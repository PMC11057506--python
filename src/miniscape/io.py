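"""Delimited-table I/O for sessions: accelerometer traces, fluorescence
traces, event tables, bouts, and cross-session registries.

All tables are plain CSV.  Conventions: times are stored both in seconds and
in 0-based imaging frames (frame = floor(t * fs)); traces are frame x neuron
with columns ``n0, n1, ...``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_accelerometer", "read_accelerometer",
    "write_traces", "read_traces",
    "write_events", "read_events",
    "write_bouts", "read_bouts",
    "write_ground_truth", "read_ground_truth",
]


def write_accelerometer(path, rec) -> None:
    pd.DataFrame({"time_s": rec.t, "ap_g": rec.ap, "ml_g": rec.ml,
                  "dv_g": rec.dv}).to_csv(path, index=False)


def read_accelerometer(path, fs: float = 15.0):
    from .kinematics import AccelerometerRecord

    df = pd.read_csv(path)
    return AccelerometerRecord(t=df["time_s"].to_numpy(), ap=df["ap_g"].to_numpy(),
                               ml=df["ml_g"].to_numpy(), dv=df["dv_g"].to_numpy(),
                               fs=fs)


def write_traces(path, traces: np.ndarray) -> None:
    """traces: (n_neurons, n_frames); stored frame x neuron."""
    cols = {f"n{i}": traces[i] for i in range(traces.shape[0])}
    pd.DataFrame(cols).to_csv(path, index=False)


def read_traces(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy().T


def write_events(path, events: pd.DataFrame) -> None:
    events.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_bouts(path, bouts: np.ndarray) -> None:
    pd.DataFrame({"onset_frame": bouts[:, 0],
                  "offset_frame": bouts[:, 1]}).to_csv(path, index=False)


def read_bouts(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["onset_frame", "offset_frame"]].to_numpy()


def write_ground_truth(path, gt) -> None:
    """Structured key-value sidecar with the generator's injected truth."""
    payload = {
        "responsive_ids": {k: np.asarray(v).tolist()
                           for k, v in gt.responsive_ids.items()},
        "modulation_sign": {str(k): int(v) for k, v in gt.modulation_sign.items()},
        "tau_s": gt.tau_s,
        "bouts": gt.bouts.tolist() if gt.bouts is not None else None,
        "coupled_trials": (gt.coupled_trials.tolist()
                           if gt.coupled_trials is not None else None),
        "spike_frames": ([np.asarray(f).tolist() for f in gt.spike_frames]
                         if gt.spike_frames is not None else None),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path):
    from .synth import GroundTruth

    d = json.loads(Path(path).read_text())
    return GroundTruth(
        responsive_ids={k: np.asarray(v, int) for k, v in d["responsive_ids"].items()},
        modulation_sign={int(k): v for k, v in d["modulation_sign"].items()},
        tau_s=d.get("tau_s"),
        bouts=np.asarray(d["bouts"], int) if d.get("bouts") is not None else None,
        coupled_trials=(np.asarray(d["coupled_trials"], int)
                        if d.get("coupled_trials") is not None else None),
        spike_frames=([np.asarray(f, int) for f in d["spike_frames"]]
                      if d.get("spike_frames") is not None else None),
    )
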