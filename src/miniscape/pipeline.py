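"""End-to-end orchestration of a session analysis with a reproducible config.

``run_pipeline`` executes kinematics -> event detection -> response
significance -> correlations -> JPSTH on a session bundle and writes tidy
result tables plus a machine-readable manifest (all parameters, seeds and the
package version) so any table can be regenerated bit-identically.  The
numbered scripts under ``analysis/`` are thin drivers over this module and
the stage functions it calls.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import correlations as corrmod
from . import events as ev
from . import jpsth as jp
from . import kinematics as kin

__all__ = ["RunConfig", "SessionBundle", "run_pipeline", "subset_events"]


@dataclass
class SessionBundle:
    """Paths (or in-memory arrays) making up one imaging session."""

    session_id: str
    stage: str = "free1"  # free1/free2/naive/intermediate/expert/advanced/extinction
    traces: np.ndarray | None = None  # (n_neurons, n_frames) dF/F
    accel: object | None = None  # kinematics.AccelerometerRecord
    events: pd.DataFrame | None = None
    centroids_um: np.ndarray | None = None


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run; round-trips through YAML."""

    out_dir: str = "results/pipeline"
    fs: float = 15.0
    eta_window_s: float = 5.0
    n_null: int = 2000
    alpha: float = 0.05
    seed: int = 0
    manual_threshold_g: float | None = None
    reliability_window_s: float = 1.0
    recruitment_window_s: float = 1.5
    jpsth_pre_s: float = 2.5
    jpsth_post_s: float = 2.5
    distance_bin_um: float = 10.0
    run_correlations: bool = True
    run_jpsth: bool = True

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def subset_events(events: pd.DataFrame, event_type: str | None = None,
                  rewarded: bool | None = None, quartile: int | None = None,
                  first_n: int | None = None, last_n: int | None = None,
                  parity: str | None = None) -> pd.DataFrame:
    """Filtered copy of an event table.

    Supports the event subsets the analyses use: by type (CS+/CS-/...), by
    rewarded flag, by acceleration-change quartile, first-n / last-n trials,
    and odd/even trials (``parity`` = 'odd' selects trials 1, 3, ... in
    1-based order, i.e. rows 0, 2, ... of the filtered table).  An empty
    result is allowed.
    """
    out = events
    if event_type is not None:
        out = out[out["type"] == event_type]
    if rewarded is not None:
        out = out[out["rewarded"] == rewarded]
    if quartile is not None:
        out = out[out["quartile"] == quartile]
    out = out.sort_values("onset_s", kind="stable").reset_index(drop=True)
    if parity is not None:
        if parity not in ("odd", "even"):
            raise ValueError("parity must be 'odd' or 'even'")
        out = out.iloc[0::2] if parity == "odd" else out.iloc[1::2]
        out = out.reset_index(drop=True)
    if first_n is not None:
        out = out.iloc[:first_n].reset_index(drop=True)
    if last_n is not None:
        out = out.iloc[-last_n:].reset_index(drop=True)
    return out


def _significance_table(traces, onsets, cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for i, trace in enumerate(traces):
        res = ev.bootstrap_significance(
            trace, onsets, window_s=cfg.eta_window_s, n_null=cfg.n_null,
            alpha=cfg.alpha, seed=int(np.random.SeedSequence(
                [cfg.seed, i]).generate_state(1)[0] % (2**31)), fs=cfg.fs)
        eta = ev.compute_eta(trace, onsets, cfg.eta_window_s, cfg.fs)
        label = ev.classify_modulation(eta) if res.significant else "nonsignificant"
        rows.append({"neuron": i, "p_value": res.p_value,
                     "significant": res.significant, "label": label,
                     "observed_area": res.observed_area})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, bundles) -> dict:
    """Run all stages on each session bundle; write tables and a manifest.

    Per-session failures are isolated: the error is recorded in the manifest
    and remaining sessions still run; the returned dict maps session id to
    its output directory or error string.  Raises at the end if any session
    failed.
    """
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    for bundle in bundles:
        try:
            status[bundle.session_id] = str(_run_session(config, bundle, out_root))
        except Exception as err:  # noqa: BLE001 - isolate per-session failures
            status[bundle.session_id] = f"ERROR: {err}"
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "sessions": status,
    }
    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    failures = {k: v for k, v in status.items() if v.startswith("ERROR")}
    if failures:
        raise RuntimeError(f"{len(failures)} session(s) failed: {failures}")
    return status


def _run_session(cfg: RunConfig, bundle: SessionBundle, out_root: Path) -> Path:
    out = out_root / bundle.session_id
    out.mkdir(parents=True, exist_ok=True)
    traces = np.asarray(bundle.traces, float)
    n_frames = traces.shape[1]

    # kinematics
    ba = bundle.accel.ba
    if cfg.manual_threshold_g is not None:
        threshold = cfg.manual_threshold_g
    else:
        threshold, _ = kin.find_movement_threshold(ba)
    bouts = kin.segment_movement(ba, threshold)
    pd.DataFrame({"onset_frame": bouts.onsets, "offset_frame": bouts.offsets}
                 ).to_csv(out / "bouts.csv", index=False)
    onsets = bouts.onsets

    # Ca2+ event detection
    from .traces import detect_events
    trains = [detect_events(t).peak_frames for t in traces]

    # response significance + modulation labels
    sig = _significance_table(traces, onsets, cfg)
    sig.to_csv(out / "significance.csv", index=False)

    # reliability (positively modulated neurons) and per-event recruitment
    rel_rows = []
    for i in sig.index[sig["label"] == "positive"]:
        rel_rows.append({"neuron": int(i), "reliability": ev.response_reliability(
            trains[i], onsets, cfg.reliability_window_s, cfg.fs)})
    pd.DataFrame(rel_rows, columns=["neuron", "reliability"]).to_csv(
        out / "reliability.csv", index=False)
    recruit = ev.population_recruitment(trains, onsets,
                                        cfg.recruitment_window_s, cfg.fs)
    pd.DataFrame({"event_index": np.arange(len(recruit)),
                  "fraction_active": recruit}).to_csv(
        out / "recruitment.csv", index=False)

    # pairwise correlations vs distance
    if cfg.run_correlations and bundle.centroids_um is not None:
        wins_rest = corrmod.rest_windows(bouts, cfg.fs)
        wins_move = corrmod.movement_windows(onsets, n_frames, cfg.fs)
        d = bundle.centroids_um
        dist = np.sqrt(((d[:, None, :] - d[None, :, :]) ** 2).sum(-1))
        rows = []
        for state, wins in (("rest", wins_rest), ("movement", wins_move)):
            if len(wins) == 0:
                continue
            r = corrmod.pairwise_correlation(traces, wins)
            curve, fit = corrmod.bin_and_regress(r, dist, cfg.distance_bin_um)
            rows.append({"state": state,
                         "mean_correlation": float(np.nanmean(curve.mean_correlation)),
                         "slope_per_um": fit.slope_per_um, "r2_adj": fit.r2_adj,
                         "p_value": fit.p_value, "n_bins": fit.n_bins})
        pd.DataFrame(rows).to_csv(out / "correlations.csv", index=False)

    # population JPSTH diagonal around movement onset
    if cfg.run_jpsth and len(onsets) >= 2:
        pos = sig.index[sig["label"] == "positive"].tolist()
        pairs = list(combinations(pos, 2)) if len(pos) >= 2 else None
        stats = jp.diagonal_analysis(
            trains, onsets, n_frames, pairs=pairs, pre_s=cfg.jpsth_pre_s,
            post_s=cfg.jpsth_post_s, fs=cfg.fs, seed=cfg.seed)
        pd.DataFrame({"lag_s": stats.lags_s, "diagonal": stats.diagonal}).to_csv(
            out / "jpsth_diagonal.csv", index=False)
        pd.DataFrame([{"baseline_mean": stats.baseline_mean,
                       "baseline_sd": stats.baseline_sd,
                       "baseline_peak": stats.baseline_peak,
                       "post_peak": stats.post_peak}]).to_csv(
            out / "jpsth_summary.csv", index=False)
    return out
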