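"""Pairwise signal correlations in rest / movement / cue windows, distance
binning, and the correlation-vs-distance regression.

For each behavioral state a set of 2 s windows is defined (rest: 2 s starting
250 ms after a movement offset, for rests lasting >= 2.5 s; movement: 2 s
centered on each onset; cue: 2 s from cue onset).  Pearson correlations are
computed per window and averaged across windows, one value per neuron pair.
Pairs are then grouped into 10 um centroid-distance bins, each bin reduced to
a single mean correlation, and the bin means regressed on bin-center distance
by ordinary least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .events import frames
from .kinematics import MovementBouts

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedCorrelationCurve",
    "RegressionFit",
    "rest_windows",
    "movement_windows",
    "cue_windows",
    "pairwise_correlation",
    "bin_and_regress",
    "annulus_correlation_profile",
]


@dataclass
class BinnedCorrelationCurve:
    bin_edges_um: np.ndarray  # half-open [lo, hi)
    bin_centers_um: np.ndarray  # non-empty bins only
    mean_correlation: np.ndarray
    pair_counts: np.ndarray


@dataclass
class RegressionFit:
    """OLS of per-bin mean correlation on bin-center distance."""

    slope_per_um: float
    intercept: float
    r2: float
    r2_adj: float
    p_value: float
    n_bins: int


def rest_windows(bouts: MovementBouts, fs: float = 15.0,
                 min_rest_s: float = 2.5, delay_s: float = 0.25,
                 window_s: float = 2.0) -> list[tuple[int, int]]:
    """One 2 s window per rest >= 2.5 s, starting 250 ms after movement offset.

    Returns half-open (start, stop) frame pairs.  Only rests that follow a
    movement termination qualify.
    """
    w = frames(window_s, fs)
    out = []
    for start, stop in bouts.rest_intervals():
        if (stop - start + 1) < min_rest_s * fs:
            continue
        s = start + frames(delay_s, fs)
        out.append((s, s + w))
    return out


def movement_windows(onsets: np.ndarray, n_frames: int, fs: float = 15.0,
                     window_s: float = 2.0) -> list[tuple[int, int]]:
    """2 s windows centered on movement onsets; incomplete windows are dropped."""
    half = frames(window_s / 2.0, fs)
    out = []
    for onset in np.asarray(onsets, int):
        s, e = onset - half, onset + half
        if s >= 0 and e <= n_frames:
            out.append((s, e))
    return out


def cue_windows(onsets: np.ndarray, n_frames: int, fs: float = 15.0,
                window_s: float = 2.0) -> list[tuple[int, int]]:
    """2 s windows starting at cue onset; incomplete windows are dropped."""
    w = frames(window_s, fs)
    out = []
    for onset in np.asarray(onsets, int):
        if onset >= 0 and onset + w <= n_frames:
            out.append((onset, onset + w))
    return out


def pairwise_correlation(traces: np.ndarray, windows) -> np.ndarray:
    """Mean windowed Pearson correlation for every neuron pair.

    Correlations are computed within each window and averaged across windows.
    Windows in which either trace is constant are skipped for that pair; a
    pair with no valid window gets NaN (logged), to be omitted downstream.
    Returns an (n, n) symmetric matrix with NaN diagonal.
    """
    traces = np.asarray(traces, float)
    n = traces.shape[0]
    if n < 2:
        raise ValueError("need at least 2 neurons")
    windows = list(windows)
    if len(windows) == 0:
        raise ValueError("need at least 1 window")
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for s, e in windows:
        seg = traces[:, s:e]
        sd = seg.std(axis=1)
        valid = sd > 0
        if valid.sum() < 2:
            continue
        z = (seg[valid] - seg[valid].mean(axis=1, keepdims=True)) / sd[valid, None]
        r = (z @ z.T) / seg.shape[1]
        vi = np.flatnonzero(valid)
        acc[np.ix_(vi, vi)] += r
        cnt[np.ix_(vi, vi)] += 1.0
    with np.errstate(invalid="ignore"):
        out = acc / cnt
    n_dead = int(np.sum(cnt[np.triu_indices(n, 1)] == 0))
    if n_dead:
        logger.info("omitting %d pair(s) with no valid correlation window", n_dead)
    np.fill_diagonal(out, np.nan)
    return out


def _bin_pairs(pair_r: np.ndarray, distances_um: np.ndarray, bin_um: float):
    iu = np.triu_indices(pair_r.shape[0], 1)
    r = pair_r[iu]
    d = distances_um[iu]
    ok = ~np.isnan(r)
    r, d = r[ok], d[ok]
    edges = np.arange(0.0, d.max() + bin_um, bin_um)
    idx = np.digitize(d, edges) - 1  # half-open [lo, hi)
    centers, means, counts = [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if not sel.any():
            continue  # empty bins dropped, not zero-filled
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        means.append(r[sel].mean())
        counts.append(int(sel.sum()))
    return BinnedCorrelationCurve(
        bin_edges_um=edges, bin_centers_um=np.array(centers),
        mean_correlation=np.array(means), pair_counts=np.array(counts))


def bin_and_regress(
    pair_r: np.ndarray,
    distances_um: np.ndarray,
    bin_um: float = 10.0,
) -> tuple[BinnedCorrelationCurve, RegressionFit]:
    """10 um distance bins, one unweighted mean correlation per bin, then OLS.

    Each non-empty bin contributes a single point regardless of its pair
    count; slope is per um.  ``r2_adj`` mirrors the adjusted-R2 convention
    (which can be negative for null fits).  Because bin means are
    heteroskedastic (pair counts differ by an order of magnitude across
    bins, and sparse far-distance bins carry high leverage), the slope
    p-value uses HC3 heteroskedasticity-robust standard errors; plain OLS
    standard errors are markedly anticonservative here.
    """
    curve = _bin_pairs(pair_r, distances_um, bin_um)
    if len(curve.bin_centers_um) < 3:
        raise ValueError("need at least 3 non-empty distance bins")
    X = sm.add_constant(curve.bin_centers_um)
    fit = sm.OLS(curve.mean_correlation, X).fit(cov_type="HC3")
    reg = RegressionFit(
        slope_per_um=float(fit.params[1]), intercept=float(fit.params[0]),
        r2=float(fit.rsquared), r2_adj=float(fit.rsquared_adj),
        p_value=float(fit.pvalues[1]), n_bins=len(curve.bin_centers_um))
    return curve, reg


def annulus_correlation_profile(
    annulus_traces: np.ndarray,
    distances_um: np.ndarray,
    bin_um: float = 10.0,
) -> BinnedCorrelationCurve:
    """Distance-binned full-session correlations between annulus signals.

    Demonstrates the spatial correlation of the neuropil background (in
    contrast to the flat somatic profile); whole-session Pearson, same 10 um
    binning as the somatic analysis.
    """
    annulus_traces = np.asarray(annulus_traces, float)
    r = pairwise_correlation(annulus_traces, [(0, annulus_traces.shape[1])])
    return _bin_pairs(r, distances_um, bin_um)
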