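"""Event-locked statistics: triggered averages, PSTHs, circular-shift
bootstrap response significance, modulation classification, reliability,
per-event recruitment, cross-session overlap, and outlier flagging.

The significance test asks whether a neuron's event-triggered average (ETA)
shows more supra-threshold structure than expected by chance.  The observed
statistic is the area between the ETA and its own 85th-percentile line over
the single longest run of consecutive supra-threshold frames.  The null is
built by circularly shifting the full-session trace by a uniform random
number of frames and recomputing the ETA around the same event times, 2,000
or 5,000 times; the p-value uses the add-one permutation estimator.

For speed, the null exploits an identity: the ETA of a circularly shifted
trace is a window of the circular event-triggered profile
``c[k] = mean_e trace[(e + k) mod T]``, which is computed once per neuron by
FFT cross-correlation.  This is exactly equivalent to shifting and
re-averaging (asserted in the test suite) as long as no retained event
window crosses the session edge, which the edge-dropping rule guarantees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Eta",
    "Psth",
    "BootstrapResult",
    "compute_eta",
    "compute_psth",
    "bootstrap_significance",
    "classify_modulation",
    "response_reliability",
    "population_recruitment",
    "expected_overlap_independent",
    "session_count_profile",
    "session_overlap",
    "filter_registration",
    "split_half_consistency",
    "flag_outliers",
    "frames",
]

FRAME_RATE = 15.0  # imaging frames / s


def frames(seconds: float, fs: float = FRAME_RATE) -> int:
    """Seconds to frames, flooring (1 s -> 15 frames, 1.5 s -> 22 frames)."""
    return int(np.floor(seconds * fs + 1e-9))


@dataclass
class Eta:
    """Event-triggered average of a continuous trace."""

    lags_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_events: int
    n_dropped: int = 0
    fs: float = FRAME_RATE


@dataclass
class Psth:
    """Peristimulus histogram of detected Ca2+ events, one frame (67 ms) per bin."""

    lags_s: np.ndarray
    counts: np.ndarray
    rate_hz: np.ndarray
    n_trials: int
    bin_s: float


@dataclass
class BootstrapResult:
    observed_area: float
    threshold: float
    run_start: int  # lag index of the longest supra-threshold run
    run_length: int
    null_areas: np.ndarray
    p_value: float
    significant: bool
    seed: int
    degenerate: bool = False


def _window_indices(event_frames, n_frames, pre_f, post_f):
    ev = np.asarray(event_frames, int)
    ok = ev[(ev - pre_f >= 0) & (ev + post_f < n_frames)]
    return ok, len(ev) - len(ok)


def compute_eta(
    trace: np.ndarray,
    event_frames: np.ndarray,
    window_s: float = 5.0,
    fs: float = FRAME_RATE,
) -> Eta:
    """Frame-aligned average of ``trace`` across events, +/- window_s / 2.

    Events whose window would cross the session bounds are dropped and
    counted in ``n_dropped``.
    """
    trace = np.asarray(trace, float)
    half = frames(window_s / 2.0, fs)
    ok, dropped = _window_indices(event_frames, len(trace), half, half)
    if len(ok) == 0:
        raise ValueError("no event with a full window inside the session")
    lags = np.arange(-half, half + 1)
    seg = trace[ok[:, None] + lags[None, :]]
    sem = seg.std(axis=0, ddof=1) / np.sqrt(len(ok)) if len(ok) > 1 else np.zeros(len(lags))
    return Eta(lags_s=lags / fs, mean=seg.mean(axis=0), sem=sem,
               n_events=len(ok), n_dropped=dropped, fs=fs)


def compute_psth(
    peak_frames_list,
    event_frames: np.ndarray,
    window_s: float = 5.0,
    fs: float = FRAME_RATE,
) -> Psth:
    """Per-bin count of Ca2+ events across trials (and neurons), 1-frame bins.

    ``peak_frames_list`` is one array of detected peak frames per neuron (a
    single array is treated as one neuron).  Counts are summed over all
    trials and neurons; ``rate_hz`` divides by trials x neurons x bin width.
    """
    if isinstance(peak_frames_list, np.ndarray) and peak_frames_list.ndim == 1:
        peak_frames_list = [peak_frames_list]
    half = frames(window_s / 2.0, fs)
    ev = np.asarray(event_frames, int)
    if len(ev) == 0:
        raise ValueError("no events")
    lags = np.arange(-half, half + 1)
    counts = np.zeros(len(lags))
    for peaks in peak_frames_list:
        peaks = np.asarray(peaks, int)
        for e in ev:
            rel = peaks - e
            sel = rel[(rel >= -half) & (rel <= half)]
            np.add.at(counts, sel + half, 1.0)
    n_units = len(peak_frames_list) * len(ev)
    return Psth(lags_s=lags / fs, counts=counts,
                rate_hz=counts / (n_units / fs), n_trials=len(ev), bin_s=1.0 / fs)


def _circular_eta_profile(trace: np.ndarray, event_frames: np.ndarray) -> np.ndarray:
    """c[k] = mean over events of trace[(e + k) mod T], via FFT."""
    T = len(trace)
    ind = np.zeros(T)
    np.add.at(ind, np.asarray(event_frames, int), 1.0)
    c = np.fft.irfft(np.fft.rfft(trace) * np.conj(np.fft.rfft(ind)), n=T)
    return c / len(event_frames)

def _area_statistic(eta: np.ndarray, percentile: float = 85.0):
    """Area between the ETA and its q-th percentile over the longest
    supra-threshold run.  Returns (area, threshold, run_start, run_length)."""
    thr = np.percentile(eta, percentile)
    above = eta > thr
    if not above.any():
        return 0.0, float(thr), -1, 0
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    lengths = ends - starts
    best = int(np.argmax(lengths))  # first longest run on ties
    s, e = int(starts[best]), int(ends[best])
    area = float((eta[s:e] - thr).sum())
    return area, float(thr), s, int(lengths[best])


def bootstrap_significance(
    trace: np.ndarray,
    event_frames: np.ndarray,
    window_s: float = 5.0,
    n_null: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    fs: float = FRAME_RATE,
    percentile: float = 85.0,
    two_sided: bool = False,
) -> BootstrapResult:
    """Circular-shift bootstrap test of event-locked modulation.

    Observed statistic: longest-run supra-threshold area of the ETA relative
    to the ETA's own ``percentile`` line.  Null: the same statistic after
    circularly shifting the session trace by a uniform random number of
    frames (>= 1) and recomputing the ETA around the same events.  The
    add-one estimator gives p = (1 + #{null >= observed}) / (1 + n_null);
    significant iff p < alpha.

    ``two_sided=True`` additionally scores the area *below* the
    (100 - percentile) line and uses the larger of the two areas as the
    statistic — a variant for suppression-dominated responses, off by
    default.
    """
    trace = np.asarray(trace, float)
    T = len(trace)
    half = frames(window_s / 2.0, fs)
    if T <= 4 * half:
        raise ValueError("session must be much longer than the ETA window")
    ok, _ = _window_indices(event_frames, T, half, half)
    if len(ok) == 0:
        raise ValueError("no event with a full window inside the session")

    def stat(eta):
        area, thr, s, ln = _area_statistic(eta, percentile)
        if two_sided:
            neg_area, *_ = _area_statistic(-eta, percentile)
            if neg_area > area:
                return neg_area, thr, s, ln
        return area, thr, s, ln

    c = _circular_eta_profile(trace, ok)
    lags = np.arange(-half, half + 1)
    obs_eta = c[lags % T]
    if np.ptp(obs_eta) == 0:
        warnings.warn("degenerate (constant) ETA; reporting p = 1")
        return BootstrapResult(0.0, float(obs_eta[0]), -1, 0, np.zeros(n_null),
                               1.0, False, seed, degenerate=True)
    obs_area, thr, run_start, run_len = stat(obs_eta)

    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, T, size=n_null)
    # ETA of the trace shifted by s == profile window starting at lag - s
    null_etas = c[(lags[None, :] - shifts[:, None]) % T]
    null_areas = np.empty(n_null)
    for i in range(n_null):
        null_areas[i] = stat(null_etas[i])[0]
    p = (1.0 + np.sum(null_areas >= obs_area)) / (1.0 + n_null)
    return BootstrapResult(
        observed_area=obs_area, threshold=thr, run_start=run_start - half,
        run_length=run_len, null_areas=null_areas, p_value=float(p),
        significant=bool(p < alpha), seed=seed)


def classify_modulation(eta: Eta) -> str:
    """'positive' if the mean ETA in (0, +1 s] exceeds the mean in [-1 s, 0).

    Applied to significantly responsive neurons only; exact ties are labeled
    positive with a warning.
    """
    lags_f = np.rint(eta.lags_s * eta.fs).astype(int)
    w = frames(1.0, eta.fs)
    pre = eta.mean[(lags_f >= -w) & (lags_f < 0)]
    post = eta.mean[(lags_f >= 1) & (lags_f <= w)]
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("ETA must span at least +/- 1 s")
    if post.mean() == pre.mean():
        warnings.warn("exact pre/post tie; labeling positive by convention")
        return "positive"
    return "positive" if post.mean() > pre.mean() else "negative"


def response_reliability(
    peak_frames: np.ndarray,
    event_frames: np.ndarray,
    window_s: float = 1.0,
    fs: float = FRAME_RATE,
) -> float:
    """Fraction of events followed by >= 1 detected transient within 1 s.

    The window is (onset, onset + window_s]; defined for neurons positively
    modulated around this event type.
    """
    ev = np.asarray(event_frames, int)
    if len(ev) == 0:
        raise ValueError("no events")
    peaks = np.asarray(peak_frames, int)
    w = frames(window_s, fs)
    hit = [(np.any((peaks > e) & (peaks <= e + w))) for e in ev]
    return float(np.mean(hit))


def population_recruitment(
    peak_frames_list,
    event_frames: np.ndarray,
    window_s: float = 1.5,
    fs: float = FRAME_RATE,
) -> np.ndarray:
    """Per-event fraction of neurons producing a transient within 1.5 s.

    Returns one fraction per event; the distribution across events is the
    per-event population recruitment.
    """
    if len(peak_frames_list) == 0:
        raise ValueError("need at least one neuron")
    ev = np.asarray(event_frames, int)
    w = frames(window_s, fs)
    out = np.zeros(len(ev))
    for peaks in peak_frames_list:
        peaks = np.asarray(peaks, int)
        for j, e in enumerate(ev):
            if np.any((peaks > e) & (peaks <= e + w)):
                out[j] += 1.0
    return out / len(peak_frames_list)


def expected_overlap_independent(p1: float, p2: float) -> float:
    """Expected both-responsive fraction if recruitment is independent: p1 * p2."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    return p1 * p2


def session_count_profile(ps) -> np.ndarray:
    """P(significant in exactly j of k sessions), j = 0..k, for independent
    per-session probabilities ``ps`` (Poisson-binomial via convolution)."""
    prof = np.array([1.0])
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
        prof = np.convolve(prof, [1.0 - p, p])
    return prof


def session_overlap(labels_a: dict, labels_b: dict, registry) -> dict:
    """Observed responsive-overlap fractions over registered cells.

    ``registry`` is an iterable of (id_in_A, id_in_B) pairs of accepted
    cross-session mappings; ``labels_*`` map cell id -> bool (significant).
    Returns fractions {a_only, b_only, both, neither} over registered cells.
    """
    registry = list(registry)
    if len(registry) == 0:
        raise ValueError("registry is empty")
    n = len(registry)
    both = a_only = b_only = neither = 0
    for ia, ib in registry:
        a, b = bool(labels_a[ia]), bool(labels_b[ib])
        both += a and b
        a_only += a and not b
        b_only += b and not a
        neither += not a and not b
    return {"a_only": a_only / n, "b_only": b_only / n,
            "both": both / n, "neither": neither / n, "n_registered": n}


def filter_registration(registry_df):
    """Accept cross-session mappings with p_same > 0.5 and centroid distance < 14 um.

    Both inequalities are strict; requires columns ``p_same`` and
    ``centroid_distance_um``.
    """
    for col in ("p_same", "centroid_distance_um"):
        if col not in registry_df.columns:
            raise ValueError(f"registry table lacks required column {col!r}")
    keep = (registry_df["p_same"] > 0.5) & (registry_df["centroid_distance_um"] < 14.0)
    return registry_df.loc[keep].reset_index(drop=True)


def split_half_consistency(
    trace: np.ndarray,
    event_frames: np.ndarray,
    scheme: str = "odd_even",
    seed: int = 0,
    **bootstrap_kwargs,
) -> dict:
    """Bootstrap significance on two halves of the trials.

    ``scheme`` is ``odd_even`` (trials 0, 2, 4, ... vs 1, 3, 5, ...) or
    ``first_last`` (first half vs last half).  Returns the two
    :class:`BootstrapResult`s and the Venn counts of significance.
    """
    ev = np.asarray(event_frames, int)
    if len(ev) < 8:
        raise ValueError("need at least 8 trials to split")
    if scheme == "odd_even":
        a, b = ev[::2], ev[1::2]
    elif scheme == "first_last":
        half = len(ev) // 2
        a, b = ev[:half], ev[half:]
    else:
        raise ValueError("scheme must be 'odd_even' or 'first_last'")
    ra = bootstrap_significance(trace, a, seed=seed, **bootstrap_kwargs)
    rb = bootstrap_significance(trace, b, seed=seed + 1, **bootstrap_kwargs)
    return {
        "split_a": ra, "split_b": rb,
        "both": ra.significant and rb.significant,
        "a_only": ra.significant and not rb.significant,
        "b_only": rb.significant and not ra.significant,
        "neither": not ra.significant and not rb.significant,
    }


def flag_outliers(values) -> np.ndarray:
    """Tukey fences: flag values beyond 1.5 IQR outside the quartiles."""
    values = np.asarray(values, float)
    if len(values) < 4:
        raise ValueError("need at least 4 values")
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    return (values > q3 + 1.5 * iqr) | (values < q1 - 1.5 * iqr)
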