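"""Joint peristimulus time histograms with shift-predictor correction.

The JPSTH measures noise correlation — the degree to which trial-by-trial
fluctuations in two neurons' event-locked responses are shared.  Each
repetition of a behavioral event is a trial; Ca2+ events are binarized into
67 ms (one-frame) bins.  The raw JPSTH entry (t1, t2) counts trials in which
neuron 1 fired in bin t1 and neuron 2 in bin t2.  The shift predictor — the
same matrix averaged over all circular trial shifts of neuron 2 — captures
correlation explained by common rate modulation; subtracting it bin by bin
and smoothing with a 2-D Gaussian (SD 1 bin) gives the corrected JPSTH.
Normalizing by the product of the SDs of the two PSTHs makes it unitless,
and the population JPSTH averages the normalized matrices over pairs.  Its
diagonal is the time course of zero-lag noise correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.ndimage import gaussian_filter

from .events import frames

__all__ = [
    "DiagonalStats",
    "binarize_trials",
    "raw_jpsth",
    "shift_predictor",
    "corrected_jpsth",
    "normalize_jpsth",
    "pair_jpsth",
    "population_jpsth",
    "population_jpsth_from_trains",
    "diagonal_analysis",
]


@dataclass
class DiagonalStats:
    """Diagonal of a population JPSTH against a far-removed baseline."""

    lags_s: np.ndarray
    diagonal: np.ndarray
    baseline_mean: float
    baseline_sd: float
    baseline_peak: float  # max in the 0.5 s window before onset
    post_peak: float  # max in the 1.5 s window after onset
    baseline_shift_s: float


def binarize_trials(
    peak_frames: np.ndarray,
    event_frames: np.ndarray,
    n_frames: int,
    pre_s: float = 2.5,
    post_s: float = 2.5,
    fs: float = 15.0,
) -> np.ndarray:
    """Trial x bin indicator of >= 1 transient per one-frame (67 ms) bin.

    Trials whose window extends past the session are dropped.  At 67 ms a bin
    holds at most one detected peak, so indicators and counts coincide.
    """
    ev = np.asarray(event_frames, int)
    if len(ev) < 2:
        raise ValueError("need at least 2 trials")
    pre, post = frames(pre_s, fs), frames(post_s, fs)
    ok = ev[(ev - pre >= 0) & (ev + post < n_frames)]
    if len(ok) == 0:
        raise ValueError("no trial fits inside the session")
    peaks = np.asarray(peak_frames, int)
    n_bins = pre + post + 1
    tm = np.zeros((len(ok), n_bins), dtype=np.int8)
    for i, e in enumerate(ok):
        rel = peaks - e
        sel = rel[(rel >= -pre) & (rel <= post)]
        tm[i, sel + pre] = 1
    return tm


def raw_jpsth(tm1: np.ndarray, tm2: np.ndarray) -> np.ndarray:
    """Entry (t1, t2) = number of trials with neuron 1 active in bin t1 and
    neuron 2 active in bin t2."""
    tm1, tm2 = np.asarray(tm1), np.asarray(tm2)
    if tm1.shape != tm2.shape:
        raise ValueError("trial matrices must share trial count and window")
    return (tm1.astype(float).T @ tm2.astype(float))


def shift_predictor(tm1: np.ndarray, tm2: np.ndarray) -> np.ndarray:
    """Average raw JPSTH over all non-zero circular shifts of neuron 2 trials.

    Trial n of neuron 1 is paired with trial n + m of neuron 2 for every
    shift m = 1..N-1, and the resulting matrices are averaged.
    """
    tm1, tm2 = np.asarray(tm1), np.asarray(tm2)
    if tm1.shape != tm2.shape:
        raise ValueError("trial matrices must share trial count and window")
    n = tm1.shape[0]
    if n < 2:
        raise ValueError("shift predictor requires at least 2 trials")
    # Summing raw_jpsth(tm1, roll(tm2, -m)) over m = 1..N-1 pairs every trial
    # of neuron 1 with every *other* trial of neuron 2 exactly once, which is
    # outer(sum1, sum2) - raw.  This closed form equals the explicit average
    # over all N-1 circular shifts (asserted against the loop in the tests).
    raw = raw_jpsth(tm1, tm2)
    s1 = tm1.astype(float).sum(axis=0)
    s2 = tm2.astype(float).sum(axis=0)
    return (np.outer(s1, s2) - raw) / (n - 1)


def corrected_jpsth(raw: np.ndarray, predictor: np.ndarray,
                    smooth_sd_bins: float = 1.0) -> np.ndarray:
    """(raw - predictor), smoothed with a 2-D Gaussian of SD 1 bin.

    The kernel is truncated at 3 SD and renormalized at the edges so the
    smoother is an average of available bins rather than shrinking toward 0.
    """
    raw, predictor = np.asarray(raw, float), np.asarray(predictor, float)
    if raw.shape != predictor.shape:
        raise ValueError("raw and predictor must have the same shape")
    diff = raw - predictor
    if smooth_sd_bins <= 0:
        return diff
    num = gaussian_filter(diff, smooth_sd_bins, mode="constant", truncate=3.0)
    den = gaussian_filter(np.ones_like(diff), smooth_sd_bins, mode="constant",
                          truncate=3.0)
    return num / den


def normalize_jpsth(corrected: np.ndarray, psth1: np.ndarray,
                    psth2: np.ndarray) -> np.ndarray:
    """Divide the corrected JPSTH by the product of the PSTH SDs.

    ``psth1`` / ``psth2`` are the per-bin event counts of the two neurons
    (column sums of their trial matrices); the SD is the scalar SD of each
    PSTH curve across bins.  A zero SD (perfectly flat PSTH) makes the pair
    unusable and raises.
    """
    sd1 = float(np.std(np.asarray(psth1, float), ddof=1))
    sd2 = float(np.std(np.asarray(psth2, float), ddof=1))
    if sd1 == 0 or sd2 == 0:
        raise ZeroDivisionError("flat PSTH: pair cannot be normalized")
    return np.asarray(corrected, float) / (sd1 * sd2)


def pair_jpsth(tm1: np.ndarray, tm2: np.ndarray,
               smooth_sd_bins: float = 1.0,
               normalization: str = "binwise") -> np.ndarray:
    """Normalized corrected JPSTH of one neuron pair from its trial matrices.

    ``normalization='binwise'`` (default) divides each (t1, t2) bin of
    raw - predictor by N times the product of the two bins' across-trial
    indicator SDs, turning every bin into a trial-by-trial correlation
    coefficient.  This is the classical JPSTH normalization; its key property
    is a rate-independent noise scale, so diagonal values at event-modulated
    times are directly comparable with a far-removed baseline.  Bins where a
    neuron never (or always) fires have no across-trial variance and are set
    to 0.  ``normalization='psth_sd'`` instead divides the smoothed corrected
    matrix by the scalar product of the SDs of the two PSTH curves
    (:func:`normalize_jpsth`); it preserves shape but leaves bin noise
    proportional to firing rate.
    """
    tm1, tm2 = np.asarray(tm1), np.asarray(tm2)
    raw = raw_jpsth(tm1, tm2)
    pred = shift_predictor(tm1, tm2)
    if normalization == "psth_sd":
        corr = corrected_jpsth(raw, pred, smooth_sd_bins)
        return normalize_jpsth(corr, tm1.sum(axis=0), tm2.sum(axis=0))
    if normalization != "binwise":
        raise ValueError("normalization must be 'binwise' or 'psth_sd'")
    n = tm1.shape[0]
    sig1 = tm1.astype(float).std(axis=0)
    sig2 = tm2.astype(float).std(axis=0)
    denom = n * np.outer(sig1, sig2)
    diff = raw - pred
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    if np.all(denom == 0):
        raise ZeroDivisionError("no bin has across-trial variance")
    return corrected_jpsth(j, np.zeros_like(j), smooth_sd_bins)


def population_jpsth(normalized_list) -> np.ndarray:
    """Elementwise mean of normalized corrected JPSTHs across pairs."""
    normalized_list = list(normalized_list)
    if len(normalized_list) == 0:
        raise ValueError("need at least one pair")
    return np.mean(np.stack(normalized_list), axis=0)


def population_jpsth_from_trains(
    peak_frames_list,
    event_frames: np.ndarray,
    n_frames: int,
    pairs=None,
    pre_s: float = 2.5,
    post_s: float = 2.5,
    fs: float = 15.0,
    smooth_sd_bins: float = 1.0,
    normalization: str = "binwise",
) -> np.ndarray:
    """Population JPSTH over pairs of neurons given their event trains.

    ``pairs`` defaults to all unordered pairs; pairs without normalizable
    variance are skipped.  Grouping by modulation label is done by passing
    the relevant pair list.
    """
    tms = [binarize_trials(p, event_frames, n_frames, pre_s, post_s, fs)
           for p in peak_frames_list]
    if pairs is None:
        pairs = list(combinations(range(len(tms)), 2))
    mats = []
    for i, j in pairs:
        try:
            mats.append(pair_jpsth(tms[i], tms[j], smooth_sd_bins, normalization))
        except ZeroDivisionError:
            continue
    return population_jpsth(mats)


def diagonal_analysis(
    peak_frames_list,
    event_frames: np.ndarray,
    n_frames: int,
    pairs=None,
    pre_s: float = 2.5,
    post_s: float = 2.5,
    fs: float = 15.0,
    far_shift_s: float = 20.0,
    baseline_window_s: float = 10.0,
    baseline_peak_s: float = 0.5,
    post_peak_s: float = 1.5,
    seed: int = 0,
    normalization: str = "binwise",
) -> DiagonalStats:
    """Population-JPSTH diagonal versus a far-removed baseline band.

    The baseline recomputes the population JPSTH around sham events — the
    real event times circularly displaced by a random shift of at least
    ``far_shift_s`` — over a ``baseline_window_s`` diagonal, and takes the
    mean and SD of that diagonal.  With the default bin-wise normalization
    both diagonals are in correlation-coefficient units with a
    rate-independent noise scale, so the band is directly comparable with
    event-locked values.  From the real diagonal, the baseline-window peak
    is the maximum in the 0.5 s before onset and the post peak the maximum
    in the 1.5 s after; per-session peak pairs feed a standard signed-rank
    comparison downstream.
    """
    rng = np.random.default_rng(seed)
    ev = np.asarray(event_frames, int)
    far = frames(far_shift_s, fs)
    if n_frames <= 2 * far:
        raise ValueError("session too short for a far-removed baseline window")
    shift = int(rng.integers(far, n_frames - far))
    sham = (ev + shift) % n_frames

    half_b = baseline_window_s / 2.0
    pop = population_jpsth_from_trains(
        peak_frames_list, ev, n_frames, pairs, pre_s, post_s, fs,
        normalization=normalization)
    sham_pop = population_jpsth_from_trains(
        peak_frames_list, sham, n_frames, pairs, half_b, half_b, fs,
        normalization=normalization)

    diag = np.diag(pop)
    pre_f, post_f = frames(pre_s, fs), frames(post_s, fs)
    lags = np.arange(-pre_f, post_f + 1) / fs
    sham_diag = np.diag(sham_pop)

    pre_peak_w = frames(baseline_peak_s, fs)
    post_peak_w = frames(post_peak_s, fs)
    lags_f = np.arange(-pre_f, post_f + 1)
    base_sel = (lags_f >= -pre_peak_w) & (lags_f < 0)
    post_sel = (lags_f >= 1) & (lags_f <= post_peak_w)
    return DiagonalStats(
        lags_s=lags,
        diagonal=diag,
        baseline_mean=float(sham_diag.mean()),
        baseline_sd=float(sham_diag.std(ddof=1)),
        baseline_peak=float(diag[base_sel].max()),
        post_peak=float(diag[post_sel].max()),
        baseline_shift_s=shift / fs,
    )
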