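"""Fluorescence-trace processing: dF/F extraction, annulus ROIs, Ca2+ event
detection, neuropil subtraction, and transient-decay fitting.

dF/F = (F - F0) / F0 with F0 the minimum over the means of 2 s windows placed
at 1 s steps across the whole recording.  Ca2+ events are local maxima of the
dF/F trace exceeding both 2 SD of the trace and the magnitude of its largest
negative deflection.  An annulus ROI is a ring of pixels with the same area
as its somatic ROI, whose inner radius is the distance from the center of
mass to the farthest ROI border point plus five pixels; annulus traces sample
the local neuropil background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "AnnulusRoi",
    "DffTrace",
    "EventTrain",
    "DecayFit",
    "DecayFitError",
    "make_annulus",
    "extract_trace",
    "compute_dff",
    "subtract_annulus",
    "detect_events",
    "fit_decay",
    "soma_annulus_eta",
]


class DecayFitError(RuntimeError):
    """Exponential-decay fit failed to converge; carries solver diagnostics."""


@dataclass
class AnnulusRoi:
    inner_radius_px: float
    outer_radius_px: float
    rows: np.ndarray
    cols: np.ndarray
    parent_area_px: int

    @property
    def area_px(self) -> int:
        return len(self.rows)


@dataclass
class DffTrace:
    f: np.ndarray
    f0: float
    dff: np.ndarray
    fs: float = 15.0


@dataclass
class EventTrain:
    """Detected Ca2+ transient peaks of one neuron."""

    peak_frames: np.ndarray
    peak_amplitudes: np.ndarray
    detection_sd: float

    @property
    def n_events(self) -> int:
        return len(self.peak_frames)


@dataclass
class DecayFit:
    """Parameters of a * exp(-t / tau) + b fitted from the peak onward."""

    tau_s: float
    a: float
    b: float
    residual: float


def make_annulus(
    mask_rows: np.ndarray,
    mask_cols: np.ndarray,
    image_shape: tuple[int, int],
    gap_px: float = 5.0,
    roi_id=None,
) -> AnnulusRoi:
    """Ring of pixels with the same area as the somatic ROI.

    Inner radius = (max distance from the ROI center of mass to an ROI pixel)
    + ``gap_px``.  The ring consists of the |ROI| pixels nearest the center of
    mass among pixels at distance >= inner radius (ties broken by distance,
    then row-major index), which matches the ROI area exactly; the implied
    outer radius equals sqrt(inner^2 + area/pi) up to rasterization.  Raises
    if the ring would be clipped by the image border.
    """
    rows = np.asarray(mask_rows, int)
    cols = np.asarray(mask_cols, int)
    if len(rows) == 0:
        raise ValueError("footprint mask is empty")
    area = len(rows)
    cy, cx = rows.mean(), cols.mean()
    r_max = np.sqrt((rows - cy) ** 2 + (cols - cx) ** 2).max()
    inner = r_max + gap_px
    outer_analytic = np.sqrt(inner**2 + area / np.pi)

    ny, nx = image_shape
    pad = int(np.ceil(outer_analytic)) + 2
    y0, y1 = int(np.floor(cy)) - pad, int(np.ceil(cy)) + pad + 1
    x0, x1 = int(np.floor(cx)) - pad, int(np.ceil(cx)) + pad + 1
    if y0 < 0 or x0 < 0 or y1 > ny or x1 > nx:
        raise ValueError(f"annulus for ROI {roi_id!r} would be clipped by the image border")

    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2).ravel()
    yy, xx = yy.ravel(), xx.ravel()
    cand = np.flatnonzero(dist >= inner)
    if len(cand) < area:  # pragma: no cover - pad guarantees enough candidates
        raise ValueError(f"annulus for ROI {roi_id!r} would be clipped by the image border")
    order = cand[np.lexsort((xx[cand], yy[cand], dist[cand]))][:area]
    return AnnulusRoi(
        inner_radius_px=float(inner),
        outer_radius_px=float(dist[order].max()),
        rows=yy[order],
        cols=xx[order],
        parent_area_px=area,
    )


def extract_trace(movie: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Per-frame mean fluorescence over the mask pixels."""
    rows = np.asarray(rows, int)
    cols = np.asarray(cols, int)
    if len(rows) == 0:
        raise ValueError("mask is empty")
    ny, nx = movie.shape[1:]
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= ny or cols.max() >= nx:
        raise ValueError("mask extends outside the movie")
    return movie[:, rows, cols].mean(axis=1)


def compute_dff(f: np.ndarray, fs: float = 15.0) -> DffTrace:
    """dF/F with F0 = minimal mean over 2 s windows at 1 s steps.

    Windows of 2 s are placed every 1 s across the recording; a final window
    anchored at the end covers any remainder.  F0 is the smallest window mean;
    dF/F = (F - F0) / F0.
    """
    f = np.asarray(f, float)
    win = int(round(2.0 * fs))
    step = int(round(1.0 * fs))
    if len(f) < win:
        raise ValueError("trace must span at least 2 s")
    starts = list(range(0, len(f) - win + 1, step))
    if starts[-1] != len(f) - win:
        starts.append(len(f) - win)
    means = [f[s : s + win].mean() for s in starts]
    f0 = float(min(means))
    if f0 <= 0:
        raise ValueError("F0 must be positive; raw fluorescence must be positive")
    return DffTrace(f=f, f0=f0, dff=(f - f0) / f0, fs=fs)


def subtract_annulus(soma_raw: np.ndarray, annulus_raw: np.ndarray) -> np.ndarray:
    """Elementwise subtraction of the annulus raw trace from the soma raw trace.

    Used only for the soma/annulus decay-kinetics comparison; somatic dF/F
    for that analysis is computed on the subtracted trace.
    """
    soma_raw = np.asarray(soma_raw, float)
    annulus_raw = np.asarray(annulus_raw, float)
    if soma_raw.shape != annulus_raw.shape:
        raise ValueError("soma and annulus traces must have equal length")
    return soma_raw - annulus_raw


def detect_events(dff: np.ndarray, sd_multiplier: float = 2.0) -> EventTrain:
    """Ca2+ transient peaks: local maxima > 2 SD and > |largest negative deflection|.

    SD is computed over the full-session dF/F trace.  Plateau peaks are
    assigned to their first frame.  A constant trace yields an empty train
    with a warning.
    """
    dff = np.asarray(dff, float)
    sd = float(dff.std())
    if sd == 0:
        warnings.warn("constant trace: no events detectable")
        return EventTrain(np.empty(0, int), np.empty(0), 0.0)
    floor = max(sd_multiplier * sd, abs(float(dff.min())) if dff.min() < 0 else 0.0)
    peaks, props = find_peaks(dff, height=floor, plateau_size=1)
    first = props.get("left_edges", peaks)
    return EventTrain(peak_frames=np.asarray(first, int),
                      peak_amplitudes=dff[first], detection_sd=sd)


def fit_decay(avg: np.ndarray, fs: float = 15.0, window_s: float = 3.0,
              peak_index: int | None = None) -> DecayFit:
    """Least-squares fit of a * exp(-t / tau) + b from the peak onward.

    ``avg`` is an event-triggered average; the fit uses up to ``window_s``
    seconds after its maximum.  ``peak_index`` overrides the peak location
    (useful when the decay must be measured from the triggering event, e.g.
    for annulus averages whose global maximum may sit far from the somatic
    event).  Raises :class:`DecayFitError` on degenerate input or
    non-convergence.
    """
    avg = np.asarray(avg, float)
    ipk = int(np.argmax(avg)) if peak_index is None else int(peak_index)
    seg = avg[ipk : ipk + int(round(window_s * fs)) + 1]
    if len(seg) < int(round(1.0 * fs)):
        raise ValueError("need at least 1 s of samples after the peak")
    if np.ptp(seg) == 0:
        raise DecayFitError("flat segment after peak: decay is undefined")
    t = np.arange(len(seg)) / fs

    def model(t, a, tau, b):
        return a * np.exp(-t / tau) + b

    a0 = seg[0] - seg[-1]
    p0 = (a0 if a0 != 0 else 1.0, 0.5, seg[-1])
    try:
        popt, _ = curve_fit(
            model, t, seg, p0=p0,
            bounds=([-np.inf, 1e-4, -np.inf], [np.inf, 60.0, np.inf]),
            maxfev=10_000)
    except RuntimeError as err:
        raise DecayFitError(f"decay fit did not converge: {err}") from err
    resid = float(np.sqrt(np.mean((model(t, *popt) - seg) ** 2)))
    return DecayFit(tau_s=float(popt[1]), a=float(popt[0]), b=float(popt[2]),
                    residual=resid)


def soma_annulus_eta(
    soma_dff: np.ndarray,
    annulus_dff: np.ndarray,
    peak_frames: np.ndarray,
    fs: float = 15.0,
    pre_s: float = 1.0,
    post_s: float = 3.0,
):
    """Average soma and annulus signals around the somatic Ca2+ peaks.

    Both signals are averaged in a [-pre_s, +post_s] window around each
    somatic peak (peaks whose window crosses the session edges are dropped);
    the two averages share the time base and feed :func:`fit_decay` per
    soma-annulus pair.  Returns ``(lags_s, soma_eta, annulus_eta, n_used)``.
    """
    soma_dff = np.asarray(soma_dff, float)
    annulus_dff = np.asarray(annulus_dff, float)
    if soma_dff.shape != annulus_dff.shape:
        raise ValueError("soma and annulus traces must have equal length")
    peaks = np.asarray(peak_frames, int)
    pre = int(round(pre_s * fs))
    post = int(round(post_s * fs))
    ok = peaks[(peaks - pre >= 0) & (peaks + post < len(soma_dff))]
    if len(ok) == 0:
        raise ValueError("no somatic events with a full averaging window")
    idx = ok[:, None] + np.arange(-pre, post + 1)[None, :]
    lags = np.arange(-pre, post + 1) / fs
    return lags, soma_dff[idx].mean(axis=0), annulus_dff[idx].mean(axis=0), len(ok)
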