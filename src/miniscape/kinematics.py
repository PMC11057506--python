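"""Head-accelerometer kinematics: total body acceleration, movement segmentation,
and acceleration-change amplitude classification.

Total body acceleration (BA) is the Euclidean norm of the three head-accelerometer
axes (anteroposterior, mediolateral, dorsoventral), in units of g.  In a freely
moving mouse its distribution is bimodal — a rest mode and a movement mode — and
the movement/rest threshold is the midpoint between the two histogram peaks.
Frames with BA above the threshold are movement frames; contiguous runs of
movement frames form movement bouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AccelerometerRecord",
    "MovementBouts",
    "AccelChangeEvent",
    "BimodalityError",
    "total_body_acceleration",
    "find_movement_threshold",
    "segment_movement",
    "classify_accel_change",
    "resample_to_frames",
]


class BimodalityError(ValueError):
    """Raised when a BA histogram does not show two separable peaks.

    Mirrors the manual fallback in practice: the caller may then supply a
    threshold by hand.
    """


@dataclass
class AccelerometerRecord:
    """3-axis head acceleration in g at a fixed sampling rate."""

    t: np.ndarray  # seconds
    ap: np.ndarray  # anteroposterior, g
    ml: np.ndarray  # mediolateral, g
    dv: np.ndarray  # dorsoventral, g
    fs: float  # samples / s

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.ap) == len(self.ml) == len(self.dv) == n):
            raise ValueError("all axes must have the same length as t")

    @property
    def ba(self) -> np.ndarray:
        """Total body acceleration, the per-sample Euclidean norm of the axes."""
        return total_body_acceleration(self.ap, self.ml, self.dv)


@dataclass
class MovementBouts:
    """Contiguous supra-threshold runs of the BA trace."""

    onsets: np.ndarray  # frame index of first movement frame per bout
    offsets: np.ndarray  # frame index of last movement frame per bout
    threshold: float  # g
    is_movement: np.ndarray  # per-frame state, True = movement

    def __post_init__(self) -> None:
        if len(self.onsets) != len(self.offsets):
            raise ValueError("onsets and offsets must pair up")
        if np.any(self.offsets < self.onsets):
            raise ValueError("every onset must precede its offset")

    @property
    def n_bouts(self) -> int:
        return len(self.onsets)

    def rest_intervals(self) -> np.ndarray:
        """(start, stop) frame pairs of rest periods *between* bouts.

        Only rests that follow a movement offset are returned; the leading
        rest (before the first bout) has no preceding movement termination.
        """
        if self.n_bouts == 0:
            return np.empty((0, 2), dtype=int)
        starts = self.offsets[:-1] + 1
        stops = self.onsets[1:] - 1
        tail_start = self.offsets[-1] + 1
        tail_stop = len(self.is_movement) - 1
        pairs = list(zip(starts, stops))
        if tail_start <= tail_stop:
            pairs.append((tail_start, tail_stop))
        out = np.array(pairs, dtype=int).reshape(-1, 2)
        return out[out[:, 1] >= out[:, 0]]


@dataclass
class AccelChangeEvent:
    """A movement (or cue) onset tagged by its acceleration-change amplitude."""

    onset: int  # frame
    amplitude: float  # g: max BA in the 2 s post window minus BA at onset
    quartile: int = 0  # 1 (small) .. 4 (large); 0 = unassigned


def total_body_acceleration(ap: np.ndarray, ml: np.ndarray, dv: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm of the three acceleration axes, in g."""
    ap, ml, dv = np.asarray(ap, float), np.asarray(ml, float), np.asarray(dv, float)
    if not (ap.shape == ml.shape == dv.shape):
        raise ValueError("axis traces must have matching shapes")
    return np.sqrt(ap**2 + ml**2 + dv**2)


def resample_to_frames(x: np.ndarray, fs_in: float, fs_out: float = 15.0) -> np.ndarray:
    """Block-average a trace sampled at ``fs_in`` down to the imaging clock.

    ``fs_in`` must be an integer multiple of ``fs_out``; a trailing partial
    block is dropped.  All downstream windows are defined in imaging frames,
    so accelerometer traces are brought to the frame clock before thresholding.
    """
    ratio = fs_in / fs_out
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError("fs_in must be an integer multiple of fs_out")
    if k == 1:
        return np.asarray(x, float).copy()
    n = (len(x) // k) * k
    return np.asarray(x[:n], float).reshape(-1, k).mean(axis=1)


def find_movement_threshold(
    ba: np.ndarray,
    n_bins: int = 100,
    smooth_bins: int = 5,
    min_separation_bins: int = 5,
) -> tuple[float, dict]:
    """Midpoint between the two dominant peaks of the BA histogram.

    The histogram uses ``n_bins`` over the observed range, smoothed with a
    moving average of ``smooth_bins`` bins; peaks are the two highest local
    maxima separated by at least ``min_separation_bins`` bins.  Returns the
    threshold in g and an audit dict with the histogram, bin centers and the
    two peak locations.

    Raises
    ------
    BimodalityError
        If fewer than two acceptable peaks are found; the caller may then set
        the threshold manually.
    """
    ba = np.asarray(ba, float)
    counts, edges = np.histogram(ba, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(smooth_bins) / smooth_bins
    smooth = np.convolve(counts, kernel, mode="same")

    # local maxima (plateaus count once, at their first bin)
    interior = (smooth[1:-1] > smooth[:-2]) & (smooth[1:-1] >= smooth[2:])
    peak_idx = np.flatnonzero(interior) + 1
    if len(peak_idx) < 2:
        raise BimodalityError("BA histogram does not show two peaks")

    # two highest maxima with sufficient separation
    order = peak_idx[np.argsort(smooth[peak_idx])[::-1]]
    first = order[0]
    second = next((i for i in order[1:] if abs(i - first) >= min_separation_bins), None)
    if second is None:
        raise BimodalityError(
            "BA histogram peaks are not separated by at least "
            f"{min_separation_bins} bins"
        )
    lo, hi = sorted((first, second))
    # a genuine bimodal distribution has a clear valley between the modes
    valley = smooth[lo : hi + 1].min()
    if valley > 0.5 * min(smooth[lo], smooth[hi]):
        raise BimodalityError("no clear valley between candidate peaks")
    threshold = 0.5 * (centers[lo] + centers[hi])
    audit = {
        "counts": counts,
        "smoothed": smooth,
        "centers": centers,
        "peak_bins": (lo, hi),
        "peak_values_g": (centers[lo], centers[hi]),
    }
    return float(threshold), audit


def segment_movement(ba: np.ndarray, threshold: float) -> MovementBouts:
    """Segment the BA trace into movement bouts at a fixed threshold.

    A frame is a movement frame iff BA > threshold; each maximal run of
    movement frames is one bout (onset = first frame, offset = last frame).
    Minimum bout length is one frame.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ba = np.asarray(ba, float)
    moving = ba > threshold
    padded = np.concatenate(([False], moving, [False]))
    d = np.diff(padded.astype(np.int8))
    onsets = np.flatnonzero(d == 1)
    offsets = np.flatnonzero(d == -1) - 1
    return MovementBouts(onsets=onsets, offsets=offsets, threshold=float(threshold),
                         is_movement=moving)


def classify_accel_change(
    ba: np.ndarray,
    onsets: np.ndarray,
    fs: float = 15.0,
    window_s: float = 2.0,
) -> list[AccelChangeEvent]:
    """Amplitude of acceleration change after each onset, split into quartiles.

    Amplitude = max BA within ``window_s`` after the onset minus BA at the
    onset.  Quartile boundaries are the empirical quartiles of the amplitudes
    in this session; boundary ties go to the lower quartile.  Quartile 1 is
    "small", quartile 4 "large".  Onsets whose window runs past the end of the
    session are dropped with a warning.  The same procedure applies to cue
    onsets.
    """
    ba = np.asarray(ba, float)
    onsets = np.asarray(onsets, int)
    w = int(round(window_s * fs))
    events: list[AccelChangeEvent] = []
    n_dropped = 0
    for onset in onsets:
        if onset + w >= len(ba):
            n_dropped += 1
            continue
        amp = float(ba[onset : onset + w + 1].max() - ba[onset])
        events.append(AccelChangeEvent(onset=int(onset), amplitude=amp))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} onset(s) whose 2 s window exceeded the session")
    if len(events) < 4:
        raise ValueError("need at least 4 usable onsets to assign quartiles")
    amps = np.array([e.amplitude for e in events])
    q1, q2, q3 = np.quantile(amps, [0.25, 0.5, 0.75])
    for e in events:
        # strict '>' sends boundary values to the lower quartile
        e.quartile = 1 + int(e.amplitude > q1) + int(e.amplitude > q2) + int(e.amplitude > q3)
    return events
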