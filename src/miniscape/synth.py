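"""Synthetic sessions with the statistical structure the analysis assumes.

Generates, with known ground truth: bimodal head-acceleration traces with
movement bouts; sparse GCaMP6f-like transient trains (1-frame rise,
exponential decay) whose rates are positively or negatively modulated after
behavioral events; 42-trial conditioning sessions with pseudo-random 10 s
CS+/CS- cues; spatial footprints on a 600 x 900 um field; small synthetic
movie patches with spatially correlated neuropil background; and trace
ensembles with a prescribed pairwise correlation-vs-distance profile.

All generators are deterministic under a fixed seed.  Defaults are the study
conditions: 15 frames/s imaging, 30 min sessions, rest/movement acceleration
modes at 0.02/0.10 g, sparse transients at 0.05 Hz with tau = 0.6 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

__all__ = [
    "SynthParams",
    "GroundTruth",
    "Footprints",
    "generate_kinematics",
    "draw_recruitment",
    "generate_traces",
    "generate_conditioning_session",
    "generate_footprints",
    "generate_movie_patch",
    "generate_correlated_traces",
]


@dataclass
class SynthParams:
    """Parameters of a synthetic imaging session.

    Rates are in Hz, times in seconds, amplitudes in dF/F units,
    accelerations in g, spatial quantities in micrometers.
    """

    seed: int = 0
    duration_s: float = 1800.0
    fs: float = 15.0
    n_neurons: int = 100
    frac_responsive: float = 0.3
    frac_negative: float = 0.0
    base_rate_hz: float = 0.05
    gain_pos: float = 4.0  # multiplicative rate gain in the post-event window
    gain_neg: float = 0.2  # rate suppression factor for negative modulation
    response_window_s: float = 1.0
    tau_s: float = 0.6  # GCaMP6f-like decay constant
    amp_mean: float = 1.0
    amp_sd: float = 0.2
    noise_sd: float = 0.1
    fov_um: tuple[float, float] = (600.0, 900.0)
    pixel_um: float = 1.2
    neuropil_corr_len_um: float = 200.0
    shared_coactivation_p: float = 0.0
    # kinematics mixture
    rest_mode_g: float = 0.02
    move_mode_g: float = 0.10
    rest_sd_g: float = 0.008
    move_sd_g: float = 0.015
    bout_dur_mean_s: float = 2.5
    rest_dur_mean_s: float = 8.0

    def __post_init__(self) -> None:
        for name in ("frac_responsive", "frac_negative", "shared_coactivation_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("fs", "base_rate_hz", "tau_s", "amp_mean", "pixel_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("noise_sd", "amp_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        n_frames = self.duration_s * self.fs
        if abs(n_frames - round(n_frames)) > 1e-6:
            raise ValueError("fs * duration_s must be an integer frame count")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fs))

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Deterministic per-stream generator fanned out from the session seed."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests."""

    responsive_ids: dict = field(default_factory=dict)  # event type -> array of ids
    modulation_sign: dict = field(default_factory=dict)  # neuron id -> +1 / -1
    spike_frames: list | None = None
    spike_amps: list | None = None
    bouts: np.ndarray | None = None  # (n_bouts, 2) onset/offset frames
    tau_s: float | None = None
    coupled_trials: np.ndarray | None = None  # trial indices carrying shared spikes
    target_correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        for sign in self.modulation_sign.values():
            if sign not in (+1, -1):
                raise ValueError("modulation signs must be +1 or -1")


@dataclass
class Footprints:
    """ROI centroids and pixel masks on a discretized field of view."""

    centroids_um: np.ndarray  # (n, 2) = (x, y)
    masks: list  # per ROI: (rows, cols) pixel index arrays
    shape_px: tuple[int, int]  # (ny, nx)
    pixel_um: float

    def distances_um(self) -> np.ndarray:
        """Pairwise Euclidean centroid distances, um."""
        d = self.centroids_um[:, None, :] - self.centroids_um[None, :, :]
        return np.sqrt((d**2).sum(axis=-1))


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def generate_kinematics(
    params: SynthParams,
    n_bouts: int | None = None,
    bout_dur_s: float | None = None,
    rng: np.random.Generator | None = None,
):
    """Bimodal total-body-acceleration trace with known movement bouts.

    BA is drawn per frame from a two-mode truncated-Gaussian mixture: rest
    frames around ``rest_mode_g`` and movement frames around ``move_mode_g``,
    with each component truncated away from the midpoint so the two modes are
    cleanly separable (the regime in which a histogram-midpoint threshold is
    well defined).  The norm is generated first and then distributed to three
    axes by per-frame random unit vectors, so the per-sample Euclidean norm of
    the emitted axes equals the generated BA exactly.

    Returns an :class:`~miniscape.kinematics.AccelerometerRecord` and the
    ground-truth bout array of (onset, offset) frame pairs.
    """
    from .kinematics import AccelerometerRecord

    if params.duration_s < 60:
        raise ValueError("session must last at least 60 s")
    sep = params.move_mode_g - params.rest_mode_g
    if sep <= 0:
        raise ValueError("movement mode must exceed rest mode (positive separation)")
    if rng is None:
        rng = params.rng(stream=1)
    n = params.n_frames
    fs = params.fs

    # alternating rest / bout schedule, in frames
    bouts: list[tuple[int, int]] = []
    if n_bouts is None or n_bouts > 0:
        t = 0
        while True:
            rest = max(int(round(3.0 * fs)),
                       int(round(rng.exponential(params.rest_dur_mean_s) * fs)))
            dur_s = bout_dur_s if bout_dur_s is not None else max(
                0.5, rng.exponential(params.bout_dur_mean_s))
            dur = max(1, int(round(dur_s * fs)))
            onset = t + rest
            offset = onset + dur - 1
            if offset >= n - int(3.0 * fs):
                break
            bouts.append((onset, offset))
            t = offset + 1
            if n_bouts is not None and len(bouts) == n_bouts:
                break
        if n_bouts is not None and len(bouts) < n_bouts:
            raise ValueError("session too short for the requested number of bouts")

    state = np.zeros(n, dtype=bool)
    for onset, offset in bouts:
        state[onset : offset + 1] = True

    rest_hi = params.rest_mode_g + 0.3 * sep
    move_lo = params.move_mode_g - 0.3 * sep
    ba = np.empty(n)
    n_rest = int((~state).sum())
    n_move = int(state.sum())
    ba[~state] = np.clip(
        rng.normal(params.rest_mode_g, params.rest_sd_g, n_rest), 1e-4, rest_hi)
    ba[state] = np.clip(
        rng.normal(params.move_mode_g, params.move_sd_g, n_move), move_lo, None)

    # distribute the norm onto 3 axes via random unit vectors
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    axes = v * ba[:, None]
    t_s = np.arange(n) / fs
    rec = AccelerometerRecord(t=t_s, ap=axes[:, 0], ml=axes[:, 1], dv=axes[:, 2], fs=fs)
    return rec, np.array(bouts, dtype=int).reshape(-1, 2)


def generate_event_times(
    params: SynthParams,
    n_events: int,
    min_gap_s: float = 8.0,
    margin_s: float = 7.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Aperiodic behavioral event frames with a minimum inter-event gap.

    Draws candidate frames uniformly and keeps the first ``n_events`` that
    respect ``min_gap_s``; aperiodicity matters because circular-shift
    controls assume no fixed phase relation between events.
    """
    if rng is None:
        rng = params.rng(stream=7)
    T = params.n_frames
    margin = int(round(margin_s * params.fs))
    gap = int(round(min_gap_s * params.fs))
    if n_events * gap >= T - 2 * margin:
        raise ValueError("session too short for the requested event schedule")
    for _ in range(100):
        t = np.sort(rng.integers(margin, T - margin, size=4 * n_events))
        keep = [int(t[0])]
        for x in t[1:]:
            if x - keep[-1] >= gap:
                keep.append(int(x))
            if len(keep) == n_events:
                return np.array(keep)
    raise RuntimeError("could not place events with the requested spacing")


# ---------------------------------------------------------------------------
# transient trains and traces
# ---------------------------------------------------------------------------

def draw_recruitment(
    params: SynthParams,
    rng: np.random.Generator | None = None,
    event_type: str = "event",
) -> GroundTruth:
    """Draw which neurons respond to an event type and with what sign.

    ``frac_responsive`` of the population is responsive; ``frac_negative`` of
    those are negatively modulated (rate suppression).  Draws are independent
    across calls, emulating stochastic session-to-session recruitment.
    """
    if rng is None:
        rng = params.rng(stream=2)
    n_resp = int(round(params.frac_responsive * params.n_neurons))
    ids = rng.choice(params.n_neurons, size=n_resp, replace=False)
    n_neg = int(round(params.frac_negative * n_resp))
    neg = set(rng.choice(ids, size=n_neg, replace=False).tolist()) if n_neg else set()
    signs = {int(i): (-1 if int(i) in neg else +1) for i in ids}
    return GroundTruth(responsive_ids={event_type: np.sort(ids)},
                       modulation_sign=signs, tau_s=params.tau_s)


def _transient_kernel(params: SynthParams) -> np.ndarray:
    """Instantaneous-rise, exp(-t/tau)-decay kernel sampled at the frame clock."""
    n_k = max(2, int(np.ceil(6.0 * params.tau_s * params.fs)))
    t = np.arange(n_k) / params.fs
    return np.exp(-t / params.tau_s)


def generate_traces(
    params: SynthParams,
    event_frames: np.ndarray | None,
    ground_truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
    coupled_trial_mask: np.ndarray | None = None,
    event_type: str = "event",
):
    """Inhomogeneous-Poisson transient trains convolved with a decay kernel.

    Each neuron emits a Bernoulli-thinned Poisson train at ``base_rate_hz``;
    responsive neurons multiply their rate by ``gain_pos`` (or ``gain_neg``
    for negative modulation) in the ``response_window_s`` window after each
    event.  Transients have amplitude ~ N(amp_mean, amp_sd) (clipped positive),
    a 1-frame rise and exp(-t/tau) decay; Gaussian noise of SD ``noise_sd`` is
    added to the trace.

    With ``shared_coactivation_p`` > 0, each event (optionally restricted by
    ``coupled_trial_mask``) carries, with that probability, one synchronized
    extra transient at a common random latency in all positively responsive
    neurons — zero-lag trial-by-trial coupling on top of the common rate
    modulation.  The decay kernel is truncated at 6 tau (tail below
    exp(-6) of the amplitude).

    Returns ``(traces, ground_truth)`` where traces is (n_neurons, n_frames)
    and the ground truth carries the injected spike frames, amplitudes and
    coupled-trial indices.
    """
    if rng is None:
        rng = params.rng(stream=3)
    n, T = params.n_neurons, params.n_frames
    fs = params.fs
    w = int(round(params.response_window_s * fs))
    if event_frames is None:
        event_frames = np.empty(0, dtype=int)
    event_frames = np.asarray(event_frames, int)
    if len(event_frames) and (event_frames.min() < 0 or event_frames.max() >= T):
        raise ValueError("event times must lie within the session")

    if ground_truth is None:
        ground_truth = draw_recruitment(params, rng=rng, event_type=event_type)
    resp = ground_truth.responsive_ids.get(event_type, np.empty(0, int))
    signs = ground_truth.modulation_sign
    if any(signs.get(int(i), +1) > 0 for i in resp) and params.gain_pos <= 1:
        raise ValueError("gain_pos must exceed 1 when positive responders are requested")
    if any(signs.get(int(i), +1) < 0 for i in resp) and not (0 <= params.gain_neg < 1):
        raise ValueError("gain_neg must lie in [0, 1) when negative responders are requested")

    # per-frame response-window mask: frames onset+1 .. onset+w
    post = np.zeros(T, dtype=bool)
    for e in event_frames:
        post[e + 1 : min(e + w + 1, T)] = True

    p_base = params.base_rate_hz / fs
    kernel = _transient_kernel(params)
    traces = np.empty((n, T))
    spike_frames: list[np.ndarray] = []
    spike_amps: list[np.ndarray] = []
    resp_set = set(int(i) for i in resp)

    # shared zero-lag coactivation draws (one latency per coupled trial)
    coupled: list[int] = []
    shared_lat: dict[int, int] = {}
    if params.shared_coactivation_p > 0 and len(event_frames):
        for j, e in enumerate(event_frames):
            if coupled_trial_mask is not None and not coupled_trial_mask[j]:
                continue
            if rng.random() < params.shared_coactivation_p:
                coupled.append(j)
                shared_lat[j] = int(rng.integers(1, w + 1))

    for i in range(n):
        rate = np.full(T, p_base)
        if i in resp_set:
            gain = params.gain_pos if signs.get(i, +1) > 0 else params.gain_neg
            rate[post] = p_base * gain
        spikes = rng.random(T) < rate
        frames = np.flatnonzero(spikes)
        amps = np.clip(rng.normal(params.amp_mean, params.amp_sd, len(frames)),
                       0.05 * params.amp_mean, None)
        if i in resp_set and signs.get(i, +1) > 0 and shared_lat:
            extra = np.array([event_frames[j] + lat for j, lat in shared_lat.items()],
                             dtype=int)
            extra = extra[extra < T]
            extra_amp = np.clip(rng.normal(params.amp_mean, params.amp_sd, len(extra)),
                                0.05 * params.amp_mean, None)
            frames = np.concatenate([frames, extra])
            amps = np.concatenate([amps, extra_amp])
            order = np.argsort(frames)
            frames, amps = frames[order], amps[order]
        impulse = np.zeros(T)
        np.add.at(impulse, frames, amps)
        sig = np.convolve(impulse, kernel)[:T]
        if params.noise_sd > 0:
            sig = sig + rng.normal(0.0, params.noise_sd, T)
        traces[i] = sig
        spike_frames.append(frames)
        spike_amps.append(amps)

    ground_truth.spike_frames = spike_frames
    ground_truth.spike_amps = spike_amps
    ground_truth.tau_s = params.tau_s
    ground_truth.coupled_trials = np.array(coupled, dtype=int)
    return traces, ground_truth


# ---------------------------------------------------------------------------
# conditioning sessions
# ---------------------------------------------------------------------------

def generate_conditioning_session(
    params: SynthParams,
    n_trials: int = 42,
    cue_s: float = 10.0,
    iti_mean_s: float = 30.0,
    reward_latency_s: float = 2.0,
    extinction: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Event table of a conditioning session: pseudo-random CS+/CS- cues.

    ``n_trials`` 10 s cues, balanced CS+/CS-, randomly spaced with mean
    inter-trial interval ``iti_mean_s`` (uniform on [0.5, 1.5] x mean).
    Pseudo-random order = balanced shuffle with at most 3 consecutive
    same-cue trials.  Each CS+ is followed by a reward event at
    ``reward_latency_s`` unless ``extinction`` is set.

    Returns a tidy event table with columns ``type`` (CS+/CS-/reward),
    ``onset_s``, ``onset_frame`` (0-based, floor(t * fs)), ``duration_s``,
    ``trial``, ``rewarded``.
    """
    if rng is None:
        rng = params.rng(stream=4)
    if n_trials % 2:
        raise ValueError("n_trials must be even for a balanced CS+/CS- split")

    labels = np.array(["CS+"] * (n_trials // 2) + ["CS-"] * (n_trials // 2))
    for _ in range(10_000):
        rng.shuffle(labels)
        runs = np.diff(np.flatnonzero(np.concatenate(
            ([True], labels[1:] != labels[:-1], [True]))))
        if runs.max() <= 3:
            break
    else:  # pragma: no cover - balanced shuffles virtually always succeed
        raise RuntimeError("could not draw a cue order with runs <= 3")

    itis = rng.uniform(0.5 * iti_mean_s, 1.5 * iti_mean_s, n_trials)
    onsets = np.cumsum(itis) + np.arange(n_trials) * cue_s
    if onsets[-1] + cue_s >= params.duration_s:
        raise ValueError("session too short for the requested trial schedule")

    rows = []
    for k, (lab, t0) in enumerate(zip(labels, onsets)):
        rewarded = bool(lab == "CS+" and not extinction)
        rows.append({"type": lab, "onset_s": float(t0), "duration_s": cue_s,
                     "trial": k, "rewarded": rewarded})
        if rewarded:
            rows.append({"type": "reward", "onset_s": float(t0 + reward_latency_s),
                         "duration_s": 0.0, "trial": k, "rewarded": True})
    df = pd.DataFrame(rows)
    df["onset_frame"] = np.floor(df["onset_s"] * params.fs).astype(int)
    return df.sort_values("onset_s", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# footprints and movies
# ---------------------------------------------------------------------------

def generate_footprints(
    params: SynthParams,
    radius_um: float = 6.0,
    min_sep_um: float = 15.0,
    margin_um: float | None = None,
    rng: np.random.Generator | None = None,
) -> Footprints:
    """Uniformly placed disc ROIs with a minimum centroid separation.

    Centroids are rejection-sampled over the field (keeping ``margin_um`` from
    the border, default the disc radius); masks are filled discs of
    ``radius_um``.  Raises if the packing is impossible within the attempt
    budget.
    """
    if rng is None:
        rng = params.rng(stream=5)
    w_um, h_um = params.fov_um
    if margin_um is None:
        margin_um = radius_um
    nx = int(round(w_um / params.pixel_um))
    ny = int(round(h_um / params.pixel_um))
    lo = np.array([margin_um, margin_um])
    hi = np.array([w_um - margin_um, h_um - margin_um])
    if np.any(hi <= lo):
        raise ValueError("margin leaves no room in the field of view")

    centroids: list[np.ndarray] = []
    attempts = 0
    max_attempts = 10_000 * max(1, params.n_neurons)
    while len(centroids) < params.n_neurons:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"cannot place {params.n_neurons} ROIs with min separation {min_sep_um} um")
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - p) >= min_sep_um for p in centroids):
            centroids.append(c)
    cents = np.array(centroids)

    r_px = radius_um / params.pixel_um
    masks = []
    for cx, cy in cents:
        px, py = cx / params.pixel_um, cy / params.pixel_um
        x0, x1 = int(np.floor(px - r_px)) - 1, int(np.ceil(px + r_px)) + 2
        y0, y1 = int(np.floor(py - r_px)) - 1, int(np.ceil(py + r_px)) + 2
        yy, xx = np.mgrid[max(0, y0) : min(ny, y1), max(0, x0) : min(nx, x1)]
        inside = (xx - px) ** 2 + (yy - py) ** 2 <= r_px**2
        masks.append((yy[inside].ravel(), xx[inside].ravel()))
    return Footprints(centroids_um=cents, masks=masks, shape_px=(ny, nx),
                      pixel_um=params.pixel_um)


def generate_movie_patch(
    footprints: Footprints,
    traces: np.ndarray,
    params: SynthParams,
    bg_amplitude: float = 1.0,
    bg_tau_s: float = 2.0,
    shot_noise_sd: float = 0.02,
    n_bg_components: int = 10,
    activity_coupling: float = 0.0,
    spike_frames: list | None = None,
    rng: np.random.Generator | None = None,
):
    """Small synthetic movie: somatic sources + correlated neuropil background.

    Pixel value = sum of footprint x trace, plus a low-rank spatially
    correlated background field (Gaussian-smoothed white-noise maps with
    correlation length ``neuropil_corr_len_um``, slow smooth time courses of
    characteristic time ``bg_tau_s``), plus white shot noise.  The background
    kinetics are deliberately slower and smoother than somatic transients.

    ``activity_coupling`` in [0, 1] mixes into every background time course a
    slow-filtered copy of the summed somatic spike train — emulating neuropil
    that reflects out-of-focus population activity, so that annulus signals
    triggered on somatic events show slower decay kinetics than the somata.

    Returns ``(movie, background)`` as (T, ny, nx) float32 arrays.
    """
    if rng is None:
        rng = params.rng(stream=6)
    ny, nx = footprints.shape_px
    if max(ny, nx) > 256:
        raise ValueError("movie patch is limited to 256 x 256 px; use a coarser grid")
    T = traces.shape[1]

    movie = np.zeros((T, ny, nx), dtype=np.float32)
    for (rows, cols), tr in zip(footprints.masks, traces):
        movie[:, rows, cols] += tr[:, None].astype(np.float32)

    background = np.zeros_like(movie)
    if bg_amplitude > 0 and n_bg_components > 0:
        sigma_px = params.neuropil_corr_len_um / (2.0 * footprints.pixel_um)
        drive = None
        if activity_coupling > 0:
            if spike_frames is None:
                raise ValueError("activity_coupling requires spike_frames")
            pop = np.zeros(T)
            for fr in spike_frames:
                np.add.at(pop, np.asarray(fr, int), 1.0)
            k = np.exp(-np.arange(int(6 * bg_tau_s * params.fs)) / (bg_tau_s * params.fs))
            drive = np.convolve(pop, k)[:T]
            drive = (drive - drive.mean()) / (drive.std() + 1e-12)
        c = float(activity_coupling)
        amp = bg_amplitude / np.sqrt(n_bg_components)
        smaps = np.empty((n_bg_components, ny * nx), dtype=np.float32)
        gmat = np.empty((T, n_bg_components), dtype=np.float32)
        for k in range(n_bg_components):
            smap = gaussian_filter(rng.standard_normal((ny, nx)), sigma_px)
            smaps[k] = (smap / (smap.std() + 1e-12)).ravel()
            g = gaussian_filter1d(rng.standard_normal(T), bg_tau_s * params.fs)
            g /= g.std() + 1e-12
            if drive is not None:
                g = np.sqrt(c) * drive + np.sqrt(1 - c) * g
            gmat[:, k] = amp * g
        background = (gmat @ smaps).reshape(T, ny, nx)
        movie += background
    if shot_noise_sd > 0:
        movie += shot_noise_sd * rng.standard_normal(movie.shape, dtype=np.float32)
    return movie, background


# ---------------------------------------------------------------------------
# prescribed correlation-vs-distance trace ensembles
# ---------------------------------------------------------------------------

def generate_correlated_traces(
    centroids_um: np.ndarray,
    corr_fn,
    n_frames: int,
    rng: np.random.Generator,
):
    """Gaussian traces whose pairwise correlation follows ``corr_fn(distance)``.

    The target matrix C_ij = corr_fn(d_ij) (unit diagonal) is projected to the
    nearest positive-semidefinite matrix by eigenvalue clipping and
    re-standardized to unit diagonal; traces are drawn as A z with A the
    matrix square root.  Returns ``(traces, realized_corr)`` where
    ``realized_corr`` is the population (not sample) correlation actually
    injected after the PSD projection — the ground truth for recovery tests.
    """
    c = np.asarray(centroids_um, float)
    d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=-1))
    C = np.asarray(corr_fn(d), float)
    np.fill_diagonal(C, 1.0)
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 1e-10, None)
    A = V * np.sqrt(w)
    Cpsd = A @ A.T
    scale = np.sqrt(np.diag(Cpsd))
    A /= scale[:, None]
    realized = Cpsd / np.outer(scale, scale)
    traces = A @ rng.standard_normal((len(c), n_frames))
    return traces, realized
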