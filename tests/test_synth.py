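"""Ground-truth fidelity and determinism of the synthetic-session generators."""

import numpy as np
import pytest
from scipy import stats

from miniscape import kinematics as kin
from miniscape import synth


class TestParams:
    @pytest.mark.parametrize("bad", [
        {"frac_responsive": 1.2}, {"frac_negative": -0.1},
        {"base_rate_hz": 0.0}, {"tau_s": -1.0},
        {"duration_s": 100.03},  # non-integer frame count
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            synth.SynthParams(**bad)

    def test_seed_fanout_is_deterministic(self):
        p = synth.SynthParams(seed=3)
        assert p.rng(1).integers(1 << 30) == p.rng(1).integers(1 << 30)
        assert p.rng(1).integers(1 << 30) != p.rng(2).integers(1 << 30)


class TestKinematicsGenerator:
    def test_deterministic_under_seed(self):
        p = synth.SynthParams(seed=9, duration_s=120.0, n_neurons=1)
        r1, b1 = synth.generate_kinematics(p)
        r2, b2 = synth.generate_kinematics(p)
        np.testing.assert_array_equal(r1.ap, r2.ap)
        np.testing.assert_array_equal(b1, b2)

    def test_histogram_has_two_modes_near_targets(self):
        p = synth.SynthParams(seed=10, duration_s=900.0, n_neurons=1)
        rec, _ = synth.generate_kinematics(p)
        _, audit = kin.find_movement_threshold(rec.ba)
        lo, hi = audit["peak_values_g"]
        assert abs(lo - 0.02) < 0.01 and abs(hi - 0.10) < 0.01

    def test_zero_bouts_gives_unimodal_rest(self):
        p = synth.SynthParams(seed=11, duration_s=120.0, n_neurons=1)
        rec, bouts = synth.generate_kinematics(p, n_bouts=0)
        assert len(bouts) == 0
        assert kin.segment_movement(rec.ba, 0.06).n_bouts == 0
        with pytest.raises(kin.BimodalityError):
            kin.find_movement_threshold(rec.ba)

    def test_nonpositive_separation_rejected(self):
        p = synth.SynthParams(seed=1, duration_s=120.0, n_neurons=1,
                              rest_mode_g=0.1, move_mode_g=0.1)
        with pytest.raises(ValueError, match="separation"):
            synth.generate_kinematics(p)


class TestTraceGenerator:
    def test_noiseless_trace_is_sum_of_decay_kernels(self):
        p = synth.SynthParams(seed=12, duration_s=120.0, n_neurons=1,
                              frac_responsive=0.0, noise_sd=0.0, tau_s=0.6,
                              base_rate_hz=0.05)
        traces, gt = synth.generate_traces(p, None, synth.GroundTruth())
        frames, amps = gt.spike_frames[0], gt.spike_amps[0]
        assert len(frames) > 0
        t = np.arange(p.n_frames)
        expected = np.zeros(p.n_frames)
        n_k = int(np.ceil(6 * p.tau_s * p.fs))  # documented kernel truncation
        for f, a in zip(frames, amps):
            stop = min(f + n_k, p.n_frames)
            expected[f:stop] += a * np.exp(-((t[f:stop] - f) / p.fs) / p.tau_s)
        np.testing.assert_allclose(traces[0], expected, atol=1e-9)
        # within the kernel support the first transient is exactly analytic
        f0, a0 = frames[0], amps[0]
        if len(frames) > 1:
            span = min(frames[1] - f0, n_k)
        else:
            span = n_k
        seg = traces[0][f0 : f0 + span]
        np.testing.assert_allclose(
            seg, a0 * np.exp(-(np.arange(span) / p.fs) / p.tau_s), atol=1e-9)

    def test_transient_counts_are_poisson(self):
        # 0.05 Hz x 1800 s = 90 expected transients per neuron
        p = synth.SynthParams(seed=13, duration_s=1800.0, n_neurons=100,
                              frac_responsive=0.0, noise_sd=0.0)
        _, gt = synth.generate_traces(p, None, synth.GroundTruth())
        counts = np.array([len(f) for f in gt.spike_frames])
        lam = 0.05 * 1800
        assert abs(counts.mean() - lam) < 3 * np.sqrt(lam / 100)
        # chi-square goodness of dispersion across 100 neurons
        chi2 = np.sum((counts - lam) ** 2 / lam)
        assert stats.chi2.sf(chi2, df=100) > 0.01

    def test_gain_multiplies_post_event_rate(self):
        p = synth.SynthParams(seed=14, duration_s=1800.0, n_neurons=40,
                              frac_responsive=1.0, gain_pos=4.0,
                              base_rate_hz=0.2, noise_sd=0.0)
        rng = p.rng(99)
        events = np.sort(rng.choice(np.arange(60, p.n_frames - 60, 60), 100,
                                    replace=False))
        _, gt = synth.generate_traces(p, events, synth.draw_recruitment(p, rng=rng))
        w = 15
        post = pre = 0
        for f in gt.spike_frames:
            for e in events:
                post += np.sum((f > e) & (f <= e + w))
                pre += np.sum((f >= e - w) & (f < e))
        ratio = post / pre
        assert ratio == pytest.approx(4.0, rel=0.25)

    def test_gain_validation(self):
        p = synth.SynthParams(seed=1, duration_s=120.0, n_neurons=4,
                              frac_responsive=0.5, gain_pos=0.9)
        with pytest.raises(ValueError, match="gain_pos"):
            synth.generate_traces(p, np.array([100]), None)
        p2 = synth.SynthParams(seed=1, duration_s=120.0, n_neurons=4,
                               frac_responsive=1.0, frac_negative=1.0,
                               gain_neg=1.5)
        with pytest.raises(ValueError, match="gain_neg"):
            synth.generate_traces(p2, np.array([100]), None)


class TestConditioningSession:
    def test_default_schedule(self):
        p = synth.SynthParams(seed=15, duration_s=2700.0, n_neurons=1)
        ev = synth.generate_conditioning_session(p)
        cues = ev[ev["type"].isin(["CS+", "CS-"])]
        assert len(cues) == 42
        assert (cues["duration_s"] == 10.0).all()
        assert (cues["type"] == "CS+").sum() == 21
        # pseudo-random: at most 3 consecutive same-cue trials
        lab = cues.sort_values("onset_s")["type"].to_numpy()
        runs = np.diff(np.flatnonzero(np.concatenate(
            ([True], lab[1:] != lab[:-1], [True]))))
        assert runs.max() <= 3
        rewards = ev[ev["type"] == "reward"]
        assert len(rewards) == 21

    def test_extinction_has_no_rewards(self):
        p = synth.SynthParams(seed=16, duration_s=2700.0, n_neurons=1)
        ev = synth.generate_conditioning_session(p, extinction=True)
        assert (ev["type"] == "reward").sum() == 0

    def test_seed_reproducibility(self):
        p = synth.SynthParams(seed=17, duration_s=2700.0, n_neurons=1)
        e1 = synth.generate_conditioning_session(p)
        e2 = synth.generate_conditioning_session(p)
        assert e1.equals(e2)

    def test_odd_trial_count_rejected(self):
        p = synth.SynthParams(seed=1, duration_s=2700.0, n_neurons=1)
        with pytest.raises(ValueError):
            synth.generate_conditioning_session(p, n_trials=41)


class TestFootprints:
    def test_min_separation_and_bounds(self):
        p = synth.SynthParams(seed=18, n_neurons=100)
        fp = synth.generate_footprints(p, min_sep_um=15.0)
        d = fp.distances_um()
        iu = np.triu_indices(100, 1)
        assert d[iu].min() >= 15.0
        assert (fp.centroids_um[:, 0] >= 0).all()
        assert (fp.centroids_um[:, 0] <= 600).all()
        assert (fp.centroids_um[:, 1] <= 900).all()

    def test_pair_distance_is_euclidean(self):
        fp = synth.Footprints(centroids_um=np.array([[0.0, 0.0], [300.0, 400.0]]),
                              masks=[], shape_px=(10, 10), pixel_um=1.2)
        assert fp.distances_um()[0, 1] == pytest.approx(500.0)

    def test_impossible_packing_rejected(self):
        p = synth.SynthParams(seed=19, n_neurons=50, fov_um=(30.0, 30.0))
        with pytest.raises(ValueError, match="cannot place"):
            synth.generate_footprints(p, min_sep_um=20.0)


class TestCorrelatedTraces:
    def test_exponential_kernel_realized_exactly(self, rng):
        cents = rng.uniform(0, 500, size=(40, 2))
        _, realized = synth.generate_correlated_traces(
            cents, lambda d: np.exp(-d / 200.0), 100, rng)
        d = np.sqrt(((cents[:, None] - cents[None]) ** 2).sum(-1))
        # exp kernel is PSD, so the projection is a no-op
        np.testing.assert_allclose(realized, np.exp(-d / 200.0), atol=1e-8)

    def test_sample_correlation_approaches_target(self, rng):
        cents = rng.uniform(0, 500, size=(30, 2))
        traces, realized = synth.generate_correlated_traces(
            cents, lambda d: np.exp(-d / 150.0), 20000, rng)
        sample = np.corrcoef(traces)
        iu = np.triu_indices(30, 1)
        assert np.abs(sample[iu] - realized[iu]).max() < 0.08
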