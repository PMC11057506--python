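"""Event-triggered averages, circular-shift bootstrap, modulation labels,
reliability, recruitment, overlap, and outlier flagging."""

import numpy as np
import pytest
from scipy import stats

from miniscape import events as ev
from miniscape import synth
from miniscape.events import _circular_eta_profile


class TestEta:
    def test_impulse_trace_gives_impulse_eta(self):
        trace = np.zeros(1000)
        onsets = np.array([100, 400, 700])
        trace[onsets] = 1.0
        eta = ev.compute_eta(trace, onsets, window_s=5.0)
        assert eta.mean[np.flatnonzero(eta.lags_s == 0)[0]] == 1.0
        assert eta.mean.sum() == pytest.approx(1.0)

    def test_two_events_hand_computed(self):
        trace = np.arange(100.0)
        eta = ev.compute_eta(trace, np.array([40, 60]), window_s=2.0)
        half = ev.frames(1.0)
        np.testing.assert_allclose(eta.mean, np.arange(50 - half, 50 + half + 1.0))

    def test_edge_events_dropped_and_counted(self):
        trace = np.zeros(200)
        eta = ev.compute_eta(trace, np.array([2, 100, 198]), window_s=5.0)
        assert eta.n_events == 1 and eta.n_dropped == 2

    def test_shuffled_events_on_noise_give_flat_eta(self, rng):
        trace = rng.normal(size=20000)
        onsets = rng.integers(100, 19900, 80)
        eta = ev.compute_eta(trace, onsets, window_s=5.0)
        assert np.abs(eta.mean).max() < 4 * eta.sem.max()


class TestPsth:
    def test_all_mass_at_zero_lag(self):
        onsets = np.array([100, 300, 500])
        psth = ev.compute_psth(onsets.copy(), onsets, window_s=5.0)
        i0 = np.flatnonzero(psth.lags_s == 0)[0]
        assert psth.counts[i0] == 3
        assert psth.counts.sum() == 3

    def test_counts_linear_in_trials(self, rng):
        peaks = rng.integers(0, 10000, 300)
        on1 = rng.integers(200, 9800, 25)
        on2 = np.concatenate([on1, on1])
        p1 = ev.compute_psth(peaks, on1, window_s=5.0)
        p2 = ev.compute_psth(peaks, on2, window_s=5.0)
        np.testing.assert_allclose(p2.counts, 2 * p1.counts)
        np.testing.assert_allclose(p2.rate_hz, p1.rate_hz)

    def test_homogeneous_train_is_flat_within_poisson_error(self):
        p = synth.SynthParams(seed=77, duration_s=1800.0, n_neurons=50,
                              frac_responsive=0.0, base_rate_hz=0.5, noise_sd=0.0)
        _, gt = synth.generate_traces(p, None, synth.GroundTruth())
        onsets = np.arange(200, p.n_frames - 200, 500)
        psth = ev.compute_psth(gt.spike_frames, onsets, window_s=5.0)
        lam = psth.counts.mean()
        assert np.abs(psth.counts - lam).max() < 5 * np.sqrt(lam)


class TestBootstrap:
    def test_null_eta_identity_with_explicit_roll(self, rng):
        """The FFT profile window equals the ETA of the rolled trace."""
        trace = rng.normal(size=5000)
        onsets = np.sort(rng.choice(np.arange(50, 4950), 40, replace=False))
        c = _circular_eta_profile(trace, onsets)
        half = ev.frames(2.5)
        lags = np.arange(-half, half + 1)
        for shift in (1, 137, 4999):
            rolled = ev.compute_eta(np.roll(trace, shift), onsets, 5.0).mean
            np.testing.assert_allclose(c[(lags - shift) % 5000], rolled, atol=1e-12)

    def test_strong_responder_is_significant(self):
        p = synth.SynthParams(seed=88, duration_s=1800.0, n_neurons=1,
                              frac_responsive=1.0, gain_pos=4.0, base_rate_hz=0.1)
        rng = p.rng(0)
        onsets = np.sort(rng.choice(np.arange(40, p.n_frames - 40), 100, replace=False))
        traces, _ = synth.generate_traces(p, onsets, synth.draw_recruitment(p, rng=rng),
                                          rng=rng)
        res = ev.bootstrap_significance(traces[0], onsets, n_null=2000, seed=5)
        assert res.significant and res.p_value < 0.05

    def test_determinism_under_seed(self, rng):
        trace = rng.normal(size=4000)
        onsets = rng.integers(100, 3900, 30)
        r1 = ev.bootstrap_significance(trace, onsets, n_null=200, seed=9)
        r2 = ev.bootstrap_significance(trace, onsets, n_null=200, seed=9)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.null_areas, r2.null_areas)

    def test_constant_trace_is_degenerate(self):
        res = ev.bootstrap_significance(np.zeros(2000), np.array([500, 1000]),
                                        n_null=100, seed=1)
        assert res.degenerate and res.p_value == 1.0 and not res.significant

    def test_null_pvalues_roughly_uniform(self):
        """Under the null the p-value distribution should pass a KS test."""
        p = synth.SynthParams(seed=99, duration_s=900.0, n_neurons=120,
                              frac_responsive=0.0, base_rate_hz=0.1)
        rng = p.rng(0)
        onsets = np.sort(rng.choice(np.arange(40, p.n_frames - 40), 60, replace=False))
        traces, _ = synth.generate_traces(p, onsets, synth.GroundTruth(), rng=rng)
        pvals = [ev.bootstrap_significance(t, onsets, n_null=500, seed=i).p_value
                 for i, t in enumerate(traces)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestModulationLabel:
    @staticmethod
    def _eta_from(mean):
        half = len(mean) // 2
        lags = np.arange(-half, len(mean) - half) / 15.0
        return ev.Eta(lags_s=lags, mean=np.asarray(mean, float),
                      sem=np.zeros(len(mean)), n_events=10)

    def test_step_responses(self):
        up = np.concatenate([np.zeros(40), np.ones(40)])
        down = up[::-1].copy()
        assert ev.classify_modulation(self._eta_from(up)) == "positive"
        assert ev.classify_modulation(self._eta_from(down)) == "negative"

    def test_time_reversal_flips_label(self, rng):
        mean = rng.normal(size=81)
        eta = self._eta_from(mean)
        rev = self._eta_from(mean[::-1])
        labels = {ev.classify_modulation(eta), ev.classify_modulation(rev)}
        assert labels == {"positive", "negative"}

    def test_suppressed_responders_labeled_negative(self):
        p = synth.SynthParams(seed=111, duration_s=1800.0, n_neurons=30,
                              frac_responsive=1.0, frac_negative=1.0,
                              gain_neg=0.2, base_rate_hz=0.3, noise_sd=0.05)
        rng = p.rng(0)
        onsets = np.sort(rng.choice(np.arange(40, p.n_frames - 40, 40), 150,
                                    replace=False))
        traces, _ = synth.generate_traces(p, onsets, synth.draw_recruitment(p, rng=rng),
                                          rng=rng)
        labels = [ev.classify_modulation(ev.compute_eta(t, onsets, 5.0))
                  for t in traces]
        assert np.mean([l == "negative" for l in labels]) >= 0.9


class TestReliabilityAndRecruitment:
    def test_reliability_counts_events(self):
        onsets = np.arange(0, 1000, 10)
        peaks = onsets[:50] + 3  # respond to exactly half the events
        assert ev.response_reliability(peaks, onsets) == 0.5
        assert ev.response_reliability(onsets + 2, onsets) == 1.0

    def test_reliability_invariant_to_event_order(self, rng):
        onsets = rng.integers(0, 5000, 40)
        peaks = rng.integers(0, 5000, 200)
        shuffled = rng.permutation(onsets)
        assert (ev.response_reliability(peaks, onsets)
                == ev.response_reliability(peaks, shuffled))

    def test_reliability_matches_binomial_probability(self):
        p = synth.SynthParams(seed=121, duration_s=1800.0, n_neurons=1,
                              frac_responsive=0.0, base_rate_hz=0.001)
        rng = p.rng(0)
        onsets = np.arange(100, p.n_frames - 100, 90)
        q = 0.3
        hit = rng.random(len(onsets)) < q
        peaks = onsets[hit] + rng.integers(1, 15, hit.sum())
        est = ev.response_reliability(peaks, onsets)
        se = np.sqrt(q * (1 - q) / len(onsets))
        assert abs(est - q) < 3 * se

    def test_recruitment_bounds(self):
        onsets = np.array([100, 300])
        silent = [np.array([], int)] * 5
        assert ev.population_recruitment(silent, onsets).max() == 0.0
        active = [onsets + 4 for _ in range(5)]
        np.testing.assert_allclose(ev.population_recruitment(active, onsets), 1.0)

    def test_recruitment_mean_matches_response_probability(self, rng):
        onsets = np.arange(100, 20000, 100)
        q = 0.25
        trains = []
        for _ in range(60):
            hit = rng.random(len(onsets)) < q
            trains.append(onsets[hit] + rng.integers(1, 20, hit.sum()))
        frac = ev.population_recruitment(trains, onsets)
        assert frac.mean() == pytest.approx(q, abs=0.03)


class TestOverlap:
    def test_independence_expectation(self):
        assert ev.expected_overlap_independent(0.22, 0.27) == pytest.approx(0.0594)
        assert round(100 * ev.expected_overlap_independent(0.22, 0.27)) == 6
        assert ev.expected_overlap_independent(0.0, 0.7) == 0.0
        assert ev.expected_overlap_independent(1.0, 1.0) == 1.0
        with pytest.raises(ValueError):
            ev.expected_overlap_independent(1.2, 0.5)

    def test_session_count_profile_sums_to_one(self):
        prof = ev.session_count_profile([0.32, 0.2, 0.1])
        assert prof.sum() == pytest.approx(1.0)
        assert len(prof) == 4
        # two equal sessions reduce to the binomial
        np.testing.assert_allclose(ev.session_count_profile([0.5, 0.5]),
                                   [0.25, 0.5, 0.25])

    def test_session_overlap_fractions(self):
        reg = [(i, i) for i in range(10)]
        a = {i: i < 4 for i in range(10)}
        b = {i: 4 <= i < 6 for i in range(10)}
        out = ev.session_overlap(a, b, reg)
        assert out["both"] == 0.0 and out["a_only"] == 0.4 and out["b_only"] == 0.2
        same = ev.session_overlap(a, a, reg)
        assert same["both"] == 0.4
        with pytest.raises(ValueError):
            ev.session_overlap(a, b, [])


class TestRegistrationFilter:
    def test_joint_criteria(self):
        import pandas as pd

        df = pd.DataFrame({
            "p_same": [0.9, 0.4, 0.9, 0.51],
            "centroid_distance_um": [10.0, 10.0, 14.0, 13.9],
        })
        kept = ev.filter_registration(df)
        assert len(kept) == 2  # row 2 fails the strict 14 um bound
        with pytest.raises(ValueError):
            ev.filter_registration(df[["p_same"]])


class TestSplitHalf:
    def test_deterministic_responder_significant_in_both_halves(self):
        p = synth.SynthParams(seed=131, duration_s=1800.0, n_neurons=1,
                              frac_responsive=1.0, gain_pos=6.0, base_rate_hz=0.1)
        rng = p.rng(0)
        onsets = np.sort(rng.choice(np.arange(40, p.n_frames - 40), 100, replace=False))
        traces, _ = synth.generate_traces(p, onsets, synth.draw_recruitment(p, rng=rng),
                                          rng=rng)
        out = ev.split_half_consistency(traces[0], onsets, "odd_even",
                                        n_null=500, seed=3)
        assert out["both"]

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            ev.split_half_consistency(rng.normal(size=2000), np.arange(5) * 100)


class TestOutliers:
    def test_high_outlier(self):
        vals = list(range(1, 10)) + [100]
        flags = ev.flag_outliers(vals)
        assert flags.sum() == 1 and flags[-1]

    def test_all_equal_and_low_extreme(self):
        assert not ev.flag_outliers([3.0] * 6).any()
        flags = ev.flag_outliers([-50, 1, 2, 3, 4, 5, 6, 7, 8, 9])
        assert flags[0] and flags.sum() == 1

    def test_frame_conversion_constants(self):
        assert ev.frames(1.0) == 15
        assert ev.frames(1.5) == 22
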