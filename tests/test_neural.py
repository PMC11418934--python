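import numpy as np
import pytest

import lidscope as ls
import lidscope.neural as nn

FPS = 20.0


def _kernel(tau=0.4, fps=FPS):
    t = np.arange(int(5 * tau * fps)) / fps
    return np.exp(-t / tau)


class TestDetectEvents:
    def test_planted_transients_localized(self):
        rng = np.random.default_rng(0)
        n = int(600 * FPS)
        tr = rng.normal(0, 0.1, n)
        truth = np.array([1234, 3000, 5000, 7000, 9000, 11000])
        k = _kernel()
        for o in truth:
            tr[o : o + k.size] += 0.5 * k  # amplitude 5x noise sd
        ev = nn.detect_events(tr, FPS)[0]
        for o in truth:
            assert np.min(np.abs(ev - o)) <= 2

    def test_noise_false_positive_rate_below_2_percent_per_second(self):
        rates = []
        for s in range(10):
            tr = np.random.default_rng(s).normal(0, 0.1, int(600 * FPS))
            rates.append(nn.detect_events(tr, FPS)[0].size / 600.0)
        assert np.mean(rates) < 0.02

    def test_flat_trace_yields_no_events(self):
        assert nn.detect_events(np.ones(1000), FPS)[0].size == 0

    def test_rate_invariant_to_trace_rescaling(self):
        rng = np.random.default_rng(1)
        tr = rng.normal(0, 0.1, int(300 * FPS))
        k = _kernel()
        for o in (500, 2000, 4000):
            tr[o : o + k.size] += 0.6 * k
        ev1 = nn.detect_events(tr, FPS)[0]
        ev2 = nn.detect_events(1000.0 * tr, FPS)[0]
        np.testing.assert_array_equal(ev1, ev2)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="tau_decay"):
            nn.EventDetectionParams(tau_decay=-1.0)


class TestEventRates:
    def test_all_moving_rate(self):
        ev = np.arange(0, 1200, 40)  # 30 events in 60 s
        moving = np.ones(1200, bool)
        r = nn.event_rates(ev, moving, FPS)
        assert r["rate_moving"] == pytest.approx(0.5)
        assert np.isnan(r["rate_resting"])

    def test_short_rest_bouts_excluded_exactly(self):
        """Bouts of 400 ms never qualify; a 500 ms bout qualifies exactly."""
        moving = np.ones(1000, bool)
        moving[100:108] = False  # 8 frames = 400 ms
        r = nn.event_rates(np.array([104]), moving, FPS)
        assert np.isnan(r["rate_resting"])
        moving[300:310] = False  # 10 frames = 500 ms
        r2 = nn.event_rates(np.array([305]), moving, FPS)
        assert r2["resting_duration"] == pytest.approx(0.5)
        assert r2["rate_resting"] == pytest.approx(1 / 0.5)

    def test_no_moving_time_flagged(self):
        with pytest.warns(UserWarning, match="no moving time"):
            r = nn.event_rates(np.array([5]), np.zeros(1000, bool), FPS)
        assert np.isnan(r["rate_moving"])

    def test_homogeneous_poisson_rate_recovered(self):
        """0.4 ev/s over 600 s: unbiased mean and nominal CI coverage."""
        from scipy.stats import chi2

        estimates, covered = [], 0
        n_seeds = 50
        moving = np.ones(int(600 * FPS), bool)
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            counts = rng.poisson(0.4 / FPS, int(600 * FPS))
            ev = np.flatnonzero(counts)
            r = nn.event_rates(ev, moving, FPS)["rate_moving"]
            estimates.append(r)
            k = int(round(r * 600))
            lo = chi2.ppf(0.025, 2 * k) / 2 / 600 if k else 0.0
            hi = chi2.ppf(0.975, 2 * (k + 1)) / 2 / 600
            covered += lo <= 0.4 <= hi
        assert np.mean(estimates) == pytest.approx(0.4, rel=0.05)
        assert covered / n_seeds >= 0.9


class TestBehaviorRelatedNeurons:
    def test_sensitivity_at_least_80_percent(self, tuned_setup):
        ctruth, occ, tuned = tuned_setup
        res = nn.behavior_related_neurons(
            ctruth.event_frames, occ, FPS, n_shuffle=1000, random_state=7
        )
        assert np.isin(tuned, res.neuron_ids).mean() >= 0.8

    def test_false_positive_rate_on_homogeneous_control(self, tuned_setup):
        _, occ, _ = tuned_setup
        states = ls.well_separated_states()
        _, _, _, truth = ls.generate_behavior_session(states, duration=300, seed=5)
        _, ctruth = ls.generate_calcium(truth, n_neurons=200, baseline_rate=0.15, seed=8)
        res = nn.behavior_related_neurons(
            ctruth.event_frames, occ, FPS, n_shuffle=1000, alpha=0.05, random_state=9
        )
        n_active = 200 - res.n_excluded_silent
        fpr = res.neuron_ids.size / n_active
        se = np.sqrt(0.05 * 0.95 / n_active)
        assert fpr <= 0.05 + 2 * se

    def test_anticorrelated_neuron_not_selected(self):
        occ = np.zeros(2000)
        occ[:700] = 1.0
        train = [np.arange(800, 2000, 10)]  # fires only outside the state
        res = nn.behavior_related_neurons(train, occ, FPS, n_shuffle=200,
                                          random_state=10)
        assert res.neuron_ids.size == 0
        assert res.r[0] < 0


class TestEnsembleOverlap:
    def test_identical_sets_full_overlap(self):
        res = nn.ensemble_overlap(np.arange(30), np.arange(30), 200, random_state=0)
        assert res["raw"] == pytest.approx(100.0)
        assert res["corrected"] == pytest.approx(100.0 - res["shuffle_mean"])

    def test_disjoint_sets_zero_raw(self):
        res = nn.ensemble_overlap(np.arange(30), np.arange(40, 70), 200, random_state=0)
        assert res["raw"] == 0.0

    def test_independent_sets_corrected_near_zero(self):
        rng = np.random.default_rng(1)
        vals = []
        for i in range(300):
            a = rng.choice(200, 30, replace=False)
            b = rng.choice(200, 40, replace=False)
            vals.append(
                nn.ensemble_overlap(a, b, 200, n_shuffle=100, random_state=i)["corrected"]
            )
        assert abs(np.mean(vals)) <= 2.0

    def test_empty_set_flagged(self):
        with pytest.warns(UserWarning, match="empty neuron set"):
            res = nn.ensemble_overlap([], [1, 2], 10)
        assert np.isnan(res["raw"])


class TestSpatialCrosscorrelation:
    def test_identical_traces_correlate_fully(self):
        rng = np.random.default_rng(2)
        tr = rng.normal(0, 1, 2000)
        traces = np.vstack([tr, tr])
        centroids = np.array([[0.0, 0.0], [0.0, 100.0]])
        prof = nn.spatial_crosscorrelation(traces, centroids)
        b = np.digitize(100.0, prof.bin_edges) - 1
        assert prof.mean_correlation[b] == pytest.approx(1.0)

    def test_bin_edges_are_nine_log_bins(self):
        edges = nn.spatial_bin_edges()
        assert edges.size == 10
        assert edges[0] == pytest.approx(15.0)
        assert edges[-1] == pytest.approx(750.0)
        np.testing.assert_allclose(np.diff(np.log(edges)), np.diff(np.log(edges))[0])

    def test_every_included_pair_in_exactly_one_bin(self):
        rng = np.random.default_rng(3)
        traces = rng.normal(0, 1, (30, 500))
        centroids = rng.uniform(0, 600, (30, 2))
        prof = nn.spatial_crosscorrelation(traces, centroids)
        assert prof.n_pairs.sum() + prof.n_excluded == 30 * 29 // 2

    def test_shared_drive_profile_decays_monotonically(self):
        states = [ls.StateSpec("move", ba_level=0.2)]
        _, _, _, truth = ls.generate_behavior_session(states, duration=300, seed=12)
        ca, _ = ls.generate_calcium(
            truth, n_neurons=120, baseline_rate=0.1, shared_drive=0.5,
            spatial_length_um=40.0, seed=13,
        )
        prof = nn.spatial_crosscorrelation(ca.traces, ca.centroids_um)
        vals = prof.mean_correlation[~np.isnan(prof.mean_correlation)]
        assert np.all(np.diff(vals) < 0.02)  # monotone decrease up to noise
        assert vals[0] > 0.3
        assert abs(vals[-1]) < 0.05

    def test_independent_traces_near_zero(self):
        rng = np.random.default_rng(4)
        traces = rng.normal(0, 1, (40, 4000))
        centroids = rng.uniform(0, 600, (40, 2))
        prof = nn.spatial_crosscorrelation(traces, centroids)
        vals = prof.mean_correlation[~np.isnan(prof.mean_correlation)]
        assert np.abs(vals).max() < 0.05

    def test_single_neuron_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            nn.spatial_crosscorrelation(np.ones((1, 100)), np.zeros((1, 2)))


class TestEventTriggeredAverage:
    def test_planted_step_gives_significant_increase(self):
        rng = np.random.default_rng(5)
        n = int(300 * FPS)
        onsets = np.arange(10.0, 290.0, 10.0)
        traces = rng.normal(0, 1, (20, n))
        for t_on in onsets:
            i = int(t_on * FPS)
            traces[:, i : i + int(1.5 * FPS)] += 2.0
        res = nn.event_triggered_average(traces, onsets, FPS)
        assert res["post_mean"] > res["pre_mean"]
        assert res["pvalue"] < 0.01

    def test_stationary_noise_not_significant(self):
        hits = 0
        onsets = np.arange(10.0, 290.0, 10.0)
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            traces = rng.normal(0, 1, (10, int(300 * FPS)))
            res = nn.event_triggered_average(traces, onsets, FPS)
            hits += res["pvalue"] < 0.05
        assert hits / 20 <= 0.2

    def test_edge_onsets_dropped_and_counted(self):
        rng = np.random.default_rng(6)
        traces = rng.normal(0, 1, (5, int(60 * FPS)))
        res = nn.event_triggered_average(traces, np.array([0.5, 30.0, 59.5]), FPS)
        assert res["n_onsets_dropped"] == 2
        assert res["n_onsets_used"] == 1
        assert res["flag"] == "under-powered"


class TestPosmodBaselineSimilarity:
    def _baseline(self, seed=7):
        states = ls.well_separated_states()
        _, _, _, truth = ls.generate_behavior_session(states, duration=300, seed=seed)
        frame_times = np.arange(int(300 * FPS)) / FPS
        imu_idx = np.minimum(
            (frame_times * truth.rate).astype(int), truth.state_per_sample.size - 1
        )
        state_f = truth.state_per_sample[imu_idx]
        occupancies = np.stack([(state_f == k).astype(float) for k in range(4)])
        return truth, occupancies

    def test_tuned_cluster_identified_and_closer(self):
        """Neurons tuned to baseline state 2 mark its cluster 'pos mod'; the
        LD cluster built from the same symbol profile has EMD 0 to it."""
        truth, occupancies = self._baseline()
        mult = np.ones((50, 4))
        mult[:20, 2] = 4.0
        _, ctruth = ls.generate_calcium(
            truth, n_neurons=50, baseline_rate=0.15, multipliers=mult, seed=8
        )
        scheme = ls.DiscretizationScheme()
        # baseline exemplars: degenerate histograms of each state's symbols
        import lidscope.ethogram as eth

        protos = [(0, 1, 2, 1), (1, 1, 0, 1), (1, 1, 2, 0), (0, 1, 0, 0)]
        exemplars = np.stack(
            [
                eth.segment_histogram(np.tile(p, (50, 1)), 0, 50, scheme)
                for p in protos
            ]
        )
        res = nn.posmod_baseline_similarity(
            exemplars[2],  # LD cluster resembling baseline state 2
            np.arange(20),
            exemplars,
            occupancies,
            [np.asarray(f) for f in ctruth.event_frames],
            FPS,
            n_shuffle=300,
            random_state=9,
        )
        assert res["flag"] == "ok"
        assert res["pos_mod_mask"][2]
        assert res["emd_pos_mod"].min() == pytest.approx(0.0, abs=1e-12)
        assert res["emd_pos_mod"].mean() < res["emd_other"].mean()

    def test_empty_tuned_set_flagged(self):
        truth, occupancies = self._baseline()
        with pytest.warns(UserWarning, match="empty tuned set"):
            res = nn.posmod_baseline_similarity(
                np.zeros(12), [], np.zeros((2, 12)), occupancies, [], FPS
            )
        assert res["flag"] == "undefined-empty-set"

    def test_silent_tuned_neurons_flagged(self):
        truth, occupancies = self._baseline()
        with pytest.warns(UserWarning, match="never active"):
            res = nn.posmod_baseline_similarity(
                np.zeros(12),
                [0, 1],
                np.zeros((2, 12)),
                occupancies,
                [np.array([]), np.array([])],
                FPS,
            )
        assert res["flag"] == "undefined-silent"
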