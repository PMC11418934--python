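import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linprog
from sklearn.metrics import adjusted_rand_score

import lidscope as ls
import lidscope.ethogram as eth


def lp_transport_emd(p, q):
    """Independent oracle: minimal-cost transport between histograms by LP."""
    n = p.size
    cost = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).ravel().astype(float)
    a_eq = []
    for i in range(n):  # row sums = p
        row = np.zeros((n, n))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(n):  # col sums = q
        col = np.zeros((n, n))
        col[:, j] = 1
        a_eq.append(col.ravel())
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=np.concatenate([p, q]),
                  bounds=(0, None), method="highs")
    assert res.success
    return res.fun


def _feature_set(ba, ga_ap, theta_head, theta_axial, rate=200.0):
    n = len(ba)
    return ls.FeatureSet(
        times=np.arange(n) / rate,
        ba=np.asarray(ba, float),
        ba_axes=np.zeros((n, 3)),
        ga_axes=np.column_stack([np.asarray(ga_ap, float), np.zeros(n), np.zeros(n)]),
        theta_head=np.asarray(theta_head, float),
        theta_axial=np.asarray(theta_axial, float),
        rate=rate,
    )


class TestDiscretize:
    def test_table_lookup(self):
        feats = _feature_set([0.2], [0.1], [-30.0], [70.0])
        sym = ls.discretize(feats)
        # BA>=0.05 -> move(1); GA 0.1 -> head-up(2); theta_head -30 -> contra(1);
        # theta_axial 70 < 90 -> twisted(0)
        np.testing.assert_array_equal(sym[0], [1, 2, 1, 0])

    def test_strong_contralateral_rotation_bin(self):
        feats = _feature_set([0.0], [0.0], [-170.0], [120.0])
        assert ls.discretize(feats)[0, 2] == 0  # below -165 deg

    def test_boundary_goes_to_upper_bin(self):
        feats = _feature_set([0.05], [-0.4], [25.0], [90.0])
        np.testing.assert_array_equal(ls.discretize(feats)[0], [1, 1, 3, 1])

    def test_bin_counts(self):
        assert ls.DiscretizationScheme().n_bins == (2, 3, 5, 2)


class TestWindowHistograms:
    def test_window_count_arithmetic(self):
        n = int(10 * 200)
        sym = np.zeros((n, 4), dtype=int)
        win = eth.window_histograms(sym, 200.0)
        assert win.hists.shape[0] == int((10 - 0.25) / 0.05) + 1 == 196

    def test_constant_symbols_degenerate_histograms(self):
        sym = np.tile([1, 2, 1, 0], (200, 1))
        win = eth.window_histograms(sym, 200.0)
        assert np.all(np.isin(win.hists, (0.0, 1.0)))

    def test_straddling_window_splits_mass_proportionally(self):
        sym = np.zeros((100, 4), dtype=int)
        sym[50:, 0] = 1  # BA symbol switches halfway
        win = eth.window_histograms(sym, 200.0, window=0.5, overlap=0.0)
        np.testing.assert_allclose(win.hists[0, :2], [0.5, 0.5])

    def test_short_session_rejected(self):
        with pytest.raises(ValueError, match="shorter than one window"):
            eth.window_histograms(np.zeros((10, 4), dtype=int), 200.0)


class TestEmd:
    def test_identity(self):
        h = np.array([0.3, 0.4, 0.3])
        assert eth.emd_1d(h, h) == 0.0

    def test_unit_ground_distance_two_bins_apart(self):
        assert eth.emd_1d(np.array([1.0, 0, 0]), np.array([0, 0, 1.0])) == 2.0

    def test_matches_lp_oracle_on_200_seeded_pairs(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(200):
            n = rng.integers(2, 7)
            p = rng.dirichlet(np.ones(n))
            q = rng.dirichlet(np.ones(n))
            worst = max(worst, abs(eth.emd_1d(p, q) - lp_transport_emd(p, q)))
        assert worst <= 1e-9

    def test_unnormalized_input_warns_and_normalizes(self):
        with pytest.warns(UserWarning, match="normaliz"):
            d = eth.emd_1d(np.array([2.0, 0.0]), np.array([0.0, 1.0]))
        assert d == pytest.approx(1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metric_properties_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 7)
        p, q, r = rng.dirichlet(np.ones(n), size=3)
        dpq = eth.emd_1d(p, q)
        assert dpq >= 0
        assert dpq == pytest.approx(eth.emd_1d(q, p))
        assert eth.emd_1d(p, p) == pytest.approx(0.0, abs=1e-12)
        assert dpq <= eth.emd_1d(p, r) + eth.emd_1d(r, q) + 1e-12

    def test_pairwise_matrix_matches_scalar(self):
        rng = np.random.default_rng(1)
        scheme = ls.DiscretizationScheme()
        sym = rng.integers(0, 2, (500, 4))
        hists = np.stack(
            [eth.segment_histogram(sym, i * 50, (i + 1) * 50, scheme) for i in range(10)]
        )
        mat = eth.pairwise_emd(hists, scheme)
        for i in range(10):
            for j in range(10):
                assert mat[i, j] == pytest.approx(eth.emd(hists[i], hists[j], scheme))


class TestSegmentHistogram:
    def test_pure_span(self):
        sym = np.tile([1, 0, 2, 1], (100, 1))
        h = eth.segment_histogram(sym, 0, 100, ls.DiscretizationScheme())
        np.testing.assert_allclose(h[:2], [0.0, 1.0])  # BA fully in move bin

    def test_mixed_span_counts(self):
        sym = np.zeros((100, 4), dtype=int)
        sym[:50, 0] = 1
        h = eth.segment_histogram(sym, 0, 100, ls.DiscretizationScheme())
        np.testing.assert_allclose(h[:2], [0.5, 0.5])

    def test_matches_direct_counting_oracle(self):
        rng = np.random.default_rng(2)
        scheme = ls.DiscretizationScheme()
        sym = np.column_stack(
            [rng.integers(0, b, 300) for b in scheme.n_bins]
        )
        h = eth.segment_histogram(sym, 37, 243, scheme)
        for k, (sl, b) in enumerate(zip(scheme.slices, scheme.n_bins)):
            counts = np.bincount(sym[37:243, k], minlength=b) / (243 - 37)
            np.testing.assert_allclose(h[sl], counts)

    def test_empty_span_rejected(self):
        with pytest.raises(ValueError, match="empty span"):
            eth.segment_histogram(np.zeros((10, 4), int), 5, 5, ls.DiscretizationScheme())


class TestChangepoints:
    def test_single_switch_detected_once(self):
        sym = np.zeros((2000, 4), dtype=int)
        sym[1000:, 3] = 1  # axial symbol switches at t = 5 s
        win = eth.window_histograms(sym, 200.0)
        cps, segs = eth.detect_changepoints(win, sym, 200.0)
        assert len(cps) == 1
        assert abs(cps[0] - 5.0) <= 0.05 + 1e-9
        assert len(segs) == 2

    def test_constant_session_has_no_changepoints(self):
        sym = np.tile([1, 1, 2, 1], (2000, 1))
        win = eth.window_histograms(sym, 200.0)
        cps, segs = eth.detect_changepoints(win, sym, 200.0)
        assert len(cps) == 0
        assert len(segs) == 1

    def test_segments_tile_session_exactly(self, segmented_four_state):
        segs = segmented_four_state["segments"]
        n = segmented_four_state["symbols"].shape[0]
        assert segs[0].start_idx == 0
        assert segs[-1].end_idx == n
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end_idx == b.start_idx
        total = sum(s.duration for s in segs)
        assert total == pytest.approx(n / 200.0)

    def test_minimum_segment_duration_enforced(self, segmented_four_state):
        assert min(s.duration for s in segmented_four_state["segments"]) >= 0.1

    def test_six_planted_transitions_recovered(self):
        """Sharp-featured session: all 6 transitions within 100 ms, none spurious."""
        from lidscope.synthetic import sharp_transition_states

        states = sharp_transition_states()
        schedule = [(0, 30), (1, 35), (2, 30), (0, 40), (1, 30), (2, 35), (0, 30)]
        imu, pose, _, truth = ls.generate_behavior_session(states, seed=3,
                                                          schedule=schedule)
        feats = ls.session_features(imu, pose)
        symbols = ls.discretize(feats)
        win = eth.window_histograms(symbols, feats.rate)
        d, _ = eth.change_signal(win)
        thr = 2.0 * float(np.mean(d))
        cps, _ = eth.detect_changepoints(win, symbols, feats.rate, threshold=thr)
        assert len(cps) == len(truth.change_points) == 6
        errs = np.abs(np.asarray(cps) - truth.change_points)
        assert errs.max() <= 0.1 + 1e-9


class TestClustering:
    def test_three_separated_behaviors_recovered(self):
        rng = np.random.default_rng(3)
        scheme = ls.DiscretizationScheme()
        protos = [(0, 0, 2, 1), (1, 2, 2, 0), (1, 1, 0, 1)]
        segs = []
        y = []
        for k, proto in enumerate(protos):
            for _ in range(100):
                sym = np.tile(proto, (60, 1))
                flips = rng.random(60) < 0.05
                sym[flips, 0] = rng.integers(0, 2, flips.sum())
                segs.append(eth.BehavioralSegment(
                    0, 0.3, 0, 60, eth.segment_histogram(sym, 0, 60, scheme)))
                y.append(k)
        lib, est = ls.cluster_segments(segs, random_state=0)
        assert lib.n_clusters == 3
        assert adjusted_rand_score(y, est.labels_) >= 0.9

    def test_identical_segments_give_one_cluster(self):
        scheme = ls.DiscretizationScheme()
        sym = np.tile([1, 1, 2, 1], (60, 1))
        h = eth.segment_histogram(sym, 0, 60, scheme)
        segs = [eth.BehavioralSegment(0, 0.3, 0, 60, h.copy()) for _ in range(20)]
        lib, _ = ls.cluster_segments(segs, random_state=0)
        assert lib.n_clusters == 1

    def test_lower_preference_does_not_increase_cluster_count(self):
        rng = np.random.default_rng(4)
        scheme = ls.DiscretizationScheme()
        segs = []
        for proto in [(0, 0, 2, 1), (1, 2, 0, 0)]:
            for _ in range(50):
                sym = np.tile(proto, (60, 1))
                flips = rng.random(60) < 0.05
                sym[flips, 3] = rng.integers(0, 2, flips.sum())
                segs.append(eth.BehavioralSegment(
                    0, 0.3, 0, 60, eth.segment_histogram(sym, 0, 60, scheme)))
        lib_med, _ = ls.cluster_segments(segs, random_state=0)
        lib_low, _ = ls.cluster_segments(segs, preference=-20.0, random_state=0)
        assert lib_low.n_clusters <= lib_med.n_clusters

    def test_order_permutation_gives_same_partition(self, clustered_four_state):
        segs = clustered_four_state["segments"]
        labels = clustered_four_state["estimator"].labels_
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(segs))
        lib2, est2 = ls.cluster_segments([segs[i] for i in perm], random_state=0)
        assert adjusted_rand_score(labels[perm], est2.labels_) == pytest.approx(1.0)

    def test_exemplars_are_members_of_their_cluster(self, clustered_four_state):
        est = clustered_four_state["estimator"]
        for c, idx in enumerate(est.exemplar_indices_):
            assert est.labels_[idx] == c

    def test_end_to_end_state_recovery(self, clustered_four_state):
        """Four planted states, each pair differing in >= 2 features: ARI >= 0.8."""
        ari = adjusted_rand_score(
            clustered_four_state["y_true"], clustered_four_state["estimator"].labels_
        )
        assert ari >= 0.8

    def test_too_few_segments_rejected(self):
        scheme = ls.DiscretizationScheme()
        sym = np.tile([1, 1, 2, 1], (60, 1))
        h = eth.segment_histogram(sym, 0, 60, scheme)
        segs = [eth.BehavioralSegment(0, 0.3, 0, 60, h) for _ in range(5)]
        with pytest.raises(ValueError, match="at least 10"):
            ls.cluster_segments(segs)


class TestRestMoveAndRoc:
    def test_rest_move_labeling(self, clustered_four_state):
        lib = clustered_four_state["library"]
        feats = clustered_four_state["features"]
        segs = clustered_four_state["segments"]
        ls.label_rest_move(lib, segs, feats.ba)
        truth = clustered_four_state["truth"]
        # states 0 and 3 are quiet (BA 0.01), 1 and 2 active (BA 0.25)
        y_true = clustered_four_state["y_true"]
        for c in range(lib.n_clusters):
            members = y_true[clustered_four_state["estimator"].labels_ == c]
            if members.size < 5:
                continue
            majority_state = np.bincount(members).argmax()
            expected = "rest" if majority_state in (0, 3) else "move"
            assert lib.rest_move[c] == expected

    def test_fraction_rule(self):
        scheme = ls.DiscretizationScheme()
        sym = np.tile([0, 1, 2, 1], (100, 1))
        h = eth.segment_histogram(sym, 0, 100, scheme)
        segs = [eth.BehavioralSegment(0, 0.5, 0, 100, h) for _ in range(4)]
        lib = eth.ClusterLibrary(scheme, np.stack([h]), np.zeros(4, dtype=int))
        ba = np.full(100, 0.01)
        ba[:60] = 0.2  # 40% sub-threshold -> move
        ls.label_rest_move(lib, segs, ba)
        assert lib.rest_move[0] == "move"
        ba2 = np.full(100, 0.01)
        ba2[:10] = 0.2  # 90% sub-threshold -> rest
        ls.label_rest_move(lib, segs, ba2)
        assert lib.rest_move[0] == "rest"

    def test_roc_separates_clusters(self, clustered_four_state):
        segs = clustered_four_state["segments"]
        X = np.stack([s.hist for s in segs])
        res = ls.roc_separability(X, clustered_four_state["estimator"].labels_,
                                  random_state=0)
        assert res["accuracy"] >= 0.95
        assert abs(res["accuracy_shuffled"] - 0.5) <= 0.05

    def test_single_cluster_rejected(self):
        X = np.tile([1.0, 0.0], (10, 6))
        with pytest.raises(ValueError, match="at least 2 clusters"):
            ls.roc_separability(X, np.zeros(10, dtype=int))


class TestLibraryMatching:
    def test_self_match_is_perfect(self, clustered_four_state):
        lib = clustered_four_state["library"]
        res = ls.match_to_library(lib.exemplar_hists, lib)
        np.testing.assert_array_equal(res["assignments"], np.arange(lib.n_clusters))
        np.testing.assert_allclose(res["matched_emd"], 0.0, atol=1e-12)

    def test_perturbed_exemplars_match_correctly(self, clustered_four_state):
        lib = clustered_four_state["library"]
        scheme = lib.scheme
        rng = np.random.default_rng(6)
        hists, expected = [], []
        for c in range(lib.n_clusters):
            for _ in range(50):
                h = lib.exemplar_hists[c].copy()
                for sl in scheme.slices:  # small symbol noise on each simplex
                    noise = rng.dirichlet(np.ones(sl.stop - sl.start))
                    h[sl] = 0.92 * h[sl] + 0.08 * noise
                hists.append(h)
                expected.append(c)
        res = ls.match_to_library(np.stack(hists), lib)
        correct = np.mean(res["assignments"] == np.asarray(expected))
        assert correct >= 0.95
        assert res["pvalue_vs_shuffle"] < 0.01

    def test_scheme_mismatch_rejected(self, clustered_four_state):
        lib = clustered_four_state["library"]
        other = ls.DiscretizationScheme(ba=(0.1,))
        with pytest.raises(ValueError, match="scheme mismatch"):
            ls.match_to_library(lib.exemplar_hists, lib, scheme=other)

    def test_library_json_roundtrip(self, tmp_path, clustered_four_state):
        lib = clustered_four_state["library"]
        p = tmp_path / "library.json"
        lib.to_json(p)
        back = eth.ClusterLibrary.from_json(p)
        np.testing.assert_allclose(back.exemplar_hists, lib.exemplar_hists)
        assert back.scheme.to_dict() == lib.scheme.to_dict()


class TestClusterPresence:
    def test_boundary_occupancy(self):
        occ = {"cond": [{0: 2.9, 1: 3.0}]}
        presence = ls.cluster_presence(occ, session_duration=600.0)
        assert presence["cond"] == [1]

    def test_scaling_with_session_duration(self):
        occ = {"cond": [{0: 1.4, 1: 1.5}]}
        presence = ls.cluster_presence(occ, session_duration=300.0)
        assert presence["cond"] == [1]

    def test_matches_direct_thresholding_oracle(self):
        rng = np.random.default_rng(7)
        occ = {
            cond: [
                {c: float(rng.uniform(0, 6)) for c in range(8)} for _ in range(4)
            ]
            for cond in ("a", "b")
        }
        presence = ls.cluster_presence(occ, session_duration=600.0)
        for cond in occ:
            for c in range(8):
                mean_occ = np.mean([s[c] for s in occ[cond]])
                assert (c in presence[cond]) == (mean_occ >= 3.0)
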