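"""Pairwise gait distances, Ward clustering, naming and circular histograms."""

import numpy as np
import pytest
from scipy.special import iv

import gaitspace as gs

from conftest import circular_mean_cycles


class TestPairwiseDistances:
    def test_matches_elementwise_gait_distance(self, metric6):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, size=(12, 5))
        cond = gs.pairwise_distances(pts, metric6)
        k = 0
        for i in range(11):
            for j in range(i + 1, 12):
                _, delta = gs.gait_distance(pts[i], pts[j], metric6)
                assert cond[k] == pytest.approx(delta)
                k += 1

    def test_duplicates_give_zero(self, metric6):
        pts = np.tile([0.1, 0.2, 0.3, 0.4, 0.5], (2, 1))
        assert gs.pairwise_distances(pts, metric6)[0] == 0.0

    def test_square_form_symmetry(self, metric6):
        from scipy.spatial.distance import squareform

        pts = np.random.default_rng(1).uniform(0, 1, size=(6, 5))
        sq = squareform(gs.pairwise_distances(pts, metric6))
        np.testing.assert_allclose(sq, sq.T)
        assert (np.diag(sq) == 0).all()


class TestWardLinkage:
    def test_two_points_single_merge(self, metric6):
        pts = np.array([[0.1] * 5, [0.2] * 5])
        tree = gs.ward_linkage(gs.pairwise_distances(pts, metric6))
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] > 0

    def test_three_tight_triads_separate_at_the_top(self, metric6):
        rng = np.random.default_rng(0)
        centers = np.array([[0.1] * 5, [0.5] * 5, [0.9] * 5])
        pts = np.vstack(
            [c + rng.normal(0, 0.005, size=(3, 5)) for c in centers]
        ) % 1.0
        tree = gs.ward_linkage(gs.pairwise_distances(pts, metric6))
        labels = gs.cut_clusters(tree, 3)
        truth = np.repeat([0, 1, 2], 3)
        for g in range(3):
            assert len(set(labels[truth == g])) == 1
        assert len(set(labels)) == 3
        # heights are monotone for Ward
        assert (np.diff(tree.heights()) >= -1e-12).all()

    def test_order_invariance_up_to_relabeling(self, metric6):
        rng = np.random.default_rng(3)
        pts = np.vstack(
            [
                gs.sample_gait_points(m, 8.0, 20, seed=rng)
                for m in gs.model_gaits(6)
            ]
        )
        perm = rng.permutation(len(pts))
        l1 = gs.cut_clusters(
            gs.ward_linkage(gs.pairwise_distances(pts, metric6)), 2
        )
        l2 = gs.cut_clusters(
            gs.ward_linkage(gs.pairwise_distances(pts[perm], metric6)), 2
        )
        # same partition: co-membership matrices agree under the permutation
        co1 = l1[perm][:, None] == l1[perm][None, :]
        co2 = l2[:, None] == l2[None, :]
        np.testing.assert_array_equal(co1, co2)


class TestCutClusters:
    def test_trivial_cuts(self, metric6):
        pts = np.random.default_rng(0).uniform(0, 1, size=(8, 5))
        tree = gs.ward_linkage(gs.pairwise_distances(pts, metric6))
        assert set(gs.cut_clusters(tree, 1)) == {1}
        assert len(set(gs.cut_clusters(tree, 8))) == 8
        with pytest.raises(ValueError):
            gs.cut_clusters(tree, 9)


class TestCentroids:
    def test_single_point_is_its_own_centroid(self):
        p = np.array([[0.2, 0.9, 0.4, 0.1, 0.6]])
        np.testing.assert_allclose(gs.cluster_centroid(p).as_array(), p[0])

    def test_circular_means_wrap(self):
        assert gs.cluster_centroid(np.array([[0.4], [0.6]])).dphi[0] == (
            pytest.approx(0.5)
        )
        assert gs.cluster_centroid(np.array([[0.9], [0.1]])).dphi[0] == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_von_mises_centroid_converges_to_mu(self, models6):
        mt = models6[1]
        pts = gs.sample_gait_points(mt, 4.0, 10_000, seed=0)
        c = gs.cluster_centroid(pts).as_array()
        err = np.abs(gs.signed_circular_delta(c, mt.point.as_array()))
        assert err.max() < 0.01


class TestNaming:
    def test_exact_model_centroid_gets_rank_one(self, metric6, models6):
        abt, mt = models6
        centroids = {1: abt.point, 2: gs.GaitPoint((0.5, 0.5, 0.45, 0.5, 0.5))}
        names = gs.name_clusters(centroids, models6, metric6)
        assert names[1] == "ABT1"
        assert names[2] == "MT1"

    def test_shared_model_ranked_by_distance(self, metric6, models6):
        centroids = {
            1: gs.GaitPoint((0.5, 0.5, 0.5, 0.5, 0.62)),
            2: gs.GaitPoint((0.5, 0.5, 0.5, 0.5, 0.55)),
        }
        names = gs.name_clusters(centroids, models6, metric6)
        assert names[2] == "MT1" and names[1] == "MT2"

    def test_eight_leg_centroids_draw_from_alt_only(self, metric8):
        models = gs.model_gaits(8)
        centroids = {1: gs.GaitPoint((0.4,) * 7), 2: gs.GaitPoint((0.6,) * 7)}
        names = gs.name_clusters(centroids, models, metric8)
        assert all(n.startswith("ALT") for n in names.values())


class TestNearestModelAssignment:
    def test_exact_model_points_classified_correctly(self, metric6, models6):
        pts = np.vstack([m.point.as_array() for m in models6])
        labels = gs.nearest_model_assignment(pts, models6, metric6)
        assert list(labels) == ["ABT", "MT"]

    def test_tie_breaks_to_canonical_order(self, metric6, models6):
        # equidistant between ABT (third coord 0) and MT (third coord 0.5)
        tie = np.array([[0.5, 0.5, 0.25, 0.5, 0.5]])
        labels = gs.nearest_model_assignment(tie, models6, metric6)
        assert labels[0] == "ABT"


class TestClusterSummaries:
    def test_single_cluster_reproduces_whole_trial_statistics(self):
        rng = np.random.default_rng(0)
        speed = rng.uniform(50, 150, 200)
        ssm = rng.normal(1.0, 0.5, 200)
        n_support = rng.integers(2, 5, 200)
        labels = np.ones(200, dtype=int)
        summary = gs.cluster_summaries(labels, speed, ssm, n_support)[1]
        assert summary.speed_mean == pytest.approx(speed.mean())
        assert summary.ssm_median == pytest.approx(np.median(ssm))
        assert sum(summary.n_support_counts.values()) == 200

    def test_ideal_tripod_summary_concentrates_at_three_supports(self, models6):
        mt = models6[1]
        fp = gs.footfall_pattern(mt, 0.5, n_strides=5, samples_per_stride=100)
        n = fp.n_support.size
        summary = gs.cluster_summaries(
            np.ones(n, int), np.full(n, 100.0), np.ones(n), fp.n_support
        )[1]
        assert summary.n_support_counts == {3: n}
        assert summary.speed_sd == pytest.approx(0.0)

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError):
            gs.cluster_summaries(
                np.ones(5, int), np.ones(4), np.ones(5), np.ones(5, int)
            )


class TestCircularHistogram:
    def test_concentrated_samples(self):
        h = gs.circular_histogram(np.full(100, 0.5))
        assert h.mean_direction == pytest.approx(0.5)
        assert h.resultant_length == pytest.approx(1.0)
        assert h.counts.sum() == 100

    def test_uniform_samples_have_vanishing_resultant(self):
        x = np.random.default_rng(0).uniform(0, 1, 10_000)
        assert gs.circular_histogram(x).resultant_length < 0.1

    @pytest.mark.parametrize("kappa", [2.0, 8.0])
    def test_von_mises_resultant_matches_bessel_ratio(self, kappa):
        pts = gs.sample_gait_points(
            gs.GaitPoint((0.25,)), kappa, 10_000, seed=0
        )
        h = gs.circular_histogram(pts[:, 0])
        expected = iv(1, kappa) / iv(0, kappa)
        assert h.resultant_length == pytest.approx(expected, abs=0.02)


class TestFullPipeline:
    def test_two_model_mixture_recovered(self, metric6, models6):
        abt, mt = models6
        rng = np.random.default_rng(0)
        pts = np.vstack(
            [
                gs.sample_gait_points(abt, 8.0, 150, seed=rng),
                gs.sample_gait_points(mt, 8.0, 150, seed=rng),
            ]
        )
        result = gs.cluster_gait_points(pts, models6, metric6, k=2, seed=0)
        assert sorted(result.names.values()) == ["ABT1", "MT1"]
        # centroids sit near their models
        for cid, name in result.names.items():
            model = abt if name == "ABT1" else mt
            err = np.abs(
                gs.signed_circular_delta(
                    result.centroids[cid].as_array(), model.point.as_array()
                )
            )
            assert err.max() < 0.05
        for (cid, mname), (mean, (lo, hi)) in result.model_proximity.items():
            assert lo <= mean <= hi
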