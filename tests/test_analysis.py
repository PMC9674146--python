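"""Weight-space analyses against brute-force oracles and hand computations."""

import numpy as np
import pytest

from somnus import analysis
from somnus.environment import DIRECTIONS, Orientation
from somnus.fixtures import PlantedFixture


# ---------------------------------------------------------------------------
# Brute-force oracles (literal transcriptions, independent of the vectorized
# implementations they check).


def prm_oracle(rfs, w_ho, orientation):
    fov = rfs.shape[1]
    total = 0.0
    for o, d in enumerate(DIRECTIONS):
        dmask = analysis.direction_mask(d, fov)
        s_o = np.zeros((fov, fov))
        for h in range(rfs.shape[0]):
            inner = np.zeros((fov, fov))
            for (a, b) in analysis.particle_masks(orientation, fov):
                pmask = np.zeros((fov, fov))
                pmask[a] = 1
                pmask[b] = 1
                overlap = rfs[h] * pmask
                inner += overlap * overlap.sum() ** 2
            s_o += w_ho[h, o] * inner
        total += (dmask * s_o).sum()
    return total


def manifold_distance_oracle(point, points):
    return min(np.sqrt(((point - x) ** 2).sum()) for x in points)


def hist2d_oracle(a, b, edges):
    counts = np.zeros((len(edges) - 1, len(edges) - 1))
    for x, y in zip(a, b):
        i = min(np.searchsorted(edges, x, side="right") - 1, len(edges) - 2)
        j = min(np.searchsorted(edges, y, side="right") - 1, len(edges) - 2)
        counts[i, j] += 1
    return counts


# ---------------------------------------------------------------------------


class TestReceptiveFields:
    def test_hidden_rf_places_weights_at_source_coordinates(self):
        fx = PlantedFixture()
        rf = analysis.receptive_field_hidden(fx.wiring, fx.w_ih, 0)
        assert rf[1, 1] == 1.0 and rf[1, 2] == 1.0
        assert rf.sum() == 2.0

    def test_output_rf_single_contributor(self):
        fx = PlantedFixture()
        rf = analysis.receptive_field_output(fx.wiring, fx.w_ih, fx.w_ho, 0)
        expected = analysis.receptive_field_hidden(fx.wiring, fx.w_ih, 0)
        assert np.allclose(rf, expected)

    def test_output_rf_weighted_average_by_hand(self):
        wiring = np.array([[0, 1], [2, 3]])
        w_ih = np.array([[1.0, 2.0], [3.0, 4.0]])
        w_ho = np.array([[0.25], [0.75]])
        rf = analysis.receptive_field_output(wiring, w_ih, w_ho, 0,
                                             input_shape=(2, 2))
        # (0.25*[1,2,0,0] + 0.75*[0,0,3,4]) / 1.0
        assert np.allclose(rf.ravel(), [0.25, 0.5, 2.25, 3.0])

    def test_zero_total_weight_errors(self):
        fx = PlantedFixture()
        with pytest.raises(ValueError):
            analysis.receptive_field_output(fx.wiring, fx.w_ih, fx.w_ho, 5)

    def test_uniform_output_weights_give_unweighted_mean(self, rng):
        wiring = rng.integers(0, 49, (6, 4))
        w_ih = rng.random((6, 4))
        w_ho = np.full((6, 8), 0.3)
        rfs = analysis.hidden_receptive_fields(wiring, w_ih)
        out = analysis.receptive_field_output(wiring, w_ih, w_ho, 2)
        assert np.allclose(out, rfs.mean(axis=0))


class TestPRM:
    def test_zero_weights_give_zero(self):
        fx = PlantedFixture(rf_weight=0.0, ho_weight=0.0)
        for o in Orientation:
            assert analysis.prm(fx.wiring, fx.w_ih, fx.w_ho, o) == 0.0

    def test_planted_fixture_hand_values(self):
        # Hidden 0: horizontal pair at (1,1)-(1,2), weight w, wired to the
        # up-left output with weight a.  Full-pair placement contributes
        # w*(2w)^2 at each pixel; the two single-pixel overlaps add w*w^2
        # each: M(1,1) = M(1,2) = 5 w^3.  Both pixels sit in the up-left
        # direction block, so PRM(horizontal) = 10 a w^3.  Vertical
        # placements overlap one pixel each (two per pixel): 4 a w^3.
        fx = PlantedFixture(rf_weight=2.0, ho_weight=0.5)
        w3a = 0.5 * 2.0 ** 3
        assert analysis.prm(fx.wiring, fx.w_ih, fx.w_ho,
                            "horizontal") == pytest.approx(10 * w3a)
        assert analysis.prm(fx.wiring, fx.w_ih, fx.w_ho,
                            "vertical") == pytest.approx(4 * w3a)

    def test_horizontal_detector_prefers_horizontal(self):
        fx = PlantedFixture()
        vals = {o: analysis.prm(fx.wiring, fx.w_ih, fx.w_ho, o)
                for o in Orientation}
        assert max(vals, key=vals.get) == Orientation.HORIZONTAL

    def test_matches_brute_force_oracle(self, rng):
        rfs = rng.random((5, 7, 7))
        w_ho = rng.random((5, 8))
        for o in Orientation:
            assert analysis.prm_from_receptive_fields(rfs, w_ho, o) == \
                pytest.approx(prm_oracle(rfs, w_ho, o), rel=1e-9)

    def test_invariant_under_hidden_permutation(self, rng):
        rfs = rng.random((6, 7, 7))
        w_ho = rng.random((6, 8))
        perm = rng.permutation(6)
        a = analysis.prm_from_receptive_fields(rfs, w_ho, "pos_diagonal")
        b = analysis.prm_from_receptive_fields(rfs[perm], w_ho[perm],
                                               "pos_diagonal")
        assert a == pytest.approx(b)

    def test_equivariant_under_quarter_rotation(self, rng):
        """Rotating receptive fields and the output direction map by 90
        degrees swaps horizontal and vertical responsiveness."""
        rfs = rng.random((6, 7, 7))
        w_ho = rng.random((6, 8))
        # rotate field coordinates: (r, c) -> (c, 6 - r); directions:
        # (dr, dc) -> (dc, -dr)
        rfs_rot = np.zeros_like(rfs)
        for r in range(7):
            for c in range(7):
                rfs_rot[:, c, 6 - r] = rfs[:, r, c]
        dir_index = {d: i for i, d in enumerate(DIRECTIONS)}
        w_rot = np.zeros_like(w_ho)
        for i, (dr, dc) in enumerate(DIRECTIONS):
            w_rot[:, dir_index[(dc, -dr)]] = w_ho[:, i]
        a = analysis.prm_from_receptive_fields(rfs, w_ho, "horizontal")
        b = analysis.prm_from_receptive_fields(rfs_rot, w_rot, "vertical")
        assert a == pytest.approx(b)


class TestTaskRelevantSynapses:
    def test_count_rule_ceil(self, rng):
        ids = analysis.task_relevant_synapses(rng.random(6272))
        assert len(ids) == 628

    def test_uniform_ties_resolved_by_index(self):
        ids = analysis.task_relevant_synapses(np.ones(100), quantile=0.9)
        assert np.array_equal(ids, np.arange(10))

    def test_dominant_weight_always_included(self, rng):
        w = np.zeros(500)
        w[137] = 1.0
        assert 137 in analysis.task_relevant_synapses(w)


class TestSVM:
    @pytest.fixture
    def clusters(self, rng):
        a = rng.normal(0.0, 0.1, (20, 30))
        b = rng.normal(1.0, 0.1, (20, 30))
        return a, b

    def test_training_duplicates_on_correct_side(self, clusters):
        a, b = clusters
        vals = analysis.svm_weight_classifier(a, b, np.vstack([a[:3], b[:3]]))
        assert np.all(vals[:3] < 0)      # Task-1 side negative
        assert np.all(vals[3:] > 0)

    def test_planted_separation_has_margin(self, clusters, rng):
        a, b = clusters
        qa = rng.normal(0.0, 0.1, (10, 30))
        qb = rng.normal(1.0, 0.1, (10, 30))
        vals = analysis.svm_weight_classifier(a, b, np.vstack([qa, qb]))
        assert vals[:10].max() < vals[10:].min()

    def test_single_class_training_rejected(self, clusters):
        a, _ = clusters
        with pytest.raises(ValueError):
            analysis.svm_weight_classifier(a, np.empty((0, 30)), a)

    def test_agrees_with_nearest_neighbour_on_separated_fixture(self, clusters, rng):
        a, b = clusters
        q = np.vstack([rng.normal(0.0, 0.1, (8, 30)),
                       rng.normal(1.0, 0.1, (8, 30))])
        svm_side = analysis.svm_weight_classifier(a, b, q) > 0
        train = np.vstack([a, b])
        labels = np.array([0] * len(a) + [1] * len(b))
        nn_side = np.array([
            labels[np.argmin(((train - x) ** 2).sum(axis=1))] for x in q]) == 1
        assert np.array_equal(svm_side, nn_side)


class TestEmbedding:
    def test_identical_snapshots_flagged_degenerate(self):
        emb = analysis.embed_trajectory(np.ones((5, 10)), "pca", 2)
        assert emb.degenerate
        assert np.allclose(emb.coords, 0)

    @pytest.mark.parametrize("method", ["pca", "kpca"])
    def test_planted_clusters_separate_on_first_component(self, method, rng):
        a = rng.normal(0, 0.05, (15, 20))
        b = rng.normal(1, 0.05, (15, 20))
        emb = analysis.embed_trajectory(np.vstack([a, b]), method, 2)
        assert not emb.degenerate
        c1 = emb.coords[:15, 0]
        c2 = emb.coords[15:, 0]
        assert max(c1.max(), c2.max()) > min(c1.min(), c2.min())  # sanity
        assert (c1.max() < c2.min()) or (c2.max() < c1.min())

    def test_deterministic(self, rng):
        X = rng.random((10, 12))
        a = analysis.embed_trajectory(X, "kpca", 2)
        b = analysis.embed_trajectory(X, "kpca", 2)
        assert np.array_equal(a.coords, b.coords)

    def test_too_few_snapshots_rejected(self):
        with pytest.raises(ValueError):
            analysis.embed_trajectory(np.eye(2), "pca", 2)


class TestManifoldDistance:
    def test_member_gives_zero(self, rng):
        pts = rng.random((8, 6))
        assert analysis.manifold_distance(pts[3], pts) == 0.0

    def test_origin_set_unit_point(self):
        assert analysis.manifold_distance(
            np.array([1.0, 0.0, 0.0]), np.zeros((1, 3))) == 1.0

    def test_matches_brute_force(self, rng):
        pts = rng.random((20, 15))
        p = rng.random(15)
        assert analysis.manifold_distance(p, pts) == pytest.approx(
            manifold_distance_oracle(p, pts), rel=1e-12)

    def test_triangle_inequality_spot_check(self, rng):
        pts = rng.random((10, 8))
        for _ in range(20):
            p, q = rng.random((2, 8))
            assert analysis.manifold_distance(p, pts) <= \
                np.linalg.norm(p - q) + analysis.manifold_distance(q, pts) + 1e-12

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            analysis.manifold_distance(np.zeros(3), np.empty((0, 3)))


class TestWeightHistogram2D:
    def test_snapshot_vs_itself_is_diagonal(self, rng):
        w = rng.random(500)
        h = analysis.weight_histogram_2d(w, w, n_bins=20)
        off_diag = h.counts.sum() - np.trace(h.counts)
        assert off_diag == 0

    def test_mass_conservation(self, rng):
        a, b = rng.random((2, 6272))
        h = analysis.weight_histogram_2d(a, b)
        assert h.counts.sum() == 6272
        assert h.marginal_x.sum() == 6272
        assert h.marginal_y.sum() == 6272

    def test_cap_applied_for_display(self, rng):
        a = np.zeros(300)
        b = np.zeros(300)
        h = analysis.weight_histogram_2d(a, b, n_bins=5, count_cap=50)
        assert h.counts.max() == 300
        assert h.capped.max() == 50

    def test_matches_brute_force(self, rng):
        a, b = rng.random((2, 400))
        h = analysis.weight_histogram_2d(a, b, n_bins=13)
        assert np.array_equal(h.counts, hist2d_oracle(a, b, h.x_edges))

    def test_small_perturbation_stays_near_diagonal(self, rng):
        a = rng.random(1000)
        bin_width = (a.max() * (1 + 1e-9)) / 25
        b = np.clip(a + rng.uniform(-bin_width / 2, bin_width / 2, 1000),
                    0, None)
        h = analysis.weight_histogram_2d(a, b, n_bins=25)
        band = sum(np.trace(h.counts, offset=k) for k in (-1, 0, 1))
        assert band == h.counts.sum()

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            analysis.weight_histogram_2d(np.zeros(3), np.zeros(4))
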