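import numpy as np
import pytest

from crossclust.clustering import (
    Assignment,
    CentroidSet,
    TrainingError,
    _centroid_pull,
    _cluster_alignment_grad,
    _per_type_weights,
    assign_targets,
    cell_alignment_loss_source,
    cell_alignment_loss_target,
    cluster_alignment_loss,
    finetune,
    init_centroids,
    nearest_centroids,
    prune_and_estimate,
    similarity_matrix,
    total_loss,
)
from crossclust.data import ExpressionDataset, LabelError

from conftest import linear_encoder


def _dataset(mat, labels=None, domain="target"):
    mat = np.asarray(mat, float)
    return ExpressionDataset(
        mat,
        [f"g{i}" for i in range(mat.shape[1])],
        [f"c{i}" for i in range(mat.shape[0])],
        domain,
        labels,
    )


def _centroids(Cs, Ct=None, names=None):
    Cs = np.asarray(Cs, float)
    Ct = Cs.copy() if Ct is None else np.asarray(Ct, float)
    names = names or [f"t{i}" for i in range(Cs.shape[0])]
    return CentroidSet(Cs, Ct, names)


class TestInitCentroids:
    # identity-like encoder: embeddings equal the first 2 input coordinates
    W = np.vstack([np.eye(2), np.zeros((2, 2))])  # 4 genes -> 2 latent

    def test_single_cell_types_give_exact_embeddings(self):
        enc = linear_encoder(self.W)
        ds = _dataset([[1, 2, 0, 0], [5, 6, 0, 0]], ["A", "B"], "source:a")
        cen = init_centroids(enc, [ds])
        np.testing.assert_allclose(cen.Cs, [[1, 2], [5, 6]])

    def test_mean_pools_across_sources(self):
        enc = linear_encoder(self.W)
        d1 = _dataset([[0, 0, 0, 0]], ["A"], "source:a")
        d2 = _dataset([[2, 0, 0, 0]], ["A"], "source:b")
        cen = init_centroids(enc, [d1, d2])
        np.testing.assert_allclose(cen.Cs, [[1, 0]])

    def test_target_copy_is_exact(self):
        enc = linear_encoder(self.W)
        ds = _dataset([[1, 2, 3, 4], [4, 3, 2, 1]], ["B", "A"], "source:a")
        cen = init_centroids(enc, [ds])
        assert np.max(np.abs(cen.Ct - cen.Cs)) == 0.0

    def test_type_names_sorted(self):
        enc = linear_encoder(self.W)
        ds = _dataset(np.eye(4), ["zeta", "alpha", "mid", "alpha"], "source:a")
        assert init_centroids(enc, [ds]).type_names == ["alpha", "mid", "zeta"]


class TestAssignTargets:
    def test_single_centroid_takes_all(self, rng):
        Z = rng.normal(size=(7, 2))
        assert np.all(nearest_centroids(Z, np.zeros((1, 2))) == 0)

    def test_tie_broken_to_lowest_index(self):
        C = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 0.0], [-1.0, 0.0]])
        # point at origin is equidistant from centroids 1 and 2 (dist 0) -> 1;
        # point at (0.0, 5) equidistant from 0 and 3 -> 0
        Z = np.array([[0.0, 0.0], [0.0, 5.0]])
        np.testing.assert_array_equal(nearest_centroids(Z, C), [1, 1])
        C2 = np.array([[1.0, 0.0], [-1.0, 0.0]])
        assert nearest_centroids(np.array([[0.0, 3.0]]), C2)[0] == 0

    def test_separated_clouds_recovered(self, rng):
        a = rng.normal(size=(5, 3)) + 10
        b = rng.normal(size=(5, 3)) - 10
        Z = np.vstack([a, b])
        C = np.vstack([a.mean(0), b.mean(0)])
        # brute-force oracle
        expected = [
            int(np.argmin([np.linalg.norm(z - c) for c in C])) for z in Z
        ]
        np.testing.assert_array_equal(nearest_centroids(Z, C), expected)
        np.testing.assert_array_equal(expected, [0] * 5 + [1] * 5)

    def test_assign_targets_via_encoder(self):
        enc = linear_encoder(TestInitCentroids.W)
        cen = _centroids([[0.0, 0.0], [10.0, 0.0]])
        tgt = _dataset([[9, 0, 0, 0], [1, 0, 0, 0]])
        asg = assign_targets(enc, tgt, cen)
        np.testing.assert_array_equal(asg.nearest, [1, 0])
        sets = asg.member_sets(2)
        np.testing.assert_array_equal(sets[0], [1])
        np.testing.assert_array_equal(sets[1], [0])


class TestCellAlignmentLosses:
    def test_zero_at_centroids(self):
        cen = _centroids([[1.0, 1.0], [2.0, 2.0]], names=["A", "B"])
        Z = np.array([[1.0, 1.0], [2.0, 2.0], [1.0, 1.0]])
        assert cell_alignment_loss_source(Z, ["A", "B", "A"], cen, 1) == 0.0

    def test_single_type_single_cell(self):
        # |S|=1, K=1, one cell at distance 2 -> (1/(2*1)) * 2 = 1
        cen = _centroids([[0.0, 0.0]], names=["A"])
        Z = np.array([[2.0, 0.0]])
        assert cell_alignment_loss_source(Z, ["A"], cen, 1) == pytest.approx(1.0)

    def test_hand_example_two_types(self):
        # |S|=1, K=2: type-A cells at distances 1 and 3, type-B at 4
        # (1/(2*2)) * [(1+3)/2 + 4/1] = 1.5
        cen = _centroids([[0.0, 0.0], [10.0, 0.0]], names=["A", "B"])
        Z = np.array([[1.0, 0.0], [3.0, 0.0], [10.0, 4.0]])
        loss = cell_alignment_loss_source(Z, ["A", "A", "B"], cen, 1)
        assert loss == pytest.approx(1.5)

    def test_target_hand_example(self):
        # |S|=1, K=1, two cells at distances 1 and 3 -> (1/2)*(1+3)/2 = 1
        cen = _centroids([[0.0, 0.0]], names=["A"])
        Z = np.array([[1.0, 0.0], [-3.0, 0.0]])
        asg = Assignment(np.array([0, 0]))
        assert cell_alignment_loss_target(Z, asg, cen, 1) == pytest.approx(1.0)

    def test_monotone_in_radial_distance(self):
        cen = _centroids([[0.0, 0.0]], names=["A"])
        asg = Assignment(np.array([0]))
        losses = [
            cell_alignment_loss_target(np.array([[r, 0.0]]), asg, cen, 1)
            for r in (0.5, 1.0, 2.0, 4.0)
        ]
        assert losses == sorted(losses)

    def test_absent_type_contributes_zero(self):
        cen = _centroids([[0.0, 0.0], [5.0, 0.0]], names=["A", "B"])
        Z = np.array([[1.0, 0.0]])
        # only type A present: (1/(2*2)) * 1 = 0.25
        assert cell_alignment_loss_source(Z, ["A"], cen, 1) == pytest.approx(0.25)

    def test_unknown_label_raises(self):
        cen = _centroids([[0.0, 0.0]], names=["A"])
        with pytest.raises(LabelError):
            cell_alignment_loss_source(np.zeros((1, 2)), ["Q"], cen, 1)

    def test_translation_invariance(self, rng):
        shift = rng.normal(size=2)
        Cs = rng.normal(size=(3, 2))
        Z = rng.normal(size=(8, 2))
        labels = list("ABCABCAB")
        base = cell_alignment_loss_source(Z, labels, _centroids(Cs, names=list("ABC")), 2)
        moved = cell_alignment_loss_source(
            Z + shift, labels, _centroids(Cs + shift, names=list("ABC")), 2
        )
        assert moved == pytest.approx(base)


class TestSimilarityMatrix:
    @pytest.mark.parametrize("n", [1, 2, 5, 10])
    def test_rows_stochastic(self, n, rng):
        cen = _centroids(rng.normal(size=(n, 4)), rng.normal(size=(n, 4)))
        P = similarity_matrix(cen).P
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(P > 0) and np.all(P < 1)

    def test_hand_example_n1_distance1(self):
        cen = _centroids([[0.0, 0.0]], [[1.0, 0.0]])
        P = similarity_matrix(cen, epsilon=1e-8, tau_c=1.0).P
        e = np.exp(1.0 / (1.0 + 1e-8))
        assert P[0, 1] == pytest.approx(e / (e + 1), rel=1e-6)
        assert P[0, 0] == pytest.approx(1 / (e + 1), rel=1e-6)

    def test_coincident_matched_pair_saturates(self):
        cen = _centroids(np.zeros((1, 3)), np.zeros((1, 3)))
        P = similarity_matrix(cen, epsilon=1e-8).P
        assert P[0, 1] == pytest.approx(1.0)
        assert P[1, 0] == pytest.approx(1.0)

    def test_mask_structure(self, rng):
        cen = _centroids(rng.normal(size=(3, 4)), rng.normal(size=(3, 4)))
        sm = similarity_matrix(cen)
        assert np.all(sm.sim[:3, :3] == 0) and np.all(sm.sim[3:, 3:] == 0)
        assert np.all(sm.sim[:3, 3:] > 0) and np.all(sm.sim[3:, :3] > 0)


class TestClusterAlignmentLoss:
    def test_matched_identical_centroids_near_zero(self):
        cen = _centroids(np.eye(3), np.eye(3))
        assert cluster_alignment_loss(similarity_matrix(cen, epsilon=1e-10)) < 1e-6

    @pytest.mark.parametrize("d", [0.1, 1.0, 10.0])
    def test_n1_closed_form(self, d):
        """For one cluster pair the loss is the binary entropy of a two-way softmax."""
        eps = 1e-8
        cen = _centroids([[0.0, 0.0]], [[d, 0.0]])
        s = 1.0 / (d + eps)
        p = np.exp(s) / (np.exp(s) + 1.0)
        expected = -(p * np.log(p) + (1 - p) * np.log(1 - p))
        loss = cluster_alignment_loss(similarity_matrix(cen, epsilon=eps))
        assert loss == pytest.approx(expected, rel=1e-8)

    def test_increasing_in_distance_toward_ln2(self):
        losses = [
            cluster_alignment_loss(similarity_matrix(_centroids([[0.0, 0.0]], [[d, 0.0]])))
            for d in (0.1, 1.0, 10.0, 1e6)
        ]
        assert losses == sorted(losses)
        assert losses[-1] == pytest.approx(np.log(2), rel=1e-4)

    def test_entropy_against_explicit_oracle(self, rng):
        cen = _centroids(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
        sm = similarity_matrix(cen)
        oracle = np.mean([-sum(p * np.log(p) for p in row if p > 0) for row in sm.P])
        assert cluster_alignment_loss(sm) == pytest.approx(oracle, abs=1e-8)

    def test_gradient_matches_finite_differences(self, rng):
        cen = _centroids(rng.normal(size=(3, 4)), rng.normal(size=(3, 4)))
        loss, gCs, gCt = _cluster_alignment_grad(cen, 1e-4, 0.7)
        h = 1e-6

        def f(Cs, Ct):
            c = CentroidSet(Cs, Ct, cen.type_names)
            return cluster_alignment_loss(similarity_matrix(c, 1e-4, 0.7))

        for C, g, is_s in [(cen.Cs, gCs, True), (cen.Ct, gCt, False)]:
            for i in range(3):
                for j in range(4):
                    Cp, Cm = C.copy(), C.copy()
                    Cp[i, j] += h
                    Cm[i, j] -= h
                    args_p = (Cp, cen.Ct) if is_s else (cen.Cs, Cp)
                    args_m = (Cm, cen.Ct) if is_s else (cen.Cs, Cm)
                    num = (f(*args_p) - f(*args_m)) / (2 * h)
                    assert g[i, j] == pytest.approx(num, abs=1e-6)


class TestTotalLoss:
    def test_sum_semantics(self):
        assert total_loss([0.0], 0.0, 0.0) == 0.0
        assert total_loss([0.5], 0.25, 0.1) == pytest.approx(0.85)
        assert total_loss([0.5, 0.25], 0.1, 0.0) == pytest.approx(0.85)


class TestCentroidStep:
    def test_gradient_step_moves_centroid_toward_members(self, rng):
        """With one target cluster, -grad points toward the member mean."""
        Z = rng.normal(size=(20, 3)) + np.array([4.0, 0.0, 0.0])
        C = np.zeros((1, 3))
        idx = np.zeros(20, dtype=int)
        inv = _per_type_weights(idx, 1, 1)
        _, _, dC = _centroid_pull(Z, C, idx, inv, 1.0)
        step = -dC[0]
        assert step @ (Z.mean(0) - C[0]) > 0


class TestFinetune:
    def _setup(self, rng):
        W = np.vstack([np.eye(2), np.zeros((3, 2))])  # 5 genes -> 2 latent
        enc = linear_encoder(W)
        src = _dataset(
            np.abs(rng.normal(size=(20, 5))) + np.repeat([[5, 0], [0, 5]], 10, 0) @ W.T * 2,
            ["A"] * 10 + ["B"] * 10,
            "source:a",
        )
        tgt = _dataset(np.abs(rng.normal(size=(16, 5))) + np.repeat([[5, 0], [0, 5]], 8, 0) @ W.T * 2)
        cen = init_centroids(enc, [src])
        return enc, cen, src, tgt

    def test_zero_epochs_noop(self, rng):
        enc, cen, src, tgt = self._setup(rng)
        params_before = {k: v.copy() for k, v in enc.params.items()}
        Cs_before = cen.Cs.copy()
        _, _, _, trace = finetune(enc, cen, [src], tgt, epochs=0)
        assert trace == []
        np.testing.assert_array_equal(cen.Cs, Cs_before)
        for k in params_before:
            np.testing.assert_array_equal(enc.params[k], params_before[k])

    def test_deterministic(self, rng):
        results = []
        for _ in range(2):
            rng2 = np.random.default_rng(5)
            enc, cen, src, tgt = self._setup(rng2)
            _, _, asg, trace = finetune(enc, cen, [src], tgt, epochs=3, seed=4, batch_size=8)
            results.append((asg.nearest.copy(), trace))
        np.testing.assert_array_equal(results[0][0], results[1][0])
        assert results[0][1] == results[1][1]

    def test_loss_decreases_on_separable_fixture(self, rng):
        enc, cen, src, tgt = self._setup(rng)
        _, _, _, trace = finetune(enc, cen, [src], tgt, epochs=15, seed=4, batch_size=8)
        assert trace[-1] < trace[0]


class TestPruneAndEstimate:
    def test_counts_nonempty_centroids(self, rng):
        cen = _centroids(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)))
        asg = Assignment(np.array([0, 0, 2, 4, 4, 4]))
        k, alive, out = prune_and_estimate(asg, cen)
        assert k == 3
        np.testing.assert_array_equal(alive, [True, False, True, False, True])
        np.testing.assert_array_equal(out.nearest, asg.nearest)

    def test_all_cells_one_centroid(self, rng):
        cen = _centroids(rng.normal(size=(4, 2)), rng.normal(size=(4, 2)))
        k, _, _ = prune_and_estimate(Assignment(np.full(9, 2)), cen)
        assert k == 1

    def test_min_cells_reassigns_orphans(self):
        Ct = np.array([[0.0, 0.0], [10.0, 0.0], [100.0, 0.0]])
        cen = _centroids(Ct.copy(), Ct)
        # clusters: 0 has 10 cells, 1 has 9 (pruned at min_cells=10), 2 has 10
        nearest = np.array([0] * 10 + [1] * 9 + [2] * 10)
        Z = np.vstack([
            np.zeros((10, 2)),
            np.tile([10.0, 0.0], (9, 1)),
            np.tile([100.0, 0.0], (10, 1)),
        ])
        k, alive, out = prune_and_estimate(Assignment(nearest), cen, min_cells=10,
                                           target_embedding=Z)
        assert k == 2
        np.testing.assert_array_equal(alive, [True, False, True])
        # orphans at x=10 are nearer the surviving centroid at 0 than at 100
        np.testing.assert_array_equal(out.nearest[10:19], 0)

    def test_degenerate_all_pruned_raises(self, rng):
        cen = _centroids(rng.normal(size=(2, 2)), rng.normal(size=(2, 2)))
        with pytest.raises(TrainingError):
            prune_and_estimate(Assignment(np.array([0, 1])), cen, min_cells=99,
                               target_embedding=np.zeros((2, 2)))


def test_recompute_source_means_tracks_embedding_means(rng):
    """Mean-recompute mode pins Cs to the current per-type embedding means."""
    W = np.vstack([np.eye(2), np.zeros((3, 2))])
    enc = linear_encoder(W)
    src = _dataset(np.abs(rng.normal(size=(12, 5))), ["A"] * 6 + ["B"] * 6, "source:a")
    tgt = _dataset(np.abs(rng.normal(size=(10, 5))))
    cen = init_centroids(enc, [src])
    enc, cen, _, _ = finetune(enc, cen, [src], tgt, epochs=2, seed=0, batch_size=6,
                              recompute_source_means=True)
    Z = enc.embed(src).vectors
    labels = np.asarray(src.labels)
    expect = np.vstack([Z[labels == t].mean(0) for t in ["A", "B"]])
    np.testing.assert_allclose(cen.Cs, expect, atol=1e-10)
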