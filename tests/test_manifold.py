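"""PCA trajectories against an SVD oracle, complete-linkage trees against
exhaustive agglomeration, and angle scores against a naive pairwise loop."""

import itertools

import numpy as np
import pandas as pd
import pytest

from valencemap import manifold
from valencemap.datasets import BinnedResponseMatrix, WindowSpec
from valencemap.manifold import _canonical_signs


def make_binned(data, n_odors=1, bin_width=0.05):
    data = np.asarray(data, dtype=float)
    return BinnedResponseMatrix(
        data,
        bin_width,
        [f"pn{i}" for i in range(data.shape[0])],
        [f"o{j}" for j in range(n_odors)],
        t_start=0.0,
        window=WindowSpec(),
    )


class TestPCA:
    def test_single_direction_captures_everything(self):
        t = np.linspace(0, 1, 40)
        data = np.outer([1.0, 2.0, -1.0], t) + 5.0
        traj = manifold.pca_trajectories(make_binned(data), n_components=2)
        assert np.isclose(traj.variance_fractions[0], 1.0)
        assert traj.variance_fractions[1] < 1e-12

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(0)
        data = rng.random((5, 40)) * 3
        X = make_binned(data)
        traj = manifold.pca_trajectories(
            X, n_components=3, subtract_first_bin=False, smooth=False
        )
        centered = data - data.mean(axis=1, keepdims=True)
        U, s, _ = np.linalg.svd(centered, full_matrices=False)
        U = _canonical_signs(U[:, :3])
        expected = U.T @ centered
        np.testing.assert_allclose(traj.trajectories["o0"], expected, atol=1e-8)
        np.testing.assert_allclose(
            traj.variance_fractions[:3], s[:3] ** 2 / (s**2).sum(), atol=1e-10
        )

    def test_trace_conservation_and_order(self):
        rng = np.random.default_rng(1)
        data = rng.random((6, 30))
        traj = manifold.pca_trajectories(make_binned(data), n_components=3)
        assert np.isclose(traj.variance_fractions.sum(), 1.0)
        assert (np.diff(traj.variance_fractions) <= 1e-12).all()

    def test_pn_order_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.random((6, 30))
        perm = rng.permutation(6)
        a = manifold.pca_trajectories(make_binned(data), smooth=False)
        b = manifold.pca_trajectories(make_binned(data[perm]), smooth=False)
        np.testing.assert_allclose(
            a.trajectories["o0"], b.trajectories["o0"], atol=1e-8
        )

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            manifold.pca_trajectories(make_binned(np.ones((3, 10))), n_components=5)


def brute_force_complete_linkage(X):
    """Exhaustive agglomeration oracle: repeatedly merge the pair of
    clusters with the smallest farthest-pair correlation distance."""
    def corr_dist(a, b):
        return 1.0 - np.corrcoef(X[a], X[b])[0, 1]

    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = max(corr_dist(a, b) for a in clusters[i] for b in clusters[j])
            if best is None or d < best[0] - 1e-12:
                best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((d, merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def scipy_merge_sets(tree, n):
    sets = [frozenset([i]) for i in range(n)]
    merges = []
    for a, b, h, _ in tree.linkage:
        merged = sets[int(a)] | sets[int(b)]
        sets.append(merged)
        merges.append((h, merged))
    return merges


class TestClustering:
    def test_identical_vectors_merge_at_zero(self):
        rng = np.random.default_rng(3)
        v = rng.random(10)
        frame = pd.DataFrame([v, v, rng.random(10)], index=["a", "b", "c"])
        tree = manifold.hierarchical_cluster(frame)
        assert np.isclose(tree.linkage[0, 2], 0.0, atol=1e-12)
        assert scipy_merge_sets(tree, 3)[0][1] == frozenset([0, 1])

    @pytest.mark.parametrize("n_items", [4, 5])
    def test_matches_exhaustive_agglomeration(self, n_items):
        rng = np.random.default_rng(4)
        X = rng.random((n_items, 12))
        frame = pd.DataFrame(X, index=[f"i{k}" for k in range(n_items)])
        tree = manifold.hierarchical_cluster(frame, optimal_ordering=False)
        got = scipy_merge_sets(tree, n_items)
        expected = brute_force_complete_linkage(X)
        for (h1, s1), (h2, s2) in zip(got, expected):
            assert s1 == s2
            assert abs(h1 - h2) < 1e-10

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.random((8, 15)))
        tree = manifold.hierarchical_cluster(frame)
        assert (np.diff(tree.linkage[:, 2]) >= -1e-12).all()

    def test_constant_vector_rejected(self):
        frame = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            manifold.hierarchical_cluster(frame)


class TestAngleScores:
    def test_orthogonal_construction_gives_net_90(self):
        app = np.array([1.0, 0.0, 0.0])
        non = np.array([0.0, 1.0, 0.0])
        frame = pd.DataFrame([app, app, app, non, non], index=list("abcde"))
        labels = {"a": True, "b": True, "c": True, "d": False, "e": False}
        scores = manifold.valence_angle_scores(frame, labels)
        assert np.isclose(scores.loc["a", "net_score"], 90.0)
        assert np.isclose(scores.loc["d", "net_score"], -90.0)

    def test_label_swap_negates_scores(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame(rng.random((6, 8)), index=list("abcdef"))
        labels = {k: k in "abc" for k in "abcdef"}
        flipped = {k: not v for k, v in labels.items()}
        a = manifold.valence_angle_scores(frame, labels)["net_score"]
        b = manifold.valence_angle_scores(frame, flipped)["net_score"]
        np.testing.assert_allclose(a.to_numpy(), -b.to_numpy(), atol=1e-10)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(7)
        X = rng.random((6, 9))
        ids = list("abcdef")
        labels = {k: k in "abd" for k in ids}
        scores = manifold.valence_angle_scores(pd.DataFrame(X, index=ids), labels)
        for i, odor in enumerate(ids):
            app_angles, non_angles = [], []
            for j, other in enumerate(ids):
                if i == j:
                    continue
                cos = X[i] @ X[j] / (np.linalg.norm(X[i]) * np.linalg.norm(X[j]))
                ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
                (app_angles if labels[other] else non_angles).append(ang)
            expected = np.mean(non_angles) - np.mean(app_angles)
            assert abs(scores.loc[odor, "net_score"] - expected) < 1e-10

    def test_positive_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        X = rng.random((5, 7))
        ids = list("abcde")
        labels = {k: k in "ab" for k in ids}
        a = manifold.valence_angle_scores(pd.DataFrame(X, index=ids), labels)
        scales = rng.uniform(0.1, 10, size=5)[:, None]
        b = manifold.valence_angle_scores(pd.DataFrame(X * scales, index=ids), labels)
        np.testing.assert_allclose(
            a["net_score"].to_numpy(), b["net_score"].to_numpy(), atol=1e-10
        )

    def test_zero_vector_rejected(self):
        frame = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], index=["z", "ok"])
        with pytest.raises(ValueError):
            manifold.valence_angle_scores(frame, {"z": True, "ok": False})
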