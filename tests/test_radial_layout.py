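import logging

import numpy as np
import pytest

from spectraclust import (
    GroupTable,
    SpectrumSet,
    centroid_polar,
    kmeans_fit,
    layout,
    main_centroid,
    render,
)
from spectraclust.clustering import ClusterModel


def _model(centroids, labels, X=None):
    centroids = np.asarray(centroids, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if X is None:
        X = centroids[labels]
    dist = np.linalg.norm(X - centroids[labels], axis=1)
    return ClusterModel(
        k=centroids.shape[0],
        centroids=centroids,
        labels=labels,
        objective=float((dist**2).sum()),
        distances=dist,
    )


def _sset(X, prefix="s"):
    X = np.asarray(X, dtype=float)
    return SpectrumSet(spectra=X, ids=[f"{prefix}{i}" for i in range(X.shape[0])], n=X.shape[1])


def assert_layout_invariants(radial, k):
    clusters, seqs = radial.clusters, radial.sequences
    # |(x, y)| equals the centroid's distance to the main centroid
    np.testing.assert_allclose(
        np.hypot(clusters["x"], clusters["y"]), clusters["d"], rtol=1e-9, atol=1e-9
    )
    # cluster angles are exactly iota * 2pi / k, all distinct
    np.testing.assert_allclose(clusters["theta"], np.arange(k) * 2 * np.pi / k, atol=0)
    # d non-decreasing in iota
    assert np.all(np.diff(clusters["d"]) >= -1e-12)
    # member offsets from their cluster position equal delta
    cx = clusters.set_index("iota")["x"]
    cy = clusters.set_index("iota")["y"]
    offx = seqs["x"].to_numpy() - cx.loc[seqs["iota"]].to_numpy()
    offy = seqs["y"].to_numpy() - cy.loc[seqs["iota"]].to_numpy()
    np.testing.assert_allclose(np.hypot(offx, offy), seqs["delta"], rtol=1e-9, atol=1e-9)


class TestMainCentroid:
    def test_midpoint(self):
        model = _model([[0.0, 0.0], [2.0, 2.0]], [0, 1])
        np.testing.assert_allclose(main_centroid(model), [1.0, 1.0])

    def test_single_cluster(self):
        model = _model([[3.0, 4.0]], [0])
        np.testing.assert_allclose(main_centroid(model), [3.0, 4.0])

    def test_unit_basis(self):
        model = _model(np.eye(3), [0, 1, 2])
        np.testing.assert_allclose(main_centroid(model), [1 / 3, 1 / 3, 1 / 3])

    def test_unweighted_by_cluster_size(self):
        # 3 points in cluster 0, 1 in cluster 1: still the centroid midpoint
        model = _model([[0.0], [4.0]], [0, 0, 0, 1])
        np.testing.assert_allclose(main_centroid(model), [2.0])


class TestCentroidPolar:
    def test_k8_angles(self):
        rng = np.random.default_rng(0)
        model = _model(rng.normal(size=(8, 3)), np.arange(8))
        _, _, theta = centroid_polar(model, main_centroid(model))
        np.testing.assert_allclose(theta, np.arange(8) * np.pi / 4)

    def test_k1_at_origin(self):
        model = _model([[1.0, 2.0]], [0])
        order, d, theta = centroid_polar(model, main_centroid(model))
        assert list(order) == [0]
        np.testing.assert_allclose(d, [0.0], atol=1e-12)
        np.testing.assert_allclose(theta, [0.0])

    def test_sorted_ascending(self):
        model = _model([[5.0], [2.0], [7.0]], [0, 1, 2])
        order, d, theta = centroid_polar(model, np.array([0.0]))
        assert list(order) == [1, 0, 2]
        np.testing.assert_allclose(d, [2.0, 5.0, 7.0])
        np.testing.assert_allclose(theta, [0.0, 2 * np.pi / 3, 4 * np.pi / 3])

    def test_distance_ties_keep_original_order(self):
        model = _model([[1.0], [-1.0], [2.0]], [0, 1, 2])
        order, _, _ = centroid_polar(model, np.array([0.0]))
        assert list(order) == [0, 1, 2]


class TestLayout:
    def test_sequence_on_its_centroid(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        model = _model(X, [0, 1], X=X)
        radial = layout(model, _sset(X))
        seqs = radial.sequences
        clusters = radial.clusters.set_index("cluster")
        for _, row in seqs.iterrows():
            np.testing.assert_allclose(row["delta"], 0.0, atol=1e-12)
            np.testing.assert_allclose(
                [row["x"], row["y"]],
                [clusters.loc[row["cluster"], "x"], clusters.loc[row["cluster"], "y"]],
                atol=1e-12,
            )

    def test_four_member_angles(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 3))
        centroid = X.mean(axis=0, keepdims=True)
        model = _model(centroid, [0, 0, 0, 0], X=X)
        radial = layout(model, _sset(X))
        assert sorted(radial.sequences["theta"]) == pytest.approx(
            [0.0, np.pi / 2, np.pi, 3 * np.pi / 2]
        )

    def test_member_angle_rank_by_delta(self):
        # ranks are assigned ascending by distance to the centroid
        X = np.array([[3.0], [1.0], [2.0], [0.0]])
        model = _model(np.array([[0.0]]), [0, 0, 0, 0], X=X)
        seqs = layout(model, _sset(X)).sequences
        order_by_theta = seqs.sort_values("theta")["delta"].to_numpy()
        np.testing.assert_allclose(order_by_theta, [0.0, 1.0, 2.0, 3.0])

    def test_invariants_on_fitted_model(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 4))
        sset = _sset(X)
        model = kmeans_fit(sset, k=5, restarts=10, seed=3)
        radial = layout(model, sset)
        assert_layout_invariants(radial, k=5)

    def test_scaling_rigidity(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 3))
        sset = _sset(X)
        model = kmeans_fit(sset, k=3, restarts=10, seed=1)
        a = layout(model, sset)
        c = 3.5
        scaled_model = _model(model.centroids * c, model.labels, X=X * c)
        b = layout(scaled_model, _sset(X * c))
        np.testing.assert_allclose(b.clusters["d"], a.clusters["d"] * c, rtol=1e-9)
        np.testing.assert_allclose(b.sequences["delta"], a.sequences["delta"] * c, rtol=1e-9)
        np.testing.assert_allclose(b.clusters["theta"], a.clusters["theta"], atol=1e-12)
        np.testing.assert_allclose(b.sequences["theta"], a.sequences["theta"], atol=1e-12)

    def test_determinism(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 3))
        sset = _sset(X)
        model = kmeans_fit(sset, k=3, restarts=5, seed=0)
        a = layout(model, sset)
        b = layout(model, sset)
        np.testing.assert_array_equal(a.sequences.to_numpy(), b.sequences.to_numpy())
        np.testing.assert_array_equal(a.clusters.to_numpy(), b.clusters.to_numpy())

    def test_bad_label_rejected(self):
        X = np.zeros((3, 2))
        model = _model(np.zeros((2, 2)), [0, 1, 1], X=X)
        model.labels[0] = 5
        with pytest.raises(ValueError, match="label"):
            layout(model, _sset(X))

    def test_row_mismatch_rejected(self):
        X = np.zeros((3, 2))
        model = _model(np.zeros((2, 2)), [0, 1, 1], X=X)
        with pytest.raises(ValueError, match="cover"):
            layout(model, _sset(np.zeros((4, 2))))


class TestRender:
    @pytest.fixture()
    def small_layout(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        sset = _sset(X)
        model = kmeans_fit(sset, k=2, restarts=5, seed=0)
        return layout(model, sset), sset

    def test_png_and_svg(self, small_layout, tmp_path):
        radial, _ = small_layout
        for ext in ("png", "svg"):
            out = tmp_path / f"plot.{ext}"
            render(radial, path=out)
            assert out.exists() and out.stat().st_size > 0

    def test_with_groups(self, small_layout, tmp_path):
        radial, sset = small_layout
        table = GroupTable.from_mapping({i: ["F1" if j % 2 else "F2"] for j, i in enumerate(sset.ids)}, ["family"])
        out = tmp_path / "plot.png"
        render(radial, groups=table, path=out)
        assert out.exists()

    def test_missing_group_fallback_warns(self, small_layout, tmp_path, caplog):
        radial, sset = small_layout
        table = GroupTable.from_mapping({sset.ids[0]: ["F1"]}, ["family"])
        with caplog.at_level(logging.WARNING):
            render(radial, groups=table, path=tmp_path / "plot.png")
        assert "missing" in caplog.text
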