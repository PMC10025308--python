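import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation
from sklearn.cross_decomposition import PLSRegression

from beesearch.embedding import (
    Ellipsoid,
    fit_pls,
    fit_separatrix,
    fit_separatrix_points,
    group_indicator,
    min_volume_ellipsoid,
    sample_ellipsoid_surface,
    separatrix_in_tile_space,
    signed_distances,
    support_vector_heatmap,
)
from beesearch.features import Grid


class TestPLS:
    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(0)
        n = 40
        y = rng.choice([0.0, 1.0], size=n)
        X = np.column_stack([y, y, rng.normal(scale=0.01, size=(n, 20))])
        model = fit_pls(X, y, 1)
        yhat = model.predict(X).ravel()
        ss_res = np.sum((y - yhat) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_cumulative_variance_nondecreasing_and_complete(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 8))
        Y = rng.normal(size=(15, 2))
        model = fit_pls(X, Y, 14)  # request full rank: truncated to rank
        cv = model.cumulative_variance
        assert np.all(np.diff(cv) >= -1e-12)
        assert cv[-1] == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_matches_independent_nipals(self):
        # single-column Y: SIMPLS and NIPALS provably coincide
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 30))
        Y = rng.normal(size=(20, 1))
        mine = fit_pls(X, Y, 3)
        sk = PLSRegression(n_components=3, scale=False).fit(X, Y)
        x_hat_mine = mine.reconstruct_x()
        x_hat_sk = sk.x_scores_ @ sk.x_loadings_.T + X.mean(axis=0)
        assert np.abs(x_hat_mine - x_hat_sk).max() <= 1e-6

    def test_excess_components_reduced(self):
        rng = np.random.default_rng(3)
        X = np.tile(rng.normal(size=(5, 1)), (1, 6))  # rank-1 X
        Y = rng.normal(size=(5, 1))
        model = fit_pls(X, Y, 4)
        assert model.n_components == 1

    def test_group_indicator(self):
        Y = group_indicator(pd.Series(["A", "B", "A", "C"]))
        assert list(Y.columns) == ["A", "B", "C"]
        np.testing.assert_allclose(Y.sum(axis=1), 1.0)
        np.testing.assert_allclose(Y.sum(axis=0), [2, 1, 1])

    def test_dataframe_names_carried(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("wxyz"))
        model = fit_pls(X, group_indicator(["A"] * 5 + ["B"] * 5), 2)
        assert model.feature_names == list("wxyz")
        assert model.group_names == ["A", "B"]


class TestMinVolumeEllipsoid:
    def test_unit_cube_gives_circumscribed_ball(self):
        corners = np.array(
            [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], float
        )
        e = min_volume_ellipsoid(corners)
        assert e.contains(corners).all()
        w = np.linalg.eigvalsh(e.shape)
        volume = 4.0 / 3.0 * np.pi / np.sqrt(np.prod(w))
        ball = 4.0 / 3.0 * np.pi * (np.sqrt(3.0) / 2.0) ** 3
        assert volume <= ball * (1 + 1e-3)
        np.testing.assert_allclose(e.center, 0.5, atol=1e-6)

    def test_points_on_sphere(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(200, 3))
        pts = 2.5 * v / np.linalg.norm(v, axis=1, keepdims=True) + [1.0, -2.0, 0.5]
        e = min_volume_ellipsoid(pts, tolerance=1e-9)
        np.testing.assert_allclose(e.center, [1.0, -2.0, 0.5], atol=1e-3)
        np.testing.assert_allclose(1.0 / np.sqrt(np.linalg.eigvalsh(e.shape)), 2.5, atol=1e-3)

    def test_repeated_point_degenerate(self):
        pts = np.tile([1.0, 2.0, 3.0], (5, 1))
        e = min_volume_ellipsoid(pts)
        assert e.degenerate
        np.testing.assert_allclose(e.center, [1.0, 2.0, 3.0])
        assert e.contains(pts).all()

    def test_coplanar_points_flagged_and_contained(self):
        rng = np.random.default_rng(6)
        pts = np.column_stack([rng.normal(size=(10, 2)), np.zeros(10)])
        e = min_volume_ellipsoid(pts)
        assert e.degenerate
        assert e.contains(pts, tol=1e-3).all()

    def test_random_clouds_contained(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            pts = rng.normal(size=(rng.integers(4, 30), 3))
            e = min_volume_ellipsoid(pts)
            assert e.contains(pts).all()


class TestSurfaceSampling:
    def test_unit_ball_count_and_radius(self):
        e = Ellipsoid(np.zeros(3), np.eye(3))
        s = sample_ellipsoid_surface(e, 441)
        assert s.shape == (441, 3)
        np.testing.assert_allclose(np.linalg.norm(s, axis=1), 1.0, atol=1e-9)
        assert len(np.unique(s.round(12), axis=0)) == 441

    def test_on_surface_contract(self):
        rng = np.random.default_rng(8)
        e = min_volume_ellipsoid(rng.normal(size=(15, 3)))
        s = sample_ellipsoid_surface(e, 441)
        np.testing.assert_allclose(e.mahalanobis_sq(s), 1.0, atol=1e-9)

    def test_semi_axes_extent(self):
        # axis-aligned ellipsoid with semi-axes (1, 2, 3): max pairwise distance ~ 6
        e = Ellipsoid(np.zeros(3), np.diag([1.0, 1.0 / 4.0, 1.0 / 9.0]))
        s = sample_ellipsoid_surface(e, 441)
        from scipy.spatial.distance import pdist

        assert pdist(s).max() == pytest.approx(6.0, abs=1e-6)


class TestSeparatrix:
    def _ball(self, center, r=1.0):
        return Ellipsoid(np.asarray(center, float), np.eye(3) / r**2)

    def test_two_balls_symmetric(self):
        sep = fit_separatrix([self._ball([0, 0, -5])], [self._ball([0, 0, 5])])
        np.testing.assert_allclose(np.abs(sep.normal), [0, 0, 1], atol=1e-6)
        assert sep.offset == pytest.approx(0.0, abs=1e-6)

    def test_linearly_separable_zero_training_error(self):
        rng = np.random.default_rng(9)
        e1 = min_volume_ellipsoid(rng.normal(size=(10, 3)) - 4)
        e2 = min_volume_ellipsoid(rng.normal(size=(10, 3)) + 4)
        sep = fit_separatrix([e1], [e2], side1_labels=["L"], side2_labels=["R"])
        s1 = sample_ellipsoid_surface(e1)
        s2 = sample_ellipsoid_surface(e2)
        assert (sep.signed_distance(s1) < 0).all()
        assert (sep.signed_distance(s2) > 0).all()
        assert sep.side_of_group == {"L": -1, "R": 1}

    def test_group_set_partitions_api(self):
        # structural adequacy: {R} vs {A..E} and {A,B} vs {C,D,E}
        rng = np.random.default_rng(10)
        ells = {
            g: min_volume_ellipsoid(rng.normal(size=(8, 3)) + mu)
            for g, mu in zip("ABCDER", [-3, -2, 2, 3, 4, -6])
        }
        sep1 = fit_separatrix([ells["R"]], [ells[g] for g in "ABCDE"])
        sep2 = fit_separatrix([ells[g] for g in "AB"], [ells[g] for g in "CDE"])
        assert sep1.normal.shape == (3,) and sep2.normal.shape == (3,)

    def test_rotation_equivariance_of_svm(self):
        rng = np.random.default_rng(11)
        pts = np.vstack([rng.normal(size=(60, 3)) - 2, rng.normal(size=(60, 3)) + 2])
        labels = np.r_[-np.ones(60), np.ones(60)]
        base = fit_separatrix_points(pts, labels)
        R = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        rotated = fit_separatrix_points(pts @ R.T, labels)
        np.testing.assert_allclose(R @ base.normal, rotated.normal, atol=1e-6)
        assert rotated.offset == pytest.approx(base.offset, abs=1e-6)

    def test_signed_distance_zero_on_plane_and_mirroring(self):
        sep = fit_separatrix([self._ball([0, 0, -5])], [self._ball([0, 0, 5])])
        on_plane = np.array([[3.0, -1.0, 0.0]])
        assert sep.signed_distance(on_plane)[0] == pytest.approx(0.0, abs=1e-6)
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(20, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        d1, _ = signed_distances(sep, pts, ["g"] * 20)
        d2, _ = signed_distances(sep, mirrored, ["g"] * 20)
        np.testing.assert_allclose(d1["distance"], -d2["distance"], atol=1e-6)

    def test_signed_distances_pairwise_mes(self):
        sep = fit_separatrix([self._ball([0, 0, -5])], [self._ball([0, 0, 5])])
        scores = np.array([[0, 0, z] for z in [-3, -2.5, -2, 2, 2.5, 3.0]])
        df, pairwise = signed_distances(sep, scores, ["lo"] * 3 + ["hi"] * 3)
        assert pairwise[("lo", "hi")].delta == 0.5
        assert df.groupby("group")["distance"].median()["hi"] > 0


def test_end_to_end_signed_distance_recovery():
    """Graded edge bias (weights 0 / 0.3 / 0.6, 12 bees per group) is
    recovered by the heat-map PLS + separatrix embedding: the extreme
    groups' signed distances reach Δmes ≥ 0.4 in ≥ 90% of 20 replicate
    cohorts."""
    from beesearch.features import heatmap_matrix
    from beesearch.pipeline import make_fixture
    from beesearch.preprocess import resample_cohort
    from beesearch.simulator import BiasConfig, GroupSpec, SimulatorConfig, generate_cohort

    landscape = make_fixture("test-area")
    cfg = SimulatorConfig()
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        spec = [
            GroupSpec("W0", 12, cfg),
            GroupSpec("W30", 12, cfg, BiasConfig("E1", 0.3)),
            GroupSpec("W60", 12, cfg, BiasConfig("E1", 0.6)),
        ]
        cohort = resample_cohort(generate_cohort(spec, landscape, seed=4000 + rep))
        X, groups = heatmap_matrix(cohort)
        model = fit_pls(X, group_indicator(groups), 3)
        ells = {
            g: min_volume_ellipsoid(model.scores[(groups == g).to_numpy()])
            for g in ("W0", "W60")
        }
        sep = fit_separatrix([ells["W0"]], [ells["W60"]])
        _, pairwise = signed_distances(sep, model.scores, groups)
        hits += pairwise[("W0", "W60")].delta >= 0.4
    assert hits / n_rep >= 0.9


class TestSupportVectorHeatmap:
    def test_single_nonzero_tile(self):
        grid = Grid()
        v = np.zeros(grid.n_tiles)
        v[9 * 19 + 9] = -0.25  # tile 99
        m = support_vector_heatmap(v, grid)
        assert m[9, 9] == -1.0
        assert np.abs(m).sum() == 1.0

    def test_normalization_and_roundtrip(self):
        rng = np.random.default_rng(13)
        v = rng.normal(size=342)
        m = support_vector_heatmap(v)
        assert np.abs(m).max() == pytest.approx(1.0)
        np.testing.assert_allclose(m.ravel() * np.abs(v).max(), v)

    def test_all_zero_vector(self):
        m = support_vector_heatmap(np.zeros(342))
        assert np.all(m == 0.0)

    def test_separatrix_pullback_shape(self):
        rng = np.random.default_rng(14)
        X = rng.dirichlet(np.ones(342), size=24)
        groups = pd.Series(["A"] * 12 + ["B"] * 12)
        model = fit_pls(X, group_indicator(groups), 3)
        e1 = min_volume_ellipsoid(model.scores[:12])
        e2 = min_volume_ellipsoid(model.scores[12:])
        sep = fit_separatrix([e1], [e2])
        v = separatrix_in_tile_space(sep, model)
        assert v.shape == (342,)
        assert support_vector_heatmap(v).shape == (18, 19)
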