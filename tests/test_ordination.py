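"""Ordination engine: transforms, NMDS, PERMANOVA, PCNM, pRDA, varpart.

Cross-check values frozen from an independent run of vegan 2.7 (rda,
adonis2, pcnm) on the same fixtures.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from streamimpact import ordination as o

# vegan::pcnm axis 1 for 20 equidistant points on a line (unit spacing)
VEGAN_PCNM1 = np.array([
    -0.090963, -0.173844, -0.241278, -0.287274, -0.307744, -0.300869,
    -0.267261, -0.209906, -0.133899, -0.045995, 0.045995, 0.133899,
    0.209906, 0.267261, 0.300869, 0.307744, 0.287274, 0.241278,
    0.173844, 0.090963,
])


class TestHellinger:
    def test_known_row(self):
        out = o.hellinger(np.array([[1.0, 0.0, 3.0]]))
        np.testing.assert_allclose(out[0], [0.5, 0.0, np.sqrt(0.75)], atol=1e-12)

    def test_rows_have_unit_sum_of_squares(self, rng):
        X = rng.integers(0, 50, size=(10, 8)) + 1
        out = o.hellinger(X)
        np.testing.assert_allclose((out**2).sum(axis=1), 1.0)

    def test_max_distance_between_compositions(self):
        out = o.hellinger(np.array([[5.0, 0.0], [0.0, 9.0]]))
        assert np.linalg.norm(out[0] - out[1]) == pytest.approx(np.sqrt(2))

    def test_zero_row_named(self):
        df = pd.DataFrame([[1, 2], [0, 0]], index=["good", "empty"])
        with pytest.raises(ValueError, match="empty"):
            o.hellinger(df)


class TestPCA:
    def test_collinear_data_single_component(self, rng):
        t = rng.normal(size=50)
        X = np.column_stack([t, 2 * t])
        res = o.pca(X)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_isotropic_cloud_splits_evenly(self, rng):
        X = rng.normal(size=(20_000, 2))
        res = o.pca(X)
        assert res.proportion_explained[0] == pytest.approx(0.5, abs=0.03)

    def test_reconstruction_identity(self, rng):
        X = rng.normal(size=(15, 4))
        res = o.pca(X)
        rec = res.scores.to_numpy() @ res.loadings.to_numpy().T + res.extras["mean"]
        np.testing.assert_allclose(rec, X, atol=1e-10)

    def test_constant_column_with_scaling_is_error(self):
        X = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="b"):
            o.pca(X, scale=True)


class TestNMDS:
    def test_perfect_planar_embedding(self, rng):
        X = rng.normal(size=(8, 2))
        D = squareform(pdist(X))
        res = o.nmds(D, k=2, n_starts=4, seed=1)
        assert res.stress < 1e-6
        assert res.converged

    def test_stress_descends_within_a_start(self, rng):
        D = squareform(pdist(rng.normal(size=(10, 4))))
        res = o.nmds(D, k=2, n_starts=6, seed=3)
        h = res.extras["stress_history"]
        assert np.all(np.diff(h) <= 1e-8)

    def test_stress_scale_invariance(self, rng):
        D = squareform(pdist(rng.normal(size=(9, 3))))
        a = o.nmds(D, k=2, n_starts=5, seed=2)
        b = o.nmds(3.0 * D, k=2, n_starts=5, seed=2)
        assert a.stress == pytest.approx(b.stress, abs=1e-12)

    def test_seed_reproducibility(self, rng):
        D = squareform(pdist(rng.normal(size=(9, 3))))
        a = o.nmds(D, k=2, n_starts=5, seed=7)
        b = o.nmds(D, k=2, n_starts=5, seed=7)
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            o.nmds(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestPermanova:
    def test_exact_enumeration_on_two_pairs(self):
        """Tight, well-separated pairs: p equals the exhaustive value 2/6."""
        pts = np.array([[0, 0], [0.1, 0], [10, 0], [10.1, 0]], dtype=float)
        D = squareform(pdist(pts))
        res = o.permanova(D, ["a", "a", "b", "b"], n_perm=49_999, seed=0)
        assert res.p_value == pytest.approx(2 / 6, abs=0.01)

    def test_matches_vegan_adonis(self, rng):
        """Frozen cross-check: vegan adonis2 gives F = 4.2687, R2 = 0.48681
        on this seeded fixture."""
        gen = np.random.default_rng(42)
        gen.normal(size=(10, 2)); gen.normal(size=(10, 1))  # fixture alignment
        for _ in range(4):
            gen.normal(size=2); gen.normal(size=10)
        pts = gen.normal(size=(12, 3))
        pts[4:8] += 1.5
        D = squareform(pdist(pts))
        res = o.permanova(D, np.repeat(["a", "b", "c"], 4), n_perm=99, seed=1)
        assert res.pseudo_f == pytest.approx(4.268678, abs=1e-5)
        assert res.r2 == pytest.approx(0.48681, abs=1e-5)
        assert res.df_among == 2 and res.df_within == 9

    def test_matches_scikit_bio(self, rng):
        """Independent-library cross-check of the pseudo-F on a random
        fixture (p-values agree only stochastically, F is deterministic)."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        pts = rng.normal(size=(14, 3))
        pts[7:] += 0.8
        D = squareform(pdist(pts))
        groups = ["a"] * 7 + ["b"] * 7
        ours = o.permanova(D, groups, n_perm=99, seed=0)
        theirs = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(D), groups, permutations=99, seed=0
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], abs=1e-10)

    def test_identical_points_flagged_degenerate(self):
        D = np.zeros((6, 6))
        res = o.permanova(D, ["a"] * 3 + ["b"] * 3, n_perm=9, seed=0)
        assert res.degenerate
        assert np.isnan(res.pseudo_f)

    def test_group_size_validation(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError):
            o.permanova(D, ["a", "a", "b"], n_perm=9)


class TestPCNM:
    def test_matches_vegan_on_transect(self):
        coords = np.column_stack([np.arange(20.0), np.zeros(20)])
        vecs, vals = o.pcnm(coords)
        r = np.corrcoef(vecs[:, 0], VEGAN_PCNM1)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_axes_are_ordered_sinusoids(self):
        """On an equidistant transect the spatial eigenvectors approximate
        cosines of increasing frequency, in eigenvalue order."""
        n = 20
        vecs, _ = o.pcnm(np.column_stack([np.arange(float(n)), np.zeros(n)]))
        i = np.arange(n)
        for k in range(4):
            cors = [
                abs(np.corrcoef(vecs[:, k], np.cos(np.pi * m * (i + 0.5) / n))[0, 1])
                for m in range(1, 10)
            ]
            assert int(np.argmax(cors)) + 1 == k + 1
            assert max(cors) > 0.8

    def test_orthogonal_centered_bounded_count(self, rng):
        P = rng.normal(size=(15, 2))
        vecs, vals = o.pcnm(P)
        assert vecs.shape[1] <= 14
        np.testing.assert_allclose(vecs.T @ vecs, np.eye(vecs.shape[1]), atol=1e-8)
        np.testing.assert_allclose(vecs.sum(axis=0), 0.0, atol=1e-8)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            o.pcnm(np.zeros((5, 2)))


class TestPartialRDA:
    def test_matches_vegan_rda(self):
        """Frozen cross-check: vegan rda gives R2 = 0.8912197,
        adjR2 = 0.8601397, eigenvalues (2.9109, 0.4908269); with the
        conditioning block the constrained fraction is 0.8733592."""
        gen = np.random.default_rng(42)
        X = gen.normal(size=(10, 2))
        Z = gen.normal(size=(10, 1))
        Y = np.column_stack(
            [X @ gen.normal(size=2) + 0.5 * gen.normal(size=10) for _ in range(4)]
        )
        res = o.rda(Y, X, n_perm=49, seed=1)
        assert res.r2 == pytest.approx(0.8912197, abs=1e-6)
        assert res.adj_r2 == pytest.approx(0.8601397, abs=1e-6)
        np.testing.assert_allclose(res.eigenvalues, [2.9109, 0.4908269], atol=1e-4)
        part = o.partial_rda(Y, X, Z=Z, n_perm=49, seed=1)
        assert part.r2 == pytest.approx(0.8733592, abs=1e-6)

    def test_empty_conditioning_equals_plain_rda(self, rng):
        Y = rng.normal(size=(12, 5))
        X = rng.normal(size=(12, 2))
        a = o.partial_rda(Y, X, Z=None, n_perm=29, seed=3)
        b = o.rda(Y, X, n_perm=29, seed=3)
        assert a.r2 == pytest.approx(b.r2)
        np.testing.assert_allclose(a.scores, b.scores)

    def test_exact_linear_response_fully_constrained(self, rng):
        X = rng.normal(size=(15, 2))
        Y = X @ rng.normal(size=(2, 6))
        res = o.rda(Y, X, n_perm=19, seed=0)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_independent_predictors_not_significant(self, rng):
        """X unrelated to Y: adjusted R2 near zero, permutation p large in
        the overwhelming majority of simulations."""
        hits_p, adj = 0, []
        n_sim = 60
        for _ in range(n_sim):
            Y = rng.normal(size=(20, 6))
            X = rng.normal(size=(20, 2))
            res = o.rda(Y, X, n_perm=99, seed=int(rng.integers(2**31 - 1)))
            hits_p += res.p_value > 0.05
            adj.append(res.adj_r2)
        assert hits_p >= 0.85 * n_sim
        assert abs(np.mean(adj)) < 0.05

    def test_rank_deficiency_names_columns(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        X["b"] = 2 * X["a"]
        Y = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="rank-deficient"):
            o.partial_rda(Y, X, n_perm=9)


class TestVariationPartitioning:
    def test_orthogonal_blocks_share_nothing(self, rng):
        n = 60
        X1 = rng.normal(size=(n, 2))
        X2 = rng.normal(size=(n, 2))
        Y = X1 @ rng.normal(size=(2, 4)) + X2 @ rng.normal(size=(2, 4))
        vp = o.variation_partitioning(Y, [X1, X2], n_perm=29, seed=0)
        assert abs(vp.fractions["X1&X2"]) < 0.05
        assert vp.fractions["X1|X2"] > 0.2

    def test_duplicated_block_is_all_shared(self, rng):
        n = 30
        X1 = rng.normal(size=(n, 2))
        Y = X1 @ rng.normal(size=(2, 4)) + 0.2 * rng.normal(size=(n, 4))
        vp = o.variation_partitioning(Y, [X1, X1.copy()], n_perm=9, seed=0)
        assert abs(vp.fractions["X1|X2"]) < 0.05
        assert vp.fractions["X1&X2"] > 0.5

    def test_inclusion_exclusion_identity(self, rng):
        n = 25
        blocks = [rng.normal(size=(n, 2)) for _ in range(3)]
        Y = rng.normal(size=(n, 5))
        vp = o.variation_partitioning(Y, blocks, n_perm=9, seed=1)
        assert sum(vp.fractions.values()) == pytest.approx(vp.total_adj_r2, abs=1e-10)
        assert vp.residual == pytest.approx(1 - vp.total_adj_r2, abs=1e-12)

    def test_too_many_blocks(self, rng):
        with pytest.raises(ValueError):
            o.variation_partitioning(rng.normal(size=(10, 2)),
                                     [rng.normal(size=(10, 1))] * 4)


class TestForwardSelect:
    def test_single_true_driver_is_selected(self, rng):
        hits = 0
        n_sim = 40
        for _ in range(n_sim):
            X = rng.normal(size=(30, 4))
            Y = np.outer(X[:, 0], rng.normal(size=3)) + 0.3 * rng.normal(size=(30, 3))
            sel = o.forward_select(Y, pd.DataFrame(X, columns=list("abcd")),
                                   alpha=0.05, n_perm=99,
                                   seed=int(rng.integers(2**31 - 1)))
            hits += sel["selected"] == ["a"]
        assert hits >= round(0.85 * n_sim)

    def test_alpha_one_selects_everything_in_gain_order(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        Y = rng.normal(size=(25, 2))
        sel = o.forward_select(Y, X, alpha=1.01, n_perm=19, seed=0)
        assert sorted(sel["selected"]) == ["a", "b", "c"]


class TestCollinearityFilter:
    def test_duplicate_column_dropped(self, rng):
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=20)})
        kept, report = o.collinearity_filter(X, r_max=0.6)
        assert kept == ["a", "c"]
        assert report[0]["dropped"] == "b"

    def test_orthogonal_columns_all_kept(self):
        X = pd.DataFrame(np.eye(4), columns=list("abcd"))
        kept, report = o.collinearity_filter(X, r_max=0.6)
        assert kept == list("abcd") and report == []

    def test_priority_order_decides(self, rng):
        z = rng.normal(size=200)
        x1 = z + 0.3 * rng.normal(size=200)
        x2 = z + 0.3 * rng.normal(size=200)          # r(1,2) ~ 0.9
        x3 = rng.normal(size=200)                     # r(1,3) ~ 0
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        kept, _ = o.collinearity_filter(X, r_max=0.6)
        assert kept == ["x1", "x3"]
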