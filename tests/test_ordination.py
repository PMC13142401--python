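import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from thermobgc import ordination as ordn


def _frame(arr, prefix="y"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestPartialRDA:
    def test_condition_equal_to_constraint_leaves_nothing(self, rng):
        x = pd.Series(rng.normal(size=20), name="x")
        Y = _frame(np.outer(x, [1.0, -2.0]) + rng.normal(scale=0.1, size=(20, 2)))
        res = ordn.partial_rda(Y, x.to_frame(), Z=x.to_frame("z"), n_permutations=0)
        assert res.r_squared == pytest.approx(0.0, abs=1e-10)

    def test_exact_linear_response_r2_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(15, 2)), columns=["a", "b"])
        Y = _frame(X.to_numpy() @ rng.normal(size=(2, 4)))
        res = ordn.partial_rda(Y, X, n_permutations=0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_r2_matches_hat_matrix_oracle(self, rng):
        n = 10
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        Z = pd.Series(rng.normal(size=n), name="depth")
        Y = _frame(rng.normal(size=(n, 5)))
        res = ordn.partial_rda(Y, X, Z=Z, n_permutations=0)
        # oracle: explicit projection matrices
        Zi = np.column_stack([np.ones(n), Z])
        Hz = Zi @ np.linalg.pinv(Zi.T @ Zi) @ Zi.T
        Yr = (np.eye(n) - Hz) @ Y.to_numpy()
        Xr = (np.eye(n) - Hz) @ X.to_numpy()
        Hx = Xr @ np.linalg.pinv(Xr.T @ Xr) @ Xr.T
        r2 = np.sum((Hx @ Yr) ** 2) / np.sum(Yr**2)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_collinear_constraint_dropped_with_name(self, rng):
        x = rng.normal(size=12)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        Y = _frame(rng.normal(size=(12, 3)))
        res = ordn.partial_rda(Y, X, n_permutations=0)
        assert res.dropped_terms == ["b"]

    def test_marginal_term_of_duplicated_constraint_is_zero(self, rng):
        x = rng.normal(size=14)
        X = pd.DataFrame({"a": x, "b": x + rng.normal(scale=1e-13, size=14)})
        Y = _frame(rng.normal(size=(14, 3)))
        res = ordn.partial_rda(Y, X, n_permutations=19, by_margin=True)
        assert any(t.statistic == 0.0 for t in res.terms.values())

    def test_permutation_p_detects_real_effect(self, rng):
        g = np.repeat([0.0, 1.0], 10)
        Y = _frame(np.outer(g, [2.0, -1.5]) + rng.normal(scale=0.3, size=(20, 2)))
        res = ordn.partial_rda(Y, pd.DataFrame({"g": g}), n_permutations=199, seed=1)
        assert res.overall.p_value == pytest.approx(1 / 200)


class TestPermanova:
    def test_euclidean_pseudo_f_equals_raw_coordinate_f(self, rng):
        """Distance-based pseudo-F equals the classical trace F on raw data."""
        Y = rng.normal(size=(18, 4))
        g = pd.Series(np.repeat(list("abc"), 6), name="g")
        overall, _ = ordn.permanova(pd.DataFrame(Y), g, n_permutations=19, seed=0)
        # direct MANOVA-trace computation from coordinates
        X, _, _ = ordn.design_matrix(g.to_frame())
        Xi = np.column_stack([np.ones(18), X])
        H = Xi @ np.linalg.pinv(Xi.T @ Xi) @ Xi.T
        Yc = Y - Y.mean(axis=0)
        ss_fit = np.sum((H @ Yc) ** 2)
        ss_res = np.sum(((np.eye(18) - H) @ Yc) ** 2)
        f = (ss_fit / 2) / (ss_res / 15)
        assert overall.statistic == pytest.approx(f, abs=1e-8)

    def test_permutation_p_close_to_exhaustive_enumeration(self, rng):
        """n=6, two groups of 3: 999-draw p within Monte-Carlo error of exact."""
        Y = pd.DataFrame(rng.normal(size=(6, 3)) + np.repeat([0, 1.5], 3)[:, None])
        g = pd.Series(list("aaabbb"), name="g")
        overall, _ = ordn.permanova(Y, g, n_permutations=999, seed=3)

        D = squareform(pdist(Y))
        G = ordn.gower_center(D)

        def f_of(labels):
            X, _, _ = ordn.design_matrix(pd.Series(labels, name="g").to_frame())
            Xi = np.column_stack([np.ones(6), X])
            H = Xi @ np.linalg.pinv(Xi.T @ Xi) @ Xi.T
            ss_x = np.sum((H - np.ones((6, 6)) / 6) * G)
            ss_r = np.sum((np.eye(6) - H) * G)
            return (ss_x / 1) / (ss_r / 4)

        f_obs = f_of(list("aaabbb"))
        stats = [
            f_of(["a" if i in combo else "b" for i in range(6)])
            for combo in itertools.combinations(range(6), 3)
        ]
        p_exact = np.mean([s >= f_obs - 1e-12 for s in stats])
        mc_se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(overall.p_value - p_exact) <= 4 * mc_se + 2e-3

    def test_matches_scikit_bio(self, rng):
        """Cross-check statistic against the independent skbio implementation."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova

        Y = rng.normal(size=(15, 4)) + np.repeat([0, 1, 2], 5)[:, None] * 0.8
        D = squareform(pdist(Y))
        g = list("aaaaabbbbbccccc")
        ours, _ = ordn.permanova(D, pd.Series(g, name="g"), is_distance=True,
                                 n_permutations=99, seed=0)
        theirs = sk_permanova(DistanceMatrix(D), grouping=g, permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"], abs=1e-8)

    def test_duplicated_marginal_term_has_zero_ss(self, rng):
        Y = pd.DataFrame(rng.normal(size=(12, 3)))
        x = rng.normal(size=12)
        model = pd.DataFrame({"a": x, "b": x})
        _, terms = ordn.permanova(Y, model, n_permutations=19, by_margin=True, seed=0)
        assert min(t.statistic for t in terms.values()) == 0.0

    def test_minimal_p_is_one_over_nperm_plus_one(self, rng):
        Y = pd.DataFrame(np.repeat([[0.0, 0.0], [10.0, 10.0]], 5, axis=0)
                         + rng.normal(scale=0.01, size=(10, 2)))
        g = pd.Series(list("aaaaabbbbb"))
        overall, _ = ordn.permanova(Y, g, n_permutations=199, seed=0)
        assert overall.p_value == pytest.approx(1 / 200)


class TestAnosim:
    def test_perfect_separation_r_is_one(self):
        pts = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
        D = squareform(pdist(pts))
        res = ordn.anosim(D, ["a", "a", "a", "b", "b", "b"], n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_random_labels_center_r_near_zero(self, rng):
        D = squareform(pdist(rng.normal(size=(16, 3))))
        rs = []
        for i in range(50):
            g = rng.permutation(np.repeat(["a", "b"], 8))
            rs.append(ordn.anosim(D, g, n_permutations=0, seed=i).statistic)
        assert abs(np.mean(rs)) < 0.05

    def test_five_point_hand_computed_ranks(self):
        # points on a line at 0, 1, 2, 10, 11; groups {0,1,2} and {10,11}
        pts = np.array([[0.0], [1.0], [2.0], [10.0], [11.0]])
        D = squareform(pdist(pts))
        g = ["a", "a", "a", "b", "b"]
        # pairwise distances: within a: 1,2,1 ; within b: 1 ; between: 10,11,9,10,8,9
        # ranks (mid for ties): d=1 ->(1+2+3)/3=2 each; d=2 -> 4; d=8 -> 5; 9->6.5; 10->8.5; 11->10
        mean_within = (2 + 4 + 2 + 2) / 4
        mean_between = (5 + 6.5 + 6.5 + 8.5 + 8.5 + 10) / 6
        expected = (mean_between - mean_within) / (10 / 2)
        res = ordn.anosim(D, g, n_permutations=0, seed=0)
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, anosim as sk_anosim

        D = squareform(pdist(rng.normal(size=(12, 3))))
        g = list("aaaabbbbcccc")
        ours = ordn.anosim(D, g, n_permutations=99, seed=0)
        theirs = sk_anosim(DistanceMatrix(D), grouping=g, permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"], abs=1e-10)

    def test_singleton_group_errors(self):
        D = squareform(pdist(np.arange(4.0)[:, None]))
        with pytest.raises(ValueError, match=">= 2 members"):
            ordn.anosim(D, ["a", "b", "b", "b"], n_permutations=9)


class TestBetadisper:
    def test_coincident_group_has_zero_dispersion(self):
        pts = np.array([[0.0, 0], [0, 0], [0, 0], [1, 1], [2, 2], [3, 3]])
        D = squareform(pdist(pts))
        _, dists = ordn.betadisper(D, ["a", "a", "a", "b", "b", "b"], n_permutations=9)
        assert np.allclose(dists.iloc[:3], 0.0, atol=1e-10)

    def test_mirror_image_groups_equal_dispersion(self, rng):
        a = rng.normal(size=(10, 2))
        pts = np.vstack([a, -a + 10])
        D = squareform(pdist(pts))
        res, _ = ordn.betadisper(D, np.repeat(["a", "b"], 10), n_permutations=199, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value > 0.5

    def test_pcoa_embedding_reproduces_euclidean_distances(self, rng):
        pts = rng.normal(size=(12, 4))
        D = squareform(pdist(pts))
        real, imag = ordn.pcoa_embedding(D)
        assert imag.shape[1] == 0  # Euclidean input: no negative eigenvalues
        D2 = squareform(pdist(real))
        np.testing.assert_allclose(D2, D, atol=1e-8)


class TestVarpart:
    def test_identical_blocks_have_no_unique_fractions(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 2)), columns=["a", "b"])
        Y = _frame(X.to_numpy() @ rng.normal(size=(2, 4)) + rng.normal(scale=0.5, size=(25, 4)))
        part = ordn.varpart(Y, X, X.copy(), n_permutations=9, seed=0)
        assert part.unique_x1 == pytest.approx(0.0, abs=1e-10)
        assert part.unique_x2 == pytest.approx(0.0, abs=1e-10)
        assert part.shared == pytest.approx(part.adj_r2_x1, abs=1e-10)

    def test_adjusted_r2_formula_value(self):
        # R^2 = 0.5, n = 11, p = 1 -> 1 - 0.5 * 10 / 9 = 0.4444...
        assert ordn.adjusted_r2(0.5, 11, 1) == pytest.approx(4.0 / 9.0, abs=1e-12)

    def test_identity_fractions_reconstruct_block_r2(self, rng):
        Y = _frame(rng.normal(size=(30, 5)))
        X1 = pd.DataFrame(rng.normal(size=(30, 2)))
        X2 = pd.DataFrame(rng.normal(size=(30, 3)))
        part = ordn.varpart(Y, X1, X2, n_permutations=9, seed=0)
        assert part.unique_x1 + part.shared == pytest.approx(part.adj_r2_x1, abs=1e-10)
        assert part.unique_x2 + part.shared == pytest.approx(part.adj_r2_x2, abs=1e-10)

    def test_orthogonal_design_recovers_structure(self):
        """Y built from X1 only: unique-X2 and shared fractions are near zero."""
        rngs = [np.random.default_rng(s) for s in range(30)]
        b_hits = 0
        c_small = 0
        for r in rngs:
            X1 = pd.DataFrame(r.normal(size=(40, 2)))
            X2 = pd.DataFrame(r.normal(size=(40, 2)))
            Y = _frame(X1.to_numpy() @ r.normal(size=(2, 5)) + r.normal(scale=0.5, size=(40, 5)))
            part = ordn.varpart(Y, X1, X2, n_permutations=0, seed=0)
            b_hits += abs(part.unique_x2) < 0.05
            c_small += abs(part.shared) < 0.05
        assert b_hits >= 28 and c_small >= 28

    def test_too_many_predictors_error(self, rng):
        Y = _frame(rng.normal(size=(5, 2)))
        X = pd.DataFrame(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="adjusted R"):
            ordn.varpart(Y, X, X, n_permutations=0)


class TestClusterSites:
    def test_three_planted_blobs_select_k3_and_recover_labels(self, rng):
        centers = np.array([[0, 0], [6, 0], [0, 6]])
        truth = np.repeat([0, 1, 2], 20)
        pts = centers[truth] + rng.normal(scale=0.4, size=(60, 2))
        scores = pd.DataFrame(pts, columns=["RDA1", "RDA2"])
        res = ordn.cluster_sites(scores, seed=0)
        assert res.chosen_k == 3
        agree = pd.crosstab(res.labels, truth).max(axis=1).sum() / 60
        assert agree == pytest.approx(1.0)

    def test_identical_points_reported_degenerate(self):
        scores = pd.DataFrame(np.zeros((10, 2)))
        res = ordn.cluster_sites(scores, k_range=(2, 4))
        assert res.degenerate and res.silhouette_best_k is None

    def test_labels_invariant_to_axis_sign_flip(self, rng):
        pts = rng.normal(size=(30, 3)) + np.repeat([[0], [5]], 15, axis=0)
        a = ordn.cluster_sites(pd.DataFrame(pts), k_range=(2, 4), seed=0)
        b = ordn.cluster_sites(pd.DataFrame(pts * np.array([-1, 1, -1])), k_range=(2, 4), seed=0)
        assert (pd.crosstab(a.labels, b.labels) > 0).sum().sum() == len(set(a.labels))

    def test_invalid_k_range_errors(self, rng):
        with pytest.raises(ValueError, match="k_range"):
            ordn.cluster_sites(pd.DataFrame(rng.normal(size=(5, 2))), k_range=(2, 10))


class TestAxisDepthCheck:
    def test_monotone_axis_rho_one(self):
        depth = pd.Series([1.0, 2, 3, 4, 5, 6], index=list("abcdef"))
        scores = pd.DataFrame({"RDA1": np.exp(depth), "RDA2": -depth}, index=depth.index)
        out = ordn.axis_depth_check(scores, depth)
        assert out.loc["RDA1", "rho"] == pytest.approx(1.0)
        assert out.loc["RDA2", "rho"] == pytest.approx(-1.0)

    def test_six_point_case_matches_exhaustive_rank_formula(self, rng):
        v = rng.normal(size=6)
        d = rng.normal(size=6)
        scores = pd.DataFrame({"RDA1": v})
        out = ordn.axis_depth_check(scores, pd.Series(d))
        rv, rd = sps.rankdata(v), sps.rankdata(d)
        expected = np.corrcoef(rv, rd)[0, 1]
        assert out.loc["RDA1", "rho"] == pytest.approx(expected, abs=1e-12)

    def test_constant_axis_reported_undefined(self):
        scores = pd.DataFrame({"RDA1": np.ones(5)})
        out = ordn.axis_depth_check(scores, pd.Series(np.arange(5.0)))
        assert np.isnan(out.loc["RDA1", "rho"]) and out.loc["RDA1", "note"] == "constant input"


def test_permutation_pvalues_reproducible(rng):
    Y = pd.DataFrame(rng.normal(size=(12, 3)))
    g = pd.Series(np.repeat(["a", "b"], 6))
    p1, _ = ordn.permanova(Y, g, n_permutations=99, seed=7)
    p2, _ = ordn.permanova(Y, g, n_permutations=99, seed=7)
    assert p1.p_value == p2.p_value and p1.statistic == p2.statistic
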