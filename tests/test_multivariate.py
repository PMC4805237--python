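"""PCA, MANOVA, Mahalanobis screen, clustering, LDA, rank correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

import cuckoomorph.multivariate as mv
from cuckoomorph import specimen_data as sd

TRAITS3 = ("t1", "t2", "t3")


def _frame(X, traits=TRAITS3, **cols):
    df = pd.DataFrame(np.asarray(X, dtype=float), columns=list(traits))
    for k, v in cols.items():
        df[k] = v
    return df


class TestPCAComposite:
    def test_perfectly_correlated_traits_load_on_one_axis(self):
        base = np.linspace(0, 1, 30)
        df = _frame(np.column_stack([base, 2 * base + 1, -3 * base]))
        res = mv.pca_composite(df, TRAITS3)
        assert res.variance_ratio[0] == pytest.approx(1.0)

    def test_equicorrelated_closed_form(self, exact_corr_sampler):
        """Sample correlation exactly 0.5 everywhere: PC1 share = (1+2*rho)/3."""
        rho = 0.5
        R = np.full((3, 3), rho)
        np.fill_diagonal(R, 1.0)
        df = _frame(exact_corr_sampler(R, n=200, seed=4))
        res = mv.pca_composite(df, TRAITS3)
        assert res.variance_ratio[0] == pytest.approx((1 + 2 * rho) / 3, abs=1e-9)

    def test_variance_ratios_sum_to_one_and_loadings_orthonormal(self, paper_table):
        res = mv.pca_composite(paper_table, sd.BILL_TRAITS)
        assert res.variance_ratio.sum() == pytest.approx(1.0)
        V = res.loadings.to_numpy()
        assert np.allclose(V.T @ V, np.eye(3), atol=1e-10)

    def test_pc1_positively_correlated_with_bill_depth(self, paper_table):
        res = mv.pca_composite(paper_table, sd.BILL_TRAITS)
        assert res.loading_correlations["bill_depth_mm"] > 0

    def test_pc1_share_at_least_third_under_nonnegative_correlation(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            L = rng.random((3, 3))
            X = rng.standard_normal((80, 3)) @ L.T  # positively mixed factors
            corr = np.corrcoef(X, rowvar=False)
            if (corr < 0).any():
                continue
            res = mv.pca_composite(_frame(X), TRAITS3)
            assert res.variance_ratio[0] >= 1 / 3 - 1e-12

    def test_constant_column_rejected(self):
        df = _frame(np.column_stack([np.arange(5.0), np.ones(5), np.arange(5.0)]))
        with pytest.raises(mv.DegenerateInputError, match="t2"):
            mv.pca_composite(df, TRAITS3)


class TestPillaiManova:
    @staticmethod
    def _mirrored(n_per_cell=6, seed=0):
        """Sexes with identical mean vectors inside every subspecies."""
        rng = np.random.default_rng(seed)
        frames = []
        for ssp, shift in (("a", 0.0), ("b", 3.0)):
            base = rng.standard_normal((n_per_cell, 3)) + shift
            for sex in ("male", "female"):
                frames.append(_frame(base, subspecies=ssp, sex=sex))
        return pd.concat(frames, ignore_index=True)

    def test_identical_adjusted_means_give_zero_trace(self):
        res = mv.pillai_manova(self._mirrored(), TRAITS3, "sex", "subspecies")
        assert res["pillai"] == pytest.approx(0.0, abs=1e-10)
        assert res["p"] > 0.99

    def test_matches_eigenvalue_oracle(self):
        """V = sum lambda_i/(1+lambda_i) over eigenvalues of H E^-1."""
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 2))
        g = np.repeat(["male", "female"], 20)
        X[g == "male"] += [0.8, -0.3]
        df = _frame(X, traits=("t1", "t2"), sex=g)
        res = mv.pillai_manova(df, ("t1", "t2"), "sex", covariate_factor=None)
        # independent oracle: explicit group-mean cross-products
        grand = X.mean(0)
        H = sum(
            (X[g == lev].shape[0])
            * np.outer(X[g == lev].mean(0) - grand, X[g == lev].mean(0) - grand)
            for lev in ("male", "female")
        )
        E = sum(
            (X[g == lev] - X[g == lev].mean(0)).T @ (X[g == lev] - X[g == lev].mean(0))
            for lev in ("male", "female")
        )
        lam = np.linalg.eigvals(H @ np.linalg.inv(E)).real
        assert res["pillai"] == pytest.approx(float(np.sum(lam / (1 + lam))), abs=1e-10)

    def test_matches_statsmodels_adjusted_for_subspecies(self, paper_table):
        statsmodels = pytest.importorskip("statsmodels.multivariate.manova")
        tbl = paper_table[paper_table.sex != "unknown"]
        res = mv.pillai_manova(tbl, sd.BILL_TRAITS, "sex", "subspecies")
        man = statsmodels.MANOVA.from_formula(
            "bill_length_mm + bill_width_mm + bill_depth_mm ~ C(subspecies) + C(sex)",
            data=tbl,
        ).mv_test()
        frame = man.results["C(sex)"]["stat"]
        assert res["pillai"] == pytest.approx(frame.loc["Pillai's trace", "Value"], abs=1e-8)
        assert res["approx_F"] == pytest.approx(frame.loc["Pillai's trace", "F Value"], rel=1e-6)
        assert res["p"] == pytest.approx(frame.loc["Pillai's trace", "Pr > F"], abs=1e-8)

    def test_requires_two_populated_levels(self):
        df = _frame(np.random.default_rng(0).standard_normal((6, 3)),
                    sex=["male"] * 6, subspecies=["a"] * 6)
        with pytest.raises(ValueError, match="levels"):
            mv.pillai_manova(df, TRAITS3, "sex", "subspecies")

    def test_collinear_traits_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(20)
        df = _frame(np.column_stack([x, 2 * x, rng.standard_normal(20)]),
                    sex=np.repeat(["male", "female"], 10), subspecies="a")
        with pytest.raises(mv.DegenerateInputError, match="collinear"):
            mv.pillai_manova(df, TRAITS3, "sex", covariate_factor=None)


class TestMahalanobisScreen:
    def test_specimen_at_centroid_has_zero_distance(self):
        X = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4], [1, 1, 1]], float)
        assert np.allclose(X.mean(0), X[-1])
        out = mv.mahalanobis_screen(_frame(X, specimen_id=list("abcde")), TRAITS3)
        assert out.set_index("specimen_id").loc["e", "squared_distance"] == pytest.approx(0, abs=1e-20)

    def test_identity_covariance_reduces_to_euclidean(self, exact_corr_sampler):
        X = exact_corr_sampler(np.eye(3), n=60, seed=9)  # sample cov exactly I
        out = mv.mahalanobis_screen(_frame(X, specimen_id=np.arange(60).astype(str)), TRAITS3)
        d2 = ((X - X.mean(0)) ** 2).sum(1)
        merged = out.set_index("specimen_id").loc[np.arange(60).astype(str)]
        assert np.allclose(merged["squared_distance"], d2, atol=1e-8)

    def test_chi_square_calibration_slope(self):
        rng = np.random.default_rng(12)
        X = rng.multivariate_normal([0, 0, 0], np.eye(3), size=1000)
        out = mv.mahalanobis_screen(_frame(X), TRAITS3)
        slope = np.polyfit(out["chi2_quantile"], out["squared_distance"], 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_singular_covariance_names_collinear_traits(self):
        x = np.arange(10.0)
        df = _frame(np.column_stack([x, x * 3, np.random.default_rng(0).standard_normal(10)]))
        with pytest.raises(mv.DegenerateInputError, match="t1.*t2"):
            mv.mahalanobis_screen(df, TRAITS3)


class TestClusterComplete:
    def test_hand_worked_heights_on_line(self):
        df = _frame(np.array([[0], [1], [10], [11], [30]]), traits=("x",))
        dend = mv.cluster_complete(df, ("x",))
        assert np.allclose(sorted(dend.heights), [1, 1, 11, 30])

    def test_identical_points_merge_at_zero(self):
        df = _frame(np.array([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0], [9.0, 9.0, 9.0]]))
        dend = mv.cluster_complete(df, TRAITS3)
        assert dend.heights[0] == 0.0

    def test_heights_monotone_non_decreasing(self, paper_table):
        dend = mv.cluster_complete(paper_table, sd.BILL_TRAITS)
        assert np.all(np.diff(dend.heights) >= -1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed, complete_linkage_oracle):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        X = rng.standard_normal((n, 3))
        dend = mv.cluster_complete(_frame(X), TRAITS3)
        merges = complete_linkage_oracle(X)
        assert np.allclose(sorted(dend.heights), sorted(h for _, _, h in merges), atol=1e-9)
        # same partition at every cut level
        for k in range(2, n):
            labels = fcluster(dend.linkage, t=k, criterion="maxclust")
            mine = {frozenset(np.flatnonzero(labels == c)) for c in np.unique(labels)}
            clusters = [frozenset([i]) for i in range(n)]
            for a, b, _ in merges[: n - k]:
                clusters = [c for c in clusters if c != a and c != b] + [a | b]
            assert mine == set(clusters)

    def test_membership_invariant_under_reordering(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 3))
        ids = [f"s{i}" for i in range(12)]
        perm = rng.permutation(12)
        d1 = mv.cluster_complete(_frame(X, specimen_id=ids), TRAITS3)
        d2 = mv.cluster_complete(_frame(X[perm], specimen_id=[ids[i] for i in perm]), TRAITS3)
        for k in (2, 3, 4):
            p1 = {frozenset(np.array(d1.ids)[d1.cut(k) == c]) for c in np.unique(d1.cut(k))}
            p2 = {frozenset(np.array(d2.ids)[d2.cut(k) == c]) for c in np.unique(d2.cut(k))}
            assert p1 == p2


class TestOptimalK:
    @staticmethod
    def _blobs(centers, n=30, sd=0.2, seed=0):
        rng = np.random.default_rng(seed)
        X = np.concatenate([rng.normal(c, sd, size=(n, 3)) for c in centers])
        return _frame(X)

    def test_two_separated_blobs(self):
        df = self._blobs([np.zeros(3), np.full(3, 8.0)])
        dend = mv.cluster_complete(df, TRAITS3)
        res = mv.optimal_k(dend, df, TRAITS3)
        assert res["k_best"] == 2
        assert res["votes"]["calinski_harabasz"] == 2
        assert res["votes"]["silhouette"] == 2

    def test_three_equidistant_blobs(self):
        centers = [np.array([0, 0, 0]), np.array([8, 0, 0]), np.array([4, 8 * np.sqrt(3) / 2, 0])]
        df = self._blobs(centers)
        dend = mv.cluster_complete(df, TRAITS3)
        assert mv.optimal_k(dend, df, TRAITS3)["k_best"] == 3

    def test_degenerate_k_skipped(self):
        df = self._blobs([np.zeros(3), np.full(3, 8.0)], n=3)
        dend = mv.cluster_complete(df, TRAITS3)
        res = mv.optimal_k(dend, df, TRAITS3, k_range=range(2, 20))
        assert res["k_best"] == 2

    def test_two_cluster_world_recovered_exactly(self):
        import cuckoomorph as cm

        table = cm.sample_specimens(cm.build_config("two_cluster", seed=0))
        dend = mv.cluster_complete(table, sd.BILL_TRAITS)
        res = mv.optimal_k(dend, table, sd.BILL_TRAITS)
        assert res["k_best"] == 2

    def test_paper_like_series_coarse_structure(self, paper_table):
        """A clinal series with intermediates: 2 or 3 coarse clusters, with
        the silhouette favoring the two-regime split."""
        dend = mv.cluster_complete(paper_table, sd.BILL_TRAITS)
        res = mv.optimal_k(dend, paper_table, sd.BILL_TRAITS)
        assert res["k_best"] in (2, 3)
        assert res["votes"]["silhouette"] == 2


class TestLDA:
    def test_two_groups_single_axis_carries_everything(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3))
        X[:20, 0] += 5
        df = _frame(X, group=np.repeat(["a", "b"], 20))
        res = mv.lda_fit(df, TRAITS3, "group")
        assert res.between_group_ratio[0] == pytest.approx(1.0)
        assert res.confusion.to_numpy().sum(axis=1) == pytest.approx(1.0)

    def test_confusion_matches_argmax_oracle(self, lda_oracle):
        rng = np.random.default_rng(5)
        X = np.concatenate([
            rng.normal([0, 0, 0], 1.0, size=(25, 3)),
            rng.normal([2, 1, 0], 1.0, size=(30, 3)),
            rng.normal([0, 2, 2], 1.0, size=(20, 3)),
        ])
        y = np.array(["a"] * 25 + ["b"] * 30 + ["c"] * 20)
        df = _frame(X, group=y)
        res = mv.lda_fit(df, TRAITS3, "group")
        pred = lda_oracle(X, y)
        expected = pd.crosstab(pd.Series(y), pd.Series(pred)).reindex(
            index=["a", "b", "c"], columns=["a", "b", "c"], fill_value=0
        )
        expected = expected.div(expected.sum(axis=1), axis=0)
        assert np.allclose(res.confusion.to_numpy(), expected.to_numpy())

    def test_confusion_invariant_under_invertible_linear_map(self):
        rng = np.random.default_rng(8)
        X = np.concatenate([rng.normal(c, 1.0, size=(25, 3)) for c in ([0, 0, 0], [2, 2, 0], [0, 3, 1])])
        y = np.repeat(["a", "b", "c"], 25)
        M = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        assert abs(np.linalg.det(M)) > 1e-6
        res1 = mv.lda_fit(_frame(X, group=y), TRAITS3, "group")
        res2 = mv.lda_fit(_frame(X @ M.T + [5, -3, 1], group=y), TRAITS3, "group")
        assert np.allclose(res1.confusion.to_numpy(), res2.confusion.to_numpy())

    def test_bill_depth_coefficient_oriented_positive(self, paper_table):
        res = mv.lda_fit(paper_table, sd.BILL_TRAITS, "region")
        assert (res.coefficients.loc["bill_depth_mm"] >= 0).all()

    def test_between_group_ratios_sum_to_one(self, paper_table):
        res = mv.lda_fit(paper_table, sd.BILL_TRAITS, "region")
        assert res.between_group_ratio.sum() == pytest.approx(1.0)

    def test_tiny_group_warns(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((23, 3))
        y = np.array(["a"] * 20 + ["b"] * 3)
        X[20:] += 4
        with pytest.warns(UserWarning, match="specimens"):
            mv.lda_fit(_frame(X, group=y), TRAITS3, "group")


class TestRankCorrelations:
    def test_identical_columns_give_unit_rho(self):
        x = np.arange(10.0)
        df = _frame(np.column_stack([x, x, x]))
        assert np.allclose(mv.rank_correlations(df, TRAITS3).to_numpy(), 1.0)

    def test_reversed_ranks_give_minus_one(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]}, dtype=float)
        rho = mv.rank_correlations(df, ("a", "b"))
        assert rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_tied_ordinals_match_average_rank_formula(self):
        """{0,1,1,2} vs {1,1,2,2}: hand-computed average-rank rho = 1/sqrt(2)."""
        df = pd.DataFrame({"a": [0, 1, 1, 2], "b": [1, 1, 2, 2]}, dtype=float)
        rho = mv.rank_correlations(df, ("a", "b"))
        assert rho.loc["a", "b"] == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_constant_column_flagged_nan(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [2, 2, 2, 2]}, dtype=float)
        with pytest.warns(UserWarning, match="constant"):
            rho = mv.rank_correlations(df, ("a", "b"))
        assert np.isnan(rho.loc["a", "b"])
        assert rho.loc["b", "b"] == 1.0

    def test_paper_like_color_scores_concordant(self, paper_table):
        rho = mv.rank_correlations(paper_table, sd.COLOR_TRAITS)
        off = rho.to_numpy()[np.triu_indices(4, 1)]
        assert (off > 0.3).all()
        assert np.allclose(rho.to_numpy(), rho.to_numpy().T)
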