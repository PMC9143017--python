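"""Endpoint statistics: PCA, clustering, silhouettes, information gain,
group tests, repeated-measures ANOVA and through-origin fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turbispec import (
    group_stats,
    information_gain,
    linearity_r2,
    pca_endpoints,
    silhouette_scores,
    spectral_cluster,
    synthesize_uptake_trial,
    uptake_anova,
)
from turbispec.errors import DegenerateInputError, InvalidArgumentError


def endpoint_frame(x, columns=("tmre", "bodipy", "hb")):
    df = pd.DataFrame(np.asarray(x, dtype=float), columns=list(columns))
    df["group"] = "g"
    df["timepoint"] = 0.0
    return df


class TestPCA:
    def test_three_endpoints_give_three_components_summing_to_100(self):
        rng = np.random.default_rng(0)
        table = endpoint_frame(rng.normal(size=(30, 3)))
        out = pca_endpoints(table, ("tmre", "bodipy", "hb"))
        assert out["pc_scores"].shape == (30, 3)
        assert out["explained_variance"].sum() == pytest.approx(100.0)
        assert np.all(np.diff(out["explained_variance"]) <= 1e-9)

    def test_uncorrelated_standardized_data_splits_variance_evenly(self):
        rng = np.random.default_rng(1)
        table = endpoint_frame(rng.normal(size=(4000, 3)))
        out = pca_endpoints(table, ("tmre", "bodipy", "hb"))
        assert np.all(np.abs(out["explained_variance"] - 100 / 3) < 4.0)

    def test_rank_one_data_puts_all_variance_in_pc1(self):
        t = np.linspace(0, 1, 25)
        table = endpoint_frame(np.column_stack([t, 2 * t, -3 * t]))
        out = pca_endpoints(table, ("tmre", "bodipy", "hb"))
        assert out["explained_variance"][0] == pytest.approx(100.0, abs=1e-8)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 3))
        a = pca_endpoints(endpoint_frame(x), ("tmre", "bodipy", "hb"))
        perm = rng.permutation(20)
        b = pca_endpoints(endpoint_frame(x[perm]), ("tmre", "bodipy", "hb"))
        np.testing.assert_allclose(b["pc_scores"], a["pc_scores"][perm], atol=1e-9)

    def test_constant_column_rejected(self):
        table = endpoint_frame(np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0)]))
        with pytest.raises(DegenerateInputError):
            pca_endpoints(table, ("tmre", "bodipy"))


class TestSpectralClustering:
    def test_separated_point_masses_recovered(self):
        pts = np.array([[0.0, 0.0]] * 5 + [[50.0, 0.0]] * 5)
        pts += np.random.default_rng(0).normal(scale=0.01, size=pts.shape)
        labels = spectral_cluster(pts, k=2, seed=0)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicated_points_co_assigned(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(size=(8, 2)), rng.normal(loc=6.0, size=(8, 2))])
        doubled = np.repeat(pts, 2, axis=0)
        labels = spectral_cluster(doubled, k=2, seed=1)
        assert np.array_equal(labels[::2], labels[1::2])

    def test_two_blob_simulation_oracle(self):
        """Two Gaussian blobs 3 SD apart, n=40: perfect agreement with truth
        (up to label swap) in >= 95% of 20 seeds."""
        perfect = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(loc=0.0, size=(20, 2))
            b = rng.normal(loc=(3.0 * np.sqrt(2), 3.0 * np.sqrt(2)), size=(20, 2))
            labels = spectral_cluster(np.vstack([a, b]), k=2, seed=seed)
            truth = np.array([0] * 20 + [1] * 20)
            agree = max(np.mean((labels - 1) == truth), np.mean((labels - 1) != truth))
            perfect += agree == 1.0
        assert perfect >= 19

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(InvalidArgumentError):
            spectral_cluster(np.zeros((3, 2)), k=4)


class TestSilhouette:
    def test_identical_points_score_zero(self):
        pts = np.zeros((6, 2))
        labels = np.array([1, 1, 1, 2, 2, 2])
        assert np.all(silhouette_scores(pts, labels) == 0.0)

    def test_hand_computed_two_pair_example(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        labels = np.array([1, 1, 2, 2])
        s = silhouette_scores(pts, labels)
        b = 0.5 * (10.0 + np.sqrt(101.0))
        assert s[0] == pytest.approx((b - 1.0) / b)  # ~0.9002

    def test_matches_reference_implementation(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(40, 3))
        labels = (pts[:, 0] > 0).astype(int)
        np.testing.assert_allclose(silhouette_scores(pts, labels),
                                   silhouette_samples(pts, labels), atol=1e-10)

    def test_singleton_cluster_scores_zero(self):
        pts = np.array([[0.0], [5.0], [6.0]])
        labels = np.array([1, 2, 2])
        assert silhouette_scores(pts, labels)[0] == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(InvalidArgumentError):
            silhouette_scores(np.zeros((4, 2)), np.ones(4))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_scores_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 12)
        pts = rng.normal(size=(n, 2))
        labels = rng.integers(1, 3, size=n)
        if np.unique(labels).size < 2:
            labels[0] = 1
            labels[1] = 2
        s = silhouette_scores(pts, labels)
        assert np.all((s >= -1.0) & (s <= 1.0))


class TestInformationGain:
    def test_constant_feature_carries_no_information(self):
        y = np.array(["a"] * 4 + ["b"] * 4)
        assert information_gain(np.ones(8), y, 2) == 0.0

    def test_perfect_separator_yields_one_bit(self):
        v = np.arange(8.0)
        y = np.array(["a"] * 4 + ["b"] * 4)
        assert information_gain(v, y, 2) == pytest.approx(1.0)

    def test_matches_brute_force_on_toy_table(self):
        """8-row toy table, 2 equal-frequency bins, hand enumeration:
        bins {1,2,3,4} vs {5,6,7,8}; labels a,a,b,a | b,b,a,b.
        H(y) = 1; H(y|bin) = H(1/4) each; IG = 1 - H(1/4)."""
        v = np.arange(1.0, 9.0)
        y = np.array(["a", "a", "b", "a", "b", "b", "a", "b"])
        h14 = -(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75))
        assert information_gain(v, y, 2) == pytest.approx(1.0 - h14)

    def test_single_label_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert information_gain(np.arange(5.0), np.zeros(5), 2) == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_by_label_entropy(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 30)
        v = rng.normal(size=n)
        y = rng.integers(0, 2, size=n)
        if np.unique(y).size < 2:
            y[0] = 1 - y[0]
        p = y.mean()
        h = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
        ig = information_gain(v, y, 3)
        assert 0.0 <= ig <= h + 1e-12


class TestGroupStats:
    def test_identical_groups_not_significant(self):
        table = pd.DataFrame({
            "group": ["a"] * 4 + ["b"] * 4,
            "timepoint": [0.0] * 8,
            "tmre": [1.0, 2.0, 3.0, 4.0] * 2,
        })
        out = group_stats(table, "tmre", "a", "b")
        assert out["wilcoxon_p"] == pytest.approx(1.0)
        assert not out["significant"]

    def test_exact_p_for_extreme_three_vs_three(self):
        """{1,2,3} vs {10,11,12}: the most extreme of C(6,3)=20 rank splits,
        two-sided exact p = 2/20 = 0.1."""
        table = pd.DataFrame({
            "group": ["a"] * 3 + ["b"] * 3,
            "timepoint": [0.0] * 6,
            "tmre": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
        })
        assert group_stats(table, "tmre", "a", "b")["wilcoxon_p"] == pytest.approx(0.1)

    def test_perfect_time_trend(self):
        table = pd.DataFrame({
            "group": ["a"] * 3 + ["b"] * 3,
            "timepoint": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "tmre": [2.0, 4.0, 6.0, 8.0, 10.0, 12.0],
        })
        assert group_stats(table, "tmre", "a", "b")["pearson_r_vs_time"] == pytest.approx(1.0)

    def test_small_group_rejected(self):
        table = pd.DataFrame({"group": ["a", "b", "b"], "timepoint": [0.0] * 3,
                              "tmre": [1.0, 2.0, 3.0]})
        with pytest.raises(InvalidArgumentError):
            group_stats(table, "tmre", "a", "b")


class TestUptakeAnova:
    def test_extreme_arm_separation_is_significant(self):
        curves = synthesize_uptake_trial({"a": (0.1, 1.0), "b": (0.1, 10.0)},
                                         n_subjects=6, seed=0)
        assert uptake_anova(curves) < 0.001

    def test_identical_kinetics_not_significant_on_median_seed(self):
        ps = [uptake_anova(synthesize_uptake_trial({"a": (0.1, 1.0), "b": (0.1, 1.0)},
                                                   n_subjects=6, seed=s))
              for s in range(11)]
        assert np.median(ps) > 0.05

    def test_missing_cells_rejected(self):
        curves = synthesize_uptake_trial({"a": (0.1, 1.0), "b": (0.1, 1.0)},
                                         n_subjects=4, seed=0)
        with pytest.raises(InvalidArgumentError):
            uptake_anova(curves.iloc[:-1])


class TestLinearity:
    def test_exact_proportionality(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = linearity_r2(x, 3 * x, through_origin=True)
        assert out["slope"] == pytest.approx(3.0)
        assert out["r2"] == pytest.approx(1.0)

    def test_hand_computed_with_outlier(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([3.0, 6.0, 10.0])
        slope = (x * y).sum() / (x * x).sum()  # 45/14
        resid = y - slope * x
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        out = linearity_r2(x, y, through_origin=True)
        assert out["slope"] == pytest.approx(slope)
        assert out["r2"] == pytest.approx(r2)

    def test_all_zero_x_rejected(self):
        with pytest.raises(DegenerateInputError):
            linearity_r2(np.zeros(5), np.arange(5.0))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_r2_never_exceeds_one(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 10.0, 8)
        y = rng.normal(size=8)
        assert linearity_r2(x, y, through_origin=True)["r2"] <= 1.0
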