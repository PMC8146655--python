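"""Profiling: standardization, K-means, elbow, BCA, composition."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from sncatlas.profiles import (
    average_and_standardize,
    between_class_analysis,
    cluster_composition,
    kmeans_lloyd,
    select_k_elbow,
)
from sncatlas.quantify import CountMatrix
from sncatlas.simulate import planted_profile_matrix


def _cm_for_profiles(counts, regions, classes):
    counts_df = pd.DataFrame(counts)
    features = pd.DataFrame(
        {"assigned_class": classes, "subtype": [""] * len(counts_df),
         "isoacceptor": [""] * len(counts_df)},
        index=counts_df.index,
    )
    samples = pd.DataFrame(
        {"region": [regions[c] for c in counts_df.columns],
         "replicate": range(len(counts_df.columns))},
        index=counts_df.columns,
    )
    cm = CountMatrix(counts_df, features, samples)
    cm.size_factors = pd.Series(1.0, index=counts_df.columns)
    return cm


class TestAverageAndStandardize:
    def _cm(self):
        counts = {
            "PAR_1": [1, 5, 4], "PAR_2": [3, 5, 6],
            "SPZ_1": [10, 5, 1], "SPZ_2": [12, 5, 3],
        }
        regions = {c: c.split("_")[0] for c in counts}
        df = pd.DataFrame(counts, index=["f1", "f2", "f3"])
        return _cm_for_profiles(df, regions, ["piRNA"] * 3)

    def test_region_columns_are_replicate_means(self):
        cm = self._cm()
        means = cm.region_means()
        assert means.loc["f1", "PAR"] == pytest.approx(2.0)
        assert means.loc["f1", "SPZ"] == pytest.approx(11.0)

    def test_constant_rows_dropped_and_logged(self):
        X, dropped = average_and_standardize(self._cm())
        assert dropped == ["f2"]
        assert list(X.index) == ["f1", "f3"]

    def test_rows_standardized(self):
        X, _ = average_and_standardize(self._cm())
        assert np.allclose(X.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(X.std(axis=1, ddof=0), 1.0, atol=1e-9)


class TestKmeans:
    X1d = pd.DataFrame({"x": [0.0, 0.1, 10.0, 10.1]}, index=list("abcd"))

    def test_two_cluster_hand_example(self):
        model = kmeans_lloyd(self.X1d, 2, n_starts=10, seed=1)
        assert model.totss == pytest.approx(100.01, abs=1e-9)
        assert model.withinss == pytest.approx(0.01, abs=1e-9)
        assert model.ratio == pytest.approx(100.0 / 100.01, abs=1e-9)
        labels = model.assignments
        assert labels["a"] == labels["b"] and labels["c"] == labels["d"]
        assert labels["a"] != labels["c"]

    def test_k_one_ratio_zero(self):
        model = kmeans_lloyd(self.X1d, 1, seed=1)
        assert model.ratio == 0.0 and model.betweenss == pytest.approx(0.0)

    def test_identical_rows_degenerate(self):
        X = pd.DataFrame(np.ones((5, 3)))
        model = kmeans_lloyd(X, 2, n_starts=5, seed=1)
        assert model.totss == 0.0 and model.ratio == 0.0
        assert model.assignments.nunique() == 1

    def test_huygens_identity_and_determinism(self):
        X, _ = planted_profile_matrix(n_clusters=4, rows_per_cluster=25, seed=3)
        m1 = kmeans_lloyd(X, 4, n_starts=20, seed=5)
        m2 = kmeans_lloyd(X, 4, n_starts=20, seed=5)
        assert m1.betweenss + m1.withinss == pytest.approx(m1.totss, rel=1e-9)
        assert (m1.assignments == m2.assignments).all()

    def test_k_above_row_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_lloyd(self.X1d, 5, seed=1)


class TestElbow:
    def test_planted_structure_recovered(self):
        X, labels = planted_profile_matrix(n_clusters=6, rows_per_cluster=40, seed=7)
        ratios, chosen, models = select_k_elbow(
            X, k_range=range(2, 11), n_starts=20, seed=7
        )
        assert chosen == 6
        assert ratios[6] >= 0.90
        assert adjusted_rand_score(labels, models[6].assignments) >= 0.95

    def test_ratio_nondecreasing_in_k(self):
        X, _ = planted_profile_matrix(n_clusters=5, rows_per_cluster=30, seed=9)
        ratios, _, _ = select_k_elbow(X, k_range=range(2, 10), n_starts=20, seed=2)
        assert (np.diff(ratios.to_numpy()) >= -1e-6).all()

    def test_none_when_no_k_qualifies(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(60, 5)))
        X = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1), axis=0)
        ratios, chosen, _ = select_k_elbow(
            X, k_range=range(2, 5), n_starts=5, seed=1, info_threshold=0.999
        )
        assert chosen is None


class TestBCA:
    def test_equal_class_means_ratio_zero(self):
        X = pd.DataFrame({"f": [1.0, -1.0, 1.0, -1.0]})
        res = between_class_analysis(X, ["g1", "g1", "g2", "g2"])
        assert res.ratio == pytest.approx(0.0, abs=1e-12)

    def test_zero_within_class_variance_ratio_one(self):
        X = pd.DataFrame({"f1": [1.0, 1.0, 5.0, 5.0], "f2": [2.0, 2.0, 0.0, 0.0]})
        res = between_class_analysis(X, ["g1", "g1", "g2", "g2"])
        assert res.ratio == pytest.approx(1.0, abs=1e-12)

    def test_one_dimensional_hand_example(self):
        X = pd.DataFrame({"f": [0.0, 2.0, 4.0, 6.0]})
        res = between_class_analysis(X, ["g1", "g1", "g2", "g2"])
        assert res.ratio == pytest.approx(0.8, abs=1e-12)

    def test_invariant_to_constant_feature(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(9, 4)))
        labels = ["a", "b", "c"] * 3
        base = between_class_analysis(X, labels).ratio
        X["const"] = 7.0
        assert between_class_analysis(X, labels).ratio == pytest.approx(base, rel=1e-12)
        assert 0.0 <= base <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            between_class_analysis(pd.DataFrame({"f": [1.0, 2.0]}), ["g", "g"])


class TestClusterComposition:
    def test_pure_pirna_cluster_and_peak_region(self):
        counts = pd.DataFrame(
            {"PAR_1": [100, 1], "CAP_1": [10, 1], "COR_1": [1, 50],
             "CAU_1": [1, 5], "SPZ_1": [1, 2]},
            index=["T" * 25, "A" * 22],
        )
        regions = {c: c.split("_")[0] for c in counts}
        cm = _cm_for_profiles(counts, regions, ["piRNA", "piRNA"])
        X, _ = average_and_standardize(cm)
        model = kmeans_lloyd(X, 2, n_starts=5, seed=1)
        comp = cluster_composition(model, cm)
        peaks = {entry["peak_region"] for entry in comp.values()}
        assert peaks == {"PAR", "COR"}
        for entry in comp.values():
            assert entry["class_shares"]["piRNA"] == pytest.approx(100.0)
            assert "u1_a10" in entry
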