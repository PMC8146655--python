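"""Count matrix, RLE normalization, composition shares, NB screen."""

import numpy as np
import pandas as pd
import pytest

from sncatlas.quantify import (
    CountMatrix,
    build_count_matrix,
    class_proportions,
    nb_differential_test,
    rle_size_factors,
)


def _cm(counts: dict, regions: dict, classes=None, subtypes=None, iso=None):
    counts_df = pd.DataFrame(counts)
    counts_df.index = [f"seq{i}" for i in range(len(counts_df))]
    n = len(counts_df)
    features = pd.DataFrame(
        {
            "assigned_class": classes or ["piRNA"] * n,
            "subtype": subtypes or [""] * n,
            "isoacceptor": iso or [""] * n,
        },
        index=counts_df.index,
    )
    samples = pd.DataFrame(
        {"region": [regions[s] for s in counts_df.columns],
         "replicate": list(range(1, len(counts_df.columns) + 1))},
        index=counts_df.columns,
    )
    return CountMatrix(counts_df, features, samples)


class TestRleSizeFactors:
    def test_closed_form_example(self):
        counts = pd.DataFrame({"s1": [2, 8], "s2": [4, 16]})
        sf = rle_size_factors(counts)
        assert sf["s1"] == pytest.approx(0.70710678, abs=1e-6)
        assert sf["s2"] == pytest.approx(1.41421356, abs=1e-6)

    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [3, 7, 1], "s2": [3, 7, 1]})
        assert np.allclose(rle_size_factors(counts), 1.0)

    def test_equivariance_under_scaling_one_sample(self):
        # scaling one sample by 10 also shifts every geometric mean by
        # 10^(1/n), so the invariant is on size-factor ratios: the scaled
        # sample's factor grows 10x relative to every other sample
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 200, size=(50, 4)),
                              columns=list("abcd"))
        base = rle_size_factors(counts)
        scaled = counts.copy()
        scaled["b"] *= 10
        sf = rle_size_factors(scaled)
        for s in "acd":
            assert sf["b"] / sf[s] == pytest.approx(10 * base["b"] / base[s], rel=1e-9)
        assert sf["a"] / sf["c"] == pytest.approx(base["a"] / base["c"], rel=1e-9)
        # normalized counts of unscaled samples are unchanged up to the
        # common 10^(1/4) rescaling absorbed by all factors
        assert np.allclose(sf[list("acd")] / base[list("acd")],
                           sf["a"] / base["a"])

    def test_zero_in_every_feature_rejected(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
        with pytest.raises(ValueError, match="positive"):
            rle_size_factors(counts)


class TestBuildCountMatrix:
    manifest = pd.DataFrame({"sample": ["s1", "s2"], "region": ["PAR", "SPZ"], "replicate": [1, 1]})

    def test_totals_conserved(self):
        tags = pd.DataFrame({"s1": [3, 1], "s2": [0, 2]}, index=["AAA", "CCC"])
        ann = pd.DataFrame({"assigned_class": ["piRNA", "unannotated"]},
                           index=["AAA", "CCC"])
        cm = build_count_matrix(tags, ann, self.manifest)
        assert cm.counts.sum().sum() == tags.sum().sum()
        assert cm.features.loc["CCC", "assigned_class"] == "unannotated"

    def test_empty_table_rejected(self):
        empty = pd.DataFrame(columns=["s1", "s2"])
        with pytest.raises(ValueError, match="empty"):
            build_count_matrix(empty, pd.DataFrame(), self.manifest)

    def test_unannotated_sequence_missing_from_annotations_rejected(self):
        tags = pd.DataFrame({"s1": [1], "s2": [1]}, index=["AAA"])
        with pytest.raises(ValueError, match="lack"):
            build_count_matrix(tags, pd.DataFrame({"assigned_class": []}), self.manifest)


class TestClassProportions:
    def test_single_region_shares(self):
        cm = _cm({"s1": [78, 22]}, {"s1": "PAR"}, classes=["piRNA", "miRNA"]).normalize()
        within, across = class_proportions(cm)
        assert within.loc["piRNA", "PAR"] == pytest.approx(78.0)
        assert across.loc["miRNA", "PAR"] == pytest.approx(100.0)

    def test_shares_sum_to_100(self):
        rng = np.random.default_rng(7)
        cm = _cm(
            {s: rng.integers(1, 100, 6) for s in ("s1", "s2")},
            {"s1": "PAR", "s2": "CAU"},
            classes=["piRNA", "miRNA", "tsRNA", "rsRNA", "piRNA", "miRNA"],
        ).normalize()
        within, across = class_proportions(cm)
        assert np.allclose(within.sum(axis=0), 100.0, atol=1e-6)
        assert np.allclose(across.sum(axis=1), 100.0, atol=1e-6)


class TestDifferential:
    def _two_group_cm(self, a_counts, b_counts):
        counts = {}
        regions = {}
        for i, col in enumerate(np.asarray(a_counts).T):
            counts[f"a{i}"] = col
            regions[f"a{i}"] = "PAR"
        for i, col in enumerate(np.asarray(b_counts).T):
            counts[f"b{i}"] = col
            regions[f"b{i}"] = "SPZ"
        cm = _cm(counts, regions)
        cm.size_factors = pd.Series(1.0, index=cm.counts.columns)
        return cm

    def test_identical_groups_not_significant(self):
        X = np.tile([[50], [200], [10]], (1, 3))
        cm = self._two_group_cm(X, X)
        res = nb_differential_test(cm, "PAR", "SPZ")
        assert np.allclose(res["log2_fold_change"], 0.0)
        assert (res["p_value"] > 0.99).all()
        assert not res["significant"].any()

    def test_fold_threshold_rule(self):
        a = np.tile([[30]], (1, 3))
        b = np.tile([[10]], (1, 3))
        res = nb_differential_test(self._two_group_cm(a, b), "PAR", "SPZ")
        assert res["fold_change"].iloc[0] == pytest.approx((30.5) / (10.5) , rel=1e-9)
        assert abs(res["log2_fold_change"].iloc[0]) > np.log2(2.5) * 0.9

    def test_bh_adjustment_monotone_and_larger_than_raw(self):
        rng = np.random.default_rng(11)
        a = rng.poisson(100, size=(200, 3))
        b = rng.poisson(100, size=(200, 3))
        res = nb_differential_test(self._two_group_cm(a, b), "PAR", "SPZ")
        assert (res["p_adjusted"] >= res["p_value"] - 1e-12).all()
        srt = res.sort_values("p_value")
        assert (np.diff(srt["p_adjusted"]) >= -1e-12).all()

    def test_missing_region_rejected(self):
        cm = self._two_group_cm(np.ones((2, 2)), np.ones((2, 2)))
        with pytest.raises(ValueError, match="replicates"):
            nb_differential_test(cm, "PAR", "COR")
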