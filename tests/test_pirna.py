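"""piRNA signatures: positional frequencies, U1/A10, lengths, mtDNA matching."""

import numpy as np
import pytest

from sncatlas.pirna import (
    length_distribution,
    mtdna_perfect_matches,
    pirbase_category_summary,
    positional_nt_frequency,
    u1_a10_summary,
)
from sncatlas.references import MtFeature, reverse_complement


class TestPositionalFrequency:
    def test_unweighted_counts(self):
        freq = positional_nt_frequency(["TAA", "TAC", "AAC"])
        assert freq.loc[1, "U"] == pytest.approx(2 / 3)
        assert freq.loc[1, "A"] == pytest.approx(1 / 3)

    def test_single_sequence_is_one_hot(self):
        freq = positional_nt_frequency(["TAG"])
        assert freq.loc[1, "U"] == 1.0 and freq.loc[2, "A"] == 1.0 and freq.loc[3, "G"] == 1.0
        assert freq.iloc[3:].to_numpy().sum() == 0.0

    def test_weights_shift_frequencies(self):
        freq = positional_nt_frequency(["TAA", "TAC", "AAC"], weights=[2, 1, 1])
        assert freq.loc[1, "U"] == pytest.approx(3 / 4)

    def test_rows_with_support_sum_to_one(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), int(rng.integers(17, 36)))) for _ in range(200)]
        w = rng.random(200) * 10
        freq = positional_nt_frequency(seqs, w)
        sums = freq.sum(axis=1)
        lengths = np.array([len(s) for s in seqs])
        for p in range(1, 36):
            if (lengths >= p).any():
                assert sums[p] == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            positional_nt_frequency(["TAA"], weights=[0.0])


class TestU1A10:
    def test_weighted_u1_share(self):
        sig = u1_a10_summary(["T" + "A" * 20, "A" * 21], weights=[8, 2])
        assert sig.u1_share == pytest.approx(0.80)
        assert sig.v1_share == pytest.approx(0.20)

    def test_a10_undefined_when_all_short(self):
        sig = u1_a10_summary(["TAAACGTAC", "AAACGTACG"])  # 9-mers
        assert sig.a10_share is None and sig.b10_share is None
        assert sig.short10_mass == pytest.approx(1.0)

    def test_scale_invariance_under_duplication(self):
        seqs = ["TACGTACGTAACGT", "AACGTACGTTACGT", "TTTTTTTTTTATTT"]
        w = [3.0, 1.0, 2.0]
        once = u1_a10_summary(seqs, w)
        twice = u1_a10_summary(seqs * 2, w * 2)
        assert twice.u1_share == pytest.approx(once.u1_share)
        assert twice.a10_share == pytest.approx(once.a10_share)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            u1_a10_summary([])


class TestLengthDistribution:
    def test_single_mode(self):
        res = length_distribution(["A" * 30] * 5)["all"]
        assert res["modes"] == [30] and not res["multimodal"]

    def test_bimodal_mixture(self):
        seqs = ["A" * 22] * 10 + ["A" * 31] * 8
        res = length_distribution(seqs)["all"]
        assert set(res["modes"]) == {22, 31} and res["multimodal"]

    def test_empty_group_histogram(self):
        res = length_distribution(["A" * 20], by=["g1"])
        assert "g1" in res and res["g1"]["histogram"].sum() == 1.0
        assert length_distribution([], weights=[], by=[]) == {}


class TestMtMatches:
    def test_plus_strand_match(self):
        matches = mtdna_perfect_matches(["GTAC"], "ACGTACGTAAGG")
        plus = [m for m in matches if m.strand == "+"]
        assert {(m.start) for m in plus} == {3}

    def test_wrap_around_on_circular_genome(self):
        matches = mtdna_perfect_matches(["TTAA"], "AAGGTT")
        assert any(m.strand == "+" and m.start == 5 for m in matches)

    def test_feature_assignment_uses_plus_strand_start(self):
        feats = [MtFeature("CDS:X", 1, 4, "+")]
        matches = mtdna_perfect_matches(["GTAC", "TAAG"], "ACGTACGTAAGG", feats)
        by_key = {(m.sequence, m.strand): m.feature for m in matches}
        assert by_key[("GTAC", "+")] == "CDS:X"        # + start 3 inside the CDS
        assert by_key[("TAAG", "+")] == "intergenic"   # + start 8 outside

    def test_matches_brute_force_oracle_with_revcomp_and_wrap(self):
        rng = np.random.default_rng(31)
        genome = "".join(rng.choice(list("ACGT"), 600))
        queries = []
        for _ in range(50):
            length = int(rng.integers(17, 36))
            start = int(rng.integers(0, 600))
            circ = (genome + genome)[start:start + length]
            queries.append(circ if rng.random() < 0.5 else reverse_complement(circ))
        queries += ["".join(rng.choice(list("ACGT"), 20)) for _ in range(20)]

        def oracle(q):
            hits = set()
            doubled = genome + genome
            for strand, query in (("+", q), ("-", reverse_complement(q))):
                for s in range(len(genome)):
                    if doubled[s:s + len(query)] == query:
                        hits.add((q, strand, s + 1))
            return hits

        expected = set().union(*(oracle(q) for q in queries))
        observed = {(m.sequence, m.strand, m.start)
                    for m in mtdna_perfect_matches(queries, genome)}
        assert observed == expected

    def test_palindrome_reported_once_per_strand(self):
        q = "ACGCGT"  # reverse complement of itself
        matches = mtdna_perfect_matches([q], "TTACGCGTTT")
        assert sorted(m.strand for m in matches) == ["+", "-"]
        assert all(m.start == 3 for m in matches)


class TestPirbaseCategories:
    def test_all_intergenic(self):
        import pandas as pd

        ann = pd.DataFrame({"target_type": ["none", "LINE"],
                            "target_location": ["intergenic", "intergenic"]})
        shares = pirbase_category_summary(ann, [5.0, 5.0])
        assert shares["target_location"]["intergenic"] == pytest.approx(1.0)

    def test_equal_split(self):
        import pandas as pd

        ann = pd.DataFrame({"target_type": ["none", "none"],
                            "target_location": ["genic", "intergenic"]})
        shares = pirbase_category_summary(ann, [3.0, 3.0])
        assert shares["target_location"]["genic"] == pytest.approx(0.5)
        assert shares["target_type"].sum() == pytest.approx(1.0)
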