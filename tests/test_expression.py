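"""RPKM, DEG filter layer, expression groups, species and novelty cascades."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nomescape.expression import (
    assign_expression_groups,
    compute_rpkm,
    deg_filter,
    longest_orf_codons,
    novel_transcript_filter,
    one_to_one_homologs,
    orf_coding_classifier,
    species_specific_genes,
)
from nomescape.io_formats import GeneModel


class TestRpkm:
    def test_arithmetic(self):
        counts = pd.DataFrame({"s1": [100]}, index=["g"])
        rpkm = compute_rpkm(counts, pd.Series({"g": 2_000}),
                            pd.Series({"s1": 10_000_000}))
        assert rpkm.loc["g", "s1"] == pytest.approx(5.0)

    def test_zero_counts_zero_rpkm(self):
        counts = pd.DataFrame({"s1": [0], "s2": [7]}, index=["g"])
        rpkm = compute_rpkm(counts, pd.Series({"g": 1_000}),
                            pd.Series({"s1": 1e6, "s2": 1e6}))
        assert rpkm.loc["g", "s1"] == 0

    def test_scale_invariance(self):
        counts = pd.Series([3, 50, 800], index=list("abc")).to_frame("s1")
        lengths = pd.Series({"a": 500, "b": 1_500, "c": 3_000})
        one = compute_rpkm(counts, lengths, pd.Series({"s1": 1e6}))
        two = compute_rpkm(counts * 2, lengths, pd.Series({"s1": 2e6}))
        pd.testing.assert_frame_equal(one, two)

    @pytest.mark.parametrize("lengths,libs", [
        ({"g": 0}, {"s1": 1e6}),
        ({"g": 100}, {"s1": 0}),
    ])
    def test_zero_length_or_library_rejected(self, lengths, libs):
        counts = pd.DataFrame({"s1": [1]}, index=["g"])
        with pytest.raises(ValueError):
            compute_rpkm(counts, pd.Series(lengths), pd.Series(libs))


class TestDegFilter:
    GROUPS = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}

    def _rpkm(self, mean_a, mean_b):
        return pd.DataFrame({"a1": [mean_a], "a2": [mean_a],
                             "b1": [mean_b], "b2": [mean_b]}, index=["g"])

    def _stats(self, log2fc, p=0.01, fdr=0.02):
        return pd.DataFrame({"log2fc": [log2fc], "p": [p], "fdr": [fdr]}, index=["g"])

    def test_all_criteria_pass(self):
        out = deg_filter(self._stats(1.5), self._rpkm(5, 1), self.GROUPS)
        assert out["is_deg"].iloc[0]
        assert out["direction"].iloc[0] == "a"

    @pytest.mark.parametrize("log2fc,p,fdr,up_rpkm,reason", [
        (1.0, 0.01, 0.02, 5.0, "log2fc exactly 1 fails the strict > 1 rule"),
        (0.9, 0.01, 0.02, 5.0, "log2fc below threshold"),
        (1.5, 0.06, 0.02, 5.0, "p above 0.05"),
        (1.5, 0.01, 0.06, 5.0, "fdr above 0.05"),
        (1.5, 0.01, 0.02, 0.8, "up-group mean RPKM not > 1"),
        (1.5, 0.01, 0.02, 1.0, "up-group mean RPKM exactly 1 fails strict rule"),
    ])
    def test_single_criterion_failures(self, log2fc, p, fdr, up_rpkm, reason):
        out = deg_filter(self._stats(log2fc, p, fdr), self._rpkm(up_rpkm, 0.1),
                         self.GROUPS)
        assert not out["is_deg"].iloc[0], reason

    def test_up_group_is_the_higher_one(self):
        out = deg_filter(self._stats(-2.0), self._rpkm(0.2, 8.0), self.GROUPS)
        assert out["is_deg"].iloc[0]
        assert out["direction"].iloc[0] == "b"
        assert out["mean_rpkm_up"].iloc[0] == pytest.approx(8.0)

    def test_missing_gene_in_rpkm_raises(self):
        with pytest.raises(KeyError):
            deg_filter(self._stats(1.5), self._rpkm(5, 1).rename(index={"g": "x"}),
                       self.GROUPS)


class TestExpressionGroups:
    @pytest.mark.parametrize("rpkm,label", [
        (15.0, "high"), (10.0, "intermediate"), (10.001, "high"),
        (1.0, "low"), (5.0, "intermediate"),
        (0.1, "silenced"), (0.5, "low"), (0.0, "silenced"),
    ])
    def test_boundaries(self, rpkm, label):
        assert assign_expression_groups(pd.Series([rpkm])).iloc[0] == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_expression_groups(pd.Series([-0.1]))

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
    def test_partition_no_gaps_no_overlaps(self, value):
        label = assign_expression_groups(pd.Series([value])).iloc[0]
        expected = ("high" if value > 10 else "intermediate" if value > 1
                    else "low" if value > 0.1 else "silenced")
        assert label == expected


class TestSpeciesSpecific:
    def _rpkm(self, means, n=4, index=None):
        idx = index or [f"g{i}" for i in range(len(means))]
        return pd.DataFrame({f"s{j}": means for j in range(n)}, index=idx)

    def test_clear_human_specific_case(self):
        ra = pd.DataFrame([[2, 3, 4, 3]], index=["g0"])
        rb = pd.DataFrame([[0.2, 0.2, 0.2, 0.2]], index=["m0"])
        hom = pd.DataFrame({"gene_a": ["g0"], "gene_b": ["m0"]})
        out = species_specific_genes(ra, rb, hom)
        assert out["a_specific"].iloc[0]
        assert not out["b_specific"].iloc[0]

    def test_fold_of_four_insufficient(self):
        ra = pd.DataFrame([[4.0] * 4], index=["g0"])
        rb = pd.DataFrame([[1.0 - 1e-9] * 4], index=["m0"])  # fold 4, mean_b < 1
        hom = pd.DataFrame({"gene_a": ["g0"], "gene_b": ["m0"]})
        out = species_specific_genes(ra, rb, hom, fold=5.0)
        assert not out["a_specific"].iloc[0]

    def test_one_to_many_discarded_before_testing(self):
        hom = pd.DataFrame({"gene_a": ["g0", "g0", "g1"],
                            "gene_b": ["m0", "m1", "m2"]})
        assert list(one_to_one_homologs(hom)["gene_a"]) == ["g1"]
        ra = self._rpkm([10, 10], index=["g0", "g1"])
        rb = self._rpkm([0.1, 0.1], index=["m0", "m2"])
        out = species_specific_genes(ra, rb, hom)
        assert list(out["gene_a"]) == ["g1"]

    def test_zero_other_mean_passes_fold_guard(self):
        ra = pd.DataFrame([[3.0] * 4], index=["g0"])
        rb = pd.DataFrame([[0.0] * 4], index=["m0"])
        hom = pd.DataFrame({"gene_a": ["g0"], "gene_b": ["m0"]})
        assert species_specific_genes(ra, rb, hom)["a_specific"].iloc[0]

    def test_matches_brute_force_criteria_on_random_fixture(self, rng):
        n = 1000
        ra = pd.DataFrame(rng.lognormal(0, 2, (n, 5)),
                          index=[f"g{i}" for i in range(n)])
        rb = pd.DataFrame(rng.lognormal(0, 2, (n, 5)),
                          index=[f"m{i}" for i in range(n)])
        hom = pd.DataFrame({"gene_a": ra.index, "gene_b": rb.index})
        out = species_specific_genes(ra, rb, hom).set_index("gene_a")
        for i in range(n):
            a = ra.iloc[i].to_numpy()
            b = rb.iloc[i].to_numpy()
            expected = ((a.mean() > 5 * b.mean() if b.mean() > 0 else a.mean() > 0)
                        and (a >= 0.1).sum() >= 2 and a.mean() > 1 and b.mean() < 1)
            assert bool(out.loc[f"g{i}", "a_specific"]) == expected


def _transcript(tid, chrom="chr1", start=100_000, length=2_000, n_exons=2):
    if n_exons == 1:
        exons = ((start, start + length),)
        end = start + length
    else:
        half = length // n_exons
        exons = tuple((start + i * (half + 500), start + i * (half + 500) + half)
                      for i in range(n_exons))
        end = exons[-1][1]
    return GeneModel(tid, chrom, "+", start, end, exons, biotype="novel")


class TestNovelTranscripts:
    KNOWN = [GeneModel("known", "chr1", "+", 0, 10_000, ((0, 10_000),))]
    WHITELIST = {"chr1", "chr2"}

    def _rpkm(self, tids, value=1.0):
        return pd.DataFrame({"s1": [value] * len(tids)}, index=tids)

    def _run(self, t, **kw):
        return novel_transcript_filter([t], self.KNOWN, self.WHITELIST,
                                       self._rpkm([t.gene_id]), **kw).iloc[0]

    def test_transcript_5kb_from_known_excluded(self):
        row = self._run(_transcript("t", start=15_000))
        assert not row["distance_ok"] and not row["retained"]

    def test_distance_exactly_10kb_excluded_but_beyond_retained(self):
        at_10kb = self._run(_transcript("t", start=20_000))
        assert not at_10kb["distance_ok"]
        beyond = self._run(_transcript("t", start=20_001))
        assert beyond["distance_ok"] and beyond["retained"]

    def test_spliced_length_boundary(self):
        short = self._run(_transcript("t", start=50_000, length=800))
        assert not short["length_ok"]
        exactly_1kb = self._run(_transcript("t", start=50_000, length=1_000))
        assert not exactly_1kb["length_ok"]  # strict: more than 1 kb

    def test_single_exon_excluded(self):
        row = self._run(_transcript("t", start=50_000, n_exons=1, length=3_000))
        assert not row["exons_ok"]
        two = self._run(_transcript("t", start=50_000, n_exons=2, length=3_000))
        assert two["exons_ok"]  # a junction exists with exactly 2 exons

    def test_unexpressed_excluded(self):
        t = _transcript("t", start=50_000)
        out = novel_transcript_filter([t], self.KNOWN, self.WHITELIST,
                                      self._rpkm(["t"], value=0.05))
        assert not out.iloc[0]["expressed"]

    def test_non_whitelisted_chromosome_dropped_with_warning(self):
        t = _transcript("t", chrom="chrUn_scaffold")
        with pytest.warns(UserWarning, match="dropped"):
            out = novel_transcript_filter([t], self.KNOWN, self.WHITELIST,
                                          self._rpkm(["t"]))
        assert not out.iloc[0]["retained"]

    def test_orf_classifier_splits_coding_noncoding(self):
        t = _transcript("t", start=50_000)
        coding_seq = "ATG" + "GCA" * 150 + "TAA"
        noncoding_seq = "ATG" + "GCA" * 20 + "TAA" + "T" * 400
        row = self._run(t, sequences={"t": coding_seq})
        assert row["coding"] == "coding"
        row = self._run(t, sequences={"t": noncoding_seq})
        assert row["coding"] == "noncoding"

    def test_longest_orf_counts_codons(self):
        assert longest_orf_codons("ATG" + "AAA" * 10 + "TGA") == 12
        assert longest_orf_codons("CCCCCC") == 0
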