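"""lncRNA-mRNA pairing, permutation null, cis calling, coexpression network."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nomescape.pairs import (
    call_cis_pairs,
    coexpression_network,
    find_pairs,
    permutation_null,
)


def _gene_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _random_rpkm(rng, gene_ids, n_samples=10):
    return pd.DataFrame(rng.lognormal(1, 1, (len(gene_ids), n_samples)),
                        index=gene_ids)


class TestFindPairs:
    def test_beyond_500kb_not_paired(self, rng):
        lnc = _gene_frame([("l1", "chr1", 0, 1_000, "+")])
        pcg = _gene_frame([("p1", "chr1", 600_000, 601_000, "+")])
        rpkm = _random_rpkm(rng, ["l1", "p1"])
        assert len(find_pairs(lnc, pcg, rpkm)) == 0

    def test_identical_vectors_have_r_one(self, rng):
        lnc = _gene_frame([("l1", "chr1", 0, 1_000, "+")])
        pcg = _gene_frame([("p1", "chr1", 50_000, 51_000, "+")])
        v = rng.lognormal(1, 1, 10)
        rpkm = pd.DataFrame([v, v], index=["l1", "p1"])
        out = find_pairs(lnc, pcg, rpkm)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_excluded(self, rng):
        lnc = _gene_frame([("l1", "chr1", 0, 1_000, "+")])
        pcg = _gene_frame([("p1", "chr1", 50_000, 51_000, "+")])
        rpkm = pd.DataFrame([np.full(10, 2.0), rng.lognormal(1, 1, 10)],
                            index=["l1", "p1"])
        assert len(find_pairs(lnc, pcg, rpkm)) == 0

    def test_overlapping_spans_have_distance_zero(self, rng):
        lnc = _gene_frame([("l1", "chr1", 10_000, 20_000, "+")])
        pcg = _gene_frame([("p1", "chr1", 15_000, 30_000, "-")])
        rpkm = _random_rpkm(rng, ["l1", "p1"])
        out = find_pairs(lnc, pcg, rpkm)
        assert out.loc[0, "distance"] == 0

    def test_matches_brute_force_all_vs_all_scan(self, rng):
        n_l, n_p = 40, 160
        lnc = _gene_frame([(f"l{i}", f"chr{1 + i % 2}", s := int(rng.integers(0, 3_000_000)),
                            s + 2_000, str(rng.choice(["+", "-"])))
                           for i in range(n_l)])
        pcg = _gene_frame([(f"p{i}", f"chr{1 + i % 2}", s := int(rng.integers(0, 3_000_000)),
                            s + 5_000, str(rng.choice(["+", "-"])))
                           for i in range(n_p)])
        rpkm = _random_rpkm(rng, list(lnc.gene_id) + list(pcg.gene_id))
        out = find_pairs(lnc, pcg, rpkm)
        got = set(zip(out["lnc_id"], out["pcg_id"]))

        expected = {}
        for l in lnc.itertuples():
            l_tss = l.start if l.strand == "+" else l.end - 1
            for p in pcg.itertuples():
                if l.chrom != p.chrom:
                    continue
                p_tss = p.start if p.strand == "+" else p.end - 1
                d = 0 if (l.start < p.end and p.start < l.end) else abs(l_tss - p_tss)
                if d <= 500_000:
                    expected[(l.gene_id, p.gene_id)] = d
        assert got == set(expected)
        # r and p match a per-pair scipy oracle
        for row in out.itertuples():
            r_ref, p_ref = stats.pearsonr(rpkm.loc[row.lnc_id], rpkm.loc[row.pcg_id])
            assert row.r == pytest.approx(r_ref, abs=1e-9)
            assert row.p == pytest.approx(p_ref, rel=1e-6, abs=1e-12)
            assert row.distance == expected[(row.lnc_id, row.pcg_id)]


class TestPermutationNull:
    CHROMS = {"chr1": 2_000_000, "chr2": 1_500_000}

    def _sets(self, rng, n_l=10, n_p=30):
        lnc = _gene_frame([(f"l{i}", "chr1", s := int(rng.integers(0, 1_900_000)),
                            s + 1_000, "+") for i in range(n_l)])
        pcg = _gene_frame([(f"p{i}", "chr1", s := int(rng.integers(0, 1_900_000)),
                            s + 3_000, "+") for i in range(n_p)])
        rpkm = _random_rpkm(rng, list(lnc.gene_id) + list(pcg.gene_id), 12)
        return lnc, pcg, rpkm

    def test_zero_reps_rejected(self, rng):
        lnc, pcg, rpkm = self._sets(rng)
        with pytest.raises(ValueError, match="positive"):
            permutation_null(lnc, pcg, rpkm, self.CHROMS, n_reps=0, seed=0)

    def test_gene_lengths_preserved_in_every_repetition(self, rng):
        lnc, pcg, rpkm = self._sets(rng)
        res = permutation_null(lnc, pcg, rpkm, self.CHROMS, n_reps=5, seed=0,
                               keep_placements=True)
        for lnc_r, pcg_r in res.params["placements"]:
            assert ((lnc_r["end"] - lnc_r["start"]).to_numpy()
                    == (lnc["end"] - lnc["start"]).to_numpy()).all()
            assert ((pcg_r["end"] - pcg_r["start"]).to_numpy()
                    == (pcg["end"] - pcg["start"]).to_numpy()).all()
            assert set(lnc_r["chrom"]) <= set(self.CHROMS)

    def test_gene_longer_than_every_chromosome_rejected(self, rng):
        lnc = _gene_frame([("l1", "chr1", 0, 3_000_000, "+")])
        pcg = _gene_frame([("p1", "chr1", 0, 1_000, "+")])
        rpkm = _random_rpkm(rng, ["l1", "p1"])
        with pytest.raises(ValueError, match="longer than every chromosome"):
            permutation_null(lnc, pcg, rpkm, self.CHROMS, n_reps=2, seed=0)

    def test_null_r_distribution_symmetric_for_independent_expression(self, rng):
        lnc, pcg, rpkm = self._sets(rng, n_l=15, n_p=40)
        # light-tailed expression: the symmetry property concerns the
        # permutation machinery, not the tail shape of any one gene set
        rpkm = pd.DataFrame(rng.normal(10, 1, rpkm.shape), index=rpkm.index)
        res = permutation_null(lnc, pcg, rpkm, self.CHROMS, n_reps=40, seed=1)
        assert len(res.null_rs) > 200
        assert abs(np.mean(res.null_rs)) < 3 * np.std(res.null_rs) / np.sqrt(
            len(res.null_rs)) + 0.02
        assert abs(stats.skew(res.null_rs)) < 0.3

    def test_reproducible_for_fixed_seed(self, rng):
        lnc, pcg, rpkm = self._sets(rng)
        a = permutation_null(lnc, pcg, rpkm, self.CHROMS, n_reps=10, seed=7)
        b = permutation_null(lnc, pcg, rpkm, self.CHROMS, n_reps=10, seed=7)
        np.testing.assert_array_equal(a.null_rs, b.null_rs)
        assert a.t_p == b.t_p


class TestCisPairs:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["lnc_id", "pcg_id", "distance", "r", "p"])

    def test_threshold_combinations(self):
        pairs = self._pairs([
            ("l", "p1", 50_000, 0.7, 0.01),    # all pass
            ("l", "p2", 10_000, 0.5, 0.001),   # r too low
            ("l", "p3", 150_000, 0.9, 0.001),  # too far
            ("l", "p4", 50_000, 0.61, 0.06),   # p too high
            ("l", "p5", 99_999, 0.61, 0.05),   # boundary: distance < 100 kb, p <= 0.05
            ("l", "p6", 100_000, 0.9, 0.001),  # boundary: distance exactly 100 kb fails
            ("l", "p7", 50_000, 0.6, 0.001),   # boundary: r exactly 0.6 fails strict >
        ])
        out = call_cis_pairs(pairs)
        assert list(out["pcg_id"]) == ["p1", "p5"]


class TestNetwork:
    def test_threshold_count_and_degrees(self):
        # three genes with pairwise r ~ (0.6, 0.7, 0.2)
        rng = np.random.default_rng(5)
        base = rng.standard_normal(200)
        x = base + 0.9 * rng.standard_normal(200)
        y = base + 0.7 * rng.standard_normal(200)
        z = rng.standard_normal(200)
        rpkm = pd.DataFrame([x, y, z], index=["a", "b", "c"]) + 10
        edges, nodes, skipped = coexpression_network(["a", "b", "c"], rpkm)
        assert len(edges) == 1 and set(edges.loc[0, ["gene_a", "gene_b"]]) == {"a", "b"}
        assert dict(zip(nodes["gene"], nodes["degree"])) == {"a": 1, "b": 1, "c": 0}
        assert skipped == []

    def test_r_exactly_at_threshold_excluded(self):
        rpkm = pd.DataFrame([[1, 2, 3, 4], [1, 2, 3, 4]], index=["a", "b"],
                            dtype=float)
        edges, _, _ = coexpression_network(["a", "b"], rpkm, r_min=1.0)
        assert len(edges) == 0  # r == 1.0 is not > 1.0

    def test_absent_gene_reported_not_fatal(self, rng):
        rpkm = _random_rpkm(rng, ["a", "b"])
        edges, nodes, skipped = coexpression_network(["a", "b", "ghost"], rpkm)
        assert skipped == ["ghost"]
        assert set(nodes["gene"]) == {"a", "b"}

    def test_matches_brute_force_all_pairs(self, rng):
        genes = [f"g{i}" for i in range(30)]
        rpkm = _random_rpkm(rng, genes, 15)
        edges, nodes, _ = coexpression_network(genes, rpkm)
        got = {frozenset((a, b)): r for a, b, r in
               edges[["gene_a", "gene_b", "r"]].itertuples(index=False)}
        expected = {}
        for i in range(30):
            for j in range(i + 1, 30):
                r = stats.pearsonr(rpkm.iloc[i], rpkm.iloc[j])[0]
                if r > 0.5:
                    expected[frozenset((genes[i], genes[j]))] = r
        assert set(got) == set(expected)
        for k in got:
            assert got[k] == pytest.approx(expected[k], abs=1e-9)
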