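"""Differential methylation: window statistics, joining, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nomescape.dmr import (
    DifferentialMethylation,
    call_dmws,
    dmr_element_enrichment,
    join_dmws,
    window_levels,
)


def _uniform_calls(rng, n_sites=300, length=3_000, level=0.7, cov=10):
    pos = np.sort(rng.choice(length, size=n_sites, replace=False))
    meth = rng.binomial(cov, level, size=n_sites)
    return pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "+",
                         "context": "WCG", "meth": meth, "unmeth": cov - meth})


@pytest.fixture()
def four_samples(rng):
    calls = {f"s{i}": _uniform_calls(rng) for i in range(4)}
    groups = {"s0": "a", "s1": "a", "s2": "b", "s3": "b"}
    return calls, groups


class TestWindowLevels:
    def test_three_kb_chromosome_tiles_into_ten_windows(self, four_samples):
        calls, groups = four_samples
        table = window_levels(calls, {"chr1": 3_000})
        assert len(table) <= 10
        starts = table.index.get_level_values("start")
        assert (starts % 300 == 0).all()

    def test_window_with_too_few_sites_in_one_sample_excluded(self, rng):
        a = _uniform_calls(rng, n_sites=300)
        b = a.iloc[:2].copy()  # second sample covers almost nothing
        table = window_levels({"s0": a, "s1": b, "s2": a.copy(), "s3": a.copy()},
                              {"chr1": 3_000})
        assert len(table) <= 1

    def test_per_sample_means_match_brute_force(self, four_samples):
        calls, groups = four_samples
        table = window_levels(calls, {"chr1": 3_000})
        for (chrom, start), row in table.iterrows():
            for sample, df in calls.items():
                sel = df[(df.pos >= start) & (df.pos < start + 300)
                         & (df.meth + df.unmeth >= 3)]
                levels = sel.meth / (sel.meth + sel.unmeth)
                assert row[sample] == pytest.approx(levels.mean(), abs=1e-12)

    def test_group_with_single_sample_rejected(self, rng):
        calls = {f"s{i}": _uniform_calls(rng) for i in range(3)}
        table = window_levels(calls, {"chr1": 3_000})
        with pytest.raises(ValueError, match="2 samples"):
            call_dmws(table, {"s0": "a", "s1": "b", "s2": "b"})


def _window_table(level_rows):
    """Build a window table from {sample: level} rows at consecutive windows."""
    samples = sorted(level_rows[0])
    idx = pd.MultiIndex.from_tuples(
        [("chr1", 300 * i) for i in range(len(level_rows))], names=["chrom", "start"])
    df = pd.DataFrame(level_rows, index=idx)[samples]
    df.insert(0, "end", [300 * i + 300 for i in range(len(level_rows))])
    return df


class TestCallDmws:
    GROUPS = {"a1": "a", "a2": "a", "a3": "a", "a4": "a",
              "b1": "b", "b2": "b", "b3": "b", "b4": "b"}

    def _row(self, a_levels, b_levels):
        row = {f"a{i+1}": v for i, v in enumerate(a_levels)}
        row.update({f"b{i+1}": v for i, v in enumerate(b_levels)})
        return row

    def test_clear_difference_called_with_ttest_oracle(self):
        a, b = (0.90, 0.88, 0.92, 0.86), (0.50, 0.55, 0.48, 0.52)
        table = _window_table([self._row(a, b)])
        out = call_dmws(table, self.GROUPS)
        assert out["is_dmw"].iloc[0]
        assert out["delta"].iloc[0] == pytest.approx(np.mean(a) - np.mean(b))
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert out["p"].iloc[0] == pytest.approx(p)
        assert p < 1e-5

    def test_identical_groups_not_called(self):
        lv = (0.7, 0.72, 0.68, 0.7)
        out = call_dmws(_window_table([self._row(lv, lv)]), self.GROUPS)
        assert not out["is_dmw"].any()

    def test_small_delta_rejected_despite_significance(self):
        a = (0.80, 0.80, 0.80, 0.80)
        b = (0.65, 0.651, 0.649, 0.65)  # delta 0.15 < 0.2, tiny p
        out = call_dmws(_window_table([self._row(a, b)]), self.GROUPS)
        assert out["p"].iloc[0] < 0.001
        assert not out["is_dmw"].any()

    def test_zero_variance_equal_means_gives_p_one(self):
        out = call_dmws(_window_table([self._row((0.7,) * 4, (0.7,) * 4)]), self.GROUPS)
        assert out["p"].iloc[0] == 1.0 and not out["degenerate"].iloc[0]

    def test_zero_variance_unequal_means_flagged(self):
        out = call_dmws(_window_table([self._row((0.9,) * 4, (0.4,) * 4)]), self.GROUPS)
        assert out["p"].iloc[0] == 0.0 and out["degenerate"].iloc[0]

    def test_fdr_is_benjamini_hochberg_over_all_windows(self, rng):
        rows = [self._row(rng.uniform(0, 1, 4), rng.uniform(0, 1, 4))
                for _ in range(50)]
        out = call_dmws(_window_table(rows), self.GROUPS)
        p = out["p"].to_numpy()
        order = np.argsort(p)
        expected = np.empty_like(p)
        m = len(p)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            expected[i] = prev
        np.testing.assert_allclose(out["fdr"].to_numpy(), expected, atol=1e-12)


def _dmw_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "fdr"])


class TestJoinDmws:
    def test_adjacent_same_direction_join(self):
        dmws = _dmw_frame([("chr1", 0, 300, "hyper_a", 0.01),
                           ("chr1", 300, 600, "hyper_a", 0.02)])
        out = join_dmws(dmws)
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (0, 600)
        assert out.loc[0, "n_windows"] == 2
        assert out.loc[0, "min_fdr"] == 0.01

    def test_gap_of_300_joins_but_600_splits(self):
        joined = join_dmws(_dmw_frame([("chr1", 0, 300, "hyper_a", 0.01),
                                       ("chr1", 600, 900, "hyper_a", 0.01)]))
        assert len(joined) == 1
        split = join_dmws(_dmw_frame([("chr1", 0, 300, "hyper_a", 0.01),
                                      ("chr1", 900, 1200, "hyper_a", 0.01)]))
        assert len(split) == 2

    def test_opposite_directions_never_join(self):
        out = join_dmws(_dmw_frame([("chr1", 0, 300, "hyper_a", 0.01),
                                    ("chr1", 300, 600, "hyper_b", 0.01)]))
        assert len(out) == 2
        assert set(out["direction"]) == {"hyper_a", "hyper_b"}

    def test_order_invariant_and_idempotent(self, rng):
        starts = np.sort(rng.choice(100, size=20, replace=False)) * 300
        rows = [("chr1", s, s + 300, str(rng.choice(["hyper_a", "hyper_b"])),
                 float(rng.uniform())) for s in starts]
        a = join_dmws(_dmw_frame(rows))
        b = join_dmws(_dmw_frame(list(reversed(rows))))
        pd.testing.assert_frame_equal(a, b)
        again = join_dmws(a.rename(columns={"min_fdr": "fdr"}))
        assert (again[["chrom", "start", "end", "direction"]].to_numpy()
                == a[["chrom", "start", "end", "direction"]].to_numpy()).all()

    def test_matches_exhaustive_small_case_oracle(self):
        # all direction assignments of 4 consecutive windows
        for dirs in itertools.product(["hyper_a", "hyper_b"], repeat=4):
            rows = [("chr1", 300 * i, 300 * i + 300, d, 0.01)
                    for i, d in enumerate(dirs)]
            out = join_dmws(_dmw_frame(rows))
            # oracle: per direction, runs of windows whose gaps are <= 300
            expected = 0
            for d in set(dirs):
                starts = [300 * i for i, x in enumerate(dirs) if x == d]
                runs = 1
                for u, v in zip(starts, starts[1:]):
                    if v - (u + 300) > 300:
                        runs += 1
                expected += runs
            assert len(out) == expected, dirs


class TestElementEnrichment:
    def test_ratio_arithmetic(self):
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        cgi = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        out = dmr_element_enrichment(dmrs, {"cgi": cgi}, {"chr1": 100_000})
        # all DMR bases in an element covering 1% of the genome -> 100x
        assert out.loc[0, "enrichment"] == pytest.approx(100.0)

    def test_uniform_random_dmrs_enrich_near_one(self, rng):
        starts = rng.integers(0, 99_000, size=400)
        dmrs = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 500})
        elem = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [50_000]})
        out = dmr_element_enrichment(dmrs, {"half": elem}, {"chr1": 100_000})
        assert out.loc[0, "enrichment"] == pytest.approx(1.0, abs=0.15)

    def test_empty_dmr_list_gives_empty_table(self):
        elem = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [100]})
        out = dmr_element_enrichment(pd.DataFrame(columns=["chrom", "start", "end"]),
                                     {"e": elem}, {"chr1": 1_000})
        assert out.empty

    def test_zero_base_element_skipped_with_warning(self):
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        with pytest.warns(UserWarning, match="zero bases"):
            out = dmr_element_enrichment(dmrs, {"none": empty}, {"chr1": 1_000})
        assert out.empty


class TestModel:
    def test_fit_recovers_planted_direction(self, tiny_study):
        model = DifferentialMethylation(
            tiny_study.methylomes, tiny_study.meth_groups,
            tiny_study.config.chrom_lengths)
        res = model.fit()
        truth = tiny_study.truth.dmrs
        for r in truth.itertuples():
            hit = res.dmrs[(res.dmrs.chrom == r.chrom) & (res.dmrs.start < r.end)
                           & (res.dmrs.end > r.start)]
            if len(hit):
                assert (hit["direction"] == r.direction).all()
        assert "DMRs" in res.summary()
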