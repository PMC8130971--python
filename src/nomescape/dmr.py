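"""Differential methylation between two sample groups on fixed 300-bp windows.

The genome is tiled with fixed windows; each window's per-sample WCG level is
the unweighted mean of qualifying site levels (>=3 reads per site, >=3 sites
per window in every sample). A window is differentially methylated (DMW) when
the difference of group means exceeds 20 percentage points with a two-tailed
pooled-variance Student t-test P <= 0.05 and Benjamini-Hochberg FDR <= 0.05.
Neighbouring same-direction DMWs within 300 bp are joined into DMRs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import intervals
from .profiles import genome_bins


def window_levels(
    sample_calls: Mapping[str, pd.DataFrame],
    chrom_lengths,
    window_size: int = 300,
    min_sites: int = 3,
    min_coverage: int = 3,
    require_all_samples: bool = True,
) -> pd.DataFrame:
    """Per-sample window methylation table.

    Returns a DataFrame indexed by (chrom, start) with one level column per
    sample plus an ``end`` column. By default only windows defined (>= 3 WCG
    sites at >= 3x) in *every* sample are retained, so the t-test sees a
    complete matrix.
    """
    per_sample = {}
    for sample, calls in sample_calls.items():
        bins = genome_bins(
            calls, chrom_lengths, track="WCG", bin_size=window_size,
            min_sites=min_sites, min_coverage=min_coverage,
        )
        per_sample[sample] = bins.set_index(["chrom", "start"])[["level"]]
    how = "inner" if require_all_samples else "outer"
    table = None
    for sample, df in per_sample.items():
        df = df.rename(columns={"level": sample})
        table = df if table is None else table.join(df, how=how)
    table = table.sort_index()
    starts = table.index.get_level_values("start").to_numpy(np.int64)
    chroms = table.index.get_level_values("chrom")
    lengths = np.array([chrom_lengths[str(c)] for c in chroms], dtype=np.int64)
    table.insert(0, "end", np.minimum(starts + window_size, lengths))
    return table


def call_dmws(
    window_table: pd.DataFrame,
    groups: Mapping[str, str],
    delta_min: float = 0.2,
    p_max: float = 0.05,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Test every window; flag DMWs.

    ``groups`` maps sample -> group label (exactly two labels, each with >= 2
    samples). ``delta`` is mean(first group) - mean(second group) with groups
    in sorted label order. Windows where both groups have zero variance get
    p := 1 when the means agree and p := 0 (flagged ``degenerate``) when they
    do not. Returns all tested windows with ``delta, t, p, fdr, direction,
    is_dmw`` columns.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    samples_a = [s for s in window_table.columns if s != "end" and groups.get(s) == labels[0]]
    samples_b = [s for s in window_table.columns if s != "end" and groups.get(s) == labels[1]]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs >= 2 samples for the t-test")

    a = window_table[samples_a].to_numpy(float)
    b = window_table[samples_b].to_numpy(float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    delta = mean_a - mean_b
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance windows are resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    degenerate = zero_var & (delta != 0)
    p = np.where(zero_var, np.where(delta == 0, 1.0, 0.0), p)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var, np.where(delta == 0, 0.0, np.inf * np.sign(delta)), t)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")

    out = window_table[["end"]].copy()
    out["mean_a"], out["mean_b"] = mean_a, mean_b
    out["delta"], out["t"], out["p"], out["fdr"] = delta, t, p, fdr
    out["degenerate"] = degenerate
    out["direction"] = np.where(delta > 0, f"hyper_{labels[0]}", f"hyper_{labels[1]}")
    out["is_dmw"] = (np.abs(delta) > delta_min) & (p <= p_max) & (fdr <= fdr_max)
    out.attrs["group_labels"] = tuple(labels)
    return out


def join_dmws(dmws: pd.DataFrame, join_distance: int = 300) -> pd.DataFrame:
    """Join same-direction DMWs whose gap is <= ``join_distance`` into DMRs.

    Joining is transitive and done independently per direction, so adjacent
    opposite-direction windows never share a DMR. Output is sorted by
    (chrom, start) and is invariant to input row order.
    """
    cols = ["chrom", "start", "end", "n_windows", "direction", "min_fdr"]
    if len(dmws) == 0:
        return pd.DataFrame(columns=cols)
    df = dmws.reset_index() if "chrom" not in dmws.columns else dmws.copy()
    rows = []
    for (chrom, direction), g in df.groupby(["chrom", "direction"]):
        g = g.sort_values("start")
        starts = g["start"].to_numpy(np.int64)
        ends = g["end"].to_numpy(np.int64)
        fdrs = g["fdr"].to_numpy(float)
        cur = [starts[0], ends[0], 1, fdrs[0]]
        for s, e, f in zip(starts[1:], ends[1:], fdrs[1:]):
            if s - cur[1] <= join_distance:
                cur[1] = max(cur[1], e)
                cur[2] += 1
                cur[3] = min(cur[3], f)
            else:
                rows.append((chrom, cur[0], cur[1], cur[2], direction, cur[3]))
                cur = [s, e, 1, f]
        rows.append((chrom, cur[0], cur[1], cur[2], direction, cur[3]))
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["chrom", "start", "direction"], kind="mergesort").reset_index(drop=True)


def dmr_element_enrichment(
    dmrs: pd.DataFrame,
    element_tracks: Mapping[str, pd.DataFrame],
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Relative enrichment of DMR bases in each genomic element class.

    enrichment(e) = (DMR bases overlapping e / total DMR bases)
                  / (bases of e / genome bases).
    Elements with zero genomic bases are skipped with a warning. An empty DMR
    list yields an empty table.
    """
    cols = ["element", "enrichment", "dmr_bases", "element_bases"]
    genome = sum(chrom_lengths.values())
    dmr_total = intervals.frame_total_length(dmrs) if len(dmrs) else 0
    rows = []
    for name, track in element_tracks.items():
        elem_total = intervals.frame_total_length(track)
        if elem_total == 0:
            warnings.warn(f"element track {name!r} covers zero bases; skipped")
            continue
        if dmr_total == 0:
            continue
        overlap = intervals.frame_intersect_length(dmrs, track)
        enr = (overlap / dmr_total) / (elem_total / genome)
        rows.append((name, enr, overlap, elem_total))
    return pd.DataFrame(rows, columns=cols)


@dataclass
class DMRResults:
    """Fitted differential-methylation results.

    Attributes
    ----------
    windows : DataFrame
        Every tested window with group means, delta, t, p, BH fdr, direction.
    dmws : DataFrame
        The significant windows.
    dmrs : DataFrame
        Joined regions: chrom, start, end, n_windows, direction, min_fdr.
    """

    windows: pd.DataFrame
    dmws: pd.DataFrame
    dmrs: pd.DataFrame
    group_labels: tuple
    params: dict = field(default_factory=dict)

    def element_enrichment(self, element_tracks, chrom_lengths) -> pd.DataFrame:
        return dmr_element_enrichment(self.dmrs, element_tracks, chrom_lengths)

    def summary(self) -> str:
        a, b = self.group_labels
        n_by_dir = self.dmrs["direction"].value_counts()
        lines = [
            "Differential methylation (300-bp window Student t, BH FDR)",
            f"  groups:            {a} vs {b}",
            f"  windows tested:    {len(self.windows)}",
            f"  DMWs:              {len(self.dmws)}",
            f"  DMRs:              {len(self.dmrs)}"
            f" (hyper_{a}: {int(n_by_dir.get(f'hyper_{a}', 0))},"
            f" hyper_{b}: {int(n_by_dir.get(f'hyper_{b}', 0))})",
            f"  thresholds:        |delta| > {self.params['delta_min']},"
            f" p <= {self.params['p_max']}, FDR <= {self.params['fdr_max']}",
        ]
        return "\n".join(lines)


class DifferentialMethylation:
    """Two-group differential methylation model over fixed genomic windows.

    Parameters
    ----------
    sample_calls : mapping of sample id -> call table (WCG track is used).
    groups : mapping of sample id -> group label (exactly two labels).
    chrom_lengths : mapping of chromosome -> length in bp.
    """

    def __init__(
        self,
        sample_calls: Mapping[str, pd.DataFrame],
        groups: Mapping[str, str],
        chrom_lengths: Mapping[str, int],
        window_size: int = 300,
        min_sites: int = 3,
        min_coverage: int = 3,
        require_all_samples: bool = True,
    ):
        missing = set(sample_calls) - set(groups)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        self.sample_calls = dict(sample_calls)
        self.groups = {s: groups[s] for s in self.sample_calls}
        self.chrom_lengths = dict(chrom_lengths)
        self.window_size = window_size
        self.min_sites = min_sites
        self.min_coverage = min_coverage
        self.require_all_samples = require_all_samples
        self._window_table = None

    def window_table(self) -> pd.DataFrame:
        if self._window_table is None:
            self._window_table = window_levels(
                self.sample_calls, self.chrom_lengths, self.window_size,
                self.min_sites, self.min_coverage, self.require_all_samples,
            )
        return self._window_table

    def fit(
        self,
        delta_min: float = 0.2,
        p_max: float = 0.05,
        fdr_max: float = 0.05,
        join_distance: int = 300,
    ) -> DMRResults:
        windows = call_dmws(self.window_table(), self.groups, delta_min, p_max, fdr_max)
        dmws = windows[windows["is_dmw"]]
        dmrs = join_dmws(dmws, join_distance)
        return DMRResults(
            windows=windows, dmws=dmws, dmrs=dmrs,
            group_labels=windows.attrs["group_labels"],
            params=dict(delta_min=delta_min, p_max=p_max, fdr_max=fdr_max,
                        join_distance=join_distance, window_size=self.window_size),
        )
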