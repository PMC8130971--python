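"""Nucleosome-depleted region detection from GCH accessibility.

Sliding 100-bp windows (20-bp step) are tested against the pooled
whole-genome GCH background with a 1-df Pearson chi-squared test on the 2x2
table of (methylated, unmethylated) GCH calls. Windows significant at
p <= 1e-10 *and* above the background level are merged; each merged region is
re-tested on its pooled counts and kept only if it still reaches p <= 1e-10,
contains more than 5 GCH sites and is longer than 140 bp. NDRs overlapping a
promoter (TSS - 1 kb .. TSS + 0.5 kb) are proximal, all others distal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals
from .profiles import qualifying_sites


@dataclass(frozen=True)
class BackgroundModel:
    """Genome-wide pooled GCH call counts."""

    m: int  # methylated calls
    u: int  # unmethylated calls

    @property
    def level(self) -> float:
        return self.m / (self.m + self.u)


def build_background(calls: pd.DataFrame, min_coverage: int = 3) -> BackgroundModel:
    """Pool methylated/unmethylated counts over all qualifying GCH sites."""
    df = qualifying_sites(calls, "GCH", min_coverage)
    if len(df) == 0:
        raise ValueError("no qualifying GCH sites to build a background from")
    return BackgroundModel(m=int(df["meth"].sum()), u=int(df["unmeth"].sum()))


def chi2_vs_background(m, u, background: BackgroundModel):
    """Pearson chi-squared statistic and p (1 df, no continuity correction)
    for pooled window counts (m, u) against the background table."""
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    bm, bu = float(background.m), float(background.u)
    n = m + u + bm + bu
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = n * (m * bu - u * bm) ** 2 / ((m + u) * (bm + bu) * (m + bm) * (u + bu))
    p = stats.chi2.sf(stat, df=1)
    return stat, p


def scan_windows(
    calls: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    background: BackgroundModel,
    window: int = 100,
    step: int = 20,
    p_max: float = 1e-10,
    min_coverage: int = 3,
) -> pd.DataFrame:
    """Significant sliding windows: p <= p_max and level above background.

    Windows with zero GCH calls are skipped. ``window`` must be a multiple of
    ``step``.
    """
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    w_steps = window // step
    df = qualifying_sites(calls, "GCH", min_coverage)
    out = []
    for chrom, g in df.groupby("chrom", observed=True):
        length = chrom_lengths[str(chrom)]
        n_steps = -(-length // step)
        idx = g["pos"].to_numpy(np.int64) // step
        step_m = np.bincount(idx, weights=g["meth"], minlength=n_steps)
        step_u = np.bincount(idx, weights=g["unmeth"], minlength=n_steps)
        if n_steps < w_steps:
            continue
        kernel = np.ones(w_steps)
        win_m = np.convolve(step_m, kernel, mode="valid")
        win_u = np.convolve(step_u, kernel, mode="valid")
        total = win_m + win_u
        has_calls = total > 0
        stat, p = chi2_vs_background(win_m, win_u, background)
        with np.errstate(invalid="ignore"):
            level = np.where(has_calls, win_m / np.maximum(total, 1), np.nan)
        sig = has_calls & (p <= p_max) & (level > background.level)
        starts = np.nonzero(sig)[0] * step
        if starts.size:
            res = pd.DataFrame({
                "chrom": str(chrom),
                "start": starts,
                "end": np.minimum(starts + window, length),
                "meth": win_m[sig].astype(np.int64),
                "unmeth": win_u[sig].astype(np.int64),
                "level": level[sig],
                "p": p[sig],
            })
            out.append(res)
    if not out:
        return pd.DataFrame(columns=["chrom", "start", "end", "meth", "unmeth", "level", "p"])
    return pd.concat(out, ignore_index=True)


def merge_and_filter(
    significant_windows: pd.DataFrame,
    calls: pd.DataFrame,
    background: BackgroundModel,
    p_max: float = 1e-10,
    min_sites: int = 5,   # kept if n_gch_sites > min_sites (strict)
    min_length: int = 140,  # kept if length > min_length (strict)
    min_coverage: int = 3,
) -> pd.DataFrame:
    """Merge overlapping/touching significant windows and re-test each region.

    All three criteria are re-evaluated on the merged region's pooled counts,
    not inherited from its windows.
    """
    cols = ["chrom", "start", "end", "gch_level", "n_gch_sites", "n_meth", "n_total", "p"]
    if len(significant_windows) == 0:
        return pd.DataFrame(columns=cols)
    df = qualifying_sites(calls, "GCH", min_coverage)
    sites = {
        str(c): (g["pos"].to_numpy(np.int64),
                 g["meth"].to_numpy(np.int64),
                 g["unmeth"].to_numpy(np.int64),
                 g["level"].to_numpy(float))
        for c, g in df.groupby("chrom", observed=True)
    }
    rows = []
    for chrom, g in significant_windows.groupby("chrom"):
        ms, me = intervals.merge_intervals(g["start"].to_numpy(), g["end"].to_numpy())
        pos, m, u, level = sites[str(chrom)]
        for s, e in zip(ms, me):
            if e - s <= min_length:
                continue
            lo, hi = np.searchsorted(pos, [s, e])
            n_sites = hi - lo
            if n_sites <= min_sites:
                continue
            rm, ru = int(m[lo:hi].sum()), int(u[lo:hi].sum())
            _, p = chi2_vs_background(rm, ru, background)
            if not (p <= p_max):
                continue
            rows.append((str(chrom), int(s), int(e), float(level[lo:hi].mean()),
                         int(n_sites), rm, rm + ru, float(p)))
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def classify_ndrs(ndrs: pd.DataFrame, promoters: pd.DataFrame) -> pd.DataFrame:
    """Label each NDR ``proximal`` if it overlaps any promoter by >= 1 bp, else ``distal``."""
    out = ndrs.copy()
    if len(out) == 0:
        out["cls"] = pd.Series(dtype=str)
        return out
    cls = np.full(len(out), "distal", dtype=object)
    prom_by_chrom = dict(tuple(promoters.groupby("chrom")))
    for chrom, idx in out.groupby("chrom").groups.items():
        prom = prom_by_chrom.get(chrom)
        if prom is None:
            continue
        sub = out.loc[idx]
        hit = intervals.overlaps_any(
            sub["start"].to_numpy(), sub["end"].to_numpy(),
            prom["start"].to_numpy(), prom["end"].to_numpy(),
        )
        cls[out.index.get_indexer(idx)[hit]] = "proximal"
    out["cls"] = cls
    return out


@dataclass
class NDRResults:
    """Called nucleosome-depleted regions plus the background they were tested against."""

    ndrs: pd.DataFrame
    background: BackgroundModel
    params: dict = field(default_factory=dict)

    def classify(self, promoters: pd.DataFrame) -> "NDRResults":
        """Return a copy with the proximal/distal class column filled in."""
        return NDRResults(classify_ndrs(self.ndrs, promoters), self.background, self.params)

    def summary(self) -> str:
        lines = [
            "Nucleosome-depleted regions (GCH vs genome background, chi-squared)",
            f"  background level:  {self.background.level:.4f}"
            f" ({self.background.m}/{self.background.m + self.background.u} calls)",
            f"  NDRs called:       {len(self.ndrs)}",
        ]
        if "cls" in self.ndrs.columns and len(self.ndrs):
            counts = self.ndrs["cls"].value_counts()
            lines.append(
                f"  proximal/distal:   {int(counts.get('proximal', 0))}"
                f"/{int(counts.get('distal', 0))}"
            )
        lines.append(
            f"  criteria:          p <= {self.params['p_max']},"
            f" > {self.params['min_sites']} GCH sites,"
            f" length > {self.params['min_length']} bp"
        )
        return "\n".join(lines)


class NucleosomeDepletion:
    """Sliding-window NDR model for one pooled GCH call table."""

    def __init__(
        self,
        calls: pd.DataFrame,
        chrom_lengths: Mapping[str, int],
        window: int = 100,
        step: int = 20,
        min_coverage: int = 3,
    ):
        self.calls = calls
        self.chrom_lengths = dict(chrom_lengths)
        self.window = window
        self.step = step
        self.min_coverage = min_coverage

    def fit(
        self, p_max: float = 1e-10, min_sites: int = 5, min_length: int = 140
    ) -> NDRResults:
        background = build_background(self.calls, self.min_coverage)
        windows = scan_windows(
            self.calls, self.chrom_lengths, background,
            self.window, self.step, p_max, self.min_coverage,
        )
        ndrs = merge_and_filter(
            windows, self.calls, background, p_max, min_sites, min_length,
            self.min_coverage,
        )
        return NDRResults(
            ndrs=ndrs, background=background,
            params=dict(p_max=p_max, min_sites=min_sites, min_length=min_length,
                        window=self.window, step=self.step),
        )
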