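"""Multiomics relationship analyses linking expression to methylation/accessibility.

Implements the expression-group metagene profiles, the 100-bin
expression-ranked gene-body curves, the promoter-level Spearman summaries
(R1: accessibility vs expression, R2: methylation vs expression), and a
scalar bell statistic B that quantifies whether a ranked curve peaks (B > 0)
or dips (B < 0) at intermediate expression. B is defined as the mean level
over bins 40-60 minus the mean over the edge bins (1-10 and 91-100); it is a
deliberately simple summary of the qualitative "bell shape".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import assign_expression_groups
from .profiles import (
    GENEBODY_LAYOUT,
    TSS_LAYOUT,
    MetageneProfile,
    metagene_profile,
)


@dataclass
class RankedBinCurve:
    """Per-bin means after ranking expressed genes and splitting into equal bins."""

    levels: np.ndarray        # mean level per bin, ascending expression
    mean_expression: np.ndarray
    bin_sizes: np.ndarray
    track: str
    n_genes: int

    @property
    def n_bins(self) -> int:
        return len(self.levels)


@dataclass
class CorrelationSummary:
    """Spearman summaries of promoter state vs expression on binned curves."""

    r1: float  # promoter accessibility (GCH) vs expression rank
    r2: float  # promoter methylation (WCG) vs expression rank
    n_bins: int

    def summary(self) -> str:
        return (
            "Promoter-state vs expression (Spearman on 100 expression bins)\n"
            f"  R1 (accessibility): {self.r1:.4f}\n"
            f"  R2 (methylation):   {self.r2:.4f}"
        )


def group_profiles(
    rpkm_summary: pd.Series,
    wcg_calls: pd.DataFrame,
    gch_calls: pd.DataFrame,
    genes,
    min_sites: int = 3,
    min_coverage: int = 3,
) -> dict:
    """Per-expression-group metagene profiles.

    Genes are partitioned by :func:`assign_expression_groups` on their summary
    RPKM; each group gets a TSS +/- 2 kb GCH profile and a gene-body +/- 5 kb
    WCG profile. Empty groups are omitted with a warning.
    """
    labels = assign_expression_groups(rpkm_summary)
    by_id = {g.gene_id: g for g in genes}
    out = {}
    for label in labels.cat.categories:
        members = [by_id[g] for g in labels.index[labels == label] if g in by_id]
        if not members:
            warnings.warn(f"expression group {label!r} is empty; profile omitted")
            continue
        out[label] = {
            "tss_gch": metagene_profile(
                gch_calls, members, TSS_LAYOUT, "GCH", min_sites, min_coverage),
            "genebody_wcg": metagene_profile(
                wcg_calls, members, GENEBODY_LAYOUT, "WCG", min_sites, min_coverage),
            "n_genes": len(members),
        }
    return out


def ranked_bin_curve(
    rpkm_summary: pd.Series,
    gene_levels: pd.Series,
    track: str,
    n_bins: int = 100,
) -> RankedBinCurve:
    """Rank expressed genes (RPKM > 0) and average their levels in equal bins.

    Genes without a defined level are dropped. Ties in RPKM are broken by
    gene id for determinism. With ``n`` genes, the first ``n mod n_bins``
    bins get the extra gene each. Raises if fewer than ``n_bins`` genes
    remain (use fewer bins).
    """
    df = pd.DataFrame({"rpkm": rpkm_summary, "level": gene_levels}).dropna()
    df = df[df["rpkm"] > 0]
    if len(df) < n_bins:
        raise ValueError(
            f"only {len(df)} expressed genes with defined levels; "
            f"need >= {n_bins} (reduce n_bins)"
        )
    # stable sort with gene-id order breaking RPKM ties, for determinism
    df = df.sort_index(kind="mergesort").sort_values("rpkm", kind="mergesort")
    n = len(df)
    q, r = divmod(n, n_bins)
    sizes = np.full(n_bins, q, dtype=np.int64)
    sizes[:r] += 1
    bin_idx = np.repeat(np.arange(n_bins), sizes)
    levels = df["level"].to_numpy(float)
    rpkm = df["rpkm"].to_numpy(float)
    level_means = np.bincount(bin_idx, weights=levels, minlength=n_bins) / sizes
    rpkm_means = np.bincount(bin_idx, weights=rpkm, minlength=n_bins) / sizes
    return RankedBinCurve(
        levels=level_means, mean_expression=rpkm_means, bin_sizes=sizes,
        track=track, n_genes=n,
    )


def bell_statistic(
    curve,
    center: tuple = (40, 60),
    edges: tuple = ((1, 10), (91, 100)),
) -> float:
    """B = mean(level over center bins) - mean(level over edge bins).

    Bin ranges are 1-based inclusive on a 100-bin curve. Undefined (NaN) bins
    are excluded from the means; more than 50% undefined bins overall raises.
    """
    levels = curve.levels if isinstance(curve, RankedBinCurve) else np.asarray(curve, float)
    if len(levels) != 100:
        raise ValueError("bell statistic is defined on 100-bin curves")
    if np.isnan(levels).mean() > 0.5:
        raise ValueError("more than half of the bins are undefined")
    c = levels[center[0] - 1:center[1]]
    e = np.concatenate([levels[lo - 1:hi] for lo, hi in edges])
    return float(np.nanmean(c) - np.nanmean(e))


def promoter_correlations(
    rpkm_summary: pd.Series,
    promoter_wcg: pd.Series,
    promoter_gch: pd.Series,
    n_bins: int = 100,
) -> CorrelationSummary:
    """R1/R2: Spearman correlation of binned promoter state with expression rank.

    Each track is binned independently via :func:`ranked_bin_curve`; the
    statistic is the Spearman correlation of the per-bin mean level with the
    bin index. All-tied levels yield NaN (undefined).
    """
    rs = {}
    for key, series in (("r1", promoter_gch), ("r2", promoter_wcg)):
        curve = ranked_bin_curve(rpkm_summary, series, track=key, n_bins=n_bins)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, _ = stats.spearmanr(np.arange(n_bins), curve.levels)
        rs[key] = float(rho)
    return CorrelationSummary(r1=rs["r1"], r2=rs["r2"], n_bins=n_bins)
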