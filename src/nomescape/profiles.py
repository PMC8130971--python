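"""Context classification and methylation/accessibility level estimation.

The two read-depth rules from NOMe-seq practice are kept separate throughout:

* a *site* contributes a level only with >= 3 reads (``min_coverage``);
* a *region* gets a level only with >= 3 qualifying sites (``min_sites``),
  and that level is the unweighted mean of the site levels (pooled read
  counts are recorded alongside so the coverage-weighted alternative stays
  computable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

WCG_TRIS = frozenset({"ACG", "TCG"})
GCH_TRIS = frozenset({"GCA", "GCT", "GCC"})

_CLASS_BY_TRI = {}
for _a in "ACGT":
    for _b in "ACGT":
        _tri = f"{_a}C{_b}"
        if _tri in WCG_TRIS:
            _CLASS_BY_TRI[_tri] = "WCG"
        elif _tri in GCH_TRIS:
            _CLASS_BY_TRI[_tri] = "GCH"
        else:
            _CLASS_BY_TRI[_tri] = "OTHER"


def classify_context(trinucleotide: str) -> str:
    """WCG (ACG/TCG), GCH (GCA/GCT/GCC) or OTHER for a C-centred trinucleotide.

    GCG and CCG are ambiguous between the endogenous and enzymatic signal and
    map to OTHER, as does anything containing N.
    """
    tri = trinucleotide.upper()
    if len(tri) != 3 or tri[1] != "C":
        raise ValueError(f"{trinucleotide!r} is not a C-centred trinucleotide")
    return _CLASS_BY_TRI.get(tri, "OTHER")


def classify_context_series(tris: pd.Series) -> pd.Series:
    """Vectorised :func:`classify_context`; non-C-centred strings become OTHER."""
    return tris.str.upper().map(_CLASS_BY_TRI).fillna("OTHER")


def site_level(meth: int, unmeth: int, min_coverage: int = 3):
    """Methylated fraction C/(C+T) of one site, or ``None`` below the depth cutoff."""
    depth = meth + unmeth
    if depth < min_coverage:
        return None
    return meth / depth


def qualifying_sites(
    calls: pd.DataFrame, track: str | None = None, min_coverage: int = 3
) -> pd.DataFrame:
    """Subset of a call table with site levels attached.

    Keeps sites of the requested track (``WCG``/``GCH``; ``None`` keeps all)
    with read depth >= ``min_coverage`` and adds a ``level`` column.
    """
    df = calls
    if track is not None:
        df = df[df["context"] == track]
    depth = df["meth"] + df["unmeth"]
    df = df[depth >= min_coverage].copy()
    df["level"] = df["meth"] / (df["meth"] + df["unmeth"])
    return df


@dataclass(frozen=True)
class MethRegion:
    """An interval with its aggregated level and qualifying-site count."""

    chrom: str
    start: int
    end: int
    level: float
    n_sites: int
    n_meth: int
    n_total: int
    track: str


def region_level(
    calls: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    track: str,
    min_sites: int = 3,
    min_coverage: int = 3,
):
    """Unweighted mean site level inside [start, end), or None if < min_sites qualify."""
    if not start < end:
        raise ValueError(f"empty interval [{start}, {end})")
    df = qualifying_sites(calls, track, min_coverage)
    df = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)]
    if len(df) < min_sites:
        return None
    return MethRegion(
        chrom=chrom, start=start, end=end,
        level=float(df["level"].mean()), n_sites=int(len(df)),
        n_meth=int(df["meth"].sum()), n_total=int((df["meth"] + df["unmeth"]).sum()),
        track=track,
    )


def genome_bins(
    calls: pd.DataFrame,
    chrom_lengths,
    track: str,
    bin_size: int = 1000,
    min_sites: int = 3,
    min_coverage: int = 3,
) -> pd.DataFrame:
    """Tile each chromosome with fixed bins and aggregate qualifying sites.

    Returns one row per bin that satisfies the >= ``min_sites`` rule, with
    columns ``chrom, start, end, level, n_sites, n_meth, n_total``. Bin
    boundaries are multiples of ``bin_size`` (the last bin is clipped).
    """
    df = qualifying_sites(calls, track, min_coverage)
    out = []
    for chrom, g in df.groupby("chrom", observed=True):
        length = chrom_lengths[str(chrom)]
        idx = g["pos"].to_numpy() // bin_size
        agg = g.assign(_bin=idx, _depth=g["meth"] + g["unmeth"]).groupby("_bin").agg(
            level=("level", "mean"),
            n_sites=("level", "size"),
            n_meth=("meth", "sum"),
            n_total=("_depth", "sum"),
        )
        agg = agg[agg["n_sites"] >= min_sites].reset_index()
        agg.insert(0, "chrom", str(chrom))
        agg.insert(1, "start", agg["_bin"].astype(np.int64) * bin_size)
        agg.insert(2, "end", np.minimum(agg["start"] + bin_size, length))
        out.append(agg.drop(columns="_bin"))
    if not out:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "level", "n_sites", "n_meth", "n_total"]
        )
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------

GENEBODY_LAYOUT = "genebody"  # 10 x 500 bp upstream | 100 body bins | 10 x 500 bp downstream
TSS_LAYOUT = "tss"            # TSS +/- 2 kb as 200 x 20 bp bins

N_BINS = {GENEBODY_LAYOUT: 120, TSS_LAYOUT: 200}
FLANK_BINS = 10
FLANK_BIN_SIZE = 500
BODY_BINS = 100
TSS_HALF = 2000
TSS_BIN_SIZE = 20


@dataclass
class MetageneProfile:
    """Across-gene average of per-gene binned levels, 5'->3' oriented."""

    layout: str
    track: str
    bins: np.ndarray          # mean level per bin (nan where no gene contributed)
    n_genes_per_bin: np.ndarray
    n_genes: int


def _genebody_boundaries(gene) -> np.ndarray:
    """121 boundary positions: flank | 100 body fractions | flank, in genomic coords."""
    body = np.floor(np.linspace(gene.start, gene.end, BODY_BINS + 1)).astype(np.int64)
    up = gene.start - FLANK_BIN_SIZE * np.arange(FLANK_BINS, 0, -1)
    down = gene.end + FLANK_BIN_SIZE * np.arange(1, FLANK_BINS + 1)
    return np.concatenate([up, body, down])


def _tss_boundaries(gene) -> np.ndarray:
    tss = gene.tss
    return tss - TSS_HALF + TSS_BIN_SIZE * np.arange(
        0, 2 * TSS_HALF // TSS_BIN_SIZE + 1
    )


def metagene_profile(
    calls: pd.DataFrame,
    genes,
    layout: str,
    track: str,
    min_sites: int = 3,
    min_coverage: int = 3,
) -> MetageneProfile:
    """Average binned levels across genes.

    Per gene, sites falling in each bin are averaged (bins with fewer than
    ``min_sites`` qualifying sites are undefined for that gene); the profile
    is the across-gene mean of the defined per-gene bin levels. Minus-strand
    genes contribute in transcriptional (5'->3') orientation. Genes shorter
    than 100 bp are skipped (with a warning) under the gene-body layout.
    """
    if layout not in N_BINS:
        raise ValueError(f"unknown layout {layout!r}")
    n_bins = N_BINS[layout]
    df = qualifying_sites(calls, track, min_coverage)
    pos_by_chrom = {
        str(c): (g["pos"].to_numpy(np.int64), g["level"].to_numpy(float))
        for c, g in df.groupby("chrom", observed=True)
    }

    total = np.zeros(n_bins)
    count = np.zeros(n_bins, dtype=np.int64)
    used = 0
    for gene in genes:
        if layout == GENEBODY_LAYOUT and gene.end - gene.start < BODY_BINS:
            warnings.warn(f"gene {gene.gene_id} shorter than {BODY_BINS} bp; skipped")
            continue
        entry = pos_by_chrom.get(gene.chrom)
        if entry is None:
            continue
        pos, level = entry
        bounds = (
            _genebody_boundaries(gene) if layout == GENEBODY_LAYOUT
            else _tss_boundaries(gene)
        )
        lo, hi = np.searchsorted(pos, [bounds[0], bounds[-1]])
        if lo == hi:
            continue
        p, v = pos[lo:hi], level[lo:hi]
        which = np.searchsorted(bounds, p, side="right") - 1
        ok = (which >= 0) & (which < n_bins)
        p, v, which = p[ok], v[ok], which[ok]
        sums = np.bincount(which, weights=v, minlength=n_bins)
        ns = np.bincount(which, minlength=n_bins)
        defined = ns >= min_sites
        with np.errstate(invalid="ignore"):
            gene_bins = sums / ns
        if gene.strand == "-":
            gene_bins = gene_bins[::-1]
            defined = defined[::-1]
        total[defined] += gene_bins[defined]
        count[defined] += 1
        used += 1

    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return MetageneProfile(layout=layout, track=track, bins=mean,
                           n_genes_per_bin=count, n_genes=used)


def interval_levels(
    calls: pd.DataFrame,
    regions: pd.DataFrame,
    track: str,
    min_sites: int = 3,
    min_coverage: int = 3,
) -> pd.Series:
    """Per-region unweighted mean site level for a table of named intervals.

    ``regions`` needs columns ``chrom, start, end, gene_id``; regions failing
    the >= ``min_sites`` rule are absent from the result.
    """
    df = qualifying_sites(calls, track, min_coverage)
    by_chrom = {
        str(c): (g["pos"].to_numpy(np.int64), g["level"].to_numpy(float))
        for c, g in df.groupby("chrom", observed=True)
    }
    out = {}
    for row in regions.itertuples(index=False):
        entry = by_chrom.get(str(row.chrom))
        if entry is None:
            continue
        pos, level = entry
        lo, hi = np.searchsorted(pos, [row.start, row.end])
        if hi - lo >= min_sites:
            out[row.gene_id] = float(level[lo:hi].mean())
    return pd.Series(out, dtype=float)


def gene_body_levels(calls, genes, track: str, min_sites: int = 3,
                     min_coverage: int = 3) -> pd.Series:
    """Per-gene mean site level over the gene body (TSS..TES)."""
    regions = pd.DataFrame(
        [(g.chrom, g.start, g.end, g.gene_id) for g in genes],
        columns=["chrom", "start", "end", "gene_id"],
    )
    return interval_levels(calls, regions, track, min_sites, min_coverage)


def promoter_levels(calls, genes, chrom_lengths=None, track: str = "GCH",
                    min_sites: int = 3, min_coverage: int = 3) -> pd.Series:
    """Per-gene mean site level over the promoter (TSS - 1 kb .. TSS + 0.5 kb)."""
    return interval_levels(calls, promoter_regions(genes, chrom_lengths),
                           track, min_sites, min_coverage)


def promoter_regions(
    genes, chrom_lengths=None, upstream: int = 1000, downstream: int = 500
) -> pd.DataFrame:
    """Strand-aware promoter intervals (default: TSS - 1 kb to TSS + 0.5 kb).

    A plus-strand gene with TSS t yields [t - upstream, t + downstream); a
    minus-strand gene mirrors to [t - downstream, t + upstream). Intervals
    are clipped at chromosome ends.
    """
    rows = []
    for g in genes:
        t = g.tss
        if g.strand == "+":
            s, e = t - upstream, t + downstream
        else:
            s, e = t - downstream, t + upstream
        s = max(s, 0)
        if chrom_lengths is not None:
            e = min(e, chrom_lengths[g.chrom])
        rows.append((g.chrom, s, e, g.gene_id, g.strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])
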