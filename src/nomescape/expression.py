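"""Expression quantification and the filter cascades built on it.

Covers RPKM computation, the differential-expression filter layer (the DE
statistic itself is a pluggable engine; the built-in default is a Welch
t-test on log2(RPKM+1)), expression-group assignment, cross-species
specifically-expressed gene classification, and the novel-transcript filter
cascade with a pluggable coding-potential classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneModel

EXPRESSION_GROUPS = ("high", "intermediate", "low", "silenced")


@dataclass
class ExpressionMatrix:
    """Genes x samples read counts and RPKM with a sample -> group mapping."""

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    groups: dict
    gene_lengths: pd.Series | None = None

    def __post_init__(self):
        if not self.counts.index.equals(self.rpkm.index) or not self.counts.columns.equals(
            self.rpkm.columns
        ):
            raise ValueError("counts and rpkm must share genes and samples")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        if not np.isfinite(self.rpkm.to_numpy()).all() or (self.rpkm.to_numpy() < 0).any():
            raise ValueError("rpkm must be finite and non-negative")

    @property
    def genes(self) -> list:
        return list(self.counts.index)

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    def samples_of(self, group: str) -> list:
        return [s for s in self.samples if self.groups[s] == group]

    def mean_rpkm(self, group: str | None = None) -> pd.Series:
        cols = self.samples if group is None else self.samples_of(group)
        return self.rpkm[cols].mean(axis=1)


def compute_rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of (merged-exon) transcript per million mapped reads.

    ``library_sizes`` defaults to the per-sample count totals.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    else:
        library_sizes = pd.Series(library_sizes).reindex(counts.columns)
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ValueError("every sample needs a positive library size")
    denom = np.outer(lengths.to_numpy() / 1e3, library_sizes.to_numpy() / 1e6)
    return pd.DataFrame(
        counts.to_numpy() / denom, index=counts.index, columns=counts.columns
    )


# ---------------------------------------------------------------------------
# Differential expression filter layer
# ---------------------------------------------------------------------------

def welch_log_rpkm_engine(expr: ExpressionMatrix, labels: Sequence[str]) -> pd.DataFrame:
    """Built-in DE statistic: Welch t-test on log2(RPKM+1), BH FDR.

    log2fc is the difference of group means of log2(RPKM+1), first label
    minus second. Any engine returning columns ``log2fc, p, fdr`` indexed by
    gene can replace it.
    """
    a = np.log2(expr.rpkm[expr.samples_of(labels[0])].to_numpy() + 1.0)
    b = np.log2(expr.rpkm[expr.samples_of(labels[1])].to_numpy() + 1.0)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"log2fc": log2fc, "p": p, "fdr": fdr}, index=expr.counts.index)


def deg_filter(
    stats_table: pd.DataFrame,
    rpkm: pd.DataFrame,
    groups: Mapping[str, str],
    log2fc_min: float = 1.0,
    p_max: float = 0.05,
    fdr_max: float = 0.05,
    min_rpkm: float = 1.0,
) -> pd.DataFrame:
    """Apply the four DEG criteria to a per-gene statistics table.

    A gene is a DEG iff |log2fc| > log2fc_min, p <= p_max, fdr <= fdr_max and
    the mean RPKM in the *up-regulated* group exceeds ``min_rpkm``. The
    returned table covers all genes with a boolean ``is_deg`` and the
    direction (label of the higher group).
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    missing = set(stats_table.index) - set(rpkm.index)
    if missing:
        raise KeyError(f"genes missing from rpkm: {sorted(missing)[:5]}")
    sub = rpkm.loc[stats_table.index]
    mean_a = sub[[s for s in rpkm.columns if groups[s] == labels[0]]].mean(axis=1)
    mean_b = sub[[s for s in rpkm.columns if groups[s] == labels[1]]].mean(axis=1)
    up_is_a = stats_table["log2fc"] > 0
    out = stats_table.copy()
    out["direction"] = np.where(up_is_a, labels[0], labels[1])
    out["mean_rpkm_up"] = np.where(up_is_a, mean_a, mean_b)
    out["is_deg"] = (
        (out["log2fc"].abs() > log2fc_min)
        & (out["p"] <= p_max)
        & (out["fdr"] <= fdr_max)
        & (out["mean_rpkm_up"] > min_rpkm)
    )
    return out


@dataclass
class DEGResults:
    table: pd.DataFrame
    group_labels: tuple
    params: dict = field(default_factory=dict)

    @property
    def degs(self) -> pd.DataFrame:
        return self.table[self.table["is_deg"]]

    def summary(self) -> str:
        a, b = self.group_labels
        d = self.degs
        return "\n".join([
            "Differential expression (filter cascade on pluggable DE statistic)",
            f"  groups:      {a} vs {b}",
            f"  genes:       {len(self.table)}",
            f"  DEGs:        {len(d)} (up in {a}: {int((d['direction'] == a).sum())},"
            f" up in {b}: {int((d['direction'] == b).sum())})",
            f"  criteria:    |log2FC| > {self.params['log2fc_min']},"
            f" p <= {self.params['p_max']}, FDR <= {self.params['fdr_max']},"
            f" up-group RPKM > {self.params['min_rpkm']}",
        ])


class DifferentialExpression:
    """Two-group DEG model: pluggable statistic engine + the filter criteria."""

    def __init__(self, expr: ExpressionMatrix, engine: Callable | None = None):
        self.expr = expr
        self.engine = engine or welch_log_rpkm_engine
        self.labels = tuple(sorted(set(expr.groups.values())))
        if len(self.labels) != 2:
            raise ValueError(f"need exactly 2 groups, got {self.labels}")

    def fit(
        self,
        log2fc_min: float = 1.0,
        p_max: float = 0.05,
        fdr_max: float = 0.05,
        min_rpkm: float = 1.0,
    ) -> DEGResults:
        stats_table = self.engine(self.expr, self.labels)
        table = deg_filter(
            stats_table, self.expr.rpkm, self.expr.groups,
            log2fc_min, p_max, fdr_max, min_rpkm,
        )
        return DEGResults(
            table=table, group_labels=self.labels,
            params=dict(log2fc_min=log2fc_min, p_max=p_max, fdr_max=fdr_max,
                        min_rpkm=min_rpkm),
        )


# ---------------------------------------------------------------------------
# Expression groups
# ---------------------------------------------------------------------------

def assign_expression_groups(rpkm: pd.Series) -> pd.Series:
    """Partition genes by summary RPKM: high > 10, intermediate (1, 10],
    low (0.1, 1], silenced <= 0.1."""
    values = pd.Series(rpkm, dtype=float)
    if (values < 0).any():
        raise ValueError("negative RPKM")
    labels = np.select(
        [values > 10, values > 1, values > 0.1],
        ["high", "intermediate", "low"],
        default="silenced",
    )
    return pd.Series(pd.Categorical(labels, categories=EXPRESSION_GROUPS),
                     index=values.index)


# ---------------------------------------------------------------------------
# Species-specific expression
# ---------------------------------------------------------------------------

def one_to_one_homologs(homologs: pd.DataFrame) -> pd.DataFrame:
    """Drop every pair involved in a one-to-many correspondence on either side."""
    h = homologs.drop_duplicates()
    ok = (~h["gene_a"].duplicated(keep=False)) & (~h["gene_b"].duplicated(keep=False))
    return h[ok].reset_index(drop=True)


def species_specific_genes(
    rpkm_a: pd.DataFrame,
    rpkm_b: pd.DataFrame,
    homologs: pd.DataFrame,
    fold: float = 5.0,
    min_expressed_samples: int = 2,
    expr_threshold: float = 0.1,
    mean_min: float = 1.0,
    other_mean_max: float = 1.0,
) -> pd.DataFrame:
    """Classify one-to-one homolog pairs as A-specific, B-specific or neither.

    Species-A-specific means (i) mean_a > fold * mean_b (ratio strictly
    greater; a zero mean_b passes whenever mean_a > 0), (ii) at least
    ``min_expressed_samples`` A samples with RPKM >= expr_threshold and
    mean_a > mean_min, and (iii) mean_b < other_mean_max. B-specific is the
    mirror image. Returns one row per tested pair with per-criterion booleans.
    """
    pairs = one_to_one_homologs(homologs)
    pairs = pairs[pairs["gene_a"].isin(rpkm_a.index) & pairs["gene_b"].isin(rpkm_b.index)]
    a = rpkm_a.loc[pairs["gene_a"]].to_numpy(float)
    b = rpkm_b.loc[pairs["gene_b"]].to_numpy(float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    n_expr_a = (a >= expr_threshold).sum(axis=1)
    n_expr_b = (b >= expr_threshold).sum(axis=1)

    fold_a = np.where(mean_b > 0, mean_a > fold * mean_b, mean_a > 0)
    fold_b = np.where(mean_a > 0, mean_b > fold * mean_a, mean_b > 0)
    a_specific = (
        fold_a & (n_expr_a >= min_expressed_samples) & (mean_a > mean_min)
        & (mean_b < other_mean_max)
    )
    b_specific = (
        fold_b & (n_expr_b >= min_expressed_samples) & (mean_b > mean_min)
        & (mean_a < other_mean_max)
    )
    return pd.DataFrame({
        "gene_a": pairs["gene_a"].to_numpy(),
        "gene_b": pairs["gene_b"].to_numpy(),
        "mean_a": mean_a, "mean_b": mean_b,
        "n_expressed_a": n_expr_a, "n_expressed_b": n_expr_b,
        "a_specific": a_specific, "b_specific": b_specific,
    })


# ---------------------------------------------------------------------------
# Novel transcript filter cascade
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf_codons(seq: str) -> int:
    """Longest ATG-initiated open reading frame (codons incl. stop) on the
    forward (sense) strand of a spliced transcript."""
    seq = seq.upper()
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, (i + 3 - start) // 3)
                start = None
    return best


def orf_coding_classifier(min_codons: int = 100) -> Callable:
    """Stand-in coding-potential classifier: coding iff longest ORF >= min_codons."""

    def classify(transcript: GeneModel, seq: str | None) -> str:
        if seq is None:
            return "unknown"
        return "coding" if longest_orf_codons(seq) >= min_codons else "noncoding"

    return classify


def novel_transcript_filter(
    assembled: Iterable[GeneModel],
    known: Iterable[GeneModel],
    chrom_whitelist: Iterable[str],
    rpkm: pd.DataFrame,
    sequences: Mapping[str, str] | None = None,
    classifier: Callable | None = None,
    min_distance: int = 10_000,
    min_length: int = 1_000,
    min_exons: int = 2,
    min_rpkm: float = 0.1,
) -> pd.DataFrame:
    """Apply the novelty filter cascade to assembled transcripts.

    A transcript is retained iff its distance to the nearest known transcript
    exceeds ``min_distance`` on both sides (overlap counts as distance 0), it
    lies on a whitelisted chromosome, its spliced length exceeds
    ``min_length``, it has at least ``min_exons`` exons (i.e. an exon-exon
    junction), and at least one sample expresses it (RPKM >= ``min_rpkm``).
    Retained transcripts get a coding/noncoding label from the pluggable
    classifier (default: longest-ORF rule on ``sequences``); retained
    noncoding transcripts are the novel lncRNA set.
    """
    classifier = classifier or orf_coding_classifier()
    whitelist = set(chrom_whitelist)
    known_by_chrom: dict = {}
    for k in known:
        known_by_chrom.setdefault(k.chrom, []).append((k.start, k.end))
    for chrom in known_by_chrom:
        known_by_chrom[chrom].sort()

    rows = []
    for t in assembled:
        on_whitelist = t.chrom in whitelist
        if not on_whitelist:
            warnings.warn(f"transcript {t.gene_id} on non-whitelisted {t.chrom}; dropped")
        dist = np.inf
        for ks, ke in known_by_chrom.get(t.chrom, ()):
            # half-open spans: overlap -> 0, else the bases between the spans
            gap = 0 if (ks < t.end and t.start < ke) else max(ks - t.end, t.start - ke)
            dist = min(dist, gap)
        distance_ok = dist > min_distance
        length_ok = t.spliced_length > min_length
        exons_ok = t.n_exons >= min_exons
        if t.gene_id in rpkm.index:
            expressed = bool((rpkm.loc[t.gene_id] >= min_rpkm).any())
        else:
            expressed = False
        retained = on_whitelist and distance_ok and length_ok and exons_ok and expressed
        coding = None
        if retained:
            seq = sequences.get(t.gene_id) if sequences else None
            coding = classifier(t, seq)
        rows.append((t.gene_id, t.chrom, dist, on_whitelist, distance_ok,
                     length_ok, exons_ok, expressed, retained, coding))
    return pd.DataFrame(rows, columns=[
        "transcript_id", "chrom", "distance_to_known", "on_whitelist",
        "distance_ok", "length_ok", "exons_ok", "expressed", "retained", "coding",
    ])
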