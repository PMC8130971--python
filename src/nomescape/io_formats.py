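"""Readers/writers for the formats the pipeline touches, and the coordinate contract.

Everything inside the package is 0-based half-open; conversion to/from the
1-based conventions of cytosine reports and GTF happens only here.

A *call table* is a :class:`pandas.DataFrame` with columns
``chrom, pos, strand, context, meth, unmeth`` — one row per strand-resolved
cytosine. ``pos`` is the 0-based position of the cytosine on the reference.
``context`` is one of ``WCG`` (ACG/TCG: endogenous CpG methylation), ``GCH``
(GCA/GCT/GCC: GpC accessibility footprint) or ``OTHER`` (ambiguous, e.g. GCG).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "unmeth"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file."""


class CoordinateError(ValueError):
    """Position outside the declared chromosome."""


@dataclass(frozen=True)
class CytosineCall:
    """A single strand-resolved cytosine with its read counts."""

    chrom: str
    pos: int  # 0-based
    strand: str
    context: str
    meth: int
    unmeth: int

    def __post_init__(self):
        if self.meth < 0 or self.unmeth < 0:
            raise ValueError("read counts must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene/transcript with strand-aware anchors.

    Coordinates are 0-based half-open. ``tss`` is ``start`` on the plus
    strand and ``end - 1`` on the minus strand; ``tes`` is the opposite end.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not self.start < self.end:
            raise ValueError(f"empty span for {self.gene_id}")
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon [{s},{e}) outside gene span of {self.gene_id}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"exons of {self.gene_id} overlap or are unsorted")
            if not s < e:
                raise ValueError(f"empty exon in {self.gene_id}")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def genes_to_frame(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Tabular view of gene models (one row per gene) for vectorised stages."""
    rows = [
        (g.gene_id, g.chrom, g.strand, g.start, g.end, g.tss, g.tes,
         g.n_exons, g.spliced_length, g.biotype)
        for g in genes
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "strand", "start", "end", "tss", "tes",
                 "n_exons", "spliced_length", "biotype"],
    )


# ---------------------------------------------------------------------------
# Reference trinucleotide context
# ---------------------------------------------------------------------------

class FastaContexts:
    """Trinucleotide lookup backed by reference sequences.

    ``sequences`` maps chromosome name to an uppercase string. Use
    :meth:`from_fasta` for on-disk references (via pyfaidx).
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "FastaContexts":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def chrom_length(self, chrom: str):
        seq = self._seqs.get(chrom)
        return None if seq is None else len(seq)

    def trinucleotide(self, chrom: str, pos: int, strand: str) -> str:
        seq = self._seqs[chrom]
        if not 0 <= pos < len(seq):
            raise CoordinateError(f"{chrom}:{pos} outside chromosome (len {len(seq)})")
        lo, hi = pos - 1, pos + 2
        tri = seq[max(lo, 0):hi]
        if lo < 0:
            tri = "N" + tri
        if hi > len(seq):
            tri = tri + "N"
        if strand == "-":
            tri = tri.translate(_COMPLEMENT)[::-1]
        return tri


class TableContexts:
    """Trinucleotide lookup backed by an explicit site table.

    Used for synthetic genomes where only cytosine sites (not full sequence)
    are materialised. The table needs columns ``chrom, pos, strand, tri``.
    """

    def __init__(self, sites: pd.DataFrame, chrom_lengths: Mapping[str, int] | None = None):
        self._by_chrom = {}
        for chrom, g in sites.groupby("chrom", observed=True):
            g = g.sort_values("pos")
            self._by_chrom[str(chrom)] = (
                g["pos"].to_numpy(np.int64),
                g["tri"].to_numpy(object),
                g["strand"].to_numpy(object),
            )
        self._lengths = dict(chrom_lengths) if chrom_lengths else None

    def chrom_length(self, chrom: str):
        return None if self._lengths is None else self._lengths.get(chrom)

    def trinucleotide(self, chrom: str, pos: int, strand: str) -> str:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        if self._lengths is not None and not 0 <= pos < self._lengths[chrom]:
            raise CoordinateError(f"{chrom}:{pos} outside chromosome")
        pos_arr, tri_arr, strand_arr = entry
        i = np.searchsorted(pos_arr, pos)
        if i < len(pos_arr) and pos_arr[i] == pos and strand_arr[i] == strand:
            return str(tri_arr[i])
        return "NNN"  # not a catalogued cytosine site


# ---------------------------------------------------------------------------
# Cytosine report (Bismark-style dialect)
# ---------------------------------------------------------------------------

def read_cytosine_report(path, genome_contexts=None) -> pd.DataFrame:
    """Read a tab-separated cytosine report into a call table.

    The file dialect is ``chrom, pos(1-based), strand, meth, unmeth[, context]``.
    Positions are converted to 0-based. When ``genome_contexts`` is given the
    WCG/GCH/OTHER class is recomputed from the reference trinucleotide and the
    file's context column (if any) is ignored; with ``genome_contexts=None``
    the file's context column is trusted as-is (only sensible for files this
    package itself wrote).
    """
    from .profiles import classify_context_series

    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=CALL_COLUMNS)
    if raw.shape[1] < 5:
        raise FormatError(f"{path}: expected >=5 tab-separated columns, got {raw.shape[1]}")

    df = raw.iloc[:, :5].copy()
    df.columns = ["chrom", "pos", "strand", "meth", "unmeth"]
    for col in ("pos", "meth", "unmeth"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise FormatError(f"{path}: malformed {col} field at line {line}")
        df[col] = coerced.astype(np.int64)
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise FormatError(f"{path}: bad strand at line {int(bad_strand.idxmax()) + 1}")
    if (df["pos"] < 1).any() or (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise FormatError(f"{path}: negative count or non-positive position")
    df["pos"] = df["pos"] - 1  # 1-based file -> 0-based internal

    if genome_contexts is not None:
        for chrom, g in df.groupby("chrom", observed=True):
            length = genome_contexts.chrom_length(str(chrom))
            if length is not None and len(g) and int(g["pos"].max()) >= length:
                raise CoordinateError(f"{path}: position beyond end of {chrom}")
        tri = [
            genome_contexts.trinucleotide(c, int(p), s)
            for c, p, s in zip(df["chrom"], df["pos"], df["strand"])
        ]
        df["context"] = classify_context_series(pd.Series(tri, index=df.index))
    elif raw.shape[1] >= 6:
        df["context"] = raw.iloc[:, 5].astype(str)
    else:
        raise FormatError(
            f"{path}: no context column and no genome_contexts to recompute it from"
        )
    return df[CALL_COLUMNS]


def write_cytosine_report(calls: pd.DataFrame, path) -> None:
    """Write a call table in the 1-based report dialect (inverse of the reader)."""
    out = calls[["chrom", "pos", "strand", "meth", "unmeth", "context"]].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


def merge_replicates(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Sum per-site read counts of two call tables from the same reference.

    A site present in only one input is copied unchanged. Conflicting context
    at the same site indicates mismatched references and raises.
    """
    key = ["chrom", "pos", "strand"]
    merged = calls_a.merge(calls_b, on=key, how="outer", suffixes=("_a", "_b"))
    both = merged["context_a"].notna() & merged["context_b"].notna()
    conflict = both & (merged["context_a"] != merged["context_b"])
    if conflict.any():
        row = merged.loc[conflict.idxmax()]
        raise ValueError(
            f"context conflict at {row['chrom']}:{int(row['pos'])} "
            f"({row['context_a']} vs {row['context_b']}): mismatched references?"
        )
    merged["context"] = merged["context_a"].fillna(merged["context_b"])
    for col in ("meth", "unmeth"):
        merged[col] = (
            merged[f"{col}_a"].fillna(0).astype(np.int64)
            + merged[f"{col}_b"].fillna(0).astype(np.int64)
        )
    merged = merged[CALL_COLUMNS].sort_values(["chrom", "pos", "strand"], kind="mergesort")
    return merged.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gene models (GTF / BED12)
# ---------------------------------------------------------------------------

def read_gene_models(path, dialect: str) -> list:
    """Parse gene models from GTF or BED12 into a list of :class:`GeneModel`.

    One model per gene; exons are merged per gene across transcripts and
    normalised to 0-based half-open coordinates.
    """
    if dialect == "GTF":
        return _read_gtf(path)
    if dialect == "BED12":
        return _read_bed12(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected GTF or BED12)")


def _read_gtf(path) -> list:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    from .intervals import merge_intervals

    genes = []
    for g in db.features_of_type("gene"):
        exons = []
        biotype = "protein_coding"
        for e in db.children(g, featuretype="exon", order_by="start"):
            exons.append((e.start - 1, e.end))  # GTF is 1-based inclusive
            bt = e.attributes.get("gene_biotype") or e.attributes.get("biotype")
            if bt:
                biotype = bt[0]
        s, e = merge_intervals([x[0] for x in exons], [x[1] for x in exons])
        genes.append(
            GeneModel(
                gene_id=g.attributes["gene_id"][0], chrom=g.seqid, strand=g.strand,
                start=g.start - 1, end=g.end, exons=tuple(zip(s.tolist(), e.tolist())),
                biotype=biotype,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _read_bed12(path) -> list:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}: line {ln}: BED12 needs 12 fields")
            chrom, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}: line {ln}: blockCount mismatch")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gene_models_bed12(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{g.n_exons}\t{sizes}\t{offsets}\n"
            )


def write_gene_models_gtf(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            for s, e in g.exons:
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                    f'gene_biotype "{g.biotype}";'
                )
                fh.write(
                    f"{g.chrom}\tnomescape\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Called regions (BED6+)
# ---------------------------------------------------------------------------

def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Write called regions as BED6+, sorted by (chrom, start).

    Expects columns ``chrom, start, end`` and optionally ``name``, ``p``,
    ``strand``; any further columns are appended after the first six. The BED
    score column is ``-log10(p)`` capped at 1000 (0 when no p-value).
    """
    df = regions.copy()
    if "name" not in df:
        df["name"] = [f"region_{i + 1}" for i in range(len(df))]
    if df["name"].duplicated().any():
        dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
        raise ValueError(f"duplicate region id {dup!r}")
    if "p" in df:
        with np.errstate(divide="ignore"):
            score = -np.log10(df["p"].astype(float).to_numpy())
        score = np.where(np.isfinite(score), np.minimum(score, 1000.0), 1000.0)
        score = np.where(df["p"].isna(), 0.0, score)
    else:
        score = np.zeros(len(df))
    df["score"] = np.round(score, 6)
    if "strand" not in df:
        df["strand"] = "."
    lead = ["chrom", "start", "end", "name", "score", "strand"]
    extra = [c for c in df.columns if c not in lead and c != "p"]
    df = df.sort_values(["chrom", "start"], kind="mergesort")
    df[lead + extra].to_csv(path, sep="\t", header=False, index=False)


def read_regions_bed(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = names[: df.shape[1]] + [f"extra_{i}" for i in range(df.shape[1] - 6)]
    return df
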