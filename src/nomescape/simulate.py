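"""Seeded synthetic NOMe-seq + RNA-seq study generator with planted ground truth.

The generator emulates the structure every downstream stage consumes:

* a desk-scale genome (default 2 chromosomes x 5 Mb) with non-overlapping
  gene models (1-10 exons), element tracks and cytosine sites at realistic
  WCG (1/50 bp) and GCH (1/20 bp) densities;
* beta-binomial per-site methylation around a 0.70 endogenous (WCG) baseline
  and a 0.15 accessibility (GCH) baseline, with planted differentially
  methylated regions between two sample groups and planted high-accessibility
  regions (NDRs);
* negative-binomial expression counts with planted two-group DEGs,
  distance-linked lncRNA-mRNA pairs sharing a latent factor calibrated to a
  target Pearson correlation, and a second-species matrix with planted
  species-specific genes;
* optional couplings that tie gene-body/promoter methylation or
  accessibility to expression rank (bell, reverse-bell, monotone), for the
  multiomics relationship analyses.

Everything is reproducible byte-for-byte from ``SimulationConfig.seed``, and
every planted feature is returned as ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import intervals
from .expression import ExpressionMatrix, compute_rpkm
from .io_formats import GeneModel, TableContexts, genes_to_frame
from .profiles import classify_context, promoter_regions

_LN2 = math.log(2.0)
_WCG_TRIS = np.array(["ACG", "TCG"])
_GCH_TRIS = np.array(["GCA", "GCT", "GCC"])


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator (all units in bp / RPKM)."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    site_density_wcg: float = 1 / 50
    site_density_gch: float = 1 / 20
    # methylome
    coverage_mean: float = 15.0
    baseline_wcg_level: float = 0.7
    baseline_gch_level: float = 0.15
    bb_precision: float = 30.0          # beta-binomial precision (a+b)
    n_meth_samples_per_group: int = 6
    # genes
    n_genes: int = 300
    n_lncrnas: int = 60
    gene_length_min: int = 2_000
    gene_length_max: int = 10_000
    lnc_length_min: int = 1_200
    lnc_length_max: int = 3_000
    max_exons: int = 10
    # planted differential methylation (level_a/level_b are the two group means)
    n_dmrs: int = 20
    dmr_delta: float = 0.3
    dmr_length: int = 1_800
    planted_dmrs: list | None = None    # rows (chrom, start, end, level_a, level_b)
    # planted accessible regions
    n_ndrs: int = 20
    ndr_length: int = 300
    ndr_gch_level: float = 0.45
    ndr_proximal_fraction: float = 0.5
    planted_ndrs: list | None = None    # rows (chrom, start, end, level)
    # expression
    group_labels: tuple = ("atrium", "ventricle")
    n_expr_samples_per_group: int = 11
    n_deg_up_a: int = 30
    n_deg_up_b: int = 30
    deg_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    expr_log2_sigma: float = 0.5
    silenced_fraction: float = 0.15
    library_size: int = 20_000_000
    # linked lncRNA-mRNA pairs
    n_linked_pairs: int = 20
    target_r: float = 0.8
    pair_max_distance: int = 100_000
    linked_base_log2_rpkm: float = 6.0
    # linked genes get a larger biological sigma so that the latent-factor
    # calibration can reach target_r on the count-noise-attenuated RPKM scale
    linked_log2_sigma: float = 1.0
    # species comparison
    n_species_specific: int = 25
    species_fold: float = 10.0
    # expression <-> methylome couplings
    couple_genebody_wcg: str = "none"    # none | bell
    couple_genebody_gch: str = "none"    # none | reverse_bell
    couple_promoter_gch: str = "none"    # none | monotone
    couple_promoter_wcg: str = "none"    # none | monotone_down

    def __post_init__(self):
        for name in ("site_density_wcg", "site_density_gch", "baseline_wcg_level",
                     "baseline_gch_level", "ndr_gch_level", "ndr_proximal_fraction",
                     "silenced_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1 < self.target_r < 1:
            raise ValueError(f"target_r must be inside (-1, 1), got {self.target_r}")
        hi = self.baseline_wcg_level
        lo = hi - self.dmr_delta
        if self.planted_dmrs is None and self.n_dmrs > 0 and not (0 <= lo <= 1 and 0 <= hi <= 1):
            raise ValueError("dmr_delta pushes a group mean outside [0, 1]")
        if self.coverage_mean < 0:
            raise ValueError("coverage_mean must be non-negative")

    @property
    def chrom_lengths(self) -> dict:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class Annotation:
    chrom_lengths: dict
    genes: list
    sites: pd.DataFrame
    contexts: TableContexts
    elements: dict
    planted_dmrs: pd.DataFrame
    planted_ndrs: pd.DataFrame
    linked_pairs: pd.DataFrame

    @property
    def pcg_genes(self) -> list:
        return [g for g in self.genes if g.biotype == "protein_coding"]

    @property
    def lnc_genes(self) -> list:
        return [g for g in self.genes if g.biotype == "lncRNA"]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _make_exons(length: int, max_exons: int, rng) -> tuple:
    """Random exon structure: up to max_exons exons with >= 50 bp segments."""
    n_ex = int(rng.integers(1, max_exons + 1))
    n_ex = min(n_ex, max(1, length // 150))
    if n_ex == 1:
        return ((0, length),)
    n_seg = 2 * n_ex - 1
    extra = rng.multinomial(length - 50 * n_seg, np.full(n_seg, 1 / n_seg))
    seg = 50 + extra
    bounds = np.concatenate([[0], np.cumsum(seg)])
    return tuple((int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_seg, 2))


def _place_blocks(blocks, config: SimulationConfig, rng):
    """Distribute blocks over chromosomes with random gaps; returns placed genes."""
    order = rng.permutation(len(blocks))
    per_chrom = np.array_split(order, config.n_chroms)
    genes = []
    for ci, idxs in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        spans = [blocks[i][-1][2] + blocks[i][-1][3] for i in idxs]  # offset+len of last member
        slack = config.chrom_length - sum(spans) - 2_000 * (len(idxs) + 1)
        if slack < 0:
            raise ValueError("genome too small to place the requested genes")
        gaps = rng.multinomial(slack, np.full(len(idxs) + 1, 1 / (len(idxs) + 1)))
        cursor = 0
        for k, bi in enumerate(idxs):
            cursor += gaps[k] + 2_000
            for gene_id, biotype, offset, length, exons_rel, strand in blocks[bi]:
                start = cursor + offset
                exons = tuple((start + s, start + e) for s, e in exons_rel)
                genes.append(GeneModel(gene_id, chrom, strand, start, start + length,
                                       exons, biotype))
            cursor += spans[k]
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _sample_sites(length: int, density: float, rng) -> np.ndarray:
    if density <= 0:
        return np.empty(0, dtype=np.int64)
    gaps = rng.geometric(density, size=int(length * density * 1.3) + 10)
    pos = np.cumsum(gaps) - 1
    while pos[-1] < length:
        extra = rng.geometric(density, size=100)
        pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
    return pos[pos < length].astype(np.int64)


def _random_disjoint(n, length, chrom_lengths, rng, grid, occupied, max_tries=10_000):
    """n random grid-aligned intervals avoiding ``occupied`` (list of (chrom,s,e))."""
    chroms = sorted(chrom_lengths)
    out = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not place requested intervals; genome too crowded")
        chrom = chroms[int(rng.integers(len(chroms)))]
        limit = (chrom_lengths[chrom] - length) // grid
        start = int(rng.integers(0, limit)) * grid
        end = start + length
        clash = any(c == chrom and s < end + 600 and start < e + 600
                    for c, s, e in occupied)
        if not clash:
            out.append((chrom, start, end))
            occupied.append((chrom, start, end))
    return out


def simulate_annotation(config: SimulationConfig, rng=None) -> Annotation:
    """Genome contexts, gene models, element tracks and planted-feature coordinates."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chrom_lengths = config.chrom_lengths

    # --- gene blocks: linked (pcg + nearby lncRNA), plain pcg, plain lncRNA
    n_linked = min(config.n_linked_pairs, config.n_lncrnas, config.n_genes)
    blocks, linked_rows = [], []
    pcg_ids = [f"gene{i + 1:04d}" for i in range(config.n_genes)]
    lnc_ids = [f"lnc{i + 1:04d}" for i in range(config.n_lncrnas)]
    li = 0
    for gi, gene_id in enumerate(pcg_ids):
        length = int(rng.integers(config.gene_length_min, config.gene_length_max + 1))
        exons = _make_exons(length, config.max_exons, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        members = [(gene_id, "protein_coding", 0, length, exons, strand)]
        if gi < n_linked:
            lnc_len = int(rng.integers(config.lnc_length_min, config.lnc_length_max + 1))
            cap = config.pair_max_distance - length - lnc_len
            if cap < 2_000:
                raise ValueError("pair_max_distance too small for the gene lengths")
            gap = int(rng.integers(1_000, min(cap, 60_000)))
            lnc_exons = _make_exons(lnc_len, 4, rng)
            lnc_strand = "+" if rng.random() < 0.5 else "-"
            members.append((lnc_ids[li], "lncRNA", length + gap, lnc_len,
                            lnc_exons, lnc_strand))
            linked_rows.append((lnc_ids[li], gene_id))
            li += 1
        blocks.append(members)
    for lnc_id in lnc_ids[li:]:
        lnc_len = int(rng.integers(config.lnc_length_min, config.lnc_length_max + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        blocks.append([(lnc_id, "lncRNA", 0, lnc_len, _make_exons(lnc_len, 4, rng), strand)])

    genes = _place_blocks(blocks, config, rng)
    by_id = {g.gene_id: g for g in genes}
    linked = pd.DataFrame(linked_rows, columns=["lnc_id", "pcg_id"])
    if len(linked):
        d = []
        for _, row in linked.iterrows():
            a, b = by_id[row["lnc_id"]], by_id[row["pcg_id"]]
            dist = 0 if (a.start < b.end and b.start < a.end) else abs(a.tss - b.tss)
            d.append(dist)
        linked["distance"] = d

    promoters = promoter_regions(genes, chrom_lengths)
    occupied = [(r["chrom"], r["start"], r["end"]) for _, r in promoters.iterrows()]

    # --- planted NDRs (grid 20) before DMRs so proximal ones sit at promoters
    if config.planted_ndrs is not None:
        ndrs = pd.DataFrame(config.planted_ndrs, columns=["chrom", "start", "end", "level"])
        ndrs["cls"] = "planted"
    else:
        n_prox = int(round(config.n_ndrs * config.ndr_proximal_fraction))
        rows = []
        prox_genes = rng.choice(len(genes), size=min(n_prox, len(genes)), replace=False)
        for gi in sorted(prox_genes):
            g = genes[gi]
            start = ((g.tss - config.ndr_length // 2) // 20) * 20
            start = max(start, 0)
            rows.append((g.chrom, start, start + config.ndr_length,
                         config.ndr_gch_level, "proximal"))
            occupied.append((g.chrom, start, start + config.ndr_length))
        n_dist = config.n_ndrs - len(rows)
        for chrom, s, e in _random_disjoint(n_dist, config.ndr_length, chrom_lengths,
                                            rng, 20, occupied):
            rows.append((chrom, s, e, config.ndr_gch_level, "distal"))
        ndrs = pd.DataFrame(rows, columns=["chrom", "start", "end", "level", "cls"])
    ndrs = ndrs.sort_values(["chrom", "start"]).reset_index(drop=True)

    # --- planted DMRs (grid 300, alternate direction)
    if config.planted_dmrs is not None:
        dmrs = pd.DataFrame(config.planted_dmrs,
                            columns=["chrom", "start", "end", "level_a", "level_b"])
    else:
        base, delta = config.baseline_wcg_level, config.dmr_delta
        rows = []
        for i, (chrom, s, e) in enumerate(
            _random_disjoint(config.n_dmrs, config.dmr_length, chrom_lengths,
                             rng, 300, occupied)
        ):
            if i % 2 == 0:
                rows.append((chrom, s, e, base, base - delta))   # hyper in group A
            else:
                rows.append((chrom, s, e, base - delta, base))   # hyper in group B
        dmrs = pd.DataFrame(rows, columns=["chrom", "start", "end", "level_a", "level_b"])
    for col in ("level_a", "level_b"):
        if len(dmrs) and not dmrs[col].between(0, 1).all():
            raise ValueError(f"planted DMR {col} outside [0, 1]")
    dmrs = dmrs.sort_values(["chrom", "start"]).reset_index(drop=True)

    # --- cytosine sites
    site_frames = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        wcg = _sample_sites(length, config.site_density_wcg, rng)
        gch = _sample_sites(length, config.site_density_gch, rng)
        gch = gch[~np.isin(gch, wcg)]
        pos = np.concatenate([wcg, gch])
        tri = np.concatenate([
            _WCG_TRIS[rng.integers(0, 2, size=len(wcg))],
            _GCH_TRIS[rng.integers(0, 3, size=len(gch))],
        ])
        strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")
        frame = pd.DataFrame({"chrom": chrom, "pos": pos, "strand": strand, "tri": tri})
        frame["context"] = [classify_context(t) for t in tri]
        site_frames.append(frame.sort_values("pos").reset_index(drop=True))
    sites = pd.concat(site_frames, ignore_index=True)

    # --- element tracks: exon/intron/intergenic partition + CGI and repeats
    elements = {"promoter": promoters[["chrom", "start", "end"]].copy()}
    ex_rows, intron_rows, span_rows = [], [], []
    for chrom in sorted(chrom_lengths):
        cg = [g for g in genes if g.chrom == chrom]
        ex_s = np.array([s for g in cg for s, e in g.exons], dtype=np.int64)
        ex_e = np.array([e for g in cg for s, e in g.exons], dtype=np.int64)
        ms, me = intervals.merge_intervals(ex_s, ex_e)
        ex_rows += [(chrom, int(s), int(e)) for s, e in zip(ms, me)]
        sp_s = np.array([g.start for g in cg], dtype=np.int64)
        sp_e = np.array([g.end for g in cg], dtype=np.int64)
        sp_ms, sp_me = intervals.merge_intervals(sp_s, sp_e)
        span_rows += [(chrom, int(s), int(e)) for s, e in zip(sp_ms, sp_me)]
        # introns: gene spans minus exons
        cursor_s, cursor_e = intervals.complement(ms, me, chrom_lengths[chrom])
        for s, e in zip(cursor_s, cursor_e):
            for gs, ge in zip(sp_ms, sp_me):
                lo, hi = max(s, gs), min(e, ge)
                if lo < hi:
                    intron_rows.append((chrom, int(lo), int(hi)))
    cols = ["chrom", "start", "end"]
    elements["exon"] = pd.DataFrame(ex_rows, columns=cols)
    elements["intron"] = pd.DataFrame(intron_rows, columns=cols)
    spans = pd.DataFrame(span_rows, columns=cols)
    inter_rows = []
    for chrom in sorted(chrom_lengths):
        g = spans[spans["chrom"] == chrom]
        cs, ce = intervals.complement(g["start"].to_numpy(), g["end"].to_numpy(),
                                      chrom_lengths[chrom])
        inter_rows += [(chrom, int(s), int(e)) for s, e in zip(cs, ce)]
    elements["intergenic"] = pd.DataFrame(inter_rows, columns=cols)
    feature_pad = [(c, s, e) for c, s, e in occupied]
    genome_bp = sum(chrom_lengths.values())
    cgi = _random_disjoint(max(1, genome_bp // 200_000), 1_000, chrom_lengths, rng,
                           200, feature_pad)
    rep = _random_disjoint(max(1, genome_bp // 100_000), 500, chrom_lengths, rng,
                           100, feature_pad)
    elements["cgi"] = pd.DataFrame(cgi, columns=cols).sort_values(cols[:2]).reset_index(drop=True)
    elements["repeat"] = pd.DataFrame(rep, columns=cols).sort_values(cols[:2]).reset_index(drop=True)

    contexts = TableContexts(sites, chrom_lengths)
    return Annotation(
        chrom_lengths=chrom_lengths, genes=genes, sites=sites, contexts=contexts,
        elements=elements, planted_dmrs=dmrs, planted_ndrs=ndrs, linked_pairs=linked,
    )


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def _apply_regions(mu_a, mu_b, sites, regions):
    """Set per-site group means inside each region (later rows win).

    ``regions`` rows carry chrom, start, end, level_a, level_b and a
    ``track`` column restricting the assignment to WCG or GCH sites.
    """
    pos_by_chrom = {}
    for chrom, g in sites.groupby("chrom", observed=True):
        pos_by_chrom[str(chrom)] = (g.index.to_numpy(), g["pos"].to_numpy(np.int64),
                                    g["context"].to_numpy(object))
    for row in regions.itertuples(index=False):
        entry = pos_by_chrom.get(str(row.chrom))
        if entry is None:
            continue
        idx, pos, ctx = entry
        lo, hi = np.searchsorted(pos, [row.start, row.end])
        sel = idx[lo:hi][ctx[lo:hi] == row.track]
        mu_a[sel] = row.level_a
        mu_b[sel] = row.level_b


def simulate_methylome(
    config: SimulationConfig,
    annotation: Annotation,
    group_assignments: Mapping[str, str],
    rng=None,
    regional_overrides: pd.DataFrame | None = None,
) -> dict:
    """Per-sample cytosine call tables with planted structure.

    Per-site methylation probability is drawn from a beta distribution whose
    mean is the configured baseline (WCG or GCH), overridden inside planted
    DMRs (per group), planted NDRs and any ``regional_overrides`` rows
    (columns ``chrom, start, end, track, level_a, level_b``; later rows win).
    Coverage is Poisson(``coverage_mean``); sites with zero coverage are
    absent from the table.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    labels = sorted(set(group_assignments.values()))
    if len(labels) > 2:
        raise ValueError(f"at most 2 methylome groups supported, got {labels}")
    sites = annotation.sites.sort_values(["chrom", "pos"]).reset_index(drop=True)
    n = len(sites)
    is_wcg = (sites["context"] == "WCG").to_numpy()
    mu_a = np.where(is_wcg, config.baseline_wcg_level, config.baseline_gch_level)
    mu_b = mu_a.copy()

    dmrs = annotation.planted_dmrs.copy()
    dmrs["track"] = "WCG"
    _apply_regions(mu_a, mu_b, sites, dmrs)
    ndrs = annotation.planted_ndrs.copy()
    ndrs["track"] = "GCH"
    ndrs["level_a"] = ndrs["level"]
    ndrs["level_b"] = ndrs["level"]
    _apply_regions(mu_a, mu_b, sites, ndrs)
    if regional_overrides is not None and len(regional_overrides):
        _apply_regions(mu_a, mu_b, sites, regional_overrides)

    k = config.bb_precision
    out = {}
    for sample in sorted(group_assignments):
        if config.coverage_mean == 0:
            out[sample] = pd.DataFrame(
                columns=["chrom", "pos", "strand", "context", "meth", "unmeth"])
            continue
        mu = mu_a if group_assignments[sample] == labels[0] else mu_b
        mu = np.clip(mu, 1e-3, 1 - 1e-3)
        p = rng.beta(mu * k, (1 - mu) * k)
        cov = rng.poisson(config.coverage_mean, size=n)
        meth = rng.binomial(cov, p)
        keep = cov > 0
        table = sites.loc[keep, ["chrom", "pos", "strand", "context"]].copy()
        table["meth"] = meth[keep]
        table["unmeth"] = (cov - meth)[keep]
        out[sample] = table.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _latent_rho(target_r: float, s2_nat: float, noise_cv2: float) -> float:
    """Latent lognormal correlation needed for a target Pearson r on the
    observed (count-noise-attenuated) RPKM scale."""
    v = math.expm1(s2_nat)
    denom = (1 + v) * (1 + noise_cv2) - 1
    val = target_r * denom
    if val >= v:
        return 1.0
    return math.log1p(val) / s2_nat


@dataclass
class SimulatedExpression:
    expr: ExpressionMatrix
    truth_degs: pd.DataFrame
    linked_pairs: pd.DataFrame
    base_log2_rpkm: pd.Series
    expr_b: ExpressionMatrix | None = None
    homologs: pd.DataFrame | None = None
    truth_species: pd.DataFrame | None = None


def _nb_counts(mu, alpha, rng):
    if alpha > 0:
        lam = rng.gamma(shape=1 / alpha, scale=mu * alpha)
    else:
        lam = mu
    return rng.poisson(lam)


def simulate_expression(
    config: SimulationConfig,
    annotation: Annotation,
    rng=None,
    with_species: bool = False,
) -> SimulatedExpression:
    """Negative-binomial expression matrices with planted DEGs, linked pairs
    and (optionally) a second species with planted species-specific genes."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    genes = annotation.genes
    gene_ids = [g.gene_id for g in genes]
    lengths = pd.Series({g.gene_id: max(g.spliced_length, 100) for g in genes})
    n_genes = len(gene_ids)
    idx_of = {g: i for i, g in enumerate(gene_ids)}
    is_pcg = np.array([g.biotype == "protein_coding" for g in genes])

    base = rng.normal(3.0, 2.0, size=n_genes)
    silenced = rng.random(n_genes) < config.silenced_fraction
    base[silenced] = rng.normal(-6.0, 1.0, size=int(silenced.sum()))

    linked = annotation.linked_pairs
    linked_idx = set()
    for _, row in linked.iterrows():
        for gid in (row["lnc_id"], row["pcg_id"]):
            i = idx_of[gid]
            base[i] = rng.normal(config.linked_base_log2_rpkm, 1.0)
            linked_idx.add(i)

    # planted DEGs among protein-coding genes outside the linked set
    eligible = [i for i in np.nonzero(is_pcg)[0] if i not in linked_idx]
    n_deg = config.n_deg_up_a + config.n_deg_up_b
    deg_pick = rng.choice(eligible, size=min(n_deg, len(eligible)), replace=False)
    up_a = deg_pick[: config.n_deg_up_a]
    up_b = deg_pick[config.n_deg_up_a:]
    base[deg_pick] = np.maximum(base[deg_pick], rng.normal(3.0, 1.0, size=len(deg_pick)))

    labels = tuple(sorted(config.group_labels))
    samples = [f"{lab}_{i + 1}" for lab in labels for i in range(config.n_expr_samples_per_group)]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}
    in_a = np.array([groups[s] == labels[0] for s in samples])
    n_samples = len(samples)

    eff = np.zeros((n_genes, n_samples))
    half = config.deg_log2fc / 2
    eff[np.ix_(up_a, in_a)] = half
    eff[np.ix_(up_a, ~in_a)] = -half
    eff[np.ix_(up_b, in_a)] = -half
    eff[np.ix_(up_b, ~in_a)] = half

    z = rng.standard_normal((n_genes, n_samples))
    lib_m = config.library_size / 1e6
    len_kb = lengths.loc[gene_ids].to_numpy() / 1e3
    sigma = np.full(n_genes, config.expr_log2_sigma)
    s2_link = (config.linked_log2_sigma * _LN2) ** 2
    for _, row in linked.iterrows():
        i, j = idx_of[row["lnc_id"]], idx_of[row["pcg_id"]]
        sigma[[i, j]] = config.linked_log2_sigma
        mu_counts = 2.0 ** base[[i, j]] * len_kb[[i, j]] * lib_m
        noise_cv2 = float(np.mean(config.nb_dispersion + 1.0 / mu_counts))
        rho = _latent_rho(config.target_r, s2_link, noise_cv2)
        f = rng.standard_normal(n_samples)
        for g in (i, j):
            z[g] = math.sqrt(rho) * f + math.sqrt(1 - rho) * rng.standard_normal(n_samples)

    log2_rpkm = base[:, None] + eff + sigma[:, None] * z
    mu = 2.0 ** log2_rpkm * len_kb[:, None] * lib_m
    counts = pd.DataFrame(_nb_counts(mu, config.nb_dispersion, rng),
                          index=gene_ids, columns=samples)
    rpkm = compute_rpkm(counts, lengths,
                        pd.Series(config.library_size, index=samples, dtype=float))
    expr = ExpressionMatrix(counts=counts, rpkm=rpkm, groups=groups,
                            gene_lengths=lengths)

    truth_degs = pd.DataFrame({
        "gene_id": [gene_ids[i] for i in np.concatenate([up_a, up_b])],
        "direction": [labels[0]] * len(up_a) + [labels[1]] * len(up_b),
        "log2fc": config.deg_log2fc,
    })
    linked_out = linked.copy()
    linked_out["target_r"] = config.target_r

    result = SimulatedExpression(
        expr=expr, truth_degs=truth_degs, linked_pairs=linked_out,
        base_log2_rpkm=pd.Series(base, index=gene_ids),
    )
    if not with_species:
        return result

    # --- second species: one-to-one homologs of the protein-coding genes
    pcg_ids = [g for g, flag in zip(gene_ids, is_pcg) if flag]
    pcg_pos = np.array([idx_of[g] for g in pcg_ids])
    base_b = base[pcg_pos] + rng.normal(0.0, 0.3, size=len(pcg_ids))
    n_spec = min(config.n_species_specific, len(pcg_ids) // 4)
    spec_pick = rng.choice(len(pcg_ids), size=2 * n_spec, replace=False)
    a_spec, b_spec = spec_pick[:n_spec], spec_pick[n_spec:]
    shift = math.log2(config.species_fold) + 3.0
    base_a_sp = rng.normal(3.5, 0.5, size=n_spec)
    base[pcg_pos[a_spec]] = base_a_sp
    base_b[a_spec] = base_a_sp - shift
    base_b_sp = rng.normal(3.5, 0.5, size=n_spec)
    base_b[b_spec] = base_b_sp
    base[pcg_pos[b_spec]] = base_b_sp - shift

    # species-A matrix rebuilt so the overridden bases take effect
    log2_rpkm = base[:, None] + eff + sigma[:, None] * z
    mu = 2.0 ** log2_rpkm * len_kb[:, None] * lib_m
    counts = pd.DataFrame(_nb_counts(mu, config.nb_dispersion, rng),
                          index=gene_ids, columns=samples)
    rpkm = compute_rpkm(counts, lengths,
                        pd.Series(config.library_size, index=samples, dtype=float))
    result.expr = ExpressionMatrix(counts=counts, rpkm=rpkm, groups=groups,
                                   gene_lengths=lengths)
    result.base_log2_rpkm = pd.Series(base, index=gene_ids)

    b_ids = [f"m_{g}" for g in pcg_ids]
    b_samples = [f"m_{s}" for s in samples]
    b_groups = {f"m_{s}": groups[s] for s in samples}
    len_kb_b = len_kb[pcg_pos]
    zb = rng.standard_normal((len(pcg_ids), n_samples))
    mu_b = 2.0 ** (base_b[:, None] + config.expr_log2_sigma * zb) * len_kb_b[:, None] * lib_m
    counts_b = pd.DataFrame(_nb_counts(mu_b, config.nb_dispersion, rng),
                            index=b_ids, columns=b_samples)
    lengths_b = pd.Series(lengths.loc[pcg_ids].to_numpy(), index=b_ids, dtype=float)
    rpkm_b = compute_rpkm(counts_b, lengths_b,
                          pd.Series(config.library_size, index=b_samples, dtype=float))
    result.expr_b = ExpressionMatrix(counts=counts_b, rpkm=rpkm_b, groups=b_groups,
                                     gene_lengths=lengths_b)

    homologs = pd.DataFrame({"gene_a": pcg_ids, "gene_b": b_ids})
    # a few one-to-many rows to exercise the homology filter
    n_multi = min(5, len(pcg_ids) - 2 * n_spec)
    multi_pool = [i for i in range(len(pcg_ids)) if i not in set(spec_pick)]
    multi = rng.choice(multi_pool, size=n_multi, replace=False)
    extra = pd.DataFrame({
        "gene_a": [pcg_ids[i] for i in multi],
        "gene_b": [f"{b_ids[i]}_alt" for i in multi],
    })
    result.homologs = pd.concat([homologs, extra], ignore_index=True)
    result.truth_species = pd.DataFrame({
        "gene_a": [pcg_ids[i] for i in np.concatenate([a_spec, b_spec])],
        "specific_to": ["a"] * n_spec + ["b"] * n_spec,
    })
    return result


# ---------------------------------------------------------------------------
# Whole-study orchestration
# ---------------------------------------------------------------------------

def _coupling_overrides(config: SimulationConfig, annotation: Annotation,
                        base_log2: pd.Series) -> pd.DataFrame | None:
    shapes = (config.couple_genebody_wcg, config.couple_genebody_gch,
              config.couple_promoter_gch, config.couple_promoter_wcg)
    if all(s == "none" for s in shapes):
        return None
    pcg = annotation.pcg_genes
    vals = base_log2.loc[[g.gene_id for g in pcg]].to_numpy()
    order = np.argsort(np.argsort(vals))
    q = order / max(len(pcg) - 1, 1)
    rows = []
    for g, qi in zip(pcg, q):
        if config.couple_genebody_wcg == "bell":
            level = 0.55 + 0.30 * (1 - (2 * qi - 1) ** 2)
            rows.append((g.chrom, g.start, g.end, "WCG", level, level))
        if config.couple_genebody_gch == "reverse_bell":
            level = 0.10 + 0.20 * (2 * qi - 1) ** 2
            rows.append((g.chrom, g.start, g.end, "GCH", level, level))
    promoters = promoter_regions(pcg, annotation.chrom_lengths)
    prom_by_gene = promoters.set_index("gene_id")
    for g, qi in zip(pcg, q):
        p = prom_by_gene.loc[g.gene_id]
        if config.couple_promoter_gch == "monotone":
            level = 0.05 + 0.40 * qi
            rows.append((g.chrom, int(p["start"]), int(p["end"]), "GCH", level, level))
        if config.couple_promoter_wcg == "monotone_down":
            level = 0.90 - 0.50 * qi
            rows.append((g.chrom, int(p["start"]), int(p["end"]), "WCG", level, level))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "track",
                                       "level_a", "level_b"])


@dataclass
class StudyTruth:
    dmrs: pd.DataFrame
    ndrs: pd.DataFrame
    degs: pd.DataFrame
    linked_pairs: pd.DataFrame
    species_specific: pd.DataFrame | None


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    annotation: Annotation
    methylomes: dict
    meth_groups: dict
    expression: ExpressionMatrix
    expression_b: ExpressionMatrix | None
    homologs: pd.DataFrame | None
    base_log2_rpkm: pd.Series
    truth: StudyTruth


def simulate_study(config: SimulationConfig, with_species: bool = True) -> SimulatedStudy:
    """Run the full generator: annotation, expression, then methylomes
    (expression first so methylome couplings can condition on it)."""
    rng = np.random.default_rng(config.seed)
    annotation = simulate_annotation(config, rng)
    sim_expr = simulate_expression(config, annotation, rng, with_species=with_species)
    overrides = _coupling_overrides(config, annotation, sim_expr.base_log2_rpkm)

    labels = tuple(sorted(config.group_labels))
    meth_groups = {
        f"meth_{lab}_{i + 1}": lab
        for lab in labels for i in range(config.n_meth_samples_per_group)
    }
    methylomes = simulate_methylome(config, annotation, meth_groups, rng,
                                    regional_overrides=overrides)

    dmr_truth = annotation.planted_dmrs.copy()
    if len(dmr_truth):
        dmr_truth["direction"] = np.where(
            dmr_truth["level_a"] > dmr_truth["level_b"],
            f"hyper_{labels[0]}", f"hyper_{labels[1]}")
    truth = StudyTruth(
        dmrs=dmr_truth, ndrs=annotation.planted_ndrs.copy(),
        degs=sim_expr.truth_degs, linked_pairs=sim_expr.linked_pairs,
        species_specific=sim_expr.truth_species,
    )
    return SimulatedStudy(
        config=config, annotation=annotation, methylomes=methylomes,
        meth_groups=meth_groups, expression=sim_expr.expr,
        expression_b=sim_expr.expr_b, homologs=sim_expr.homologs,
        base_log2_rpkm=sim_expr.base_log2_rpkm, truth=truth,
    )


def write_study(study: SimulatedStudy, outdir) -> None:
    """Serialise a study to plain-text files (byte-stable for a fixed seed)."""
    from .io_formats import write_cytosine_report, write_gene_models_bed12, write_gene_models_gtf

    out = Path(outdir)
    (out / "calls").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    (out / "elements").mkdir(exist_ok=True)
    for sample in sorted(study.methylomes):
        write_cytosine_report(study.methylomes[sample], out / "calls" / f"{sample}.tsv")
    write_gene_models_bed12(study.annotation.genes, out / "genes.bed12")
    write_gene_models_gtf(study.annotation.genes, out / "genes.gtf")
    kw = dict(sep="\t", float_format="%.6g")
    study.expression.counts.to_csv(out / "counts.tsv", **kw)
    study.expression.rpkm.to_csv(out / "rpkm.tsv", **kw)
    pd.Series(study.expression.groups).rename("group").to_csv(out / "groups.tsv", sep="\t")
    pd.Series(study.meth_groups).rename("group").to_csv(out / "meth_groups.tsv", sep="\t")
    if study.expression_b is not None:
        study.expression_b.counts.to_csv(out / "counts_speciesB.tsv", **kw)
        study.expression_b.rpkm.to_csv(out / "rpkm_speciesB.tsv", **kw)
        study.homologs.to_csv(out / "homologs.tsv", sep="\t", index=False)
    for name, track in study.annotation.elements.items():
        track.to_csv(out / "elements" / f"{name}.bed", sep="\t", header=False, index=False)
    study.truth.dmrs.to_csv(out / "truth" / "dmrs.tsv", index=False, **kw)
    study.truth.ndrs.to_csv(out / "truth" / "ndrs.tsv", index=False, **kw)
    study.truth.degs.to_csv(out / "truth" / "degs.tsv", index=False, **kw)
    study.truth.linked_pairs.to_csv(out / "truth" / "linked_pairs.tsv", index=False, **kw)
    if study.truth.species_specific is not None:
        study.truth.species_specific.to_csv(out / "truth" / "species_specific.tsv",
                                            index=False, **kw)
    study.annotation.sites.to_csv(out / "contexts.tsv", sep="\t", index=False)
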