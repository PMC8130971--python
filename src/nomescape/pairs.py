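"""lncRNA - protein-coding gene correlation with a genome-shuffle permutation null.

Candidate pairs are same-chromosome genes within 500 kb (TSS-to-TSS distance;
0 when the spans overlap); each pair's Pearson correlation is computed over
samples. The null rearranges every gene uniformly at random across the genome
(chromosome chosen with probability proportional to its length, start uniform
where the gene fits, length preserved), re-derives pairs, and re-computes
correlations from the genes' *real* expression vectors; the real and pooled
null correlation distributions are compared with a two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


def _standardize(rpkm: pd.DataFrame):
    """Rows scaled to zero mean, unit norm; constant rows flagged invalid."""
    x = rpkm.to_numpy(float)
    x = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((x ** 2).sum(axis=1))
    valid = norm > 0
    z = np.divide(x, norm[:, None], out=np.zeros_like(x), where=valid[:, None])
    return z, valid


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def _tss(frame: pd.DataFrame) -> np.ndarray:
    return np.where(frame["strand"].to_numpy() == "+",
                    frame["start"].to_numpy(np.int64),
                    frame["end"].to_numpy(np.int64) - 1)


def _pair_indices(lnc: pd.DataFrame, pcg: pd.DataFrame, max_distance: int):
    """Index pairs (into lnc/pcg frames) with TSS distance <= max_distance.

    Distance is 0 when spans overlap. Assumes gene lengths are below
    ``max_distance`` so every span-overlapping pair is already inside the TSS
    search window.
    """
    out_l, out_r, out_d = [], [], []
    lnc_tss_all, pcg_tss_all = _tss(lnc), _tss(pcg)
    for chrom in np.intersect1d(lnc["chrom"].unique(), pcg["chrom"].unique()):
        li = np.nonzero((lnc["chrom"] == chrom).to_numpy())[0]
        pi = np.nonzero((pcg["chrom"] == chrom).to_numpy())[0]
        p_tss = pcg_tss_all[pi]
        order = np.argsort(p_tss)
        pi, p_tss = pi[order], p_tss[order]
        p_start = pcg["start"].to_numpy(np.int64)[pi]
        p_end = pcg["end"].to_numpy(np.int64)[pi]
        for i in li:
            t = lnc_tss_all[i]
            lo = np.searchsorted(p_tss, t - max_distance, side="left")
            hi = np.searchsorted(p_tss, t + max_distance, side="right")
            if lo == hi:
                continue
            sel = pi[lo:hi]
            d = np.abs(p_tss[lo:hi] - t)
            s, e = lnc["start"].iat[i], lnc["end"].iat[i]
            overlap = (p_start[lo:hi] < e) & (s < p_end[lo:hi])
            d = np.where(overlap, 0, d)
            out_l.extend([i] * len(sel))
            out_r.extend(sel.tolist())
            out_d.extend(d.tolist())
    return (np.array(out_l, dtype=np.int64), np.array(out_r, dtype=np.int64),
            np.array(out_d, dtype=np.int64))


def find_pairs(
    lnc: pd.DataFrame,
    pcg: pd.DataFrame,
    rpkm: pd.DataFrame,
    max_distance: int = 500_000,
) -> pd.DataFrame:
    """All lncRNA/protein-coding pairs within ``max_distance``, with Pearson r and p.

    ``lnc``/``pcg`` are gene tables with columns ``gene_id, chrom, start,
    end, strand`` (see :func:`nomescape.io_formats.genes_to_frame`); ``rpkm``
    holds the expression vectors. Pairs whose members include a constant
    expression vector are excluded (correlation undefined).
    """
    lnc = lnc.reset_index(drop=True)
    pcg = pcg.reset_index(drop=True)
    li, pi, dist = _pair_indices(lnc, pcg, max_distance)
    if len(li) == 0:
        return pd.DataFrame(columns=["lnc_id", "pcg_id", "distance", "r", "p"])
    z, valid = _standardize(rpkm.loc[lnc["gene_id"].tolist() + pcg["gene_id"].tolist()])
    zl, vl = z[: len(lnc)], valid[: len(lnc)]
    zp, vp = z[len(lnc):], valid[len(lnc):]
    ok = vl[li] & vp[pi]
    r = (zl[li] * zp[pi]).sum(axis=1)
    n = rpkm.shape[1]
    p = _pearson_p(r, n)
    out = pd.DataFrame({
        "lnc_id": lnc["gene_id"].to_numpy()[li],
        "pcg_id": pcg["gene_id"].to_numpy()[pi],
        "distance": dist, "r": r, "p": p,
    })[ok]
    return out.sort_values(["lnc_id", "pcg_id"], kind="mergesort").reset_index(drop=True)


def _random_placement(frame: pd.DataFrame, chrom_names, chrom_lengths, rng) -> pd.DataFrame:
    lengths = np.array([chrom_lengths[c] for c in chrom_names], dtype=np.int64)
    gene_len = (frame["end"] - frame["start"]).to_numpy(np.int64)
    if gene_len.max(initial=0) > lengths.max(initial=0):
        raise ValueError("a gene is longer than every chromosome")
    probs = lengths / lengths.sum()
    ci = rng.choice(len(chrom_names), size=len(frame), p=probs)
    # rejection for the rare gene that does not fit its drawn chromosome
    bad = gene_len > lengths[ci]
    while bad.any():
        ci[bad] = rng.choice(len(chrom_names), size=int(bad.sum()), p=probs)
        bad = gene_len > lengths[ci]
    start = (rng.random(len(frame)) * (lengths[ci] - gene_len + 1)).astype(np.int64)
    out = frame.copy()
    out["chrom"] = np.asarray(chrom_names, dtype=object)[ci]
    out["start"] = start
    out["end"] = start + gene_len
    return out


@dataclass
class PermutationResult:
    """Real vs genome-shuffle null correlation distributions."""

    real_pairs: pd.DataFrame
    null_rs: np.ndarray
    n_reps: int
    t_stat: float
    t_p: float
    null_pair_counts: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def real_rs(self) -> np.ndarray:
        return self.real_pairs["r"].to_numpy()

    def summary(self) -> str:
        rr, nr = self.real_rs, self.null_rs
        return "\n".join([
            "lncRNA-mRNA correlation vs genome-shuffle permutation null",
            f"  real pairs:    {len(rr)} (mean r {np.mean(rr):.4f},"
            f" median {np.median(rr):.4f})" if len(rr) else "  real pairs:    0",
            f"  null pairs:    {len(nr)} pooled over {self.n_reps} shuffles"
            f" (mean r {np.mean(nr):.4f}, median {np.median(nr):.4f})",
            f"  t-test:        t = {self.t_stat:.3f}, two-tailed p = {self.t_p:.3g}",
        ])


def permutation_null(
    lnc: pd.DataFrame,
    pcg: pd.DataFrame,
    rpkm: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    n_reps: int = 1000,
    seed: int | None = None,
    max_distance: int = 500_000,
    keep_placements: bool = False,
) -> PermutationResult:
    """Compare real pair correlations against the genome-shuffle null."""
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    rng = np.random.default_rng(seed)
    chrom_names = sorted(chrom_lengths)
    real = find_pairs(lnc, pcg, rpkm, max_distance)

    order = list(lnc["gene_id"]) + list(pcg["gene_id"])
    z, valid = _standardize(rpkm.loc[order])
    zl, vl = z[: len(lnc)], valid[: len(lnc)]
    zp, vp = z[len(lnc):], valid[len(lnc):]

    null_rs = []
    pair_counts = np.zeros(n_reps, dtype=np.int64)
    placements = [] if keep_placements else None
    for rep in range(n_reps):
        lnc_r = _random_placement(lnc, chrom_names, chrom_lengths, rng)
        pcg_r = _random_placement(pcg, chrom_names, chrom_lengths, rng)
        if keep_placements:
            placements.append((lnc_r, pcg_r))
        li, pi, _ = _pair_indices(lnc_r, pcg_r, max_distance)
        if len(li) == 0:
            continue
        ok = vl[li] & vp[pi]
        r = (zl[li[ok]] * zp[pi[ok]]).sum(axis=1)
        pair_counts[rep] = len(r)
        null_rs.append(r)
    null_rs = np.concatenate(null_rs) if null_rs else np.empty(0)

    if len(real) >= 2 and len(null_rs) >= 2:
        t_stat, t_p = stats.ttest_ind(real["r"], null_rs, equal_var=False)
    else:
        t_stat, t_p = np.nan, np.nan
    result = PermutationResult(
        real_pairs=real, null_rs=null_rs, n_reps=n_reps,
        t_stat=float(t_stat), t_p=float(t_p), null_pair_counts=pair_counts,
        params=dict(max_distance=max_distance, seed=seed),
    )
    if keep_placements:
        result.params["placements"] = placements
    return result


class PairPermutationTest:
    """Model wrapper: real lncRNA-mRNA pairing vs its permutation null."""

    def __init__(
        self,
        lnc: pd.DataFrame,
        pcg: pd.DataFrame,
        rpkm: pd.DataFrame,
        chrom_lengths: Mapping[str, int],
        max_distance: int = 500_000,
    ):
        self.lnc, self.pcg, self.rpkm = lnc, pcg, rpkm
        self.chrom_lengths = dict(chrom_lengths)
        self.max_distance = max_distance

    def fit(self, n_reps: int = 1000, seed: int | None = None) -> PermutationResult:
        return permutation_null(
            self.lnc, self.pcg, self.rpkm, self.chrom_lengths,
            n_reps=n_reps, seed=seed, max_distance=self.max_distance,
        )


def call_cis_pairs(
    pairs: pd.DataFrame,
    r_min: float = 0.6,
    p_max: float = 0.05,
    max_distance: int = 100_000,
) -> pd.DataFrame:
    """cis-regulatory pairs: r > r_min, p <= p_max and distance < max_distance."""
    keep = (pairs["r"] > r_min) & (pairs["p"] <= p_max) & (pairs["distance"] < max_distance)
    return pairs[keep].reset_index(drop=True)


def coexpression_network(
    gene_list,
    rpkm: pd.DataFrame,
    r_min: float = 0.5,
):
    """All-pairs coexpression network over a curated gene set.

    Unordered pairs with Pearson r strictly above ``r_min`` become edges
    weighted by r; the node table carries each gene's degree. Genes absent
    from the matrix are returned in the skipped list.
    """
    genes = [g for g in gene_list if g in rpkm.index]
    skipped = [g for g in gene_list if g not in rpkm.index]
    z, valid = _standardize(rpkm.loc[genes])
    edges = []
    for i in range(len(genes)):
        if not valid[i]:
            continue
        for j in range(i + 1, len(genes)):
            if not valid[j]:
                continue
            r = float((z[i] * z[j]).sum())
            if r > r_min:
                edges.append((genes[i], genes[j], r))
    edges_df = pd.DataFrame(edges, columns=["gene_a", "gene_b", "r"])
    degree = pd.Series(0, index=pd.Index(genes, name="gene"), dtype=int)
    for a, b, _ in edges:
        degree[a] += 1
        degree[b] += 1
    nodes_df = degree.rename("degree").reset_index()
    return edges_df, nodes_df, skipped
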