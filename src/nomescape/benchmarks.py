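"""Planted-truth benchmark scenarios for the analysis stages.

Each function simulates studies under the package's stated study conditions,
runs the corresponding analysis stage, and scores the result against the
planted ground truth. They are used both by the test suite and by the
acceptance script; every number they return is computed at call time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import intervals
from .dmr import DifferentialMethylation
from .expression import DifferentialExpression
from .integration import bell_statistic, promoter_correlations, ranked_bin_curve
from .io_formats import genes_to_frame
from .ndr import NucleosomeDepletion
from .pairs import PairPermutationTest
from .profiles import gene_body_levels, promoter_levels
from .simulate import SimulationConfig, simulate_study


# ---------------------------------------------------------------------------
# Differential methylation
# ---------------------------------------------------------------------------

def dmr_recovery(seeds) -> dict:
    """Base-level recall/precision of the DMR caller on planted DMRs.

    Conditions: 2 chromosomes x 5 Mb, 6 samples/group, 15x coverage, one WCG
    site per 50 bp, 20 planted DMRs with a 0.3 group-mean difference.
    """
    tp = called = truth_bases = 0
    for seed in seeds:
        cfg = SimulationConfig(seed=int(seed), site_density_gch=0.0)
        study = simulate_study(cfg, with_species=False)
        res = DifferentialMethylation(
            study.methylomes, study.meth_groups, cfg.chrom_lengths).fit()
        tp += intervals.frame_intersect_length(res.dmrs, study.truth.dmrs)
        called += intervals.frame_total_length(res.dmrs)
        truth_bases += intervals.frame_total_length(study.truth.dmrs)
    return {"recall": tp / truth_bases, "precision": tp / called if called else 0.0,
            "n_truth_bases": truth_bases}


def dmr_null_rate(seeds) -> dict:
    """Mean fraction of tested windows called with no planted DMRs."""
    fracs = []
    n_windows = 0
    for seed in seeds:
        cfg = SimulationConfig(seed=int(seed), site_density_gch=0.0, n_dmrs=0)
        study = simulate_study(cfg, with_species=False)
        res = DifferentialMethylation(
            study.methylomes, study.meth_groups, cfg.chrom_lengths).fit()
        fracs.append(res.windows["is_dmw"].mean())
        n_windows += len(res.windows)
    return {"window_call_fraction": float(np.mean(fracs)), "n_seeds": len(fracs),
            "n_windows": n_windows}


# ---------------------------------------------------------------------------
# Nucleosome depletion
# ---------------------------------------------------------------------------

def _ndr_config(seed: int, n_ndrs: int = 20) -> SimulationConfig:
    return SimulationConfig(seed=int(seed), site_density_wcg=0.0, n_dmrs=0,
                            n_ndrs=n_ndrs, n_meth_samples_per_group=1)


def ndr_recovery(seeds) -> dict:
    """Recall and boundary error for planted 300-bp NDRs at 15x coverage."""
    hits = total = 0
    boundary_errors = []
    for seed in seeds:
        cfg = _ndr_config(seed)
        study = simulate_study(cfg, with_species=False)
        calls = study.methylomes[sorted(study.methylomes)[0]]
        res = NucleosomeDepletion(calls, cfg.chrom_lengths).fit()
        for r in study.truth.ndrs.itertuples():
            total += 1
            ov = res.ndrs[(res.ndrs.chrom == r.chrom) & (res.ndrs.start < r.end)
                          & (res.ndrs.end > r.start)]
            if len(ov):
                hits += 1
                start, end = int(ov["start"].min()), int(ov["end"].max())
                boundary_errors.append((abs(start - r.start) + abs(end - r.end)) / 2)
    return {"recall": hits / total,
            "boundary_error_bp": float(np.mean(boundary_errors)),
            "n_planted": total}


def ndr_null_calls(seeds) -> dict:
    """Total NDRs called when none are planted (expected ~0 at p <= 1e-10)."""
    n = 0
    for seed in seeds:
        cfg = _ndr_config(seed, n_ndrs=0)
        study = simulate_study(cfg, with_species=False)
        calls = study.methylomes[sorted(study.methylomes)[0]]
        n += len(NucleosomeDepletion(calls, cfg.chrom_lengths).fit().ndrs)
    return {"total_calls": n, "n_seeds": len(seeds)}


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def deg_recovery(seed: int) -> dict:
    """Recall of planted DEGs (|log2FC| = 2, 8 vs 8 samples) and false calls."""
    cfg = SimulationConfig(seed=int(seed), site_density_wcg=0.0,
                           site_density_gch=0.0, n_meth_samples_per_group=0,
                           n_expr_samples_per_group=8)
    study = simulate_study(cfg, with_species=False)
    res = DifferentialExpression(study.expression).fit()
    truth = set(study.truth.degs["gene_id"])
    called = set(res.degs.index)
    return {"recall": len(truth & called) / len(truth),
            "false_calls": len(called - truth), "n_planted": len(truth)}


def deg_null_rate(seeds) -> dict:
    """Fraction of genes called with no planted effects (log2fc = 0)."""
    called = tested = 0
    for seed in seeds:
        cfg = SimulationConfig(seed=int(seed), site_density_wcg=0.0,
                               site_density_gch=0.0, n_meth_samples_per_group=0,
                               deg_log2fc=0.0, n_linked_pairs=0)
        study = simulate_study(cfg, with_species=False)
        res = DifferentialExpression(study.expression).fit()
        called += len(res.degs)
        tested += len(res.table)
    return {"gene_call_fraction": called / tested, "n_genes": tested}


# ---------------------------------------------------------------------------
# lncRNA-mRNA permutation test
# ---------------------------------------------------------------------------

def _pair_config(seed: int, n_linked: int) -> SimulationConfig:
    return SimulationConfig(seed=int(seed), n_linked_pairs=n_linked,
                            site_density_wcg=0.0, site_density_gch=0.0,
                            n_dmrs=0, n_ndrs=0, n_meth_samples_per_group=0)


def _restricted_sets(study, n_extra_lnc: int, n_extra_pcg: int):
    """DEG-like input sets: planted linked genes plus a margin of unlinked ones."""
    gf = genes_to_frame(study.annotation.genes).set_index("gene_id")
    linked = study.truth.linked_pairs
    lnc_linked, pcg_linked = set(linked["lnc_id"]), set(linked["pcg_id"])
    lnc_ids = list(linked["lnc_id"]) + [
        g for g in gf[gf.biotype == "lncRNA"].index if g not in lnc_linked
    ][:n_extra_lnc]
    pcg_ids = list(linked["pcg_id"]) + [
        g for g in gf[gf.biotype == "protein_coding"].index if g not in pcg_linked
    ][:n_extra_pcg]
    return gf.loc[lnc_ids].reset_index(), gf.loc[pcg_ids].reset_index()


def permutation_power(seeds, n_reps: int = 200) -> dict:
    """Fraction of runs with planted correlated pairs where real-vs-null p < 0.05."""
    sig = 0
    for seed in seeds:
        cfg = _pair_config(seed, n_linked=20)
        study = simulate_study(cfg, with_species=False)
        lnc, pcg = _restricted_sets(study, n_extra_lnc=10, n_extra_pcg=30)
        res = PairPermutationTest(lnc, pcg, study.expression.rpkm,
                                  cfg.chrom_lengths).fit(n_reps=n_reps, seed=int(seed))
        sig += res.t_p < 0.05
    return {"significant_fraction": sig / len(seeds), "n_runs": len(seeds)}


def permutation_calibration(seeds, n_reps: int = 200) -> dict:
    """Fraction of runs with independent expression where p > 0.05 (well-calibrated)."""
    ok = 0
    for seed in seeds:
        cfg = _pair_config(seed, n_linked=0)
        study = simulate_study(cfg, with_species=False)
        gf = genes_to_frame(study.annotation.genes).set_index("gene_id")
        lnc = gf[gf.biotype == "lncRNA"].iloc[:30].reset_index()
        pcg = gf[gf.biotype == "protein_coding"].iloc[:50].reset_index()
        res = PairPermutationTest(lnc, pcg, study.expression.rpkm,
                                  cfg.chrom_lengths).fit(n_reps=n_reps, seed=int(seed))
        ok += res.t_p > 0.05
    return {"nonsignificant_fraction": ok / len(seeds), "n_runs": len(seeds)}


# ---------------------------------------------------------------------------
# Multiomics couplings
# ---------------------------------------------------------------------------

def _coupling_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=int(seed), n_chroms=1, chrom_length=1_500_000, n_genes=150,
        n_lncrnas=0, n_linked_pairs=0, n_dmrs=0, n_ndrs=0,
        n_meth_samples_per_group=1, silenced_fraction=0.05,
        couple_genebody_wcg="bell", couple_genebody_gch="reverse_bell",
        couple_promoter_gch="monotone", couple_promoter_wcg="monotone_down",
    )


def coupling_run(seed: int) -> dict:
    """One run: bell statistics for gene-body WCG/GCH and promoter R1/R2."""
    cfg = _coupling_config(seed)
    study = simulate_study(cfg, with_species=False)
    calls = study.methylomes[sorted(study.methylomes)[0]]
    genes = study.annotation.pcg_genes
    rpkm = study.expression.mean_rpkm().loc[[g.gene_id for g in genes]]
    body_wcg = gene_body_levels(calls, genes, "WCG")
    body_gch = gene_body_levels(calls, genes, "GCH")
    b_wcg = bell_statistic(ranked_bin_curve(rpkm, body_wcg, "WCG"))
    b_gch = bell_statistic(ranked_bin_curve(rpkm, body_gch, "GCH"))
    cs = promoter_correlations(
        rpkm,
        promoter_wcg=promoter_levels(calls, genes, cfg.chrom_lengths, "WCG"),
        promoter_gch=promoter_levels(calls, genes, cfg.chrom_lengths, "GCH"),
    )
    return {"bell_wcg": b_wcg, "bell_gch": b_gch, "r1": cs.r1, "r2": cs.r2}


def coupling_fractions(seeds) -> dict:
    runs = [coupling_run(s) for s in seeds]
    return {
        "bell_wcg_positive_fraction": float(np.mean([r["bell_wcg"] > 0 for r in runs])),
        "bell_gch_negative_fraction": float(np.mean([r["bell_gch"] < 0 for r in runs])),
        "r1_above_0.9_fraction": float(np.mean([r["r1"] > 0.9 for r in runs])),
        "mean_bell_wcg": float(np.mean([r["bell_wcg"] for r in runs])),
        "mean_bell_gch": float(np.mean([r["bell_gch"] for r in runs])),
        "mean_r1": float(np.mean([r["r1"] for r in runs])),
        "mean_r2": float(np.mean([r["r2"] for r in runs])),
        "n_runs": len(runs),
    }


# ---------------------------------------------------------------------------
# Global levels
# ---------------------------------------------------------------------------

def global_levels(seed: int) -> dict:
    """Genome-wide mean WCG and GCH levels of one simulated sample (percent)."""
    cfg = SimulationConfig(seed=int(seed), n_dmrs=0, n_ndrs=0,
                           n_meth_samples_per_group=1)
    study = simulate_study(cfg, with_species=False)
    calls = study.methylomes[sorted(study.methylomes)[0]]
    out = {}
    for track in ("WCG", "GCH"):
        sub = calls[calls.context == track]
        depth = sub.meth + sub.unmeth
        ok = depth >= 3
        levels = (sub.meth[ok] / depth[ok])
        out[track.lower() + "_percent"] = float(levels.mean() * 100)
    return out
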