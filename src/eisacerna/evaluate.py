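"""Simulation studies: calibration and recovery of the planted effects.

These routines run the full pipeline on generated data and score it against
the ground truth — type-I error of the moderated t on null data, sensitivity
and false-discovery proportion for the planted stabilized class, and
recovery of the planted sponge lncRNA axis (correlation ranking, target-set
enrichment, miRNA-intersection). They back both the test suite and the
reproducibility script, so the numbers those report are always recomputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cerna, gsea, normde, simdata, triplets
from .eisa import eisa_deltas

__all__ = [
    "null_calibration",
    "eisa_recovery",
    "sponge_axis_run",
    "sponge_recovery",
]


def null_calibration(
    n_genes: int = 10_000,
    seed: int = 7,
    n_reps: int = 3,
) -> dict[str, float]:
    """Type-I error and EISA false-call rate on effect-free data.

    Simulates ``n_genes`` null genes in a two-group design (``n_reps`` per
    group, one cell line/timepoint) and returns the fraction of moderated-t
    p-values below 0.05 and the fraction of genes called post-transcriptional
    at FDR < 0.05.
    """
    design = simdata.default_design(
        cell_lines=("U2932",), timepoints=(8,), n_reps=n_reps
    )
    cfg = simdata.SimConfig(
        n_genes=n_genes,
        n_lnc=2,
        frac_transcriptional=0.0,
        frac_stabilized=0.0,
        frac_degraded=0.0,
        lnc_effect_log2fc=0.0,
        sponge_coupling=0.0,
        design=design,
        seed=seed,
    )
    pair, design_table, _truth = simdata.simulate_counts(cfg)
    de = normde.de_table(pair.exon_counts, design_table)
    res = eisa_deltas(pair, design_table)
    return {
        "type1_error": float((de.table["p_value"] < 0.05).mean()),
        "eisa_pt_call_rate": float(
            res["class_label"].isin(["stabilized", "degraded"]).mean()
        ),
        "n_genes_tested": int(len(de.table)),
    }


def eisa_recovery(
    seeds: range | list[int] = range(20),
    n_genes: int = 2000,
) -> dict[str, float]:
    """Sensitivity and FDP for the planted stabilized class, averaged over seeds.

    Each replicate simulates the default two-cell-line time-course design
    (3 replicates per condition), runs the exon-intron analysis on the
    treated-vs-control contrast, and scores the ``stabilized`` calls against
    the planted truth (lncRNA features are excluded from the gene-level
    scoring).
    """
    sens, fdp = [], []
    for seed in seeds:
        cfg = simdata.SimConfig(n_genes=n_genes, seed=int(seed))
        pair, design_table, truth = simdata.simulate_counts(cfg)
        res = eisa_deltas(pair, design_table).set_index("gene_id")
        res = res[~res.index.map(lambda g: truth.gene_class[g] == "lncRNA")]
        true_stab = {g for g, c in truth.gene_class.items() if c == "stabilized"}
        called = set(res.index[res["class_label"] == "stabilized"])
        testable = true_stab & set(res.index)
        sens.append(len(called & true_stab) / len(testable))
        fdp.append(len(called - true_stab) / max(len(called), 1))
    return {
        "sensitivity": float(np.mean(sens)),
        "fdp": float(np.mean(fdp)),
        "n_seeds": len(sens),
    }


def sponge_axis_run(
    seed: int,
    n_genes: int = 2000,
    n_perm: int = 1000,
    n_decoy_mirnas: int = 20,
) -> dict:
    """One end-to-end sponge-axis inference run scored against the truth.

    Simulates counts, selects differentially expressed lncRNA candidates,
    correlates them with the per-sample stabilization index of the
    stabilized/degraded transcripts, ranks candidates by mean correlation
    with the planted target set, runs preranked enrichment on the top
    candidate's ranking, and intersects the miRNA-interaction tables.
    """
    cfg = simdata.SimConfig(n_genes=n_genes, seed=int(seed))
    pair, design_table, truth = simdata.simulate_counts(cfg)

    de = normde.de_table(pair.exon_counts, design_table)
    cands = cerna.select_candidate_lncs(de)
    res = eisa_deltas(pair, design_table)
    keep = [
        g
        for g in res.loc[res["class_label"].isin(["stabilized", "degraded"]), "gene_id"]
        if truth.gene_class.get(g) != "lncRNA"
    ]
    stab = cerna.stabilization_index(pair, genes=keep)
    lnc_expr = normde.log_cpm(
        pair.exon_counts, normde.tmm_factors(pair.exon_counts)
    ).values.loc[cands["lnc_id"]]
    corr = cerna.correlate_lnc(stab, lnc_expr)

    target_rows = corr[corr["gene_id"].isin(set(truth.sponge_targets))]
    mean_r = (
        target_rows.groupby("lnc_id")["r"].mean().sort_values(ascending=False)
    )
    sponge_first = bool(mean_r.index[0] == truth.sponge_lnc_id)

    ranking = gsea.rank_inputs("correlation", corr, lnc_id=truth.sponge_lnc_id)
    lnc2mir, mir2gene, sets = simdata.simulate_interactions(
        truth, n_decoy_mirnas=n_decoy_mirnas, seed=int(seed)
    )
    gres = gsea.permutation_stats(ranking, sets, n_perm=n_perm, seed=int(seed))
    row = gres[gres["set_name"] == "SPONGE_TARGETS"]
    enriched = bool(row["enriched"].iloc[0]) if not row.empty else False

    mirna_sets, trips = triplets.intersect_mirnas(
        lnc2mir, mir2gene, truth.sponge_lnc_id, truth.sponge_targets
    )
    return {
        "sponge_ranks_first": sponge_first,
        "n_candidates": int(len(cands)),
        "target_set_enriched": enriched,
        "gsea_row": row,
        "mean_r": mean_r,
        "common_mirnas": sorted(mirna_sets["common"]),
        "shared_mirna": truth.shared_mirna_id,
        "n_triplets": int(len(trips)),
    }


def sponge_recovery(
    seeds: range | list[int] = range(20),
    n_genes: int = 2000,
    n_perm: int = 1000,
) -> dict[str, float]:
    """Fraction of seeds where the sponge ranks first / its set is enriched."""
    first, enr, cands = [], [], []
    for seed in seeds:
        out = sponge_axis_run(seed, n_genes=n_genes, n_perm=n_perm)
        first.append(out["sponge_ranks_first"])
        enr.append(out["target_set_enriched"])
        cands.append(out["n_candidates"])
    return {
        "rank_first_fraction": float(np.mean(first)),
        "enriched_fraction": float(np.mean(enr)),
        "min_candidates": int(min(cands)),
        "n_seeds": len(first),
    }
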