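"""Competing-endogenous-RNA candidate ranking by correlation with stabilization.

A miRNA sponge de-represses its miRNAs' targets, so target transcripts should
be *more stabilized* in exactly the samples where the sponge lncRNA is high.
The per-sample stabilization index of a gene is its exon log2-CPM minus its
intron log2-CPM, centered per gene (the per-sample analogue of the
Δexon − Δintron contrast estimate). Candidate lncRNAs — differentially
expressed lncRNA-biotype features — are then scored by the Pearson
correlation of their per-sample log2-CPM with each gene's stabilization
index; per-lncRNA gene rankings by r feed the preranked enrichment step.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .counting import CountPair
from .normde import DeResult, log_cpm, tmm_factors

__all__ = [
    "stabilization_index",
    "correlate_lnc",
    "select_candidate_lncs",
    "rank_by_correlation",
    "write_rnk",
]


def stabilization_index(
    pair: CountPair,
    genes: list[str] | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Per-sample centered exon-minus-intron log2-CPM (genes x samples).

    Higher values mean the mature transcript is over-represented relative to
    nascent transcription in that sample. Genes with missing intron data
    (all-zero intron rows) are dropped. Doubling exon and intron together in
    a sample leaves the index unchanged up to normalization.
    """
    exon, intron = pair.exon_counts, pair.intron_counts
    if genes is not None:
        exon, intron = exon.loc[genes], intron.loc[genes]
    ok = (intron.sum(axis=1) > 0) & (exon.sum(axis=1) > 0)
    exon, intron = exon[ok], intron[ok]
    le = log_cpm(exon, tmm_factors(exon), prior_count=prior_count).values
    li = log_cpm(intron, tmm_factors(intron), prior_count=prior_count).values
    diff = le - li
    return diff.sub(diff.mean(axis=1), axis=0)


def _pearson_table(
    x: pd.DataFrame, y: pd.DataFrame
) -> pd.DataFrame:
    """All-pairs Pearson r and two-sided p between rows of x (genes) and y (lncs)."""
    xa = x.to_numpy(dtype=float)
    ya = y.to_numpy(dtype=float)
    n = xa.shape[1]
    xc = xa - xa.mean(axis=1, keepdims=True)
    yc = ya - ya.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc.T) / np.outer(xs, ys)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    rows = []
    for i, g in enumerate(x.index):
        for j, l in enumerate(y.index):
            rows.append((g, l, r[i, j], p[i, j], n))
    out = pd.DataFrame(rows, columns=["gene_id", "lnc_id", "r", "p", "n"])
    bad = (xs == 0)[:, None] | (ys == 0)[None, :]
    out["flagged"] = bad.ravel()
    out.loc[out["flagged"], ["r", "p"]] = np.nan
    return out


def correlate_lnc(
    stab: pd.DataFrame,
    lnc_expr: pd.DataFrame,
    candidates: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each gene's stabilization index with each lncRNA.

    ``stab`` is the genes x samples index matrix; ``lnc_expr`` lncRNA
    log2-CPM over the same samples. Zero-variance vectors give flagged rows
    with missing r (excluded from any downstream ranking). Requires at least
    three shared samples.
    """
    if candidates is not None:
        missing = set(candidates) - set(lnc_expr.index)
        if missing:
            raise ValueError(f"candidate lncRNAs missing from expression: {sorted(missing)}")
        lnc_expr = lnc_expr.loc[candidates]
    shared = [s for s in stab.columns if s in set(lnc_expr.columns)]
    if len(shared) < 3:
        raise ValueError("need at least three shared samples for correlation")
    return _pearson_table(stab[shared], lnc_expr[shared])


def select_candidate_lncs(
    de: DeResult | pd.DataFrame,
    biotype: pd.Series | None = None,
    alpha: float = 0.05,
    lnc_prefix: str = "LNC",
) -> pd.DataFrame:
    """Differentially expressed lncRNA-biotype features, split by logFC sign.

    ``biotype`` maps feature id -> biotype string ("lncRNA" marks
    candidates); when absent, features whose id starts with ``lnc_prefix``
    are treated as lncRNAs. Returns columns (lnc_id, logFC, adj_p_value,
    direction).
    """
    table = de.table if isinstance(de, DeResult) else de
    if table.empty:
        return pd.DataFrame(columns=["lnc_id", "logFC", "adj_p_value", "direction"])
    if biotype is not None:
        is_lnc = table["feature_id"].map(biotype).eq("lncRNA")
    else:
        is_lnc = table["feature_id"].str.startswith(lnc_prefix)
    sig = table[is_lnc & (table["adj_p_value"] < alpha)].copy()
    sig["direction"] = np.where(sig["logFC"] > 0, "upregulated", "downregulated")
    return sig.rename(columns={"feature_id": "lnc_id"})[
        ["lnc_id", "logFC", "adj_p_value", "direction"]
    ].reset_index(drop=True)


def rank_by_correlation(corr: pd.DataFrame, lnc_id: str) -> pd.Series:
    """Genes ranked (descending) by Pearson r with one lncRNA; ties by gene id."""
    sub = corr[(corr["lnc_id"] == lnc_id) & ~corr["r"].isna()]
    sub = sub.sort_values(["r", "gene_id"], ascending=[False, True])
    return pd.Series(sub["r"].to_numpy(), index=sub["gene_id"].to_numpy(), name=lnc_id)


def write_rnk(ranking: pd.Series, path: str | Path) -> None:
    """Two-column gene/score file in the GSEA RNK dialect."""
    ranking.to_csv(path, sep="\t", header=False)
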