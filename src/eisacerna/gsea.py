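"""Preranked gene-set enrichment: weighted KS running statistic with permutation FDR.

Given a gene ranking (descending score) and gene sets, the enrichment score
(ES) is the signed maximum deviation from zero of a running sum that
increments at set members ("hits") by |score|^p normalized over the hits and
decrements at non-members by 1/(N - Nh). Significance comes from gene-label
permutations (the only permutation scheme available to a preranked list):
the nominal p compares |ES| with same-sign permuted scores, the normalized
ES (NES) divides ES by the mean same-sign permuted magnitude, the FDR q uses
the standard two-tailed NES tabulation over all sets and permutations
pooled, and the FWER p uses the per-permutation extreme-NES null. A set is
flagged enriched at nominal p < 0.05 and FDR q < 0.25.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "enrichment_score",
    "permutation_stats",
    "rank_inputs",
    "read_gmt",
    "read_rnk",
    "GSEA_COLUMNS",
]

GSEA_COLUMNS = [
    "set_name", "size", "es", "nes", "nom_p", "fdr_q", "fwer_p",
    "enriched", "leading_edge",
]


# ---------------------------------------------------------------------------
# File dialects
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one set per line — name TAB description TAB member TAB member..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_rnk(path: str | Path) -> pd.Series:
    """RNK: gene TAB score; returned sorted descending, ties by gene id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"], comment="#")
    s = pd.Series(df["score"].to_numpy(dtype=float), index=df["gene"].astype(str))
    return _sort_ranking(s)


def _sort_ranking(scores: pd.Series) -> pd.Series:
    if scores.index.has_duplicates:
        dups = scores.index[scores.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene ids in ranking: {dups[:5]}")
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return scores.loc[order]


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def _es_at_positions(
    pos: np.ndarray, weights: np.ndarray, n_total: int
) -> tuple[np.ndarray, np.ndarray]:
    """ES for each row of hit positions (n_perm x k), plus argmax hit index.

    The running sum is piecewise linear between hits, so its extrema occur
    immediately after a hit (candidate maxima) or immediately before one
    (candidate minima); both are evaluated in closed form from the sorted hit
    positions without walking all n_total genes.
    """
    pos = np.sort(pos, axis=1)
    k = pos.shape[1]
    w = weights[pos]
    wsum = w.sum(axis=1, keepdims=True)
    wsum = np.where(wsum == 0, 1.0, wsum)           # all-zero scores: flat hits
    chit = np.cumsum(w, axis=1) / wsum
    miss_denom = max(n_total - k, 1)
    miss = (pos - np.arange(k)) / miss_denom
    after = chit - miss                              # value just after each hit
    before = np.concatenate(
        [np.zeros((pos.shape[0], 1)), chit[:, :-1]], axis=1
    ) - miss                                         # value just before each hit
    max_dev = np.maximum(after.max(axis=1), 0.0)
    min_dev = np.minimum(before.min(axis=1), 0.0)
    es = np.where(max_dev >= -min_dev, max_dev, min_dev)
    arg = np.where(
        max_dev >= -min_dev, after.argmax(axis=1), before.argmin(axis=1)
    )
    return es, arg


def enrichment_score(
    scores: pd.Series,
    gene_set: list[str] | set[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score of one set against a ranked list.

    Parameters
    ----------
    scores
        Ranking scores indexed by unique gene id; sorted internally
        (descending, ties broken by id).
    gene_set
        Member gene ids; genes absent from the ranking are ignored.
    weight
        Exponent p on |score| for hit increments (p=0 is the classic KS).

    Returns (es, running_sum over all positions, leading-edge genes).
    Raises ``ValueError`` when the set does not intersect the ranking.
    """
    scores = _sort_ranking(scores)
    genes = scores.index.to_numpy()
    n = len(genes)
    members = set(gene_set) & set(genes)
    if not members:
        raise ValueError("gene set does not intersect the ranking")
    hit = np.isin(genes, list(members))
    pos = np.flatnonzero(hit)
    weights = np.abs(scores.to_numpy(dtype=float)) ** weight

    es_arr, arg = _es_at_positions(pos[None, :], weights, n)
    es = float(es_arr[0])

    # full running sum, for plots and brute-force comparison
    w_hit = weights * hit
    denom = w_hit.sum() if w_hit.sum() > 0 else 1.0
    step = np.where(hit, w_hit / denom, -1.0 / max(n - len(pos), 1))
    running = np.cumsum(step)

    peak = pos[int(arg[0])]
    if es >= 0:
        leading = [g for g in genes[: peak + 1] if g in members]
    else:
        leading = [g for g in genes[peak:] if g in members]
    return es, running, leading


# ---------------------------------------------------------------------------
# Permutation NES / nominal p / FDR / FWER
# ---------------------------------------------------------------------------

def permutation_stats(
    scores: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
    nom_p_cut: float = 0.05,
    fdr_cut: float = 0.25,
) -> pd.DataFrame:
    """Gene-label permutation statistics for every eligible set.

    Sets outside [min_size, max_size] after intersection with the ranking are
    skipped. The nominal p uses the add-one estimator over same-sign permuted
    scores, so it is never smaller than 1/(n_perm+1).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    scores = _sort_ranking(scores)
    genes = scores.index.to_numpy()
    n = len(genes)
    weights = np.abs(scores.to_numpy(dtype=float)) ** weight
    rng = np.random.default_rng(seed)

    eligible: list[tuple[str, np.ndarray]] = []
    skipped: list[str] = []
    gene_pos = {g: i for i, g in enumerate(genes)}
    for name, members in sets.items():
        pos = np.array(sorted(gene_pos[g] for g in set(members) if g in gene_pos))
        if pos.size < min_size or pos.size > max_size or pos.size >= n:
            skipped.append(name)
            continue
        eligible.append((name, pos))
    if not eligible:
        return pd.DataFrame(columns=GSEA_COLUMNS)

    obs_es: dict[str, float] = {}
    leading: dict[str, list[str]] = {}
    perm_nes_pos: list[np.ndarray] = []   # per set, permuted NES > 0
    perm_nes_neg: list[np.ndarray] = []
    rows = []
    nes_perm_by_set: dict[str, np.ndarray] = {}

    for name, pos in eligible:
        es, _run, lead = enrichment_score(
            pd.Series(scores.to_numpy(), index=genes), genes[pos], weight
        )
        obs_es[name] = es
        leading[name] = lead
        k = pos.size
        perm_pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
        es_perm, _ = _es_at_positions(perm_pos, weights, n)
        pos_mask = es_perm > 0
        neg_mask = es_perm < 0
        mean_pos = es_perm[pos_mask].mean() if pos_mask.any() else np.nan
        mean_neg = np.abs(es_perm[neg_mask]).mean() if neg_mask.any() else np.nan
        nes_perm = np.where(
            es_perm >= 0,
            es_perm / mean_pos if np.isfinite(mean_pos) else np.nan,
            es_perm / mean_neg if np.isfinite(mean_neg) else np.nan,
        )
        nes_perm_by_set[name] = nes_perm
        perm_nes_pos.append(nes_perm[nes_perm > 0])
        perm_nes_neg.append(nes_perm[nes_perm < 0])

        if es >= 0:
            same = es_perm[pos_mask]
            nes = es / mean_pos if np.isfinite(mean_pos) else np.nan
        else:
            same = es_perm[neg_mask]
            nes = -abs(es) / mean_neg if np.isfinite(mean_neg) else np.nan
        b = int(np.sum(np.abs(same) >= abs(es))) if same.size else 0
        nom_p = (b + 1) / (same.size + 1)
        rows.append({"set_name": name, "size": k, "es": es, "nes": nes, "nom_p": nom_p})

    table = pd.DataFrame(rows)

    # FDR q: pooled two-tailed NES tabulation (permuted vs observed fractions)
    all_pos = np.concatenate(perm_nes_pos) if perm_nes_pos else np.array([])
    all_neg = np.concatenate(perm_nes_neg) if perm_nes_neg else np.array([])
    obs_nes = table["nes"].to_numpy()
    fdr = np.ones(len(table))
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            fdr[i] = np.nan
            continue
        if nes >= 0:
            num = np.mean(all_pos >= nes) if all_pos.size else 1.0
            den = np.mean(obs_nes[np.isfinite(obs_nes) & (obs_nes >= 0)] >= nes)
        else:
            num = np.mean(all_neg <= nes) if all_neg.size else 1.0
            den = np.mean(obs_nes[np.isfinite(obs_nes) & (obs_nes < 0)] <= nes)
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0
    # enforce monotonicity per sign: a more extreme NES never has larger q
    for sign_mask in (obs_nes >= 0, obs_nes < 0):
        idx = np.flatnonzero(sign_mask & np.isfinite(obs_nes))
        if idx.size:
            order = idx[np.argsort(-np.abs(obs_nes[idx]))]
            fdr[order] = np.minimum.accumulate(fdr[order])
    table["fdr_q"] = fdr

    # FWER p: per-permutation extreme NES null
    nes_mat = np.vstack([nes_perm_by_set[name] for name, _ in eligible])
    max_pos = np.max(np.where(nes_mat > 0, nes_mat, -np.inf), axis=0)
    min_neg = np.min(np.where(nes_mat < 0, nes_mat, np.inf), axis=0)
    fwer = np.ones(len(table))
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            fwer[i] = np.nan
        elif nes >= 0:
            vals = max_pos[np.isfinite(max_pos)]
            fwer[i] = (np.sum(vals >= nes) + 1) / (vals.size + 1)
        else:
            vals = min_neg[np.isfinite(min_neg)]
            fwer[i] = (np.sum(vals <= nes) + 1) / (vals.size + 1)
    table["fwer_p"] = fwer

    table["enriched"] = (table["nom_p"] < nom_p_cut) & (table["fdr_q"] < fdr_cut)
    table["leading_edge"] = [",".join(leading[nm]) for nm in table["set_name"]]
    return table[GSEA_COLUMNS].sort_values("set_name").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Ranking sources
# ---------------------------------------------------------------------------

def rank_inputs(
    source: str,
    table: pd.DataFrame,
    lnc_id: str | None = None,
) -> pd.Series:
    """Build a descending ranking from a results table.

    ``source`` selects the score column: ``logFC`` (differential-expression
    table), ``pt_score`` (exon-intron results), or ``correlation``
    (correlation table, requires ``lnc_id``). Ties break by gene id.
    """
    if source == "logFC":
        s = pd.Series(table["logFC"].to_numpy(), index=table["feature_id"].astype(str))
    elif source == "pt_score":
        s = pd.Series(table["pt_score"].to_numpy(), index=table["gene_id"].astype(str))
    elif source == "correlation":
        if lnc_id is None:
            raise ValueError("correlation ranking requires lnc_id")
        sub = table[(table["lnc_id"] == lnc_id) & table["r"].notna()]
        s = pd.Series(sub["r"].to_numpy(), index=sub["gene_id"].astype(str))
    else:
        raise ValueError(f"unknown ranking source: {source!r}")
    return _sort_ranking(s)
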