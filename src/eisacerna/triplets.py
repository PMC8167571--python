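"""lncRNA-miRNA-mRNA sponge-axis nomination from interaction tables.

A candidate sponge axis requires a miRNA that targets both the lncRNA and a
gene of interest: the Venn intersection of {miRNAs binding the lncRNA} with
{miRNAs binding each gene} nominates triplets, and the significance of a
target-set overlap is an upper-tail hypergeometric test. A seed-match
scanner (reverse complement of miRNA positions 2-8 with the canonical 8mer /
7mer-m8 / 7mer-A1 anchors) provides site-level support; it is a deliberately
simple, clearly-labelled pattern scan, not a trained site-prediction model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

__all__ = [
    "load_interactions",
    "intersect_mirnas",
    "overlap_test",
    "seedmatch_scan",
    "SeedSite",
]

_COMPLEMENT = str.maketrans("ACGUT", "UGCAA")


def load_interactions(path: str | Path, origin: str = "curated") -> pd.DataFrame:
    """Load a source_id/target_id/evidence TSV; duplicate pairs are dropped."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source_id", "target_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"interaction table needs columns {sorted(required)}")
    if "evidence" not in df.columns:
        df["evidence"] = ""
    df["origin"] = origin
    return df.drop_duplicates(["source_id", "target_id"]).reset_index(drop=True)


def intersect_mirnas(
    lnc2mir: pd.DataFrame,
    mir2gene: pd.DataFrame,
    lnc_id: str,
    gene_ids: list[str],
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Venn membership of miRNA sets and the resulting sponge triplets.

    Returns ``(mirna_sets, triplets)`` where ``mirna_sets`` maps the lncRNA
    id and every gene id to its miRNA set (case-sensitive ids; unknown ids
    give empty sets), and ``triplets`` holds one row per
    (lnc, miRNA, gene) with the miRNA in the pairwise intersection, sorted
    deterministically. The ``common`` key holds the intersection across the
    lncRNA and all genes.
    """
    lnc_set = set(lnc2mir.loc[lnc2mir["source_id"] == lnc_id, "target_id"])
    sets: dict[str, set[str]] = {lnc_id: lnc_set}
    rows = []
    common = set(lnc_set)
    for g in gene_ids:
        gset = set(mir2gene.loc[mir2gene["target_id"] == g, "source_id"])
        sets[g] = gset
        common &= gset
        for m in sorted(lnc_set & gset):
            rows.append({"lnc_id": lnc_id, "mirna_id": m, "gene_id": g})
    sets["common"] = common
    triplets = pd.DataFrame(rows, columns=["lnc_id", "mirna_id", "gene_id"])
    triplets = triplets.sort_values(["mirna_id", "gene_id"]).reset_index(drop=True)
    return sets, triplets


def overlap_test(size_a: int, size_b: int, overlap: int, universe: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap) for two sets in a universe."""
    if not (0 <= overlap <= min(size_a, size_b) <= universe):
        raise ValueError("inconsistent set sizes for overlap test")
    if max(size_a, size_b) > universe:
        raise ValueError("set larger than universe")
    return float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))


@dataclass
class SeedSite:
    """One seed-complementary site on a transcript (0-based offset)."""

    site_type: str      # 8mer, 7mer-m8 or 7mer-A1
    start: int          # offset of the site's first base on the transcript
    end: int            # half-open end
    sequence: str


def _clean_rna(seq: str, what: str) -> str:
    s = seq.upper().replace("T", "U")
    if not s or set(s) - set("ACGU"):
        raise ValueError(f"invalid {what} alphabet: expected DNA/RNA letters")
    return s


def seedmatch_scan(
    mirna: str,
    transcript: str,
    site_types: tuple[str, ...] = ("8mer", "7mer-m8", "7mer-A1"),
) -> list[SeedSite]:
    """Canonical miRNA seed sites on a transcript, by exhaustive scan.

    The seed is miRNA positions 2-7 (5'->3'); a site is the reverse
    complement of the seed on the transcript, extended per type: ``7mer-m8``
    adds a match to miRNA position 8, ``7mer-A1`` adds an A opposite
    position 1, ``8mer`` requires both. Overlapping sites of different types
    are all reported; within a type, every occurrence is reported.
    """
    mi = _clean_rna(mirna, "miRNA")
    if len(mi) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    tx = _clean_rna(transcript, "transcript")

    def rc(s: str) -> str:
        return s.translate(_COMPLEMENT)[::-1]

    seed_match = rc(mi[1:7])          # complements of positions 2-7
    m8 = rc(mi[7])                    # complement of position 8
    patterns = {
        "8mer": m8 + seed_match + "A",
        "7mer-m8": m8 + seed_match,
        "7mer-A1": seed_match + "A",
    }
    sites: list[SeedSite] = []
    for st in site_types:
        if st not in patterns:
            raise ValueError(f"unknown site type: {st!r}")
        pat = patterns[st]
        start = tx.find(pat)
        while start != -1:
            sites.append(SeedSite(st, start, start + len(pat), pat))
            start = tx.find(pat, start + 1)
    sites.sort(key=lambda s: (s.start, s.site_type))
    return sites
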