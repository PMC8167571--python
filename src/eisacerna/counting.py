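"""Exonic and intronic read counting from a GTF annotation and SAM/BAM alignments.

Gene models are built as the union of all annotated exons of a gene; introns
are the complement of that union within the gene span. A read is *exonic* for
a gene when any aligned base overlaps the exon union, *intronic* when it
overlaps an intron and no base touches an exon — the nascent-transcript
signal that serves as a transcription-rate proxy once divided by total intron
length (mean intronic coverage). Reads assignable to more than one gene are
discarded from both matrices and tallied in a QC report.

Coordinates are handled 0-based half-open internally; GTF's 1-based inclusive
coordinates are converted at the parsing boundary. For spliced (N-CIGAR)
alignments each aligned block is tested independently and any exonic block
makes the read exonic. Strand is ignored unless ``stranded=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "CountPair",
    "build_gene_models",
    "count_reads",
    "intronic_coverage",
    "read_count_pair",
]


@dataclass
class GeneModel:
    """Exon union and intron complement of one gene (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    exon_union: list[tuple[int, int]]
    intron_regions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.intron_regions:
            self.intron_regions = self._complement(self.exon_union)

    @staticmethod
    def _complement(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
        introns = []
        for (s0, e0), (s1, _e1) in zip(exons, exons[1:]):
            if s1 > e0:
                introns.append((e0, s1))
        return introns

    @property
    def span(self) -> tuple[int, int]:
        return self.exon_union[0][0], self.exon_union[-1][1]

    @property
    def total_intron_length(self) -> int:
        return sum(e - s for s, e in self.intron_regions)


@dataclass
class CountPair:
    """Matched exonic and intronic count matrices over identical genes/samples."""

    exon_counts: pd.DataFrame
    intron_counts: pd.DataFrame
    intron_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.exon_counts.shape != self.intron_counts.shape:
            raise ValueError("exon and intron matrices must have identical shape")
        if not self.exon_counts.index.equals(self.intron_counts.index):
            raise ValueError("gene order must be identical across matrices")
        if not self.exon_counts.columns.equals(self.intron_counts.columns):
            raise ValueError("sample order must be identical across matrices")
        if (self.exon_counts.values < 0).any() or (self.intron_counts.values < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return self.exon_counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.exon_counts.columns.tolist()


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def build_gene_models(gtf_path: str | Path) -> dict[str, GeneModel]:
    """Build per-gene exon-union models from a GTF (exon features only).

    Raises ``ValueError`` naming the offending line number on malformed input.
    Single-exon genes get an empty intron list (total intron length 0).
    """
    exons: dict[str, dict] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                s0, e0 = int(start) - 1, int(end)   # 1-based inclusive -> 0-based half-open
            except ValueError as exc:
                raise ValueError(f"malformed GTF line {lineno}: bad coordinates") from exc
            if s0 < 0 or e0 <= s0:
                raise ValueError(f"malformed GTF line {lineno}: bad interval {start}-{end}")
            attrs = _parse_gtf_attributes(attr)
            gid = attrs.get("gene_id")
            if not gid:
                raise ValueError(f"malformed GTF line {lineno}: missing gene_id")
            rec = exons.setdefault(gid, {"chrom": chrom, "strand": strand, "ivs": []})
            rec["ivs"].append((s0, e0))
    models = {}
    for gid, rec in exons.items():
        models[gid] = GeneModel(
            gene_id=gid,
            chrom=rec["chrom"],
            strand=rec["strand"],
            exon_union=_merge_intervals(rec["ivs"]),
        )
    return models


def _build_trees(
    models: dict[str, GeneModel], stranded: bool
) -> dict:
    """chrom (or chrom+strand) -> (exon tree, intron tree) of gene ids."""
    trees: dict = {}
    for m in models.values():
        key = (m.chrom, m.strand) if stranded else m.chrom
        ex, intr = trees.setdefault(key, (IntervalTree(), IntervalTree()))
        for s, e in m.exon_union:
            ex.addi(s, e, m.gene_id)
        for s, e in m.intron_regions:
            intr.addi(s, e, m.gene_id)
    return trees


def count_reads(
    models: dict[str, GeneModel],
    alignment_paths: list[str | Path] | str | Path,
    sample_ids: list[str] | None = None,
    stranded: bool = False,
) -> tuple[CountPair, pd.DataFrame]:
    """Count exonic and intronic reads per gene for one or more SAM/BAM files.

    Assignment rule per read: collect the genes whose exon union any aligned
    block overlaps (those are exonic candidates) and the genes whose introns
    a block overlaps without any exonic overlap for that gene (intronic
    candidates). A read assignable to more than one gene overall is dropped
    as ambiguous. Unmapped, secondary and supplementary records are skipped.
    Returns the CountPair and a QC table of skipped/ambiguous tallies.
    """
    if isinstance(alignment_paths, (str, Path)):
        alignment_paths = [alignment_paths]
    if sample_ids is None:
        sample_ids = [Path(p).stem for p in alignment_paths]

    gene_ids = sorted(models)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    trees = _build_trees(models, stranded)

    exon = np.zeros((len(gene_ids), len(sample_ids)), dtype=np.int64)
    intron = np.zeros_like(exon)
    qc_rows = []

    for j, path in enumerate(alignment_paths):
        n_ambig = n_unmapped = n_nochrom = n_secondary = 0
        mode = "rb" if str(path).endswith(".bam") else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
            for rec in af:
                if rec.is_unmapped:
                    n_unmapped += 1
                    continue
                if rec.is_secondary or rec.is_supplementary:
                    n_secondary += 1
                    continue
                key = (
                    (rec.reference_name, "-" if rec.is_reverse else "+")
                    if stranded
                    else rec.reference_name
                )
                if key not in trees:
                    n_nochrom += 1
                    continue
                ex_tree, in_tree = trees[key]
                blocks = rec.get_blocks()
                exonic_genes: set[str] = set()
                intronic_genes: set[str] = set()
                for s, e in blocks:
                    exonic_genes |= {iv.data for iv in ex_tree.overlap(s, e)}
                    intronic_genes |= {iv.data for iv in in_tree.overlap(s, e)}
                intronic_genes -= exonic_genes       # any exonic overlap wins
                hit_genes = exonic_genes | intronic_genes
                if len(hit_genes) > 1:
                    n_ambig += 1
                    continue
                if not hit_genes:
                    continue
                g = hit_genes.pop()
                if g in exonic_genes:
                    exon[gidx[g], j] += 1
                else:
                    intron[gidx[g], j] += 1
        qc_rows.append(
            {
                "sample_id": sample_ids[j],
                "ambiguous": n_ambig,
                "unmapped": n_unmapped,
                "secondary_or_supplementary": n_secondary,
                "unknown_chrom": n_nochrom,
            }
        )

    pair = CountPair(
        exon_counts=pd.DataFrame(exon, index=gene_ids, columns=sample_ids),
        intron_counts=pd.DataFrame(intron, index=gene_ids, columns=sample_ids),
        intron_lengths=pd.Series(
            {g: models[g].total_intron_length for g in gene_ids}, name="intron_length"
        ),
    )
    return pair, pd.DataFrame(qc_rows)


def intronic_coverage(pair: CountPair) -> pd.DataFrame:
    """Mean intronic coverage: intron reads / total intron length (reads/base).

    Genes without introns get NaN (missing), never zero, so downstream code
    can distinguish "no signal" from "undefined".
    """
    if pair.intron_lengths is None:
        raise ValueError("CountPair lacks intron lengths")
    lengths = pair.intron_lengths.reindex(pair.intron_counts.index).astype(float)
    lengths = lengths.where(lengths > 0)            # 0 -> NaN, flags zero-intron genes
    return pair.intron_counts.div(lengths, axis=0)


def read_count_pair(
    exon_path: str | Path,
    intron_path: str | Path,
    intron_lengths_path: str | Path | None = None,
) -> CountPair:
    """Load a CountPair from the TSV schema written by the simulator."""
    exon = pd.read_csv(exon_path, sep="\t", index_col=0)
    intron = pd.read_csv(intron_path, sep="\t", index_col=0)
    lengths = None
    if intron_lengths_path is not None:
        lengths = pd.read_csv(intron_lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return CountPair(exon_counts=exon, intron_counts=intron, intron_lengths=lengths)
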