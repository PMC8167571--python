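"""Synthetic RNA-seq data with planted transcriptional and post-transcriptional effects.

The generator emulates a two-cell-line drug-vs-vehicle time-course experiment:
negative-binomial exonic and intronic counts over the same genes, a design
table (cell line x treatment x timepoint x replicate), and a planted miRNA
sponge: one lncRNA induced by treatment whose per-sample (realized) expression
drives the stabilization of a known target-gene set. Genes fall in four
classes:

``null``
    no change anywhere.
``transcriptional``
    exon AND intron means shift together by the effect size in treated
    samples (transcription change, carried into the mature transcript).
``stabilized``
    exon mean rises (effect size plus a sponge-coupling term proportional to
    the centered realized lncRNA log-expression of each sample); intron mean
    unchanged — the signature of post-transcriptional stabilization.
``degraded``
    exon mean falls in treated samples; intron mean unchanged.

Counts are NB(mu, phi) with Var = mu + phi*mu^2, so phi = 0 is the Poisson
limit. Library sizes are drawn uniformly and applied as multiplicative depth
factors, which gives TMM normalization real work to do. Everything is
reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .counting import CountPair

__all__ = [
    "SimConfig",
    "GroundTruth",
    "default_design",
    "simulate_counts",
    "simulate_annotation_and_reads",
    "simulate_interactions",
    "write_sim_outputs",
]

GENE_CLASSES = ("null", "transcriptional", "stabilized", "degraded")


def default_design(
    cell_lines: tuple[str, ...] = ("U2932", "TMD8"),
    treatments: tuple[str, ...] = ("DMSO", "drug"),
    timepoints: tuple[int, ...] = (4, 8, 12),
    n_reps: int = 3,
) -> list[tuple[str, str, int, int]]:
    """Full-factorial design rows (cell_line, treatment, timepoint, replicate)."""
    return [
        (cl, tr, tp, r + 1)
        for cl in cell_lines
        for tr in treatments
        for tp in timepoints
        for r in range(n_reps)
    ]


@dataclass
class SimConfig:
    """Parameters of the count simulator.

    Proportions are fractions of protein-coding genes per planted class and
    must sum to at most 1 (the remainder is null). ``effect_log2fc`` is the
    planted effect beta in log2 units; ``intron_fraction`` the expected
    intronic/exonic baseline mean ratio; ``nb_dispersion`` phi in
    Var = mu + phi*mu^2; ``sponge_coupling`` the log2 shift of stabilized-gene
    exon means per unit of centered sponge-lncRNA log2-expression;
    ``lnc_noise_sd`` the per-sample biological SD (log2) of the sponge lncRNA
    around its condition mean, the jitter that the coupled targets inherit.
    """

    n_genes: int = 2000
    n_lnc: int = 10
    frac_transcriptional: float = 0.10
    frac_stabilized: float = 0.10
    frac_degraded: float = 0.05
    effect_log2fc: float = 1.0
    intron_fraction: float = 0.15
    nb_dispersion: float = 0.1
    libsize_range: tuple[float, float] = (5e5, 1.5e6)
    design: list[tuple[str, str, int, int]] = field(default_factory=default_design)
    sponge_coupling: float = 1.0
    lnc_effect_log2fc: float = 2.0
    lnc_noise_sd: float = 0.5
    n_sponge_targets: int = 50
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.frac_transcriptional, self.frac_stabilized, self.frac_degraded)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("class fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ValueError("class fractions must sum to at most 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")
        lo, hi = self.libsize_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("libsize_range must be positive and ordered")
        if self.n_genes < 1 or self.n_lnc < 1:
            raise ValueError("need at least one gene and one lncRNA")
        counts = pd.DataFrame(
            self.design, columns=["cell_line", "treatment", "timepoint", "replicate"]
        ).groupby(["cell_line", "treatment", "timepoint"]).size()
        if (counts < 2).any():
            raise ValueError(
                "every (cell_line, treatment, timepoint) condition needs >=2 "
                "replicates; correlation and DE are undefined otherwise"
            )


@dataclass
class GroundTruth:
    """Planted truth: per-gene class, sponge axis identities, true effects."""

    gene_class: dict[str, str]
    sponge_lnc_id: str
    sponge_targets: list[str]
    shared_mirna_id: str
    true_logfc: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, phi) with Var = mu + phi*mu^2; phi=0 falls back to Poisson."""
    if phi == 0:
        return rng.poisson(mu)
    size_param = 1.0 / phi
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def simulate_counts(
    config: SimConfig,
) -> tuple[CountPair, pd.DataFrame, GroundTruth]:
    """Simulate matched exonic/intronic count matrices with planted truth.

    Returns the count pair, the design table (sample_id, cell_line,
    treatment, timepoint, replicate) and the :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    design = pd.DataFrame(
        config.design, columns=["cell_line", "treatment", "timepoint", "replicate"]
    )
    design.insert(
        0,
        "sample_id",
        [
            f"{r.cell_line}_{r.treatment}_{r.timepoint}h_r{r.replicate}"
            for r in design.itertuples()
        ],
    )
    n_samples = len(design)
    treated = (design["treatment"] != "DMSO").to_numpy(dtype=float)

    gene_ids = [f"GENE{i:05d}" for i in range(config.n_genes)]
    lnc_ids = [f"LNC{i:03d}" for i in range(config.n_lnc)]
    all_ids = gene_ids + lnc_ids

    # class assignment over protein-coding genes
    n_tr = int(round(config.frac_transcriptional * config.n_genes))
    n_st = int(round(config.frac_stabilized * config.n_genes))
    n_de = int(round(config.frac_degraded * config.n_genes))
    perm = rng.permutation(config.n_genes)
    classes = np.array(["null"] * config.n_genes, dtype=object)
    classes[perm[:n_tr]] = "transcriptional"
    classes[perm[n_tr:n_tr + n_st]] = "stabilized"
    classes[perm[n_tr + n_st:n_tr + n_st + n_de]] = "degraded"

    beta = config.effect_log2fc
    sign = rng.choice([-1.0, 1.0], size=config.n_genes)
    true_logfc = np.zeros(config.n_genes)
    true_logfc[classes == "transcriptional"] = (beta * sign)[classes == "transcriptional"]
    true_logfc[classes == "stabilized"] = beta
    true_logfc[classes == "degraded"] = -beta

    stab_idx = np.flatnonzero(classes == "stabilized")
    n_targets = min(config.n_sponge_targets, stab_idx.size)
    target_idx = rng.choice(stab_idx, size=n_targets, replace=False) if n_targets else np.array([], dtype=int)
    sponge_targets = sorted(gene_ids[i] for i in target_idx)
    sponge_lnc = lnc_ids[0]

    # sponge lncRNA realized per-sample log2 shift: induction + biological noise
    lnc_shift = config.lnc_effect_log2fc * treated + rng.normal(
        0.0, config.lnc_noise_sd, size=n_samples
    )
    lnc_centered = lnc_shift - lnc_shift.mean()

    # decoy lncRNAs: differentially expressed but uncoupled, so candidate
    # selection has real competitors
    lnc_true = np.zeros(config.n_lnc)
    lnc_true[0] = config.lnc_effect_log2fc
    decoy_fc = rng.uniform(0.5, 1.5, size=config.n_lnc - 1) * rng.choice(
        [-1.0, 1.0], size=config.n_lnc - 1
    )
    lnc_true[1:] = decoy_fc

    base = 2.0 ** rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=len(all_ids)
    )
    exon_mu = np.tile(base[:, None], (1, n_samples))
    intron_mu = config.intron_fraction * exon_mu.copy()

    shift = np.zeros((len(all_ids), n_samples))
    for i in range(config.n_genes):
        cls = classes[i]
        if cls == "transcriptional":
            shift[i] = true_logfc[i] * treated
            intron_mu[i] *= 2.0 ** shift[i]          # transcription moves both
        elif cls == "stabilized":
            shift[i] = beta * treated
        elif cls == "degraded":
            shift[i] = -beta * treated
    if n_targets:
        shift[target_idx] += config.sponge_coupling * lnc_centered
        # realized planted effect of targets includes the coupling term
        coupling_contrast = config.sponge_coupling * (
            lnc_centered[treated == 1].mean() - lnc_centered[treated == 0].mean()
        )
        true_logfc[target_idx] = beta + coupling_contrast
    for j in range(config.n_lnc):
        row = config.n_genes + j
        shift[row] = lnc_shift if j == 0 else lnc_true[j] * treated
        intron_mu[row] *= 2.0 ** shift[row]      # lncRNA induction is transcriptional
    exon_mu *= 2.0 ** shift

    # depth: target library sizes uniform in range, applied multiplicatively
    target_lib = rng.uniform(*config.libsize_range, size=n_samples)
    depth = target_lib / exon_mu.sum(axis=0)
    exon_mu *= depth
    intron_mu *= depth

    exon = _nb_draw(rng, exon_mu, config.nb_dispersion)
    intron = _nb_draw(rng, intron_mu, config.nb_dispersion)

    intron_lengths = rng.integers(1_000, 20_000, size=len(all_ids))
    pair = CountPair(
        exon_counts=pd.DataFrame(exon, index=all_ids, columns=design["sample_id"]),
        intron_counts=pd.DataFrame(intron, index=all_ids, columns=design["sample_id"]),
        intron_lengths=pd.Series(intron_lengths, index=all_ids, name="intron_length"),
    )

    gene_class = {g: str(c) for g, c in zip(gene_ids, classes)}
    gene_class.update({l: "lncRNA" for l in lnc_ids})
    truth = GroundTruth(
        gene_class=gene_class,
        sponge_lnc_id=sponge_lnc,
        sponge_targets=sponge_targets,
        shared_mirna_id="miR-21-3p",
        true_logfc={
            **{g: float(f) for g, f in zip(gene_ids, true_logfc)},
            **{l: float(f) for l, f in zip(lnc_ids, lnc_true)},
        },
    )
    return pair, design, truth


# ---------------------------------------------------------------------------
# Toy annotation + aligned reads (fixture for the counting module)
# ---------------------------------------------------------------------------

def simulate_annotation_and_reads(
    config: SimConfig,
    out_dir: str | Path,
    reads_per_gene: tuple[int, int] = (6, 4),
    read_length: int = 50,
    n_boundary_reads: int = 1,
) -> tuple[Path, Path, CountPair]:
    """Emit a toy GTF and SAM whose exact expected counts are returned.

    Each gene gets two exons separated by one intron, all on one chromosome.
    ``reads_per_gene`` = (exonic, intronic) reads placed wholly inside the
    respective intervals; ``n_boundary_reads`` additional reads straddle the
    first exon-intron boundary and are counted exonic (any exonic overlap
    makes a read exonic). Single-end, ungapped reads only.
    """
    if config.n_genes > 100:
        raise ValueError("toy fixture supports at most 100 genes")
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    exon_len, intron_len, gap = 400, 600, 1_000
    gene_span = 2 * exon_len + intron_len
    chrom = "chr1"
    chrom_len = config.n_genes * (gene_span + gap) + gap

    n_ex, n_in = reads_per_gene
    gene_ids = [f"GENE{i:05d}" for i in range(config.n_genes)]
    gtf_path = out_dir / "toy.gtf"
    sam_path = out_dir / "toy.sam"

    reads: list[tuple[str, int]] = []   # (read name, 0-based start)
    exp_exon = np.zeros(config.n_genes, dtype=int)
    exp_intron = np.zeros(config.n_genes, dtype=int)
    intron_lengths = np.full(config.n_genes, intron_len)

    with open(gtf_path, "w") as gtf:
        for i, gid in enumerate(gene_ids):
            start0 = gap + i * (gene_span + gap)          # 0-based
            e1 = (start0, start0 + exon_len)              # half-open
            iv = (e1[1], e1[1] + intron_len)
            e2 = (iv[1], iv[1] + exon_len)
            attrs = f'gene_id "{gid}"; transcript_id "{gid}.1";'
            for feat, (s, e) in (("exon", e1), ("exon", e2)):
                gtf.write(
                    f"{chrom}\ttoy\t{feat}\t{s + 1}\t{e}\t.\t+\t.\t{attrs}\n"
                )
            for k in range(n_ex):
                pick = e1 if rng.random() < 0.5 else e2
                pos = int(rng.integers(pick[0], pick[1] - read_length + 1))
                reads.append((f"{gid}_ex{k}", pos))
            exp_exon[i] = n_ex
            for k in range(n_in):
                pos = int(rng.integers(iv[0], iv[1] - read_length + 1))
                reads.append((f"{gid}_in{k}", pos))
            exp_intron[i] = n_in
            for k in range(n_boundary_reads):
                pos = e1[1] - read_length // 2            # straddles boundary
                reads.append((f"{gid}_bd{k}", pos))
            exp_exon[i] += n_boundary_reads

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": chrom_len}],
    }
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam:
        for name, pos in reads:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = name
            a.query_sequence = "A" * read_length
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = f"{read_length}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            sam.write(a)

    sample = "toy_sample"
    expected = CountPair(
        exon_counts=pd.DataFrame(exp_exon, index=gene_ids, columns=[sample]),
        intron_counts=pd.DataFrame(exp_intron, index=gene_ids, columns=[sample]),
        intron_lengths=pd.Series(intron_lengths, index=gene_ids, name="intron_length"),
    )
    return gtf_path, sam_path, expected


# ---------------------------------------------------------------------------
# Interaction tables and gene sets
# ---------------------------------------------------------------------------

def simulate_interactions(
    truth: GroundTruth,
    n_decoy_mirnas: int = 20,
    n_decoy_targets: int = 50,
    seed: int = 0,
    n_noise_in_set: int = 25,
    n_decoy_sets: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """lncRNA->miRNA and miRNA->gene tables plus GMT-style gene sets.

    The shared miRNA targets both the sponge lncRNA and every sponge target.
    Decoy miRNAs target either the lncRNA or genes — never both — so the
    planted axis is the unique member of the Venn intersection. One gene set
    is the sponge target set diluted with null genes; the rest are random.
    """
    rng = np.random.default_rng(seed)
    lnc = truth.sponge_lnc_id
    shared = truth.shared_mirna_id
    targets = list(truth.sponge_targets)
    null_genes = sorted(g for g, c in truth.gene_class.items() if c == "null")

    decoy_mirnas = [f"miR-D{i:03d}" for i in range(n_decoy_mirnas)]
    decoy_genes = list(
        rng.choice(null_genes, size=min(n_decoy_targets, len(null_genes)), replace=False)
    )

    lnc2mir = [(lnc, shared, "curated")]
    mir2gene = [(shared, g, "curated") for g in targets]
    for m in decoy_mirnas:
        if rng.random() < 0.5:
            lnc2mir.append((lnc, m, "curated"))
            for g in rng.choice(decoy_genes, size=min(3, len(decoy_genes)), replace=False):
                mir2gene.append((m, g, "curated"))
        else:
            pool = targets + decoy_genes
            for g in rng.choice(pool, size=min(3, len(pool)), replace=False):
                mir2gene.append((m, g, "curated"))

    lnc2mir_df = pd.DataFrame(lnc2mir, columns=["source_id", "target_id", "evidence"])
    mir2gene_df = pd.DataFrame(mir2gene, columns=["source_id", "target_id", "evidence"])
    lnc2mir_df = lnc2mir_df.drop_duplicates(["source_id", "target_id"]).reset_index(drop=True)
    mir2gene_df = mir2gene_df.drop_duplicates(["source_id", "target_id"]).reset_index(drop=True)

    noise = list(
        rng.choice(
            [g for g in null_genes if g not in decoy_genes],
            size=min(n_noise_in_set, len(null_genes)),
            replace=False,
        )
    )
    sets: dict[str, list[str]] = {"SPONGE_TARGETS": sorted(targets) + sorted(noise)}
    coding = sorted(g for g, c in truth.gene_class.items() if c != "lncRNA")
    set_size = max(15, len(targets))
    for i in range(n_decoy_sets):
        members = rng.choice(coding, size=min(set_size, len(coding)), replace=False)
        sets[f"RANDOM_SET_{i:02d}"] = sorted(members)
    return lnc2mir_df, mir2gene_df, sets


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def write_sim_outputs(
    out_dir: str | Path,
    pair: CountPair,
    design: pd.DataFrame,
    truth: GroundTruth,
    lnc2mir: pd.DataFrame | None = None,
    mir2gene: pd.DataFrame | None = None,
    sets: dict[str, list[str]] | None = None,
) -> None:
    """Write the standard TSV/JSON/GMT bundle of a simulation run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pair.exon_counts.to_csv(out / "exon_counts.tsv", sep="\t", index_label="gene_id")
    pair.intron_counts.to_csv(out / "intron_counts.tsv", sep="\t", index_label="gene_id")
    pair.intron_lengths.rename("intron_length").to_csv(
        out / "intron_lengths.tsv", sep="\t", index_label="gene_id"
    )
    design.to_csv(out / "design.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
    if lnc2mir is not None:
        lnc2mir.to_csv(out / "lnc2mir.tsv", sep="\t", index=False)
    if mir2gene is not None:
        mir2gene.to_csv(out / "mir2gene.tsv", sep="\t", index=False)
    if sets is not None:
        write_gmt(sets, out / "sets.gmt")
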