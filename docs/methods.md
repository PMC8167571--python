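# Methods

## Exon–intron split analysis

For a contrast between conditions, exonic and intronic count matrices over
the same genes are normalized independently (each matrix gets its own TMM
factors, because exonic and intronic libraries have different compositions)
and fitted per gene with a linear model on log2-CPM. Δexon and Δintron are
the contrast estimates from the two fits. The post-transcriptional score is
Δexon − Δintron (equivalently, the log2 of the fold-change ratio whose value
1 marks purely transcriptional modulation). Its significance comes from the
same moderated fit applied to the per-sample difference of exon and intron
log2-CPM; since the contrast estimate is linear in the data, the score from
the difference fit equals Δexon − Δintron exactly, and the test accounts for
the correlated noise of the two measurements within a sample.

Classification: `stabilized` / `degraded` require FDR-adjusted p < 0.05 on
the score **and** |score| ≥ 0.585 log2 (1.5-fold). The literature on this
analysis states only the ratio criterion (≠ 1) without a numeric tolerance,
so the effect floor is a documented design choice to avoid calling noise,
not an inferred cutoff; both knobs are arguments. `transcriptional` requires
a significant exon change without a post-transcriptional call; the rest is
`unchanged`. Genes must pass the CPM filter in both matrices and have
nonzero intron counts in more than half the samples; others are excluded
rather than imputed (intron signal is too sparse to impute honestly).

## Statistical engine

- **Filter**: CPM > 1 in ≥ 3 samples (the standard bulk low-expression rule);
  both values are arguments.
- **TMM**: pairwise trimmed mean of M-values against a reference sample
  (upper-quartile-closest-to-mean rule), genes nonzero in both samples,
  double trim 30% on M and 5% on A, inverse-asymptotic-variance weights,
  factors rescaled to geometric mean 1. Trim constants are the canonical
  defaults. The implementation is verified against edgeR's
  `calcNormFactors` to 1e-6 in the test suite.
- **log2-CPM**: pseudocount 0.5 scaled by relative effective library size,
  library size inflated by twice the scaled prior, so zeros are finite and
  the transform matches edgeR's `cpm(log=TRUE)`.
- **Moderated t**: per-gene OLS, then empirical-Bayes shrinkage of residual
  variances with (d₀, s₀²) estimated by the closed-form moments estimator on
  log variances (digamma/trigamma corrections; trigamma inverted by Newton
  iteration). Genes with zero residual variance are excluded from the
  estimation but still shrunk. d₀ = ∞ (all spread attributable to chance)
  falls back to a normal reference. Verified against limma's `eBayes` to
  1e-8 in the test suite.
- **BH**: delegated to `statsmodels.stats.multitest`.

## Sponge (ceRNA) inference

The per-sample stabilization index of a gene is exon log2-CPM minus intron
log2-CPM, centered per gene — the per-sample analogue of the score above.
Candidate lncRNAs are lncRNA-biotype features with DE adjusted p < 0.05,
split by logFC sign. Each candidate is correlated (Pearson, two-sided t
transform on n−2 df) with the index of every stabilized/degraded transcript.
Pooling is global by default and per cell line as an option (`--scope`),
because either choice is defensible: pooling doubles the sample count while
per-cell-line pooling protects against line-specific baselines. Ranking for
enrichment uses r itself; p-values are reported but not used for ranking.

## Preranked enrichment

Weighted KS statistic with weight p = 1: hits increment the running sum by
|score|^p normalized over hits, misses decrement by 1/(N − N_hits); the ES
is the signed maximum deviation. Significance uses gene-label permutations —
the only scheme available to a preranked list. Nominal p is the add-one
fraction of same-sign permuted scores at least as extreme (hence never below
1/(n_perm+1)); NES divides ES by the mean same-sign permuted magnitude; the
FDR q is the standard pooled two-tailed NES tabulation with per-sign
monotonicity enforcement; the FWER p uses the per-permutation extreme-NES
null. Sets are flagged enriched at nominal p < 0.05 and FDR q < 0.25. Set
size bounds 15–500 and n_perm = 1000 are the classic defaults. Permuted
scores are computed in closed form from sorted hit positions (the running
sum is piecewise linear, so extrema occur only adjacent to hits), which is
what makes 20 × 1000-permutation studies take seconds.

## Triplet nomination

MiRNA sets for the lncRNA and each gene of interest are intersected
case-sensitively; a triplet is emitted per miRNA in a pairwise intersection,
and the `common` region across all entities nominates the sponge-shared
miRNA. Overlap significance is the upper-tail hypergeometric
P(X ≥ k); the universe defaults to all miRNAs in either loaded table and is
configurable. Site-level support comes from a canonical seed-match scan
(reverse complement of miRNA positions 2–7 with 8mer/7mer-m8/7mer-A1
anchors). This scanner is a deliberately simple, clearly labelled pattern
scan (`origin=seedmatch`); trained site-prediction models are out of scope.

## Read counting

Gene models: exon union across all transcripts; introns are the complement
within the gene span (the deterministic EISA convention). A read is exonic
for a gene if any aligned block overlaps the exon union, intronic if it
overlaps an intron with no exonic overlap for that gene — so no read ever
counts in both matrices for one gene. Reads assignable to more than one gene
are discarded and tallied in the QC table (the assignment mode of the
original counting tool is not recoverable from the published description;
this rule is fixed and documented instead of guessed). Spliced (N-CIGAR)
blocks are tested independently; mate records of paired-end data are counted
independently; strand is ignored unless `stranded=True`. Intronic coverage
divides intron counts by total intron length; zero-intron genes yield NaN,
never 0. Coordinates are 0-based half-open internally; GTF converts at the
parse boundary.

## qPCR

ΔCT = CT_target − CT_reference; ΔΔCT subtracts the arithmetic mean control
ΔCT per target (and per optional grouping, e.g. timepoint);
FC = efficiency^−ΔΔCT with efficiency fixed at 2.0 (per-well efficiency
estimation is out of scope; the parameter is exposed). Stability index =
FC_mature / FC_pre.

## Synthetic data

The generator emulates a two-cell-line, DMSO-vs-drug, 4/8/12 h design with
3 replicates per condition (replicate count is a free choice; 3 is the
common bulk RNA-seq design). Counts are NB(μ, φ) with Var = μ + φμ²
(φ = 0.1 default, typical for cell-line RNA-seq; φ = 0 is the Poisson
limit). Gene baselines are log-normal (log2 mean 6, sd 1.5); intronic means
are 0.15 × the exonic baseline (introns are much shallower than exons);
library sizes are uniform in (0.5M, 1.5M) and applied multiplicatively so
TMM has real work to do. Planted classes: transcriptional genes shift exon
and intron together by ±β (β = 1 log2); stabilized genes shift the exon
mean only by +β; degraded genes by −β. The sponge lncRNA is induced 2 log2
in treated samples with per-sample biological noise (sd 0.5 log2); its
50 target genes (a subset of the stabilized class) additionally shift their
exon mean by coupling × the centered realized lncRNA log-expression
(coupling = 1), so the planted correlation survives replicate noise and the
recorded true effect of targets includes the coupling contrast. Decoy
lncRNAs are differentially expressed but uncoupled, so candidate selection
has real competitors; lncRNA induction moves introns too (it is
transcriptional). Interaction tables plant one shared miRNA targeting the
sponge and all its targets; decoy miRNAs target either the lncRNA or genes,
never both, so the planted axis is the unique common intersection.

What this emulates — and does not: NB sampling, composition and depth
effects, replicate noise and a realized (not idealized) sponge coupling. It
does not model positional read biases, isoform switching, overlapping genes,
ambiguous multi-mappers, batch effects, or intron retention, so passing
recovery tests demonstrates correctness of the inference machinery, not
robustness to every artifact of real libraries. The toy annotation/read
fixture uses single-end, ungapped reads placed wholly inside known intervals
(plus deliberate boundary-straddlers); spliced reads are exercised by unit
tests, not by the fixture.

## Verification studies (what the reproducibility script computes)

- enrichment score vs an explicit brute-force running sum, 100 random
  50-gene instances (exact);
- TMM vs a hand-computed trimmed weighted mean on a 5-gene toy (1e-8) and
  unit factors on identical columns;
- null calibration on 10⁴ effect-free genes, two groups of 3: moderated-t
  size at α = 0.05 and EISA post-transcriptional call rate;
- stabilized-class recovery over 20 seeds of the default 2000-gene design:
  sensitivity and false-discovery proportion;
- sponge recovery over 20 seeds: fraction where the planted lncRNA ranks
  first by mean target-set correlation among ≥ 5 DE candidates, and fraction
  where its target set is flagged enriched;
- miRNA-intersection exactness with 20 decoys; hypergeometric tail vs
  exhaustive enumeration for all universes ≤ 12;
- counting-fixture reproduction; ΔΔCT and stability-index identities.

Problem sizes (2000 genes for recovery, 10⁴ for calibration, 1000
permutations, 20 seeds) are chosen so each study estimates its rate with
adequate precision while the whole script completes in seconds.

## Known limitations

- Preranked permutation p-values are gene-label based and anti-conservative
  relative to sample permutation when genes are co-expressed.
- The correlation step does not control for the global treatment effect, so
  any treatment-responsive lncRNA correlates somewhat with stabilized
  transcripts; the planted-coupling design reflects this (decoys compete
  through the shared treatment component and lose only because the sponge
  also captures replicate-level jitter).
- Time-course structure is not modelled; contrasts are fit per design, as in
  per-timepoint panels.
- The DE module covers a single two-level treatment factor by default;
  arbitrary design/contrast matrices are accepted but not auto-built.
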