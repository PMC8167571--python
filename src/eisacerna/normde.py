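"""Filtering, TMM normalization, log2-CPM and moderated differential expression.

This module is the statistical engine of the pipeline: raw count matrices are
filtered on counts-per-million, normalized between samples with the trimmed
mean of M-values (TMM) so that composition differences do not masquerade as
differential expression, transformed to log2-CPM, and tested per gene with an
ordinary least-squares linear model whose residual variances are shrunk by an
empirical-Bayes (moderated t) procedure. Multiplicity is handled with
Benjamini-Hochberg step-up FDR.

Conventions
-----------
Count matrices are pandas DataFrames with genes as rows and samples as
columns. Design matrices are (samples x coefficients) arrays; contrasts are
coefficient-length vectors. The moderated t follows the hierarchical model
in which gene-wise variances s2_g on d_g degrees of freedom are scaled
chi-square around a gene-specific sigma2_g, and 1/sigma2_g is itself
scaled chi-square with prior df d0 and prior value s02: the posterior
variance is s2_tilde = (d0*s02 + d_g*s2_g) / (d0 + d_g) and the moderated t
is referred to a t distribution on d0 + d_g df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NormalizedMatrix",
    "DeResult",
    "filter_by_cpm",
    "tmm_factors",
    "log_cpm",
    "moderated_fit",
    "bh_adjust",
    "de_table",
]

DE_COLUMNS = ["feature_id", "logFC", "AveExpr", "t", "p_value", "adj_p_value"]


@dataclass
class NormalizedMatrix:
    """log2-CPM values with the normalization metadata that produced them."""

    values: pd.DataFrame          # genes x samples, log2-CPM
    norm_factors: pd.Series       # per-sample TMM factors, geometric mean 1
    lib_sizes: pd.Series          # per-sample total counts
    prior_count: float


@dataclass
class DeResult:
    """Per-feature differential-expression statistics (Table-1-style schema)."""

    table: pd.DataFrame           # columns DE_COLUMNS, one row per feature
    df_prior: float
    s2_prior: float

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["adj_p_value"] < alpha]


# ---------------------------------------------------------------------------
# CPM filter
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million without log transform (filtering scale)."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    return counts.div(lib_sizes, axis=1) * 1e6


def filter_by_cpm(
    counts: pd.DataFrame,
    min_cpm: float = 1.0,
    min_samples: int = 3,
) -> list[str]:
    """Features with CPM > ``min_cpm`` in at least ``min_samples`` samples.

    Defaults mirror the standard low-expression filter for bulk RNA-seq
    (CPM above one in three or more samples).
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    keep = ((cpm(counts, lib) > min_cpm).sum(axis=1) >= min_samples)
    retained = counts.index[keep].tolist()
    if not retained:
        raise ValueError("CPM filter removed every feature")
    return retained


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values, Robinson & Oshlack)
# ---------------------------------------------------------------------------

def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    sum_trim: float,
    a_cutoff: float,
) -> float:
    """log2 scaling factor of ``obs`` against ``ref`` (one pair of samples)."""
    ok = (obs > 0) & (ref > 0)
    obs = obs[ok].astype(float)
    ref = ref[ok].astype(float)
    if obs.size == 0:
        return 0.0
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    keep = a > a_cutoff
    m, a, v = m[keep], a[keep], v[keep]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 0.0
    # weighted by inverse asymptotic (delta-method) variance of M
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    a_cutoff: float = -1e10,
) -> pd.Series:
    """Per-sample TMM normalization factors, rescaled to geometric mean 1.

    M-values (log ratios) and A-values (log abundances) are computed against a
    reference sample on genes nonzero in both, doubly trimmed (30% on M, 5% on
    A by default) and averaged with inverse asymptotic-variance weights. The
    reference, when unspecified, is the sample whose upper-quartile CPM is
    closest to the mean upper quartile.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"samples with zero total count: {bad}")
    if ref_sample is None:
        uq = cpm(counts, lib).quantile(0.75, axis=0)
        ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy()
    n_ref = lib[ref_sample]
    logf = np.array(
        [
            _tmm_pair(
                counts[s].to_numpy(), ref, lib[s], n_ref,
                logratio_trim, sum_trim, a_cutoff,
            )
            for s in counts.columns
        ]
    )
    factors = 2.0 ** logf
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


# ---------------------------------------------------------------------------
# log2-CPM
# ---------------------------------------------------------------------------

def log_cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> NormalizedMatrix:
    """log2 counts-per-million on TMM-effective library sizes.

    The pseudocount is scaled by each sample's relative effective library size
    (prior_s = prior * L_s / mean(L)) and the library size is inflated by twice
    the scaled prior, so zero counts map to finite values and the transform is
    invariant to a common rescaling of counts and library sizes.
    """
    lib = counts.sum(axis=0).astype(float)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    eff = lib * factors.reindex(counts.columns)
    prior_s = prior_count * eff / eff.mean()
    adj = counts.add(prior_s, axis=1)
    denom = eff + 2.0 * prior_s
    values = np.log2(adj.div(denom, axis=1) * 1e6)
    return NormalizedMatrix(
        values=values,
        norm_factors=factors.copy(),
        lib_sizes=lib,
        prior_count=prior_count,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated linear model
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior_var(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments estimate of (d0, s0^2) from log gene-wise variances.

    Matches the log-scale moments of the scaled-F model for gene variances:
    e_g = log(s2_g) corrected for the chi-square bias has mean log(s02) plus a
    d0 term and excess variance trigamma(d0/2). Genes with zero sample
    variance are excluded here but still shrunk downstream. Returns
    d0 = inf when the observed spread is no larger than chance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = e.mean()
    excess = np.mean((e - ebar) ** 2) * s2.size / (s2.size - 1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * _trigamma_inverse(excess)
    s02 = np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s02)


def moderated_fit(
    norm: NormalizedMatrix | pd.DataFrame,
    design: np.ndarray,
    contrast: np.ndarray,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> DeResult:
    """Per-gene OLS fit with empirical-Bayes variance shrinkage.

    Parameters
    ----------
    norm
        log2-CPM matrix (genes x samples) or a :class:`NormalizedMatrix`.
    design
        Full-rank (samples x p) design matrix.
    contrast
        Length-p vector; the reported effect is ``contrast @ beta``.

    ``prior_df``/``prior_var`` override the estimated (d0, s02); a prior df
    of 0 disables shrinkage and recovers the ordinary t.

    Returns a :class:`DeResult` whose table carries logFC (the contrast
    estimate in log2 units), AveExpr (row mean log2-CPM), the moderated t,
    its two-sided p-value and the BH-adjusted p-value.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    y = values.to_numpy(dtype=float)
    x = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float)
    n, p = x.shape
    if y.shape[1] != n:
        raise ValueError("design rows must match sample columns")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is not full rank")
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom: add replicates")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv                      # genes x p
    resid = y - beta @ x.T
    s2 = np.sum(resid**2, axis=1) / df_resid
    effect = beta @ c
    unscaled_se = float(np.sqrt(c @ xtx_inv @ c))

    d0, s02 = estimate_prior_var(s2, df_resid)
    if prior_df is not None:
        d0 = prior_df
    if prior_var is not None:
        s02 = prior_var
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    t = effect / (np.sqrt(s2_post) * unscaled_se)
    if np.isinf(df_total):
        p_val = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p_val = 2.0 * stats.t.sf(np.abs(t), df_total)

    table = pd.DataFrame(
        {
            "feature_id": values.index,
            "logFC": effect,
            "AveExpr": y.mean(axis=1),
            "t": t,
            "p_value": p_val,
            "adj_p_value": bh_adjust(p_val),
        }
    ).reset_index(drop=True)
    return DeResult(table=table, df_prior=d0, s2_prior=s02)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, tie-safe)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Design/contrast helpers and the standard end-to-end DE run
# ---------------------------------------------------------------------------

def treatment_design(design_table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Intercept + treatment-indicator design with a treated-vs-control contrast.

    ``design_table`` needs a ``treatment`` column; the control level is
    whichever of DMSO/control is present, else the lexicographically first.
    """
    levels = sorted(design_table["treatment"].unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly two treatment levels, got {levels}")
    control = "DMSO" if "DMSO" in levels else ("control" if "control" in levels else levels[0])
    treated = [lv for lv in levels if lv != control][0]
    ind = (design_table["treatment"] == treated).astype(float).to_numpy()
    design = np.column_stack([np.ones(len(ind)), ind])
    contrast = np.array([0.0, 1.0])
    return design, contrast


def de_table(
    counts: pd.DataFrame,
    design_table: pd.DataFrame,
    min_cpm: float = 1.0,
    min_samples: int = 3,
    prior_count: float = 0.5,
) -> DeResult:
    """Filter, TMM-normalize, log-CPM transform and test treated vs control."""
    counts = counts[design_table["sample_id"]] if "sample_id" in design_table else counts
    kept = filter_by_cpm(counts, min_cpm=min_cpm, min_samples=min_samples)
    sub = counts.loc[kept]
    factors = tmm_factors(sub)
    norm = log_cpm(sub, factors, prior_count=prior_count)
    design, contrast = treatment_design(design_table)
    return moderated_fit(norm, design, contrast)
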