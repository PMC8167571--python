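"""Unit and property tests for filtering, TMM, log-CPM, moderated t and BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eisacerna import (
    bh_adjust,
    filter_by_cpm,
    log_cpm,
    moderated_fit,
    tmm_factors,
)
from eisacerna.normde import cpm, estimate_prior_var


def _matrix_with_cpm(cpm_values, libsize=10_000_000):
    """One gene with exact CPM values plus a filler gene absorbing the rest."""
    counts = np.array(cpm_values) * libsize / 1e6
    filler = libsize - counts
    return pd.DataFrame(
        np.vstack([counts, filler]).astype(int),
        index=["target", "filler"],
        columns=[f"s{i}" for i in range(len(cpm_values))],
    )


class TestCpmFilter:
    def test_paper_rule_cpm_above_one_in_three_samples(self):
        counts = _matrix_with_cpm([1.5, 1.2, 0.1, 2.0])
        assert "target" in filter_by_cpm(counts, min_cpm=1.0, min_samples=3)

    def test_below_threshold_in_too_many_samples_removed(self):
        counts = _matrix_with_cpm([1.5, 1.2, 0.1, 0.2])
        assert "target" not in filter_by_cpm(counts, min_cpm=1.0, min_samples=3)

    def test_all_zero_gene_removed_and_vacuous_filter(self, toy_counts):
        kept = filter_by_cpm(toy_counts, min_cpm=1.0, min_samples=3)
        assert "g5" not in kept
        assert filter_by_cpm(toy_counts, min_samples=0) == list(toy_counts.index)

    def test_all_filtered_raises(self, toy_counts):
        with pytest.raises(ValueError, match="every feature"):
            filter_by_cpm(toy_counts, min_cpm=1e9, min_samples=1)


class TestTmm:
    def test_identical_columns_give_unit_factors(self, toy_counts):
        dup = pd.concat([toy_counts["s1"]] * 3, axis=1)
        dup.columns = ["a", "b", "c"]
        f = tmm_factors(dup)
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference_absorbed(self, toy_counts):
        two = toy_counts[["s1"]].copy()
        two["s2"] = toy_counts["s1"] * 2
        f = tmm_factors(two)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_five_gene_toy_matches_hand_computation(self):
        # independent spreadsheet-style evaluation of the trimmed weighted mean
        a = np.array([100.0, 200.0, 300.0, 400.0, 1000.0])
        b = np.array([80.0, 260.0, 420.0, 370.0, 1870.0])
        counts = pd.DataFrame({"A": a, "B": b}, index=[f"g{i}" for i in range(5)])
        na, nb = a.sum(), b.sum()
        m = [float(np.log2((b[i] / nb) / (a[i] / na))) for i in range(5)]
        av = [float(0.5 * np.log2((b[i] / nb) * (a[i] / na))) for i in range(5)]
        v = [
            (nb - b[i]) / (nb * b[i]) + (na - a[i]) / (na * a[i])
            for i in range(5)
        ]
        # rank-based double trim: n=5 keeps M-ranks 2..4 and A-ranks 1..5
        order_m = sorted(range(5), key=lambda i: m[i])
        rank_m = {g: r + 1 for r, g in enumerate(order_m)}
        order_a = sorted(range(5), key=lambda i: av[i])
        rank_a = {g: r + 1 for r, g in enumerate(order_a)}
        kept = [i for i in range(5) if 2 <= rank_m[i] <= 4 and 1 <= rank_a[i] <= 5]
        f_log = sum(m[i] / v[i] for i in kept) / sum(1.0 / v[i] for i in kept)
        expected = np.array([1.0, 2.0**f_log])
        expected /= np.exp(np.mean(np.log(expected)))
        got = tmm_factors(counts, ref_sample="A").to_numpy()
        assert np.allclose(got, expected, atol=1e-8)

    def test_geometric_mean_is_one(self, small_sim):
        pair, _, _ = small_sim
        f = tmm_factors(pair.exon_counts)
        assert abs(np.mean(np.log(f))) < 1e-12

    def test_zero_total_sample_rejected(self, toy_counts):
        bad = toy_counts.copy()
        bad["s1"] = 0
        with pytest.raises(ValueError, match="zero total"):
            tmm_factors(bad)


class TestLogCpm:
    def test_direct_formula_without_prior(self):
        counts = _matrix_with_cpm([100.0, 100.0], libsize=1_000_000)
        norm = log_cpm(counts, prior_count=0.0)
        assert norm.values.loc["target", "s0"] == pytest.approx(np.log2(100), abs=1e-9)

    def test_zero_counts_stay_finite(self, toy_counts):
        norm = log_cpm(toy_counts, tmm_factors(toy_counts))
        assert np.isfinite(norm.values.to_numpy()).all()

    def test_scale_invariance_of_cpm(self, toy_counts):
        a = cpm(toy_counts)
        b = cpm(toy_counts * 2)
        assert np.allclose(a, b, atol=1e-9)
        # with the prior, doubling depth perturbs only near-zero counts
        f = tmm_factors(toy_counts)
        la = log_cpm(toy_counts, f).values
        lb = log_cpm(toy_counts * 2, f).values
        high = toy_counts.min(axis=1) > 10
        assert np.allclose(la[high], lb[high], atol=0.01)


class TestModeratedFit:
    design = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
    contrast = np.array([0.0, 1.0])

    def _null_matrix(self, n_genes, seed=0, sigma=1.0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(5.0, sigma, size=(n_genes, 6)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(6)],
        )

    def test_zero_prior_df_recovers_ordinary_t(self):
        y = self._null_matrix(50)
        res = moderated_fit(y, self.design, self.contrast, prior_df=0.0)
        grp = y.to_numpy()
        diff = grp[:, 3:].mean(axis=1) - grp[:, :3].mean(axis=1)
        s2 = (grp[:, :3].var(axis=1, ddof=1) + grp[:, 3:].var(axis=1, ddof=1)) / 2
        t_ord = diff / np.sqrt(s2 * (2 / 3))
        assert np.allclose(res.table["t"], t_ord, atol=1e-9)

    def test_equal_true_variance_posterior_consistent(self):
        # all genes share one true variance: shrinkage should leave the
        # average posterior variance at the average gene-wise variance
        sigma2 = 0.49
        y = self._null_matrix(5000, seed=3, sigma=np.sqrt(sigma2))
        res = moderated_fit(y, self.design, self.contrast)
        grp = y.to_numpy()
        s2 = (grp[:, :3].var(axis=1, ddof=1) + grp[:, 3:].var(axis=1, ddof=1)) / 2
        d0, s02 = res.df_prior, res.s2_prior
        post = (d0 * s02 + 4 * s2) / (d0 + 4) if np.isfinite(d0) else s02
        assert np.mean(post) == pytest.approx(np.mean(s2), rel=0.02)
        assert s02 == pytest.approx(sigma2, rel=0.05)

    def test_null_p_values_uniform(self):
        from scipy import stats

        y = self._null_matrix(10_000, seed=5)
        res = moderated_fit(y, self.design, self.contrast)
        ks = stats.kstest(res.table["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_rank_deficient_design_rejected(self):
        y = self._null_matrix(10)
        bad = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="full rank"):
            moderated_fit(y, bad, self.contrast)

    def test_no_residual_df_rejected(self):
        y = self._null_matrix(10).iloc[:, :2]
        design = np.column_stack([np.ones(2), [0, 1]])
        with pytest.raises(ValueError, match="replicates"):
            moderated_fit(y, design, self.contrast)

    def test_recovers_planted_logfc_on_simulated_counts(self):
        from eisacerna import SimConfig, de_table, simulate_counts

        pair, design_table, truth = simulate_counts(SimConfig(n_genes=2000, seed=11))
        res = de_table(pair.exon_counts, design_table)
        table = res.table.set_index("feature_id")
        true = pd.Series(truth.true_logfc)
        shared = table.index.intersection(true.index)
        coding = [g for g in shared if truth.gene_class[g] != "lncRNA"]
        bias = (table.loc[coding, "logFC"] - true.loc[coding]).mean()
        assert abs(bias) < 0.1


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_order_invariance_and_bounds(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm = bh_adjust(p[perm])
        assert np.allclose(np.sort(adj_perm), np.sort(adj))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=40))
    def test_monotone_after_sorting(self, pvals):
        p = np.sort(np.array(pvals))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()


def test_prior_var_estimator_recovers_known_prior():
    # variances drawn from the scaled chi-square hierarchy itself
    rng = np.random.default_rng(9)
    d0_true, s02_true, dg = 8.0, 0.5, 4
    sigma2 = s02_true * d0_true / rng.chisquare(d0_true, size=20_000)
    s2 = sigma2 * rng.chisquare(dg, size=20_000) / dg
    d0, s02 = estimate_prior_var(s2, dg)
    assert d0 == pytest.approx(d0_true, rel=0.1)
    assert s02 == pytest.approx(s02_true, rel=0.05)


def test_cpm_scale(toy_counts):
    c = cpm(toy_counts)
    assert np.allclose(c.sum(axis=0), 1e6)
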