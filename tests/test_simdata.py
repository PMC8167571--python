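"""Simulator contracts: NB moments, planted structure, determinism, round-trips."""

import numpy as np
import pandas as pd
import pytest

from eisacerna import (
    GroundTruth,
    SimConfig,
    default_design,
    read_count_pair,
    simulate_counts,
    simulate_interactions,
    write_sim_outputs,
)
from eisacerna.simdata import _nb_draw


class TestConfigValidation:
    def test_fraction_sum_constraint(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(frac_transcriptional=0.5, frac_stabilized=0.4,
                      frac_degraded=0.3).validate()

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            SimConfig(nb_dispersion=-0.1).validate()

    def test_single_replicate_design_rejected(self):
        design = default_design(n_reps=1)
        with pytest.raises(ValueError, match="replicates"):
            SimConfig(design=design).validate()


class TestNbSampling:
    @pytest.mark.parametrize("mu,phi", [(50.0, 0.1), (200.0, 0.05), (20.0, 0.0)])
    def test_mean_and_variance_match_parameterization(self, mu, phi, rng):
        n = 20_000
        draws = _nb_draw(rng, np.full(n, mu), phi)
        var = mu + phi * mu**2
        se_mean = np.sqrt(var / n)
        assert abs(draws.mean() - mu) < 3 * se_mean
        # SE of the sample variance from the fourth central moment
        m4 = ((draws - draws.mean()) ** 4).mean()
        se_var = np.sqrt((m4 - var**2) / n)
        assert abs(draws.var(ddof=1) - var) < 3 * se_var


class TestPlantedStructure:
    def test_all_null_config_has_no_exon_intron_divergence(self):
        cfg = SimConfig(n_genes=300, frac_transcriptional=0, frac_stabilized=0,
                        frac_degraded=0, lnc_effect_log2fc=0, sponge_coupling=0,
                        seed=2)
        pair, design, truth = simulate_counts(cfg)
        assert all(c in ("null", "lncRNA") for c in truth.gene_class.values())
        treated = design["treatment"] != "DMSO"
        ex, innt = pair.exon_counts, pair.intron_counts
        d_ex = np.log2(ex.loc[:, treated.values].mean(1) + 1) - np.log2(
            ex.loc[:, ~treated.values].mean(1) + 1)
        d_in = np.log2(innt.loc[:, treated.values].mean(1) + 1) - np.log2(
            innt.loc[:, ~treated.values].mean(1) + 1)
        assert abs((d_ex - d_in).mean()) < 0.05

    def test_poisson_limit_transcriptional_doubling(self):
        # dispersion 0, equal depth, beta=1: treated mean = 2x control per
        # gene after removing the global depth factor (estimated from the
        # null genes, whose means are constant by construction)
        design = default_design(cell_lines=("U2932",), timepoints=(8,), n_reps=50)
        cfg = SimConfig(n_genes=60, n_lnc=1, frac_transcriptional=0.5,
                        frac_stabilized=0, frac_degraded=0, nb_dispersion=0.0,
                        libsize_range=(1e6, 1e6), lnc_effect_log2fc=0,
                        sponge_coupling=0, design=design, seed=8)
        pair, dt, truth = simulate_counts(cfg)
        treated = (dt["treatment"] != "DMSO").to_numpy()
        n = treated.sum()
        null_genes = [g for g, c in truth.gene_class.items() if c == "null"]
        depth = pair.exon_counts.loc[null_genes].mean(axis=0).to_numpy()
        genes = [g for g, c in truth.gene_class.items() if c == "transcriptional"]
        ok = 0
        for g in genes:
            row = pair.exon_counts.loc[g].to_numpy(dtype=float) / depth
            mt, mc = row[treated].mean(), row[~treated].mean()
            log2_ratio = np.log2(mt / mc)
            # delta-method SE of the log2 mean ratio under Poisson counts
            raw = pair.exon_counts.loc[g].to_numpy(dtype=float)
            se = np.sqrt(
                1 / (n * raw[treated].mean()) + 1 / (n * raw[~treated].mean())
            ) / np.log(2)
            if abs(log2_ratio - truth.true_logfc[g]) < 3 * se:
                ok += 1
        assert ok >= 0.9 * len(genes)

    def test_stabilized_genes_have_exon_only_shift(self):
        cfg = SimConfig(n_genes=500, seed=3)
        pair, dt, truth = simulate_counts(cfg)
        treated = (dt["treatment"] != "DMSO").to_numpy()
        stab = [g for g, c in truth.gene_class.items() if c == "stabilized"]
        # depth-normalize against the null genes before comparing conditions
        null_genes = [g for g, c in truth.gene_class.items() if c == "null"]
        innt = pair.intron_counts.loc[stab].to_numpy(dtype=float)
        innt = innt / pair.intron_counts.loc[null_genes].mean(axis=0).to_numpy()
        d_in = np.log2(innt[:, treated].mean(1) + 1e-6) - np.log2(
            innt[:, ~treated].mean(1) + 1e-6)
        assert abs(d_in.mean()) < 0.1                 # population delta-intron 0
        ex = pair.exon_counts.loc[stab].to_numpy(dtype=float)
        ex = ex / pair.exon_counts.loc[null_genes].mean(axis=0).to_numpy()
        d_ex = np.log2(ex[:, treated].mean(1)) - np.log2(ex[:, ~treated].mean(1))
        assert d_ex.mean() > 0.5                      # exon shifted up

    def test_sponge_targets_subset_of_stabilized(self, small_sim):
        _, _, truth = small_sim
        stab = {g for g, c in truth.gene_class.items() if c == "stabilized"}
        assert set(truth.sponge_targets) <= stab
        assert len(truth.sponge_targets) > 0

    def test_determinism_bit_identical(self):
        cfg = SimConfig(n_genes=100, seed=42)
        p1, d1, t1 = simulate_counts(cfg)
        p2, d2, t2 = simulate_counts(SimConfig(n_genes=100, seed=42))
        assert p1.exon_counts.equals(p2.exon_counts)
        assert p1.intron_counts.equals(p2.intron_counts)
        assert t1.gene_class == t2.gene_class


class TestInteractions:
    def test_no_decoys_intersection_is_shared_mirna(self, small_sim):
        _, _, truth = small_sim
        lnc2mir, mir2gene, _ = simulate_interactions(truth, n_decoy_mirnas=0, seed=1)
        lnc_mirs = set(lnc2mir["target_id"])
        gene_mirs = set(mir2gene["source_id"])
        assert lnc_mirs & gene_mirs == {truth.shared_mirna_id}

    def test_decoys_never_create_extra_common_mirnas(self, small_sim):
        # brute-force set enumeration over every miRNA in the tables
        _, _, truth = small_sim
        lnc2mir, mir2gene, _ = simulate_interactions(truth, n_decoy_mirnas=30, seed=5)
        targets_mirs = {
            g: set(mir2gene.loc[mir2gene["target_id"] == g, "source_id"])
            for g in truth.sponge_targets
        }
        lnc_mirs = set(
            lnc2mir.loc[lnc2mir["source_id"] == truth.sponge_lnc_id, "target_id"]
        )
        common = lnc_mirs.copy()
        for mirs in targets_mirs.values():
            common &= mirs
        assert common == {truth.shared_mirna_id}

    def test_seed_determinism(self, small_sim):
        _, _, truth = small_sim
        a = simulate_interactions(truth, seed=9)
        b = simulate_interactions(truth, seed=9)
        assert a[0].equals(b[0]) and a[1].equals(b[1]) and a[2] == b[2]

    def test_gmt_set_contains_targets_plus_noise(self, small_sim):
        _, _, truth = small_sim
        _, _, sets = simulate_interactions(truth, seed=1)
        members = set(sets["SPONGE_TARGETS"])
        assert set(truth.sponge_targets) <= members
        assert len(members) > len(truth.sponge_targets)


class TestRoundTrips:
    def test_truth_json_round_trip(self, tmp_path, small_sim):
        _, _, truth = small_sim
        truth.to_json(tmp_path / "truth.json")
        back = GroundTruth.from_json(tmp_path / "truth.json")
        assert back == truth

    def test_counts_tsv_round_trip(self, tmp_path, small_sim):
        pair, design, truth = small_sim
        write_sim_outputs(tmp_path, pair, design, truth)
        back = read_count_pair(
            tmp_path / "exon_counts.tsv",
            tmp_path / "intron_counts.tsv",
            tmp_path / "intron_lengths.tsv",
        )
        assert back.exon_counts.equals(pair.exon_counts)
        assert back.intron_counts.equals(pair.intron_counts)
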