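"""Tests of the synthetic-data generator: determinism, conservation laws,
distributional limits, and ground-truth guarantees."""

import numpy as np
import pandas as pd
import pytest

import allelic as al
from allelic.errors import ConfigError
from allelic.simulate import orientation_betas


class TestConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("pi_functional", 1.5),
            ("rho_true", 0.5),
            ("dna_depth_mean", 0),
            ("umi_length", 0),
            ("n_rna_reps", 0),
            ("centisnp_or", -1),
            ("mu_dup", -0.5),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigError, match=field):
            al.SimConfig(n_snps=10, **{field: value})


class TestDesign:
    def test_null_fraction_forced(self):
        cfg = al.SimConfig(n_snps=100, pi_functional=0.0, seed=1)
        _, truth = al.simulate_design(cfg)
        assert (truth["beta_true"] == 0).all()

    def test_functional_count_matches_seeded_draw(self):
        # Binomial(1000, 0.2) draw; exact value frozen for this seed.
        cfg = al.SimConfig(n_snps=1000, pi_functional=0.2, seed=7)
        _, truth = al.simulate_design(cfg)
        n_functional = int((truth["beta_true"] != 0).sum())
        assert n_functional == 214
        # and plausibly Binomial(1000, 0.2): well within 5 sd of the mean
        assert abs(n_functional - 200) < 5 * np.sqrt(1000 * 0.2 * 0.8)

    def test_negative_controls_carry_no_effect(self):
        cfg = al.SimConfig(n_snps=3000, pi_functional=0.3, pi_asb=0.3, seed=2)
        designs, truth = al.simulate_design(cfg)
        nc = truth.merge(designs, on="snp_id").query("category == 'negative_control'")
        assert len(nc) > 0
        assert (nc["beta_true"] == 0).all()
        assert (nc["gamma_true"] == 0).all()

    def test_biallelic_with_distinct_alleles(self):
        designs, _ = al.simulate_design(al.SimConfig(n_snps=500, seed=3))
        assert (designs["ref_allele"] != designs["alt_allele"]).all()
        assert designs["ref_allele"].isin(list("ACGT")).all()

    def test_centisnp_functional_association_near_configured_or(self):
        cfg = al.SimConfig(n_snps=20000, pi_functional=0.2, centisnp_or=2.5, seed=4)
        designs, truth = al.simulate_design(cfg)
        m = designs.merge(truth, on="snp_id")
        centi = m["category"] == "CentiSNP"
        func = m["beta_true"] != 0
        a, b = (centi & func).sum(), (centi & ~func).sum()
        c, d = (~centi & func).sum(), (~centi & ~func).sum()
        sample_or = (a * d) / (b * c)
        assert 2.0 < sample_or < 3.1

    def test_deterministic_given_seed(self):
        cfg = al.SimConfig(n_snps=200, seed=5)
        d1, t1 = al.simulate_design(cfg)
        d2, t2 = al.simulate_design(cfg)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(t1, t2)


class TestDnaCounts:
    def test_balanced_library_limit(self):
        cfg = al.SimConfig(n_snps=50, lib_imbalance_conc=np.inf, seed=1)
        _, truth = al.simulate_design(cfg)
        assert (truth["p_dna_true"] == 0.5).all()

    def test_poisson_limit_mean(self):
        cfg = al.SimConfig(
            n_snps=10000, dna_depth_mean=100, nb_size=np.inf, n_dna_reps=1, seed=6
        )
        designs, truth = al.simulate_design(cfg)
        dna = al.simulate_dna_counts(designs, truth, cfg)
        totals = dna["ref_count"] + dna["alt_count"]
        se = np.sqrt(100 / len(totals))
        assert abs(totals.mean() - 100) < 3 * se
        # Poisson: variance approximately equals the mean
        assert 90 < totals.var() < 110

    def test_bit_identical_rerun(self):
        cfg = al.SimConfig(n_snps=100, seed=8)
        designs, truth = al.simulate_design(cfg)
        a = al.simulate_dna_counts(designs, truth, cfg)
        b = al.simulate_dna_counts(designs, truth, cfg)
        pd.testing.assert_frame_equal(a, b)


class TestRnaSimulation:
    def test_no_duplication_reads_equal_molecules(self):
        cfg = al.SimConfig(n_snps=100, mu_dup=0.0, n_rna_reps=2, seed=9)
        designs, truth = al.simulate_design(cfg)
        counts = al.simulate_rna_counts(designs, truth, cfg)
        mols = al.simulate_rna_molecules(designs, truth, cfg)
        assert len(mols) == int((counts["ref_count"] + counts["alt_count"]).sum())

    def test_null_read_fraction_converges_to_library_proportion(self):
        cfg = al.SimConfig(
            n_snps=1, pi_functional=0.0, rho_true=0.0, rna_depth_mean=10000,
            nb_size=np.inf, n_rna_reps=1, mu_dup=0.0, seed=10,
        )
        designs, truth = al.simulate_design(cfg)
        counts = al.simulate_rna_counts(designs, truth, cfg)
        r = counts["ref_count"].sum()
        n = int((counts["ref_count"] + counts["alt_count"]).sum())
        p = truth["p_dna_true"].iloc[0]
        assert abs(r / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_positive_effect_shifts_reference_fraction(self):
        # beta = +1 on a balanced library: expected ref fraction expit(1) ~ 0.731
        cfg = al.SimConfig(
            n_snps=200, pi_functional=1.0, tau_beta=0.0, rho_true=0.0,
            lib_imbalance_conc=np.inf, rna_depth_mean=500, n_rna_reps=2,
            mu_dup=0.0, seed=11,
        )
        designs, truth = al.simulate_design(cfg)
        truth = truth.assign(beta_true=1.0)
        counts = al.simulate_rna_counts(designs, truth, cfg)
        frac = counts["ref_count"].sum() / (counts["ref_count"] + counts["alt_count"]).sum()
        expected = 1 / (1 + np.exp(-1))
        n = (counts["ref_count"] + counts["alt_count"]).sum()
        assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

    def test_conservation_ref_plus_alt(self):
        cfg = al.SimConfig(n_snps=50, mu_dup=1.0, n_rna_reps=2, seed=12)
        designs, truth = al.simulate_design(cfg)
        counts = al.simulate_rna_counts(designs, truth, cfg)
        assert (counts["ref_count"] >= 0).all() and (counts["alt_count"] >= 0).all()
        mols = al.simulate_rna_molecules(designs, truth, cfg)
        # every read belongs to one of the two alleles of its SNP
        assert set(mols["allele"].unique()) <= {"ref", "alt"}

    def test_beta_mixing_matches_betabinomial_variance(self):
        # Equivalence oracle: empirical variance of the simulated counts
        # matches N p q (1 + (N-1) rho) within 3 se of the variance estimate.
        rho, N, p = 0.05, 100, 0.5
        cfg = al.SimConfig(
            n_snps=20000, pi_functional=0.0, rho_true=rho, rna_depth_mean=N,
            nb_size=np.inf, lib_imbalance_conc=np.inf, n_rna_reps=1,
            mu_dup=0.0, seed=13,
        )
        designs, truth = al.simulate_design(cfg)
        counts = al.simulate_rna_counts(designs, truth, cfg)
        pooled = al.pool_orientations(counts)
        tot = (pooled["ref_count"] + pooled["alt_count"]).to_numpy()
        r = pooled["ref_count"].to_numpy()
        # condition on totals: use deviation from expectation given N_i
        resid = r - tot * p
        target = np.mean(tot * p * (1 - p) * (1 + (tot - 1) * rho))
        emp = np.mean(resid**2)
        se = np.std(resid**2) / np.sqrt(len(resid))
        assert abs(emp - target) < 3 * se

    def test_orientation_specific_effects_only_in_opposite_config(self):
        cfg = al.SimConfig(
            n_snps=2000, pi_functional=1.0, tau_beta=0.5,
            direction_specific_factor="CTCF", seed=14,
        )
        designs, truth = al.simulate_design(cfg)
        ob = orientation_betas(designs, truth, cfg)
        m = ob.merge(designs[["snp_id", "motif_factor", "motif_strand"]], on="snp_id")
        ctcf = m[m["motif_factor"] == "CTCF"]
        match = (ctcf["motif_strand"] == "+") == (ctcf["orientation"] == "forward")
        assert (ctcf.loc[match, "beta_eff"] == 0).all()
        assert (ctcf.loc[~match, "beta_eff"] != 0).any()
        other = m[m["motif_factor"] != "CTCF"]
        merged_truth = other.merge(truth, on="snp_id")
        assert np.allclose(merged_truth["beta_eff"], merged_truth["beta_true"])


class TestBindingSimulation:
    def test_null_binding_fractions_share_proportion(self):
        cfg = al.SimConfig(
            n_snps=2000, pi_asb=0.0, rho_true=0.0, fraction_depth_mean=500,
            n_bind_reps=1, n_concentrations=1, seed=15,
        )
        designs, truth = al.simulate_design(cfg)
        counts, _ = al.simulate_binding_counts(designs, truth, cfg)
        frac_means = {}
        for frac, chunk in counts.groupby("fraction"):
            frac_means[frac] = (
                chunk["ref_count"].sum()
                / (chunk["ref_count"] + chunk["alt_count"]).sum()
            )
        assert abs(frac_means["bound"] - frac_means["unbound"]) < 0.01

    def test_footprint_regions_have_elevated_log2_ratio(self):
        cfg = al.SimConfig(
            n_snps=3000, region_logfc_mean_fp=2.0, region_logfc_mean_bg=0.0,
            fraction_depth_mean=200, seed=16,
        )
        designs, truth = al.simulate_design(cfg)
        _, regions = al.simulate_binding_counts(designs, truth, cfg)
        mat = regions.pivot_table(
            index="region_id", columns="fraction", values="count", aggfunc="sum"
        )
        lfc = np.log2((mat["bound"] + 0.5) / (mat["unbound"] + 0.5))
        fp = designs.set_index("region_id")["has_target_footprint"].reindex(mat.index)
        mean_fp = lfc[fp.to_numpy()].mean()
        se = lfc[fp.to_numpy()].std() / np.sqrt(int(fp.sum()))
        assert abs(mean_fp - 2.0) < 3 * se
        assert mean_fp > lfc[~fp.to_numpy()].mean() + 1.0

    def test_determinism(self):
        cfg = al.SimConfig(n_snps=50, seed=17)
        designs, truth = al.simulate_design(cfg)
        a1, r1 = al.simulate_binding_counts(designs, truth, cfg)
        a2, r2 = al.simulate_binding_counts(designs, truth, cfg)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(r1, r2)
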