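import pandas as pd
import pytest

import allelic as al


@pytest.fixture(scope="session")
def null_sim():
    """A null library (no true effects) with moderate overdispersion."""
    cfg = al.SimConfig(
        n_snps=2000,
        pi_functional=0.0,
        pi_asb=0.0,
        rho_true=0.02,
        rna_depth_mean=100,
        n_rna_reps=3,
        mu_dup=0.0,
        seed=101,
    )
    designs, truth = al.simulate_design(cfg)
    dna = al.simulate_dna_counts(designs, truth, cfg)
    props = al.estimate_dna_proportions(dna)
    rna = al.simulate_rna_counts(designs, truth, cfg)
    return {"config": cfg, "designs": designs, "truth": truth,
            "dna": dna, "props": props, "rna": rna}


@pytest.fixture(scope="session")
def signal_sim():
    """A library where 20% of SNPs carry true allelic effects."""
    cfg = al.SimConfig(
        n_snps=2000,
        pi_functional=0.2,
        tau_beta=0.5,
        rho_true=0.02,
        rna_depth_mean=200,
        n_rna_reps=5,
        mu_dup=0.0,
        seed=202,
    )
    designs, truth = al.simulate_design(cfg)
    dna = al.simulate_dna_counts(designs, truth, cfg)
    props = al.estimate_dna_proportions(dna)
    rna = al.simulate_rna_counts(designs, truth, cfg)
    return {"config": cfg, "designs": designs, "truth": truth,
            "dna": dna, "props": props, "rna": rna}


@pytest.fixture()
def toy_dna():
    return pd.DataFrame(
        {
            "snp_id": ["s1"],
            "p0": [0.5],
            "var0": [1e-9],
            "d_total": [100000],
            "testable": [True],
        }
    )


def make_counts(ref, alt, snp_id="s1", replicate=1):
    return pd.DataFrame(
        {
            "snp_id": [snp_id],
            "replicate": [replicate],
            "fraction": ["RNA"],
            "ref_count": [ref],
            "alt_count": [alt],
        }
    )
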