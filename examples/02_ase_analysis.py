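"""Allele-specific expression analysis end to end.

Simulates RNA reads with PCR duplicates, collapses them by UMI, tests each
SNP's RNA allele ratio against the plasmid DNA proportion per replicate,
combines replicates by fixed-effects meta-analysis, and reports FDR calls
and the genomic inflation factor with and without deduplication.
"""

import allelic as al
from allelic.molecules import count_reads, dedup_umi

cfg = al.SimConfig(n_snps=3000, pi_functional=0.2, mu_dup=3.0, seed=7)
designs, truth = al.simulate_design(cfg)
dna_props = al.estimate_dna_proportions(al.simulate_dna_counts(designs, truth, cfg))
mols = al.simulate_rna_molecules(designs, truth, cfg)

for label, counts in (("dedup", dedup_umi(mols)), ("no dedup", count_reads(mols))):
    results, rho_by_rep = al.run_ase(counts, dna_props)
    meta = al.fixed_effects(results)
    meta, n_sig = al.call_significant(meta, fdr=0.10)
    lam = al.genomic_inflation(meta["pvalue"]).lambda_gc
    print(f"[{label:8s}] median rho = {sorted(rho_by_rep.values())[4]:.4f}; "
          f"ASE calls at FDR<10% = {n_sig}; lambda_GC = {lam:.2f}")

print("\nthe dedup lambda sits above 1 only because 20% of SNPs carry real")
print("effects; the much larger no-dedup lambda is PCR duplicates")
print("masquerading as signal, and its extra 'calls' are mostly false:")
truth_calls = truth.merge(meta[["snp_id", "significant"]], on="snp_id")
tp = truth_calls.loc[truth_calls["significant"], "beta_true"].ne(0).mean()
print(f"fraction of no-dedup calls that are truly functional: {tp:.2f}")
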