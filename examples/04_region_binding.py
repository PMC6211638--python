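"""Region-level bound/unbound enrichment with the joint call gate.

Simulates region totals where footprint-bearing regions have elevated
occupancy, runs the negative-binomial Wald test, and shows that the joint
gate (log2fc > 1 AND FDR < 1%) calls the occupied regions while footprint
regions are enriched among the calls.
"""

import allelic as al
from allelic.region import test_regions

cfg = al.SimConfig(
    n_snps=2000, frac_footprint=0.3, region_logfc_mean_fp=2.0,
    region_logfc_mean_bg=0.0, fraction_depth_mean=200, seed=21,
)
designs, truth = al.simulate_design(cfg)
_, region_counts = al.simulate_binding_counts(designs, truth, cfg)

results = test_regions(region_counts, lfc_threshold=1.0, fdr=0.01)
n_called = int(results["bound_call"].sum())
print(f"regions called bound (log2fc > 1 & FDR < 1%): {n_called} / {len(results)}")

m = results.merge(designs[["region_id", "has_target_footprint"]], on="region_id")
called = set(m.loc[m["bound_call"], "region_id"])
footprint = set(m.loc[m["has_target_footprint"], "region_id"])
enr = al.fisher_enrichment(called, footprint, set(m["region_id"]),
                           name="target footprint")
print(f"footprint enrichment among calls: OR = {enr.odds_ratio:.1f} "
      f"[{enr.ci95_low:.1f}, {enr.ci95_high:.1f}], p = {enr.pvalue:.2g}")
print("an OR far above 1 means bound calls concentrate in regions that")
print("carry the target factor's footprint, as designed into the truth.")
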