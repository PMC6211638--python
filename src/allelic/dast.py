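"""Differential allele-specific binding: the bound-vs-unbound contrast.

Allelic imbalance measured in the bound fraction alone confounds true
binding effects with plasmid library imbalance.  The differential test
contrasts the two fractions -- both tested against the same reference
proportion (pooled bound + unbound DNA) -- so any shared imbalance cancels:

    delta_beta = beta_bound - beta_unbound,
    se_delta   = sqrt(se_bound^2 + se_unbound^2),
    z = delta_beta / se_delta.

Replicates are combined with unweighted Stouffer within each factor
concentration, the concentration-level Z's are Stouffer-combined again for
the overall call, and BH correction is applied within each level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ase import estimate_overdispersion, test_ase
from .combine import adjust_pvalues, stouffer_combine
from .errors import PairingError
from .molecules import estimate_dna_proportions


def delta_ast(bound: pd.DataFrame, unbound: pd.DataFrame) -> pd.DataFrame:
    """Pair bound/unbound ASE results and test their difference.

    Both inputs are result tables from :func:`allelic.ase.test_ase` computed
    against the same reference proportion.  Pairing is on snp_id, replicate
    and (when present) concentration; duplicated keys raise
    :class:`PairingError`, while SNPs missing from one fraction are
    returned with NaN statistics and ``testable = False``.
    """
    keys = [
        c
        for c in ("snp_id", "replicate", "concentration")
        if c in bound.columns and c in unbound.columns
    ]
    if not keys:
        raise PairingError("no shared pairing columns between bound and unbound")
    for name, df in (("bound", bound), ("unbound", unbound)):
        if df.duplicated(subset=keys).any():
            raise PairingError(f"duplicate {keys} keys in {name} results")
    m = bound.merge(
        unbound, on=keys, how="outer", suffixes=("_b", "_u"), validate="one_to_one"
    )
    delta = m["beta_b"] - m["beta_u"]
    se = np.sqrt(m["se_b"] ** 2 + m["se_u"] ** 2)
    z = delta / se
    t_b = m.get("testable_b", pd.Series(True, index=m.index))
    t_u = m.get("testable_u", pd.Series(True, index=m.index))
    testable = (
        (t_b == True).to_numpy()  # noqa: E712 -- NaN from the outer merge is False
        & (t_u == True).to_numpy()  # noqa: E712
        & delta.notna().to_numpy()
    )
    testable = pd.Series(testable, index=m.index)
    out = m[keys].copy()
    out["delta_beta"] = delta.where(testable)
    out["se_delta"] = se.where(testable)
    out["z"] = z.where(testable)
    out["pvalue"] = 2.0 * norm.sf(np.abs(out["z"]))
    out["testable"] = testable
    return out


def combine_asb(
    dast_results: pd.DataFrame, fdr: float = 0.10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stouffer over replicates within concentration, then over concentrations.

    Returns ``(per_concentration, overall)``.  Both levels get BH q-values
    and an FDR call; ``overall`` additionally reports how many
    concentrations called each SNP individually (``n_conc_significant``,
    the union view of the per-concentration calls).
    """
    per_conc = stouffer_combine(
        dast_results, group_cols=["snp_id", "concentration"], z_col="z"
    )
    per_conc = per_conc.rename(columns={"z_comb": "z_conc", "k": "n_replicates"})
    per_conc["qvalue"] = np.nan
    for conc, idx in per_conc.groupby("concentration", observed=True).groups.items():
        per_conc.loc[idx, "qvalue"] = adjust_pvalues(
            per_conc.loc[idx, "pvalue"].to_numpy(), method="bh"
        )
    per_conc["significant"] = per_conc["qvalue"] < fdr

    overall = stouffer_combine(per_conc, group_cols=["snp_id"], z_col="z_conc")
    overall = overall.rename(columns={"z_comb": "z_overall", "k": "n_concentrations"})
    overall["qvalue"] = adjust_pvalues(overall["pvalue"].to_numpy(), method="bh")
    overall["significant"] = overall["qvalue"] < fdr
    n_sig = (
        per_conc.groupby("snp_id", observed=True)["significant"]
        .sum()
        .rename("n_conc_significant")
    )
    overall = overall.merge(n_sig.reset_index(), on="snp_id", how="left")
    return per_conc, overall


def run_dast(
    binding_counts: pd.DataFrame,
    rho: float | str = "auto",
    include_dna_variance: bool = True,
    fdr: float = 0.10,
) -> dict:
    """Full differential-binding analysis from bound/unbound allele counts.

    The reference proportion is estimated from the pooled bound + unbound
    counts (all concentrations and replicates).  Each (fraction,
    concentration, replicate) library is tested separately against it with
    its own method-of-moments overdispersion, paired into the differential
    statistic, and combined.  Returns a dict with keys ``dna``,
    ``per_replicate``, ``per_concentration``, ``overall``.
    """
    dna = estimate_dna_proportions(binding_counts)
    per_lib = []
    for (fraction, conc, rep), chunk in binding_counts.groupby(
        ["fraction", "concentration", "replicate"], observed=True
    ):
        rho_lib = (
            estimate_overdispersion(chunk, dna).rho if rho == "auto" else float(rho)
        )
        res = test_ase(
            chunk, dna, rho=rho_lib, include_dna_variance=include_dna_variance
        )
        per_lib.append(res)
    results = pd.concat(per_lib, ignore_index=True)
    bound = results[results["fraction"] == "bound"].drop(columns=["fraction"])
    unbound = results[results["fraction"] == "unbound"].drop(columns=["fraction"])
    paired = delta_ast(bound, unbound)
    per_conc, overall = combine_asb(paired, fdr=fdr)
    return {
        "dna": dna,
        "per_replicate": paired,
        "per_concentration": per_conc,
        "overall": overall,
    }
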