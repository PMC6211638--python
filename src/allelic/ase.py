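"""Beta-binomial test of allelic imbalance in RNA against the DNA proportion.

For each SNP and replicate, the reference and alternate RNA molecule counts
are compared with the reference proportion of the plasmid DNA library.  The
effect is the log-odds difference

    beta = logit(p_hat) - logit(p0),    p_hat = (R + 1/2) / (N + 1),

with a delta-method standard error combining beta-binomial sampling
variance (variance inflation ``1 + (N - 1) rho``) with, optionally, the
sampling uncertainty of the DNA proportion itself:

    Var(beta) = (1 + (N - 1) rho) / (N p_hat (1 - p_hat))
              + var0 / (p0 (1 - p0))^2.

The z-score beta/se is the combining currency for the meta-analytic
machinery; a single genome-wide overdispersion rho is estimated per
replicate by method of moments.  An exact beta-binomial tail test is
available as a small-N fallback where the normal approximation is shaky.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import betabinom, binom, norm

from .errors import EstimationError


@dataclasses.dataclass
class DispersionEstimate:
    """Genome-wide beta-binomial overdispersion for one library."""

    rho: float
    n_snps_used: int
    method: str = "mom"


def _merged(counts: pd.DataFrame, dna: pd.DataFrame) -> pd.DataFrame:
    m = counts.merge(
        dna[["snp_id", "p0", "var0", "testable"]], on="snp_id", how="left"
    )
    m["testable"] = m["testable"].fillna(False).astype(bool)
    return m


def estimate_overdispersion(
    counts: pd.DataFrame,
    dna: pd.DataFrame,
    min_snps: int = 50,
) -> DispersionEstimate:
    """Method-of-moments overdispersion from one library's counts.

    rho = max(0, sum_i[(R_i - N_i p0_i)^2 - N_i p0_i q0_i - N_i^2 var0_i]
                 / sum_i[N_i (N_i - 1) p0_i q0_i]),

    clamped to [0, 0.49].  The ``N^2 var0`` term removes the contribution of
    the DNA-proportion sampling error to the squared deviations, so that
    error is not double counted when it is also propagated into the test's
    standard error.  Rows with untestable DNA or N < 1 are ignored.

    Note this marginal estimator charges genuinely imbalanced SNPs to the
    dispersion, so on data with true effects it is biased upward by the
    average squared effect (a conservative direction for the test).  When
    several replicates of the same library design are available,
    :func:`estimate_overdispersion_pooled` separates the shared allelic
    effect from replicate-level dispersion and is free of that bias.
    """
    m = _merged(counts, dna)
    m = m[m["testable"]]
    r = m["ref_count"].to_numpy(float)
    n = r + m["alt_count"].to_numpy(float)
    keep = n >= 1
    r, n = r[keep], n[keep]
    p0 = m["p0"].to_numpy(float)[keep]
    if len(n) == 0:
        raise EstimationError("no testable SNPs for overdispersion estimation")
    if len(n) < min_snps:
        warnings.warn(
            f"only {len(n)} testable SNPs for overdispersion estimation "
            f"(recommend >= {min_snps})",
            stacklevel=2,
        )
    q0 = 1.0 - p0
    var0 = m["var0"].to_numpy(float)[keep]
    num = np.sum((r - n * p0) ** 2 - n * p0 * q0 - n**2 * var0)
    den = np.sum(n * (n - 1.0) * p0 * q0)
    if den <= 0:
        warnings.warn(
            "overdispersion denominator is zero (all N <= 1); returning rho = 0",
            stacklevel=2,
        )
        return DispersionEstimate(rho=0.0, n_snps_used=int(len(n)))
    rho = float(np.clip(num / den, 0.0, 0.49))
    return DispersionEstimate(rho=rho, n_snps_used=int(len(n)))


def estimate_overdispersion_pooled(
    counts: pd.DataFrame, min_snps: int = 50
) -> DispersionEstimate:
    """Signal-robust overdispersion from between-replicate variation.

    The true allelic effect of a SNP is a property of the sequence and is
    shared by every replicate, whereas overdispersion is drawn independently
    per replicate.  Within-SNP deviations of the per-replicate reference
    fractions from their across-replicate mean therefore isolate the
    dispersion: with y_ij = R_ij / N_ij and pi_i the pooled fraction,

        E[ sum_j (y_ij - ybar_i)^2 ] =
            (1 - 1/k_i) * pi_i q_i * sum_j [ 1/N_ij + rho (N_ij - 1)/N_ij ],

    which is solved for a single rho pooled over replicates by method of
    moments.  Needs >= 2 replicates per SNP (SNPs with fewer are ignored);
    requires no DNA reference at all.
    """
    work = counts[(counts["ref_count"] + counts["alt_count"]) >= 1]
    if "orientation" in work.columns and work["orientation"].nunique() > 1:
        from .molecules import pool_orientations

        work = pool_orientations(work)
    r = work["ref_count"].to_numpy(float)
    n = r + work["alt_count"].to_numpy(float)
    y = r / n
    g = work.groupby("snp_id", observed=True)
    k = g["replicate"].transform("count").to_numpy(float)
    ok = k >= 2
    if not ok.any():
        raise EstimationError("pooled overdispersion needs >= 2 replicates per SNP")
    snp = work["snp_id"].to_numpy()[ok]
    r, n, y, k = r[ok], n[ok], y[ok], k[ok]

    df_rep = pd.DataFrame({"snp_id": snp, "r": r, "n": n, "y": y, "k": k})
    agg = df_rep.groupby("snp_id", observed=True).agg(
        ybar=("y", "mean"),
        r_sum=("r", "sum"),
        n_sum=("n", "sum"),
        k=("k", "first"),
    )
    n_used = len(agg)
    if n_used < min_snps:
        warnings.warn(
            f"only {n_used} SNPs with >= 2 replicates for pooled "
            f"overdispersion (recommend >= {min_snps})",
            stacklevel=2,
        )
    merged = df_rep.merge(agg[["ybar", "r_sum", "n_sum"]], on="snp_id")
    pi = merged["r_sum"] / merged["n_sum"]
    piq = (pi * (1 - pi)).to_numpy()
    resid2 = ((merged["y"] - merged["ybar"]) ** 2).to_numpy()
    shrink = (1.0 - 1.0 / merged["k"]).to_numpy()
    nn = merged["n"].to_numpy(float)
    num = np.sum(resid2 - shrink * piq / nn)
    den = np.sum(shrink * piq * (nn - 1.0) / nn)
    if den <= 0:
        warnings.warn("degenerate depths; returning rho = 0", stacklevel=2)
        return DispersionEstimate(rho=0.0, n_snps_used=n_used, method="within-snp")
    rho = float(np.clip(num / den, 0.0, 0.49))
    return DispersionEstimate(rho=rho, n_snps_used=n_used, method="within-snp")


def _exact_pvalues(
    r: np.ndarray, n: np.ndarray, p0: np.ndarray, rho: float
) -> np.ndarray:
    """Two-sided beta-binomial tail p-values (doubled smaller tail, capped)."""
    out = np.empty(len(r))
    for i, (ri, ni, pi) in enumerate(zip(r, n, p0)):
        ni = int(ni)
        if rho > 0:
            scale = (1.0 - rho) / rho
            dist = betabinom(ni, pi * scale, (1.0 - pi) * scale)
        else:
            dist = binom(ni, pi)
        lower = dist.cdf(ri)
        upper = dist.sf(ri - 1)
        out[i] = min(1.0, 2.0 * min(lower, upper))
    return out


def test_ase(
    counts: pd.DataFrame,
    dna: pd.DataFrame,
    rho: float | DispersionEstimate = 0.0,
    include_dna_variance: bool = True,
    exact_below: int | None = None,
) -> pd.DataFrame:
    """Per-row allelic-imbalance test against the DNA proportion.

    ``counts`` is an allele-count table; every row (snp x replicate, and
    orientation if not pooled) is tested independently.  Returns a result
    table with beta, se, z, two-sided pvalue, n_rna and a ``testable``
    flag; rows with N = 0 or no usable DNA proportion carry NaN statistics.

    ``include_dna_variance`` toggles propagation of the DNA-proportion
    sampling variance into the standard error.  ``exact_below``, if set,
    replaces the normal-approximation p-value with an exact beta-binomial
    tail probability for rows with N below the threshold.
    """
    if isinstance(rho, DispersionEstimate):
        rho = rho.rho
    if not 0.0 <= rho < 0.5:
        raise ValueError(f"rho must be in [0, 0.5), got {rho}")
    m = _merged(counts, dna)
    r = m["ref_count"].to_numpy(float)
    a = m["alt_count"].to_numpy(float)
    n = r + a
    p0 = m["p0"].to_numpy(float)
    var0 = m["var0"].to_numpy(float)
    testable = m["testable"].to_numpy() & (n >= 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_hat = (r + 0.5) / (n + 1.0)
        beta = logit(p_hat) - logit(p0)
        var = (1.0 + (n - 1.0) * rho) / (n * p_hat * (1.0 - p_hat))
        if include_dna_variance:
            var = var + var0 / (p0 * (1.0 - p0)) ** 2
        se = np.sqrt(var)
        z = beta / se
        pvalue = 2.0 * norm.sf(np.abs(z))

    if exact_below is not None:
        small = testable & (n < exact_below)
        if small.any():
            pvalue[small] = _exact_pvalues(r[small], n[small], p0[small], rho)

    for arr in (beta, se, z, pvalue):
        arr[~testable] = np.nan

    out_cols = [c for c in ("snp_id", "orientation", "replicate", "fraction", "concentration") if c in m.columns]
    out = m[out_cols].copy()
    out["beta"] = beta
    out["se"] = se
    out["z"] = z
    out["pvalue"] = pvalue
    out["n_rna"] = n.astype(np.int64)
    out["testable"] = testable
    return out


def run_ase(
    counts: pd.DataFrame,
    dna: pd.DataFrame,
    rho: float | str = "auto",
    pool_orientation: bool = True,
    include_dna_variance: bool = True,
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Per-replicate ASE tests with per-replicate overdispersion.

    With ``rho="auto"`` a genome-wide rho is estimated by method of moments
    separately for each replicate (each sequencing library has its own
    dispersion); pass a float to fix it.  Returns ``(results, rho_by_rep)``.
    """
    from .molecules import pool_orientations

    work = pool_orientations(counts) if pool_orientation and "orientation" in counts.columns else counts
    results = []
    rho_by_rep: dict[int, float] = {}
    for rep, chunk in work.groupby("replicate", observed=True):
        if rho == "auto":
            est = estimate_overdispersion(chunk, dna)
            rho_rep = est.rho
        else:
            rho_rep = float(rho)
        rho_by_rep[rep] = rho_rep
        results.append(
            test_ase(chunk, dna, rho=rho_rep, include_dna_variance=include_dna_variance)
        )
    out = pd.concat(results, ignore_index=True)
    return out, rho_by_rep
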