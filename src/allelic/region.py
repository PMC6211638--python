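"""Region-level bound-vs-unbound enrichment test.

Calls constructs overrepresented in the bound library with a documented,
deliberately simple negative-binomial Wald test: median-of-ratios size
factors, a method-of-moments dispersion pooled across regions of similar
mean (no shrinkage curves, no outlier filtering), and a Wald test on the
log2 fold change.  A region is called bound only at the joint gate
log2fc > 1 AND FDR < 1% -- the fold-change threshold is a hard gate, not a
test against 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .combine import adjust_pvalues

_LN2 = np.log(2.0)
_MIN_DISPERSION = 1e-8


def size_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors per sample (column).

    The reference is the per-region geometric mean over regions positive in
    every sample; each sample's factor is the median ratio of its counts to
    that reference.  If no region is positive in all samples, falls back to
    total-count scaling (normalized to geometric mean 1) with a warning.
    """
    if count_matrix.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    mat = count_matrix.to_numpy(float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        warnings.warn(
            "no region is positive in every sample; "
            "falling back to total-count size factors",
            stacklevel=2,
        )
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("a sample has zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(factors, index=count_matrix.columns, name="size_factor")
    logs = np.log(mat[all_pos])
    ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(factors, index=count_matrix.columns, name="size_factor")


def _counts_to_matrix(region_counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Long region-count table -> (region x sample matrix, sample -> fraction)."""
    if "sample_id" not in region_counts.columns:
        region_counts = region_counts.assign(
            sample_id=region_counts["fraction"].astype(str)
            + "_r"
            + region_counts["replicate"].astype(str)
        )
    mat = region_counts.pivot_table(
        index="region_id", columns="sample_id", values="count", aggfunc="sum", fill_value=0
    )
    frac = (
        region_counts.drop_duplicates("sample_id")
        .set_index("sample_id")["fraction"]
        .reindex(mat.columns)
    )
    return mat, frac


def estimate_dispersions(
    matrix: pd.DataFrame,
    factors: pd.Series,
    fractions: pd.Series,
    n_bins: int = 10,
) -> pd.Series:
    """Per-region NB dispersion alpha, pooled in bins of similar mean.

    For each region and condition, the within-condition moment equation
    E[(k/s - q)^2] = q * mean(1/s) + alpha q^2 yields a crude per-region
    alpha; regions are then binned into ``n_bins`` quantile bins of overall
    normalized mean and each region receives its bin's median alpha,
    floored at 1e-8.
    """
    y = matrix.to_numpy(float) / factors.to_numpy(float)[None, :]
    alpha_num = np.zeros(len(matrix))
    alpha_den = np.zeros(len(matrix))
    for frac in fractions.unique():
        cols = (fractions == frac).to_numpy()
        if cols.sum() < 2:
            continue
        yj = y[:, cols]
        s = factors.to_numpy(float)[cols]
        q = yj.mean(axis=1)
        v = yj.var(axis=1, ddof=1)
        alpha_num += v - q * np.mean(1.0 / s)
        alpha_den += q**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(alpha_den > 0, alpha_num / alpha_den, np.nan)
    base_mean = y.mean(axis=1)
    order = pd.qcut(
        pd.Series(base_mean).rank(method="first"), q=min(n_bins, len(matrix)), labels=False
    )
    alpha = np.full(len(matrix), _MIN_DISPERSION)
    for b in np.unique(order):
        idx = order.to_numpy() == b
        vals = alpha_raw[idx]
        vals = vals[np.isfinite(vals)]
        med = np.median(vals) if len(vals) else 0.0
        alpha[idx] = max(_MIN_DISPERSION, med)
    return pd.Series(alpha, index=matrix.index, name="dispersion")


def test_regions(
    region_counts: pd.DataFrame,
    lfc_threshold: float = 1.0,
    fdr: float = 0.01,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Bound-vs-unbound NB Wald test for every region.

    ``region_counts`` is a long table with columns region_id, sample_id (or
    fraction + replicate), fraction in {bound, unbound}, count.  For each
    fraction the normalized mean is q = (sum k + pseudocount) / sum s with

        Var(ln q) = 1 / (q * sum s) + alpha * sum(s^2) / (sum s)^2,

    log2fc = (ln q_bound - ln q_unbound)/ln 2, Wald z against 0, BH across
    regions, and ``bound_call = (log2fc > lfc_threshold) & (qvalue < fdr)``.
    All-zero regions are returned untestable with NaN statistics.
    """
    mat, frac_of = _counts_to_matrix(region_counts)
    if not set(frac_of.unique()) >= {"bound", "unbound"}:
        raise ValueError("region counts must contain bound and unbound samples")
    factors = size_factors(mat)
    alpha = estimate_dispersions(mat, factors, frac_of)

    stats = {}
    for frac in ("bound", "unbound"):
        cols = (frac_of == frac).to_numpy()
        k_sum = mat.to_numpy(float)[:, cols].sum(axis=1)
        s = factors.to_numpy(float)[cols]
        s_sum, s2_sum = s.sum(), (s**2).sum()
        q = (k_sum + pseudocount) / s_sum
        var_ln = 1.0 / (q * s_sum) + alpha.to_numpy() * s2_sum / s_sum**2
        stats[frac] = (q, var_ln, k_sum)

    qb, vb, kb = stats["bound"]
    qu, vu, ku = stats["unbound"]
    log2fc = (np.log(qb) - np.log(qu)) / _LN2
    se = np.sqrt(vb + vu) / _LN2
    z = log2fc / se
    pvalue = 2.0 * norm.sf(np.abs(z))
    testable = (kb + ku) > 0

    out = pd.DataFrame(
        {
            "region_id": mat.index,
            "log2fc": np.where(testable, log2fc, np.nan),
            "se": np.where(testable, se, np.nan),
            "pvalue": np.where(testable, pvalue, np.nan),
            "base_mean": (mat.to_numpy(float) / factors.to_numpy()[None, :]).mean(axis=1),
            "testable": testable,
        }
    ).reset_index(drop=True)
    out["qvalue"] = np.nan
    ok = out["testable"].to_numpy()
    if ok.any():
        out.loc[ok, "qvalue"] = adjust_pvalues(
            np.clip(out.loc[ok, "pvalue"].to_numpy(), 1e-300, 1.0), method="bh"
        )
    out["bound_call"] = (out["log2fc"] > lfc_threshold) & (out["qvalue"] < fdr)
    out["bound_call"] = out["bound_call"].fillna(False).astype(bool)
    return out
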