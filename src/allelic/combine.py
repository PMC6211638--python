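"""Combining per-replicate results and multiple-testing machinery.

Fixed-effects (inverse-variance) meta-analysis across replicates, Stouffer
combination of z-scores, Benjamini-Hochberg / Bonferroni adjustment, the
median-based genomic inflation factor, and FDR-threshold calling.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm
from statsmodels.stats.multitest import multipletests

# Median of the chi-square distribution with 1 df; lambda_GC divides by it.
CHI2_MEDIAN_1DF = float(chi2.ppf(0.5, 1))  # 0.4549...


@dataclasses.dataclass
class InflationReport:
    """Median-based genomic inflation factor over a set of p-values."""

    lambda_gc: float
    n_pvalues: int


def _validate_pvalues(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def fixed_effects(
    results: pd.DataFrame,
    group_cols: Sequence[str] = ("snp_id",),
    beta_col: str = "beta",
    se_col: str = "se",
    adjust: bool = True,
) -> pd.DataFrame:
    """Inverse-variance-weighted meta-analysis within each group.

    w_i = 1/se_i^2; beta_meta = sum(w b)/sum(w); se_meta = 1/sqrt(sum w);
    z = beta_meta/se_meta; two-sided p.  Rows with NaN beta/se (untestable)
    are dropped before combining; a single replicate passes through.  With
    ``adjust=True`` a BH q-value across groups is appended.
    """
    work = results.dropna(subset=[beta_col, se_col])
    if len(work) == 0:
        raise ValueError("no results to combine")
    if (work[se_col] <= 0).any():
        raise ValueError("all standard errors must be > 0")
    w = 1.0 / work[se_col] ** 2
    tmp = work.assign(_w=w, _wb=w * work[beta_col])
    g = tmp.groupby(list(group_cols), observed=True)
    sw = g["_w"].sum()
    swb = g["_wb"].sum()
    k = g.size()
    beta_meta = swb / sw
    se_meta = 1.0 / np.sqrt(sw)
    z = beta_meta / se_meta
    p = 2.0 * norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "beta_meta": beta_meta,
            "se_meta": se_meta,
            "z_meta": z,
            "pvalue": p,
            "k": k.astype(int),
        }
    ).reset_index()
    if adjust:
        out["qvalue"] = adjust_pvalues(out["pvalue"].to_numpy(), method="bh")
    return out


def stouffer(z_values: Iterable[float]) -> tuple[float, float]:
    """Unweighted Stouffer combination: Z = sum(z)/sqrt(k), two-sided p."""
    z = np.asarray(list(z_values), dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("no z-scores to combine")
    Z = float(z.sum() / np.sqrt(z.size))
    return Z, float(2.0 * norm.sf(abs(Z)))


def stouffer_combine(
    results: pd.DataFrame,
    group_cols: Sequence[str],
    z_col: str = "z",
) -> pd.DataFrame:
    """Vectorized unweighted Stouffer combination within groups."""
    work = results.dropna(subset=[z_col])
    if len(work) == 0:
        raise ValueError("no z-scores to combine")
    g = work.groupby(list(group_cols), observed=True)[z_col]
    Z = g.sum() / np.sqrt(g.count())
    out = pd.DataFrame({"z_comb": Z, "k": g.count().astype(int)}).reset_index()
    out["pvalue"] = 2.0 * norm.sf(np.abs(out["z_comb"]))
    return out


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: BH step-up or Bonferroni."""
    p = _validate_pvalues(pvalues)
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method.lower())
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def genomic_inflation(pvalues) -> InflationReport:
    """lambda_GC = median(chi2_1 quantile of 1 - p) / 0.4549.

    The denominator is the median of the chi-square distribution with one
    degree of freedom (0.4549 to four figures); lambda near 1 indicates a
    calibrated test, above 1 inflation.
    """
    p = _validate_pvalues(pvalues)
    stats = chi2.isf(p, df=1)
    return InflationReport(
        lambda_gc=float(np.median(stats) / CHI2_MEDIAN_1DF),
        n_pvalues=int(p.size),
    )


def call_significant(
    meta: pd.DataFrame, fdr: float = 0.10, q_col: str = "qvalue"
) -> tuple[pd.DataFrame, int]:
    """Flag rows with q-value below the FDR threshold; returns (df, count)."""
    out = meta.copy()
    out["significant"] = out[q_col] < fdr
    return out, int(out["significant"].sum())
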