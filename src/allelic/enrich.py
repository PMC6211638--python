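"""Annotation enrichment by Fisher's exact test.

Generic 2x2 enrichment of an annotation among significant calls over a
stated universe, the motif-direction analysis (per-transcription-factor
enrichment of allelic effects in match vs opposite oligo/motif strand
configurations), and the ASE x ASB overlap test.

Odds ratios are the conditional maximum-likelihood estimate (the exact-test
convention, with its exact 95% CI); the sample cross-product ratio is also
reported.  Match/opposite convention: an oligo/motif pair is a *match* when
the motif strand equals the strand transcribed by the reporter --

    motif strand '+', oligo forward  -> match
    motif strand '-', oligo reverse  -> match
    otherwise                        -> opposite
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio as _conditional_or

from .combine import adjust_pvalues


@dataclasses.dataclass
class ContingencyTable:
    """2x2 table: rows annotated / not, columns significant / not."""

    a: int  # annotated & significant
    b: int  # annotated & not significant
    c: int  # not annotated & significant
    d: int  # not annotated & not significant

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.a + self.b + self.c + self.d <= 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclasses.dataclass
class EnrichmentResult:
    annotation_name: str
    table: ContingencyTable
    odds_ratio: float  # conditional MLE
    sample_odds_ratio: float
    ci95_low: float
    ci95_high: float
    pvalue: float
    adjusted_pvalue: float = float("nan")


def fisher_pvalue(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table (no OR/CI machinery)."""
    arr = ContingencyTable(a, b, c, d).as_array()
    return float(fisher_exact(arr, alternative="two-sided")[1])


def fisher_table(
    a: int, b: int, c: int, d: int, name: str = "annotation"
) -> EnrichmentResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns the conditional-MLE odds ratio with its exact 95% CI; a zero
    margin yields an OR of 0 or inf with the one-sided CI bound pinned at
    the corresponding boundary.
    """
    table = ContingencyTable(a, b, c, d)
    arr = table.as_array()
    _, pvalue = fisher_exact(arr, alternative="two-sided")
    res = _conditional_or(arr, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    with np.errstate(divide="ignore", invalid="ignore"):
        sample_or = (a * d) / (b * c) if b * c > 0 else (np.inf if a * d > 0 else np.nan)
    return EnrichmentResult(
        annotation_name=name,
        table=table,
        odds_ratio=float(res.statistic),
        sample_odds_ratio=float(sample_or),
        ci95_low=float(ci.low),
        ci95_high=float(ci.high),
        pvalue=float(pvalue),
    )


def fisher_enrichment(
    significant: Iterable,
    annotated: Iterable,
    universe: Iterable,
    name: str = "annotation",
) -> EnrichmentResult:
    """Enrichment of ``annotated`` among ``significant`` over ``universe``.

    Both sets must be subsets of the universe (rows outside it raise).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sig = set(significant)
    ann = set(annotated)
    if not sig <= uni or not ann <= uni:
        raise ValueError("significant and annotated sets must be subsets of the universe")
    a = len(ann & sig)
    b = len(ann - sig)
    c = len(sig - ann)
    d = len(uni) - a - b - c
    return fisher_table(a, b, c, d, name=name)


def direction_configs(designs: pd.DataFrame) -> pd.DataFrame:
    """Match/opposite configuration for each SNP-oligo pair with a motif.

    Expands each design row into its oligo orientations and labels the
    configuration per the module convention.  SNPs without a motif factor
    are omitted.
    """
    with_motif = designs[designs["motif_factor"].astype(str) != ""].copy()
    rows = []
    for orient in ("forward", "reverse"):
        chunk = with_motif[
            with_motif["oligo_orientations"].str.contains(orient)
        ].copy()
        match = (chunk["motif_strand"] == "+") == (orient == "forward")
        rows.append(
            pd.DataFrame(
                {
                    "snp_id": chunk["snp_id"],
                    "oligo_direction": orient,
                    "motif_factor": chunk["motif_factor"],
                    "motif_strand": chunk["motif_strand"],
                    "configuration": np.where(match, "match", "opposite"),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def direction_analysis(
    ase_flags: pd.DataFrame,
    configs: pd.DataFrame,
    alpha: float = 0.05,
    min_per_config: int = 2,
) -> pd.DataFrame:
    """Per-factor enrichment of allelic effects by oligo/motif configuration.

    ``ase_flags`` has one row per SNP-oligo pair with columns snp_id,
    oligo_direction (or orientation) and a boolean ``significant``;
    ``configs`` comes from :func:`direction_configs`.  For each factor a
    2x2 of configuration (match/opposite) x significance is tested with
    Fisher's exact test; p-values are Bonferroni-adjusted over the factors
    tested.  Factors with fewer than ``min_per_config`` pairs in either
    configuration are skipped with a warning.
    """
    flags = ase_flags.rename(columns={"orientation": "oligo_direction"})
    merged = configs.merge(
        flags[["snp_id", "oligo_direction", "significant"]],
        on=["snp_id", "oligo_direction"],
        how="inner",
    )
    records = []
    for factor, chunk in merged.groupby("motif_factor", observed=True):
        is_match = chunk["configuration"] == "match"
        if is_match.sum() < min_per_config or (~is_match).sum() < min_per_config:
            warnings.warn(
                f"factor {factor}: fewer than {min_per_config} SNP-oligo pairs "
                "in one configuration; skipped",
                stacklevel=2,
            )
            continue
        sig = chunk["significant"].astype(bool)
        res = fisher_table(
            int((is_match & sig).sum()),
            int((is_match & ~sig).sum()),
            int((~is_match & sig).sum()),
            int((~is_match & ~sig).sum()),
            name=str(factor),
        )
        records.append(res)
    if not records:
        return pd.DataFrame(
            columns=[
                "motif_factor", "a", "b", "c", "d", "odds_ratio",
                "sample_odds_ratio", "ci95_low", "ci95_high", "pvalue",
                "p_bonferroni", "significant",
            ]
        )
    out = pd.DataFrame(
        {
            "motif_factor": [r.annotation_name for r in records],
            "a": [r.table.a for r in records],
            "b": [r.table.b for r in records],
            "c": [r.table.c for r in records],
            "d": [r.table.d for r in records],
            "odds_ratio": [r.odds_ratio for r in records],
            "sample_odds_ratio": [r.sample_odds_ratio for r in records],
            "ci95_low": [r.ci95_low for r in records],
            "ci95_high": [r.ci95_high for r in records],
            "pvalue": [r.pvalue for r in records],
        }
    )
    out["p_bonferroni"] = adjust_pvalues(
        np.clip(out["pvalue"].to_numpy(), 1e-300, 1.0), method="bonferroni"
    )
    out["significant"] = out["p_bonferroni"] < alpha
    return out


def overlap_ase_asb(
    ase_calls: Iterable,
    asb_calls: Iterable,
    universe: Iterable,
    name: str = "ASE x ASB",
) -> tuple[EnrichmentResult, int]:
    """Enrichment of binding calls among expression calls.

    The universe must be the SNPs testable in *both* assays -- restricting
    it changes the table and hence the odds ratio, which is why overlap
    odds ratios quoted against different universes differ.  Returns the
    enrichment result and the overlap count.
    """
    res = fisher_enrichment(ase_calls, asb_calls, universe, name=name)
    return res, res.table.a
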