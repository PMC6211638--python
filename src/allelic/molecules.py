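"""UMI deduplication and aggregation of molecule records into allele counts.

PCR duplicates share the UMI attached to their parent molecule, so within
each (snp, orientation, allele, replicate, fraction[, concentration]) group
the number of distinct UMIs is the number of molecules.  Collapse is by
exact UMI match -- no edit-distance clustering -- which is the minimal,
well-defined contract and what the bundled simulator emulates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import EstimationError, FormatError

GROUP_COLS = ("snp_id", "orientation", "replicate", "fraction", "concentration")
ALLELES = ("ref", "alt")


def _present_group_cols(records: pd.DataFrame) -> list[str]:
    return [c for c in GROUP_COLS if c in records.columns]


def _validate_umis(umi: pd.Series) -> None:
    if umi.dtype == object or pd.api.types.is_string_dtype(umi):
        lengths = umi.str.len()
        if lengths.nunique() > 1:
            raise FormatError(
                "inconsistent UMI lengths: "
                f"found {sorted(lengths.unique())[:5]}"
            )


def _group_allele_counts(records: pd.DataFrame, distinct_umis: bool) -> pd.DataFrame:
    """Count reads (or distinct UMIs) per group x allele, pivoted wide."""
    for col in ("snp_id", "orientation", "allele", "replicate", "fraction"):
        if col not in records.columns:
            raise FormatError(f"molecule table is missing column {col!r}")
    bad = ~records["allele"].isin(ALLELES)
    if bool(np.asarray(bad).any()):
        raise FormatError("allele column must contain only 'ref'/'alt'")

    group_cols = _present_group_cols(records)
    codes = []
    dims = []
    uniques = {}
    for col in group_cols:
        c, u = pd.factorize(records[col], use_na_sentinel=False)
        codes.append(c.astype(np.int64))
        dims.append(max(len(u), 1))
        uniques[col] = u
    allele_codes = (records["allele"].to_numpy() == "alt").astype(np.int64)
    codes.append(allele_codes)
    dims.append(2)
    gid = np.ravel_multi_index(codes, dims)

    if distinct_umis:
        _validate_umis(records["umi"])
        umi = records["umi"]
        if pd.api.types.is_integer_dtype(umi):
            umi_codes = umi.to_numpy(np.uint64)
            umi_dim = int(umi_codes.max()) + 1 if len(umi_codes) else 1
        else:
            c, u = pd.factorize(umi)
            umi_codes = c.astype(np.uint64)
            umi_dim = max(len(u), 1)
        key = gid.astype(np.uint64) * np.uint64(umi_dim) + umi_codes
        present = np.unique(key) // np.uint64(umi_dim)
        gid_u, counts = np.unique(present.astype(np.int64), return_counts=True)
    else:
        gid_u, counts = np.unique(gid, return_counts=True)

    unraveled = np.unravel_index(gid_u // 2, [d for d in dims[:-1]])
    out = {}
    for col, idx in zip(group_cols, unraveled):
        out[col] = np.asarray(uniques[col])[idx]
    long = pd.DataFrame(out)
    long["allele"] = np.where(gid_u % 2 == 0, "ref", "alt")
    long["n"] = counts

    wide = (
        long.pivot_table(
            index=group_cols, columns="allele", values="n", fill_value=0, aggfunc="sum"
        )
        .reset_index()
    )
    for al in ALLELES:
        if al not in wide.columns:
            wide[al] = 0
    wide = wide.rename(columns={"ref": "ref_count", "alt": "alt_count"})
    wide.columns.name = None
    cols = group_cols + ["ref_count", "alt_count"]
    return (
        wide[cols]
        .sort_values(group_cols, kind="mergesort")
        .reset_index(drop=True)
    )


def dedup_umi(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates: reads sharing a UMI within a group count once.

    Returns an allele-count table (one row per group, ``ref_count`` /
    ``alt_count`` columns holding numbers of distinct UMIs).  Raises
    :class:`FormatError` if string UMIs have inconsistent lengths.
    """
    if "umi" not in records.columns:
        raise FormatError("molecule table is missing column 'umi'")
    return _group_allele_counts(records, distinct_umis=True)


def count_reads(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate raw reads into allele counts without removing duplicates."""
    return _group_allele_counts(records, distinct_umis=False)


def pool_orientations(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum ref/alt counts over oligo orientation within each group."""
    group_cols = [c for c in GROUP_COLS if c in counts.columns and c != "orientation"]
    out = (
        counts.groupby(group_cols, as_index=False, sort=True, observed=True)[
            ["ref_count", "alt_count"]
        ].sum()
    )
    out.insert(1, "orientation", "pooled")
    return out


def estimate_dna_proportions(
    dna_counts: pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Pooled reference proportion of the DNA library per SNP.

    Pools ref/alt over every row supplied (replicates, orientations) and
    applies a symmetric Haldane-Anscombe pseudocount so p0 stays off the
    boundary: ``p0 = (Dref + c) / (Dref + Dalt + 2c)`` with sampling
    variance ``p0 (1 - p0) / (Dref + Dalt + 2c)``.  SNPs absent from the
    DNA library (zero total) are flagged ``testable = False`` with NaN
    estimates rather than raising.
    """
    if len(dna_counts) == 0:
        raise EstimationError("no DNA counts supplied")
    pooled = dna_counts.groupby("snp_id", as_index=False, observed=True)[
        ["ref_count", "alt_count"]
    ].sum()
    d_total = (pooled["ref_count"] + pooled["alt_count"]).to_numpy(float)
    denom = d_total + 2 * pseudocount
    p0 = (pooled["ref_count"].to_numpy(float) + pseudocount) / denom
    var0 = p0 * (1.0 - p0) / denom
    testable = d_total > 0
    return pd.DataFrame(
        {
            "snp_id": pooled["snp_id"],
            "p0": np.where(testable, p0, np.nan),
            "var0": np.where(testable, var0, np.nan),
            "d_total": d_total.astype(np.int64),
            "testable": testable,
        }
    )


def filter_testable(
    counts: pd.DataFrame,
    dna: pd.DataFrame,
    min_rna_total: int = 5,
    min_dna_total: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Keep SNPs with enough pooled RNA and DNA molecules to test.

    ``counts`` is an allele-count table (any fractions); the RNA filter is
    applied to the pooled total over all its rows per SNP.  Returns the
    filtered counts plus a summary dict with per-reason drop counts.
    """
    rna_tot = (
        counts.assign(total=counts["ref_count"] + counts["alt_count"])
        .groupby("snp_id", observed=True)["total"]
        .sum()
    )
    dna_ok = dna.set_index("snp_id")
    dna_tot = dna_ok["d_total"].reindex(rna_tot.index).fillna(0)
    dna_testable = dna_ok["testable"].reindex(rna_tot.index).fillna(False).astype(bool)

    pass_rna = rna_tot >= min_rna_total
    pass_dna = (dna_tot >= min_dna_total) & dna_testable
    keep = pass_rna & pass_dna
    kept_snps = set(rna_tot.index[keep])
    filtered = counts[counts["snp_id"].isin(kept_snps)].reset_index(drop=True)
    summary = {
        "n_input": int(len(rna_tot)),
        "n_kept": int(keep.sum()),
        "dropped_low_rna": int((~pass_rna).sum()),
        "dropped_low_dna": int((~pass_dna).sum()),
        "min_rna_total": int(min_rna_total),
        "min_dna_total": int(min_dna_total),
    }
    return filtered, summary


def molecules_from_bam(
    bam_path: str,
    snps: pd.DataFrame,
    replicate: int,
    fraction: str,
    umi_separator: str = "_",
) -> pd.DataFrame:
    """Thin adapter turning an aligned BAM/SAM into molecule records.

    ``snps`` needs columns snp_id, chrom, pos (1-based), ref_allele,
    alt_allele.  The UMI is taken as the final ``umi_separator``-delimited
    field of the read name (the convention UMI-aware pipelines use).  Reads
    whose base at the SNP matches neither allele are skipped.  Requires
    pysam (optional dependency).
    """
    import pysam  # optional; deliberately imported lazily

    rows = []
    with pysam.AlignmentFile(bam_path) as bam:
        for snp in snps.itertuples(index=False):
            pos0 = int(snp.pos) - 1
            for read in bam.fetch(str(snp.chrom), pos0, pos0 + 1):
                if read.is_unmapped or read.query_sequence is None:
                    continue
                pairs = dict(
                    (r, q) for q, r in read.get_aligned_pairs(matches_only=True)
                )
                qpos = pairs.get(pos0)
                if qpos is None:
                    continue
                base = read.query_sequence[qpos].upper()
                if base == str(snp.ref_allele).upper():
                    allele = "ref"
                elif base == str(snp.alt_allele).upper():
                    allele = "alt"
                else:
                    continue
                umi = read.query_name.rsplit(umi_separator, 1)[-1]
                orientation = "reverse" if read.is_reverse else "forward"
                rows.append((snp.snp_id, orientation, allele, umi, replicate, fraction))
    return pd.DataFrame(
        rows,
        columns=["snp_id", "orientation", "allele", "umi", "replicate", "fraction"],
    )
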