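"""Table readers/writers, UMI encoding, QQ reporting and config loading.

Every interchange format is TSV with documented headers; annotations come
in as BED (0-based half-open, converted to 1-based inclusive on read) and
the optional simulated oligo library goes out as FASTA.  All writers
round-trip: ``read(write(x))`` equals ``x`` up to dtype.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError

_UMI_BASES = np.array(["A", "C", "G", "T"])

SCHEMAS = {
    "designs": [
        "snp_id", "region_id", "ref_allele", "alt_allele", "oligo_orientations",
        "motif_factor", "motif_strand", "category", "has_target_footprint",
    ],
    "truth": ["snp_id", "beta_true", "gamma_true", "p_dna_true", "region_logfc_true"],
    "molecules": ["snp_id", "orientation", "allele", "umi", "replicate", "fraction"],
    "counts": ["snp_id", "orientation", "replicate", "fraction", "ref_count", "alt_count"],
    "dna_proportions": ["snp_id", "p0", "var0", "d_total", "testable"],
    "region_counts": ["region_id", "sample_id", "fraction", "replicate", "concentration", "count"],
}


def encode_umis(codes: np.ndarray, umi_length: int) -> np.ndarray:
    """Integer UMI codes -> ACGT strings (base-4, most significant first)."""
    codes = np.asarray(codes, dtype=np.uint64)
    letters = np.empty((len(codes), umi_length), dtype="U1")
    rem = codes.copy()
    for j in range(umi_length - 1, -1, -1):
        letters[:, j] = _UMI_BASES[(rem % 4).astype(int)]
        rem //= 4
    return np.array(["".join(row) for row in letters])


def decode_umis(strings: Sequence[str]) -> np.ndarray:
    """ACGT UMI strings -> integer codes (inverse of :func:`encode_umis`)."""
    lookup = {"A": 0, "C": 1, "G": 2, "T": 3}
    out = np.zeros(len(strings), dtype=np.uint64)
    for i, s in enumerate(strings):
        code = 0
        for ch in s:
            try:
                code = code * 4 + lookup[ch]
            except KeyError:
                raise FormatError(f"invalid UMI base {ch!r} in {s!r}") from None
        out[i] = code
    return out


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path, kind: Optional[str] = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"motif_factor": str, "motif_strand": str})
    except Exception as exc:  # pragma: no cover - message formatting
        raise FormatError(f"{path}: could not parse TSV ({exc})") from exc
    if kind is not None:
        required = SCHEMAS.get(kind)
        if required is None:
            raise ValueError(f"unknown table kind {kind!r}")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing} for {kind} table")
    for col in ("motif_factor", "motif_strand"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def write_molecules(records: pd.DataFrame, path, umi_length: Optional[int] = None) -> None:
    """Write molecule records with UMIs rendered as ACGT strings."""
    out = records.copy()
    if pd.api.types.is_integer_dtype(out["umi"]):
        if umi_length is None:
            raise ValueError("umi_length is required to encode integer UMI codes")
        out["umi"] = encode_umis(out["umi"].to_numpy(), umi_length)
    write_table(out, path)


def read_bed(path) -> pd.DataFrame:
    """Read a BED annotation (0-based half-open) into 1-based inclusive coords."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least chrom/start/end")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    out = df.copy()
    out["pos_start"] = df["start"].astype(int) + 1  # 1-based inclusive
    out["pos_end"] = df["end"].astype(int)
    return out


def write_oligo_fasta(designs: pd.DataFrame, path, seed: int = 0) -> None:
    """Emit a synthetic 230-mer oligo FASTA: 15 bp constant adapter flanks
    around 200 bp of random regulatory sequence with the SNP allele at the
    center.  Two records per SNP-orientation (one per allele); sequence
    content is placeholder (no motif/GC realism)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    left_adapter = "ACACTCTTTCCCTAC"[:15]
    right_adapter = "GTGACTGGAGTTCAG"[:15]
    records = []
    for row in designs.itertuples(index=False):
        backbone = "".join(rng.choice(_UMI_BASES, 200))
        center = 100
        for allele_label, base in (("ref", row.ref_allele), ("alt", row.alt_allele)):
            seq = backbone[:center] + str(base) + backbone[center + 1:]
            full = left_adapter + seq + right_adapter
            records.append(
                SeqRecord(
                    Seq(full),
                    id=f"{row.snp_id}|{allele_label}",
                    description=f"category={row.category}",
                )
            )
    SeqIO.write(records, str(path), "fasta")


def qq_table(pvalues, labels=None) -> pd.DataFrame:
    """Observed vs expected -log10 p-value quantiles, optionally stratified.

    Within each stratum, sorted p-values are matched to uniform expected
    quantiles (i - 1/2)/m.  The table backs the QQ plot and is what tests
    assert on.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if labels is None:
        labels = np.repeat("all", p.size)
    labels = np.asarray(labels)
    frames = []
    for lab in pd.unique(labels):
        ps = np.sort(p[labels == lab])
        m = ps.size
        expected = (np.arange(1, m + 1) - 0.5) / m
        frames.append(
            pd.DataFrame(
                {
                    "stratum": lab,
                    "expected_neglog10": -np.log10(expected),
                    "observed_neglog10": -np.log10(np.clip(ps, 1e-300, 1.0)),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def qq_plot(table: pd.DataFrame, path) -> None:
    """Render a QQ plot from a :func:`qq_table` table to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for lab, chunk in table.groupby("stratum", observed=True):
        ax.scatter(
            chunk["expected_neglog10"], chunk["observed_neglog10"], s=6, label=str(lab)
        )
    lim = float(table[["expected_neglog10", "observed_neglog10"]].max().max())
    ax.plot([0, lim], [0, lim], color="grey", lw=1, ls="--")
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    """Load a YAML pipeline/simulation config into a plain dict."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return data


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
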